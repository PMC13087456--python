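"""Reference-based cell-composition estimation.

Per-sample cell-type fractions are the solution of a constrained least
squares problem: minimize ||y - R w||^2 subject to w >= 0 and sum(w) = 1.
The solver is a penalized non-negative least squares initialization followed
by an SLSQP polish of the exact quadratic program and a final exact simplex
projection (clipping float-level negatives and renormalizing). The same
solver serves methylation beta matrices and expression signature matrices —
only the reference differs.

Group comparison of estimated fractions uses a per-cell-type two-sided Welch
t-test by default (Mann-Whitney available), with raw-threshold significance
tiers and an optional BH column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intron_retention import bh_adjust

__all__ = ["estimate_fractions", "compare_fractions", "solve_simplex_lsq"]


def solve_simplex_lsq(reference: np.ndarray, y: np.ndarray, sum_to_one: bool = True) -> np.ndarray:
    """Solve min ||y - R w||^2 s.t. w >= 0 (and sum w = 1 when requested)."""
    n_types = reference.shape[1]
    if sum_to_one:
        lam = 10.0 * max(1.0, float(np.abs(reference).max())) * reference.shape[0]
        aug_r = np.vstack([reference, lam * np.ones((1, n_types))])
        aug_y = np.concatenate([y, [lam]])
        w0, _ = optimize.nnls(aug_r, aug_y)
        total = w0.sum()
        w0 = w0 / total if total > 0 else np.full(n_types, 1.0 / n_types)

        rtr = reference.T @ reference
        rty = reference.T @ y

        def objective(w: np.ndarray) -> float:
            return float(w @ rtr @ w - 2.0 * rty @ w)

        def grad(w: np.ndarray) -> np.ndarray:
            return 2.0 * (rtr @ w - rty)

        res = optimize.minimize(
            objective,
            w0,
            jac=grad,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * n_types,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-16},
        )
        w = res.x if res.success else w0
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        return w
    w, _ = optimize.nnls(reference, y)
    return w


@dataclass
class MixtureEstimate:
    """Estimated per-sample cell-type fractions."""

    weights: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series  # per sample ||y - R w||


def estimate_fractions(
    samples: pd.DataFrame,
    reference: pd.DataFrame,
    sum_to_one: bool = True,
) -> MixtureEstimate:
    """Estimate cell-type fractions for every sample column.

    ``samples`` is features × samples, ``reference`` features × cell types;
    the feature sets are intersected (order-independent) and must leave at
    least as many features as cell types. A rank-deficient reference is an
    error naming the collinear columns.
    """
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least two cell types")
    if reference.columns.duplicated().any():
        raise ValueError("reference cell-type names must be unique")
    if reference.isna().any().any():
        raise ValueError("reference must have no missing entries")
    common = samples.index.intersection(reference.index)
    if len(common) < reference.shape[1]:
        raise ValueError(
            f"only {len(common)} shared features for {reference.shape[1]} cell types"
        )
    common = sorted(common)  # permutation-invariant feature order
    ref = reference.loc[common]
    r = ref.to_numpy(dtype=float)
    if np.linalg.matrix_rank(r) < r.shape[1]:
        cor = np.corrcoef(r.T)
        pairs = [
            (ref.columns[i], ref.columns[j])
            for i in range(r.shape[1])
            for j in range(i + 1, r.shape[1])
            if abs(cor[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient reference; collinear columns: {pairs}")

    weights, residuals = {}, {}
    for s in samples.columns:
        y = samples.loc[common, s].to_numpy(dtype=float)
        w = solve_simplex_lsq(r, y, sum_to_one=sum_to_one)
        weights[s] = w
        residuals[s] = float(np.linalg.norm(y - r @ w))
    wdf = pd.DataFrame(weights, index=ref.columns).T
    return MixtureEstimate(weights=wdf, residual_norm=pd.Series(residuals, name="residual_norm"))


def compare_fractions(
    estimates: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    test: Literal["welch_t", "mann_whitney"] = "welch_t",
    bh: bool = False,
) -> pd.DataFrame:
    """Per-cell-type two-sided comparison of estimated fractions.

    ``estimates`` is samples × cell types. Significance tiers follow raw
    thresholds ('*' p<0.05, '**' p<0.01); set ``bh=True`` to add an
    ``adjusted_p`` column (tiers stay raw — the correction option is exposed,
    not imposed). Groups need at least two samples each.
    """
    case_samples, control_samples = list(case_samples), list(control_samples)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for ct in estimates.columns:
        x = estimates.loc[case_samples, ct].to_numpy(dtype=float)
        y = estimates.loc[control_samples, ct].to_numpy(dtype=float)
        if test == "welch_t":
            if np.var(x) == 0 and np.var(y) == 0:
                statv, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
            else:
                res = stats.ttest_ind(x, y, equal_var=False)
                statv, p = float(res.statistic), float(res.pvalue)
        elif test == "mann_whitney":
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            statv, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        tier = "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append((ct, float(np.mean(x)), float(np.mean(y)), statv, p, tier))
    out = pd.DataFrame(
        rows, columns=["cell_type", "case_mean", "control_mean", "statistic", "p_value", "tier"]
    ).set_index("cell_type")
    if bh:
        out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
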