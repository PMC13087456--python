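"""Intron-retention quantification and differential testing.

Per-intron retention is summarized as PSI = retained / (retained + spliced)
(orientation flag available: the alternative reports the spliced fraction).
Case-vs-control testing uses a two-sided Welch t-test on logit-transformed
PSI with a coverage-aware pseudocount, Benjamini-Hochberg adjustment across
tested introns, and a one-directional effect-size gate (retention increase).
Gene-level calls and the two-cohort / known-U12 contingency classification
mirror the downstream Venn-style analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_psi",
    "test_differential_ir",
    "call_gene_level",
    "classify_cohort_overlap",
    "bh_adjust",
    "GeneIRCategory",
    "plot_psi_heatmap",
]


@dataclass
class PSIMatrix:
    """Per-intron per-sample retention fractions with coverage.

    ``psi`` is NaN exactly where coverage < the min_coverage used to build it.
    """

    psi: pd.DataFrame  # introns x samples, NaN = insufficient coverage
    coverage: pd.DataFrame  # introns x samples, retained + spliced
    min_coverage: int


def compute_psi(
    retained: pd.DataFrame,
    spliced: pd.DataFrame,
    min_coverage: int = 10,
    orientation: Literal["retention", "splicing"] = "retention",
) -> PSIMatrix:
    """Compute PSI from paired count matrices (introns × samples).

    PSI is retained/(retained+spliced) under the default retention
    orientation, or spliced/(retained+spliced) under ``splicing``. Entries
    with coverage below ``min_coverage`` are missing (NaN).
    """
    if not retained.index.equals(spliced.index) or not retained.columns.equals(spliced.columns):
        raise ValueError("retained and spliced matrices must share both axes")
    if (retained.to_numpy() < 0).any() or (spliced.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    coverage = retained + spliced
    num = retained if orientation == "retention" else spliced
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = num / coverage
    psi = psi.where(coverage >= min_coverage)
    return PSIMatrix(psi=psi, coverage=coverage, min_coverage=min_coverage)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _logit_psi(retained: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Logit of PSI with pseudocount 0.5/(coverage+1) keeping values finite."""
    p = (retained + 0.5) / (coverage + 1.0)
    return np.log(p / (1.0 - p))


def test_differential_ir(
    psi: PSIMatrix,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    alpha: float = 0.05,
    min_effect: float = 0.05,
    direction: Literal["increase", "two_sided"] = "increase",
) -> pd.DataFrame:
    """Per-intron differential retention, cases vs controls.

    Returns a DataFrame indexed by intron id with columns
    ``delta_psi, p_value, adjusted_p, tested, significant``. Introns with
    fewer than two non-missing PSI values in either group are reported
    untested (NaN p). Significance requires BH-adjusted p < alpha AND a
    retention increase of at least ``min_effect`` (or |delta| under
    ``two_sided``).
    """
    case_samples, control_samples = list(case_samples), list(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("both groups must be non-empty")
    for s in case_samples + control_samples:
        if s not in psi.psi.columns:
            raise ValueError(f"sample {s!r} not in PSI matrix")

    psi_c = psi.psi[case_samples].to_numpy(dtype=float)
    psi_k = psi.psi[control_samples].to_numpy(dtype=float)
    cov_c = psi.coverage[case_samples].to_numpy(dtype=float)
    cov_k = psi.coverage[control_samples].to_numpy(dtype=float)

    ok_c, ok_k = ~np.isnan(psi_c), ~np.isnan(psi_k)
    tested = (ok_c.sum(axis=1) >= 2) & (ok_k.sum(axis=1) >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(psi_c, axis=1) - np.nanmean(psi_k, axis=1)
        # logit with coverage-aware pseudocount; NaNs propagate and are omitted
        yc = np.where(ok_c, _logit_psi(psi_c * cov_c, cov_c), np.nan)
        yk = np.where(ok_k, _logit_psi(psi_k * cov_k, cov_k), np.nan)
        p_val = stats.ttest_ind(yc, yk, axis=1, equal_var=False, nan_policy="omit").pvalue
        p_val = np.asarray(p_val, dtype=float)
        # degenerate rows (both groups constant): identical means -> 1, else 0
        var_c, var_k = np.nanvar(yc, axis=1), np.nanvar(yk, axis=1)
        degenerate = tested & (var_c == 0) & (var_k == 0)
        p_val[degenerate] = np.where(
            np.nanmean(yc, axis=1)[degenerate] == np.nanmean(yk, axis=1)[degenerate], 1.0, 0.0
        )
    p_val[~tested] = np.nan

    out = pd.DataFrame(
        {"delta_psi": delta, "p_value": p_val, "tested": tested}, index=psi.psi.index
    )
    out.index.name = "intron_id"
    out["adjusted_p"] = np.nan
    mask = out["tested"].to_numpy()
    if mask.any():
        out.loc[mask, "adjusted_p"] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    effect_ok = (
        out["delta_psi"] >= min_effect
        if direction == "increase"
        else out["delta_psi"].abs() >= min_effect
    )
    out["significant"] = mask & (out["adjusted_p"] < alpha) & effect_ok
    return out


def call_gene_level(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: Literal["any", "majority", "fisher"] = "any",
    alpha: float = 0.05,
) -> set[str]:
    """Aggregate intron-level results to a significant gene set.

    Rules (the downstream analysis did not state one; ``any`` is the default):

    - ``any``: >= 1 significant intron;
    - ``majority``: more than half of the gene's tested introns significant;
    - ``fisher``: Fisher-combined intron p-values, BH across genes at alpha,
      with the direction gate requiring at least one intron passing min_effect
      (approximated here by requiring >= 1 intron with positive delta).
    """
    unknown = [i for i in results.index if i not in annotation.index]
    if unknown:
        raise ValueError(f"introns missing from annotation: {unknown[:5]}")
    gene_of = annotation["gene"]
    df = results.join(gene_of)

    if rule == "any":
        return set(df.loc[df["significant"], "gene"])
    if rule == "majority":
        tested = df[df["tested"]]
        frac = tested.groupby("gene")["significant"].mean()
        return set(frac.index[frac > 0.5])
    if rule == "fisher":
        tested = df[df["tested"]]
        genes, combined = [], []
        for gene, grp in tested.groupby("gene"):
            stat_p = stats.combine_pvalues(grp["p_value"].to_numpy(), method="fisher").pvalue
            if (grp["delta_psi"] > 0).any():
                genes.append(gene)
                combined.append(stat_p)
        if not genes:
            return set()
        adj = bh_adjust(combined)
        return {g for g, a in zip(genes, adj) if a < alpha}
    raise ValueError(f"unknown gene rule {rule!r}")


@dataclass(frozen=True)
class GeneIRCategory:
    gene: str
    significant_in: frozenset[str]  # subset of {"A", "B"}
    known_u12: bool

    @property
    def novel_candidate(self) -> bool:
        return bool(self.significant_in) and not self.known_u12


def classify_cohort_overlap(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    annotation: pd.DataFrame,
) -> tuple[list[GeneIRCategory], dict[str, int]]:
    """Cross two cohorts' significant gene sets against the known-U12 annotation.

    A gene counts as known U12 when any of its annotated introns carries class
    ``U12``; hidden U12 genes (class ``unknown``) therefore land in the novel
    categories, mirroring the database-absent slice of the Venn analysis.

    Returns per-gene categories plus the full 2x2x2 contingency, keyed
    ``A<0|1>_B<0|1>_U12<0|1>`` (genes significant nowhere are counted from the
    annotation universe).
    """
    genes_a, genes_b = set(genes_a), set(genes_b)
    known_u12 = set(annotation.loc[annotation["spliceosome_class"] == "U12", "gene"])
    universe = set(annotation["gene"]) | genes_a | genes_b
    missing = (genes_a | genes_b) - set(annotation["gene"])
    if missing:
        raise ValueError(f"significant genes missing from annotation: {sorted(missing)[:5]}")

    categories = []
    counts = {f"A{a}_B{b}_U12{u}": 0 for a in (0, 1) for b in (0, 1) for u in (0, 1)}
    for gene in sorted(universe):
        in_a, in_b, known = gene in genes_a, gene in genes_b, gene in known_u12
        counts[f"A{int(in_a)}_B{int(in_b)}_U12{int(known)}"] += 1
        sig = frozenset(c for c, flag in (("A", in_a), ("B", in_b)) if flag)
        if sig:
            categories.append(GeneIRCategory(gene=gene, significant_in=sig, known_u12=known))
    counts["known_u12_significant"] = sum(
        1 for c in categories if c.known_u12
    )
    counts["novel_in_both"] = sum(
        1 for c in categories if c.novel_candidate and c.significant_in == frozenset({"A", "B"})
    )
    return categories, counts


def plot_psi_heatmap(psi: pd.DataFrame, path: str, top_n: int = 25) -> None:
    """Plain clustered-matrix plot of the most variable introns.

    Rows and columns are ordered by complete-linkage hierarchical clustering
    on Euclidean distance; missing PSI entries are imputed with the row mean
    for ordering/plotting only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    filled = psi.apply(lambda r: r.fillna(r.mean()), axis=1).dropna(how="any")
    top = filled.loc[filled.var(axis=1).sort_values(ascending=False).index[:top_n]]
    if len(top) >= 3:
        row_order = hierarchy.leaves_list(hierarchy.linkage(pdist(top.to_numpy()), "complete"))
        col_order = hierarchy.leaves_list(hierarchy.linkage(pdist(top.to_numpy().T), "complete"))
        top = top.iloc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(top.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(top.shape[1]), top.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(top.shape[0]), top.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="PSI (retention)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
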