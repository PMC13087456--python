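"""Weighted co-expression network analysis.

Correlation-power adjacency (signed by default), topological overlap,
average-linkage module detection with a static tree cut, module eigengenes,
Bonferroni-corrected module-trait correlation, and hypergeometric gene-set
enrichment against user-supplied GMT sets.

The static cut is a deliberate simplification of the canonical dynamic
hybrid tree cut: it is deterministic and adequate for well-separated modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intron_retention import bh_adjust

__all__ = [
    "NetworkConfig",
    "pick_soft_threshold",
    "compute_adjacency",
    "compute_tom",
    "tom_from_adjacency",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "enrich_modules",
]

# color-style arbitrary module names, assigned by decreasing module size
_MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
UNASSIGNED = "unassigned"


@dataclass
class NetworkConfig:
    powers: Sequence[int] = tuple(range(1, 21))
    signed: bool = True
    scale_free_target_r2: float = 0.8
    cut_height: float = 0.25
    min_module_size: int = 30

    def __post_init__(self) -> None:
        if len(self.powers) == 0:
            raise ValueError("powers must be non-empty")
        if any(p < 1 for p in self.powers):
            raise ValueError("powers must be positive integers")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must be in (0, 1]")


def _drop_zero_variance(expr: pd.DataFrame) -> pd.DataFrame:
    keep = expr.std(axis=1, ddof=0) > 0
    out = expr.loc[keep]
    if out.empty:
        raise ValueError("all genes have zero variance")
    return out


def compute_adjacency(expr: pd.DataFrame, power: int, signed: bool = True) -> np.ndarray:
    """Correlation-power adjacency over genes (rows of ``expr``), zero diagonal.

    Signed: ((1 + cor)/2)^power; unsigned: |cor|^power.
    """
    cor = np.corrcoef(expr.to_numpy())
    if not np.isfinite(cor).all():
        bad = expr.index[~np.isfinite(cor).all(axis=1)].tolist()
        raise ValueError(f"non-finite correlations involving genes: {bad[:5]}")
    adj = ((1.0 + cor) / 2.0) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


@dataclass
class SoftThresholdResult:
    power: int
    r2_by_power: dict[int, float] = field(default_factory=dict)
    warning: bool = False  # True when no power met the target R^2


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-frequency vs log-binned-connectivity regression."""
    k = connectivity[connectivity > 0]
    if k.size < 4 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logs = []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        logs.append((math.log10(members.mean()), math.log10(members.size / k.size)))
    if len(logs) < 3:
        return 0.0
    x, y = np.array(logs).T
    if np.ptp(x) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pick_soft_threshold(expr: pd.DataFrame, config: NetworkConfig) -> SoftThresholdResult:
    """Choose the soft-threshold power by scale-free topology fit.

    Returns the smallest scanned power whose fit R^2 reaches the target; if
    none does, the power maximizing R^2 with ``warning=True``. Zero-variance
    genes are dropped before correlation.
    """
    expr = _drop_zero_variance(expr)
    if expr.shape[0] < 10 or expr.shape[1] < 4:
        raise ValueError("need >= 10 genes and >= 4 samples")
    r2s: dict[int, float] = {}
    for power in config.powers:
        adj = compute_adjacency(expr, power, config.signed)
        r2s[power] = _scale_free_r2(adj.sum(axis=1))
        if r2s[power] >= config.scale_free_target_r2:
            return SoftThresholdResult(power=power, r2_by_power=r2s, warning=False)
    best = max(r2s, key=lambda p: (r2s[p], -p))
    return SoftThresholdResult(power=best, r2_by_power=r2s, warning=True)


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1."""
    k = adj.sum(axis=1)
    shared = adj @ adj
    k_min = np.minimum.outer(k, k)
    tom = (shared + adj) / (k_min + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize against float jitter


def compute_tom(expr: pd.DataFrame, power: int, signed: bool = True) -> pd.DataFrame:
    """Topological overlap matrix of the correlation-power network.

    Symmetric with unit diagonal and entries in [0, 1]; see
    :func:`tom_from_adjacency` for the formula.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    adj = compute_adjacency(expr, power, signed)
    tom = tom_from_adjacency(adj)
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Assign genes to modules by average-linkage clustering of 1 - TOM.

    Static cut at ``config.cut_height``; clusters smaller than
    ``min_module_size`` become ``unassigned``. Module names are color-style
    labels assigned deterministically by decreasing size (ties broken by the
    smallest member's gene order).
    """
    t = tom.to_numpy()
    if t.shape[0] != t.shape[1] or not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("TOM must be square and symmetric")
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")

    genes = tom.index
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    kept = [idx for idx in clusters.values() if len(idx) >= config.min_module_size]
    kept.sort(key=lambda idx: (-len(idx), min(idx)))

    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    for rank, idx in enumerate(kept):
        name = _MODULE_COLORS[rank] if rank < len(_MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[idx] = name
    return labels


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Returns samples × modules. Each eigengene is sign-aligned so that its
    correlation with the module's mean expression profile is positive. A
    single-gene module's eigengene is that standardized gene.
    """
    modules = [m for m in assignment.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no modules to summarize")
    eig = {}
    for m in sorted(modules):
        genes = assignment.index[assignment == m]
        x = expr.loc[genes].to_numpy(dtype=float)  # genes x samples
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        if z.shape[0] == 1:
            e = z[0]
        else:
            # first left singular vector of samples x genes
            u, s, _ = np.linalg.svd(z.T, full_matrices=False)
            e = u[:, 0] * s[0] / np.sqrt(max(z.shape[0] - 1, 1))
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[m] = e
    return pd.DataFrame(eig, index=expr.columns)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of every (module eigengene, trait) pair.

    Bonferroni multiplicity is modules × traits (the displayed grid). Constant
    traits yield an undefined (NaN, flagged) entry rather than an error.
    Returns a tidy DataFrame with one row per pair.
    """
    if not eigengenes.index.equals(traits.index):
        traits = traits.loc[eigengenes.index]
    n_pairs = eigengenes.shape[1] * traits.shape[1]
    rows = []
    for module in eigengenes.columns:
        for trait in traits.columns:
            x = eigengenes[module].to_numpy(dtype=float)
            y = traits[trait].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                rows.append((module, trait, np.nan, np.nan, np.nan, False, True))
                continue
            r, p = stats.pearsonr(x, y)
            adj = min(1.0, p * n_pairs)
            rows.append((module, trait, r, p, adj, adj < alpha, False))
    return pd.DataFrame(
        rows,
        columns=["module", "trait", "r", "p_value", "bonferroni_p", "significant", "undefined"],
    )


def enrich_modules(
    assignment: pd.Series,
    gene_sets: dict[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each module in each gene set.

    Background is every profiled gene (assigned or not). p = P(X >= overlap);
    BH adjustment is applied across gene sets within each module. Empty gene
    sets (after background intersection) are skipped.
    """
    background = set(assignment.index)
    n_bg = len(background)
    rows = []
    for module in sorted(m for m in assignment.unique() if m != UNASSIGNED):
        members = set(assignment.index[assignment == module])
        module_rows = []
        for name in sorted(gene_sets):
            in_bg = set(gene_sets[name]) & background
            if not in_bg:
                continue
            overlap = len(members & in_bg)
            # P(X >= overlap) for X ~ Hypergeom(N=n_bg, K=|set|, n=|module|)
            p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), len(members)))
            module_rows.append((module, name, overlap, len(in_bg), len(members), p))
        if module_rows:
            adj = bh_adjust([r[-1] for r in module_rows])
            rows.extend((*r, float(a)) for r, a in zip(module_rows, adj))
    return pd.DataFrame(
        rows,
        columns=["module", "gene_set", "overlap", "set_size", "module_size", "p_value", "adjusted_p"],
    )
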