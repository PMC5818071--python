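"""Unsigned weighted coexpression network construction and module detection.

The network is the standard WGCNA construction: a robust correlation matrix
(biweight midcorrelation), an unsigned soft-threshold adjacency
``a_ij = |cor_ij|**beta`` with the power chosen to maximise scale-free
topology fit, topological overlap similarity, and average-linkage
hierarchical clustering of ``1 - TOM`` into modules.  Genes left outside any
module of at least ``min_module_size`` members are assigned to the reserved
"grey" label; surviving modules are named by colour in decreasing size
order so reports read like standard WGCNA output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "bicor",
    "correlation_matrix",
    "adjacency",
    "scale_free_fit",
    "SoftThresholdResult",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "intramodular_connectivity",
    "MODULE_COLORS",
]

#: WGCNA's colour sequence, assigned to modules by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"
GOLD = "gold"

_BICOR_TUNING = 9.0  # Tukey biweight tuning constant, in units of MAD


def _biweight_transform(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight-centred vectors plus a zero-MAD (Pearson fallback) flag.

    Rows whose median absolute deviation is zero cannot be biweighted; they
    fall back to plain mean-centring (Pearson behaviour), which keeps the
    correlation defined whenever the row is non-constant.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (values - med) / (_BICOR_TUNING * mad)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    w[~np.isfinite(w)] = 0.0
    centred = (values - med) * w
    if fallback.any():
        centred[fallback] = values[fallback] - values[fallback].mean(axis=1, keepdims=True)
    return centred, fallback


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Observations are weighted by ``w = (1-u^2)^2`` for ``|u| < 1`` with
    ``u = (x - median) / (9 * MAD)``; the correlation is the cosine of the
    weighted centred vectors.  A zero-MAD vector triggers a Pearson fallback
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional vectors of equal length")
    if len(x) < 4:
        raise ValueError("bicor requires at least 4 observations")
    centred, fallback = _biweight_transform(np.vstack([x, y]))
    if fallback.any():
        # a zero-MAD vector makes the biweight undefined; the pair drops to
        # plain Pearson so the result stays a recognised correlation
        warnings.warn("zero MAD: falling back to Pearson correlation", stacklevel=2)
        stacked = np.vstack([x, y])
        centred = stacked - stacked.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    if (norms == 0).any():
        raise ValueError("constant vector: correlation undefined")
    return float(np.clip(centred[0] @ centred[1] / (norms[0] * norms[1]), -1.0, 1.0))


def correlation_matrix(expr: pd.DataFrame, method: str = "bicor") -> pd.DataFrame:
    """All-pairs gene correlation matrix (genes x genes), symmetric with unit diagonal."""
    if expr.shape[1] < 4:
        raise ValueError("correlation matrix requires at least 4 samples")
    values = expr.to_numpy(dtype=float)
    if method == "bicor":
        centred, fallback = _biweight_transform(values)
        if fallback.any():
            warnings.warn(
                f"{int(fallback.sum())} genes with zero MAD fell back to Pearson",
                stacklevel=2,
            )
    elif method == "pearson":
        centred = values - values.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    constant = norms[:, 0] == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes: correlations set to 0", stacklevel=2)
        norms[constant] = 1.0
    unit = centred / norms
    cor = np.clip(unit @ unit.T, -1.0, 1.0)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = (cor + cor.T) / 2.0
    out = pd.DataFrame(cor, index=expr.index, columns=expr.index)
    out.attrs["method"] = method
    return out


def adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``a_ij = |cor_ij|**beta``.

    The diagonal is stored as zero so connectivities are plain row sums.
    """
    if beta < 1:
        raise ValueError("soft-threshold power beta must be >= 1")
    adj = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(adj, 0.0)
    out = pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    out.attrs["beta"] = beta
    return out


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit index of a connectivity vector.

    Genes are binned by connectivity into ``n_bins`` equal-width bins;
    log10(bin frequency) is regressed on log10(mean bin connectivity) over
    the non-empty bins.  Returns ``(fit_index, slope)`` where the fit index
    is the regression R-squared if the slope is negative (a power-law decay)
    and 0 otherwise.
    """
    k = np.asarray(k, dtype=float)
    if k.min() == k.max():
        warnings.warn("constant connectivity: scale-free fit undefined", stacklevel=2)
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins) / len(k)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    keep = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
    if keep.sum() < 3:
        warnings.warn("fewer than 3 non-empty bins: scale-free fit undefined", stacklevel=2)
        return 0.0, 0.0
    x = np.log10(mean_k[keep])
    y = np.log10(freq[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    fit = r2 if slope < 0 else 0.0
    return float(fit), float(slope)


@dataclass
class SoftThresholdResult:
    beta: float
    fit_index: float
    slope: float
    reached_target: bool
    table: pd.DataFrame  # per-beta fit indices and slopes


def pick_soft_threshold(
    expr: pd.DataFrame,
    beta_grid: tuple[float, ...] | None = None,
    target_r2: float = 0.8,
    method: str = "bicor",
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Smallest power on the grid whose scale-free fit reaches ``target_r2``.

    If no power reaches the target the maximising power is returned with
    ``reached_target=False``.
    """
    if expr.shape[0] < 50:
        raise ValueError("soft-threshold selection needs at least 50 genes")
    grid = tuple(beta_grid) if beta_grid else tuple(range(1, 21))
    if not grid:
        raise ValueError("beta grid must be non-empty")
    cor_abs = np.abs(correlation_matrix(expr, method=method).to_numpy())
    np.fill_diagonal(cor_abs, 0.0)
    rows = []
    for beta in grid:
        k = (cor_abs**beta).sum(axis=1)
        fit, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"beta": beta, "fit_index": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table["fit_index"] >= target_r2]
    if len(reaching):
        row = reaching.iloc[0]
        reached = True
    else:
        row = table.loc[table["fit_index"].idxmax()]
        reached = False
        warnings.warn(
            f"no power on the grid reaches fit index {target_r2}; "
            f"using beta={row['beta']} (fit {row['fit_index']:.3f})",
            stacklevel=2,
        )
    return SoftThresholdResult(
        beta=float(row["beta"]),
        fit_index=float(row["fit_index"]),
        slope=float(row["slope"]),
        reached_target=reached,
        table=table,
    )


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the sum over shared neighbours ``u != i, j`` and ``TOM_ii = 1``.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is zero, so [i,j] = sum over u != i,j
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (min_k + 1.0 - a)
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 50,
    cut_height_fraction: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of ``1 - TOM`` into colour-labelled modules.

    The dendrogram is cut with a static height cut (fully specified and
    reproducible, in place of WGCNA's dynamic tree cut).  By default the cut
    height is chosen by scanning merge-height quantiles and keeping the
    lowest cut that maximises the number of clusters of at least
    ``min_module_size`` members; on the strongly right-skewed dendrograms
    high soft-threshold powers produce, a fixed fraction of the height range
    either dissolves or fuses the modules, while the scan is scale-free.
    Passing ``cut_height_fraction`` forces the classic fixed cut at
    ``min + fraction * (max - min)`` of the merge-height range.

    Clusters smaller than ``min_module_size`` fall into "grey"; the rest get
    colour names by decreasing size.  Returns a gene -> label Series
    covering every gene.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = tom.index
    n = len(genes)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count: all genes grey", stacklevel=2)
        return pd.Series(GREY, index=genes, name="module")
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    tree = linkage(squareform(dissim, checks=False), method="average")
    heights = tree[:, 2]
    if cut_height_fraction is not None:
        cut = heights.min() + cut_height_fraction * (heights.max() - heights.min())
    else:
        cut = _scan_cut_height(tree, min_module_size)
    raw = fcluster(tree, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    surviving = sizes[sizes >= min_module_size].index
    # colour assignment by decreasing size, ties by smallest member gene id
    ordered = sorted(
        surviving,
        key=lambda c: (-int(sizes[c]), min(genes[labels.to_numpy() == c])),
    )
    color_of = {}
    for rank, cluster in enumerate(ordered):
        color_of[cluster] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    out = labels.map(lambda c: color_of.get(c, GREY))
    out.name = "module"
    return out


def _scan_cut_height(tree: np.ndarray, min_module_size: int) -> float:
    """Static cut chosen by cluster-count persistence across heights.

    Candidate cuts are quantiles of the merge heights (the upper half of the
    distribution, where cluster structure resolves), so the scan adapts to
    arbitrarily skewed dendrograms without any absolute height convention.
    For each candidate the number of clusters of at least
    ``min_module_size`` members is recorded; the modal (most persistent)
    non-zero count is taken as the true module count, and the lowest cut
    achieving it is returned -- persistence guards against transient
    over-merged partitions near the dendrogram top, and the lowest cut gives
    the purest clusters.
    """
    heights = np.sort(np.unique(tree[:, 2]))
    if len(heights) < 2:
        return float(heights[-1])
    quantile_cands = np.quantile(heights, np.linspace(0.5, 0.999, 100))
    # midpoints of the widest inter-merge gaps cover sparse height regions
    # that quantiles of a dense merge distribution would miss
    gaps = np.diff(heights)
    top_gaps = np.argsort(gaps)[::-1][:50]
    gap_cands = (heights[top_gaps] + heights[top_gaps + 1]) / 2.0
    candidates = np.unique(np.concatenate([quantile_cands, gap_cands]))

    counts = np.empty(len(candidates), dtype=int)
    for i, cut in enumerate(candidates):
        sizes = np.bincount(fcluster(tree, t=cut, criterion="distance"))
        counts[i] = int((sizes >= min_module_size).sum())
    if (counts <= 0).all():
        return float(heights[-1])

    # weight each count by how persistently it holds, measured both as the
    # share of quantile candidates (merge-density scale) and as the share of
    # the height range covered by the widest gaps (absolute-height scale);
    # a single scale fails on either very skewed or very discrete dendrograms
    quantile_counts = counts[np.isin(candidates, quantile_cands)]
    height_span = heights[-1] - heights[0]
    weight: dict[int, float] = {}
    for c in np.unique(counts[counts > 0]):
        q_share = float((quantile_counts == c).sum()) / max(len(quantile_counts), 1)
        gap_share = 0.0
        for g in top_gaps:
            mid = (heights[g] + heights[g + 1]) / 2.0
            idx = np.searchsorted(candidates, mid)
            if idx < len(candidates) and counts[idx] == c:
                gap_share += gaps[g] / height_span
        weight[c] = 0.5 * q_share + 0.5 * gap_share
    best_count = max(weight, key=lambda c: (weight[c], c))
    # place the cut in the widest height gap where that count holds -- the
    # most stable location; fall back to the lowest achieving candidate
    for g in top_gaps[np.argsort(gaps[top_gaps])[::-1]]:
        mid = (heights[g] + heights[g + 1]) / 2.0
        if counts[np.searchsorted(candidates, mid)] == best_count:
            return float(mid)
    return float(candidates[np.flatnonzero(counts == best_count)[0]])


def intramodular_connectivity(adj: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Per-gene total and within-module connectivity.

    ``kTotal_i`` is the row sum of the adjacency; ``kWithin_i`` sums only
    over co-members of gene i's module.  Grey genes get kWithin over grey
    co-members but are excluded from hub and ranking analyses downstream.
    """
    missing = adj.index.difference(assignment.index)
    if len(missing):
        raise ValueError(f"assignment lacks {len(missing)} genes present in the adjacency")
    labels = assignment.reindex(adj.index)
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    k_within = np.empty_like(k_total)
    codes, _ = pd.factorize(labels)
    for code in np.unique(codes):
        members = codes == code
        k_within[members] = a[np.ix_(members, members)].sum(axis=1)
    return pd.DataFrame(
        {"module": labels.to_numpy(), "kTotal": k_total, "kWithin": k_within},
        index=adj.index,
    )
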