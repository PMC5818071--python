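"""Raw intensities to analysis-ready matrix.

log2 transform, classic quantile normalisation, probe-to-gene collapsing by
arithmetic mean, and the top-N variance filter that restricts the network to
the most variable genes (5000 by default downstream).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "log2_transform",
    "quantile_normalize",
    "collapse_probes_mean",
    "filter_top_variable",
]


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; every value must be strictly positive."""
    values = expr.to_numpy(dtype=float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity at gene {expr.index[i]!r}, sample {expr.columns[j]!r}; "
            "log2 transform requires positive values"
        )
    out = pd.DataFrame(np.log2(values), index=expr.index, columns=expr.columns)
    out.attrs["stage"] = "log2"
    return out


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalisation across samples (columns).

    Each column's rank-r value is replaced by the cross-column mean of the
    rank-r order statistics; ties within a column receive the mean of their
    tied rank-means.  After the transform every column holds the identical
    multiset of values (up to tie handling).
    """
    if expr.isna().to_numpy().any():
        raise ValueError("quantile normalisation requires a complete matrix")
    if expr.shape[1] < 2:
        warnings.warn("single sample: quantile normalisation is a no-op", stacklevel=2)
        out = expr.copy()
        out.attrs["stage"] = "normalized"
        return out
    values = expr.to_numpy(dtype=float)
    order = np.sort(values, axis=0)
    rank_means = order.mean(axis=1)  # mean of each order statistic across columns
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        assigned = np.empty_like(col)
        assigned[np.argsort(col, kind="stable")] = rank_means
        # ties within a column receive the mean of their tied rank-means
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    result = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    result.attrs["stage"] = "normalized"
    return result


def collapse_probes_mean(expr: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """One row per gene = arithmetic mean of its probe rows.

    Probes missing from the mapping are dropped with a warning.  Gene order
    of the result is lexicographic for determinism.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = expr.index.to_series().map(probe_to_gene)
    unmapped = mapped.isna()
    if unmapped.any():
        warnings.warn(
            f"dropping {int(unmapped.sum())} probes absent from the probe map", stacklevel=2
        )
    kept = expr.loc[~unmapped.to_numpy()]
    genes = mapped.dropna()
    collapsed = kept.groupby(genes.to_numpy()).mean()
    collapsed = collapsed.sort_index()
    collapsed.index.name = "gene_id"
    collapsed.attrs["stage"] = expr.attrs.get("stage", "raw")
    return collapsed


def filter_top_variable(expr: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the ``n`` genes with largest sample variance.

    Ties are broken lexicographically by gene id so the selection is
    deterministic.  If fewer than ``n`` genes exist, all are kept with a
    warning.
    """
    if n <= 0:
        raise ValueError("n must be a positive count")
    if expr.shape[0] <= n:
        if expr.shape[0] < n:
            warnings.warn(
                f"requested top {n} genes but only {expr.shape[0]} available; keeping all",
                stacklevel=2,
            )
        out = expr.copy()
        out.attrs["stage"] = "filtered"
        return out
    variances = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-variances[g], g))
    out = expr.loc[order[:n]]
    out.attrs["stage"] = "filtered"
    return out
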