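"""Module eigengenes, membership, and gene/module--trait statistics.

The module eigengene (ME) is the first principal component of the module's
standardised expression across samples -- a one-vector-per-sample summary.
Gene significance (GS) is the correlation between a gene's expression and a
sample trait; module significance is the corresponding eigengene--trait
correlation.  Reporting thresholds follow the pipeline defaults: GS p <= 0.05
for genes and p <= 0.1 for modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.network import GREY

__all__ = [
    "module_eigengene",
    "module_membership_kme",
    "gene_significance",
    "module_trait_matrix",
    "top_hubs",
    "gs_kwithin_scatter",
]


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def _cor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t distribution, n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def module_eigengene(
    expr: pd.DataFrame,
    assignment: pd.Series,
    include_grey: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module, computed on standardised genes.

    Returns ``(eigengenes, variance_explained)``: eigengenes as a
    modules x samples frame with unit-norm rows, each sign-oriented so the
    mean correlation with its member genes is positive.
    """
    labels = assignment.reindex(expr.index)
    modules = [m for m in labels.dropna().unique() if include_grey or m != GREY]
    if not modules:
        raise ValueError("no modules to summarise")
    rows, varexp = {}, {}
    for module in modules:
        sub = expr.loc[labels == module].to_numpy(dtype=float)
        z = _standardize(sub)
        if sub.shape[0] == 1:
            me = z[0] / np.linalg.norm(z[0])
            varexp[module] = 1.0
        else:
            _, s, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
            varexp[module] = float(s[0] ** 2 / (s**2).sum())
        member_cors = _row_cor(z, me)
        if member_cors.mean() < 0:
            me = -me
        rows[module] = me
    eigengenes = pd.DataFrame(rows, index=expr.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(varexp, name="variance_explained")


def _row_cor(rows: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix row with a vector."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vector - vector.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    denom[denom == 0] = np.inf
    return np.clip(rc @ vc / denom, -1.0, 1.0)


def module_membership_kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME(i, m) = Pearson correlation between gene i and module eigengene m."""
    values = expr.to_numpy(dtype=float)
    out = {}
    for module in eigengenes.index:
        out[module] = _row_cor(values, eigengenes.loc[module].to_numpy(dtype=float))
    kme = pd.DataFrame(out, index=expr.index)
    kme.columns.name = "module"
    return kme


def gene_significance(expr: pd.DataFrame, trait: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-gene correlation with a sample trait plus its p-value.

    Binary traits are encoded 0/1 before correlating; p-values come from the
    t distribution with n-2 degrees of freedom.
    """
    trait = np.asarray(pd.Series(trait).astype(float))
    if len(trait) != expr.shape[1]:
        raise ValueError("trait must align with the sample columns")
    if np.std(trait) == 0:
        raise ValueError("constant trait: gene significance undefined")
    gs = _row_cor(expr.to_numpy(dtype=float), trait)
    return pd.DataFrame(
        {"GS": gs, "GS_p": _cor_pvalue(gs, expr.shape[1])}, index=expr.index
    )


def module_trait_matrix(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    p_threshold: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Module x trait correlations, p-values, and significance flags.

    Trait columns are numeric encodings (e.g. case indicator, one-vs-rest
    time-point indicators).  A module--trait pair is flagged significant at
    ``p <= p_threshold`` (0.1 by default).
    """
    if traits.shape[1] < 1:
        raise ValueError("at least one trait required")
    n = eigengenes.shape[1]
    cor = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    pval = cor.copy()
    me_values = eigengenes.to_numpy(dtype=float)
    for trait_name in traits.columns:
        t = traits[trait_name].astype(float).to_numpy()
        if np.std(t) == 0:
            raise ValueError(f"constant trait {trait_name!r}")
        r = _row_cor(me_values, t)
        cor[trait_name] = r
        pval[trait_name] = _cor_pvalue(r, n)
    return {"correlation": cor, "p_value": pval, "significant": pval <= p_threshold}


def top_hubs(stats_table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Per-module hub genes: the ``n`` largest kWithin, descending.

    Ties break by gene id.  Modules with fewer than ``n`` members return all
    members with ``short_module=True``.  Grey genes never appear.
    """
    if n <= 0:
        raise ValueError("hub count must be positive")
    frames = []
    for module, sub in stats_table[stats_table["module"] != GREY].groupby("module"):
        # largest kWithin first; ties resolved by gene id (the index)
        ordered = sub.iloc[np.lexsort((sub.index.to_numpy(), -sub["kWithin"].to_numpy()))]
        hubs = ordered.head(n).copy()
        hubs["hub_rank"] = np.arange(1, len(hubs) + 1)
        hubs["short_module"] = len(sub) < n
        frames.append(hubs)
    if not frames:
        return pd.DataFrame(columns=list(stats_table.columns) + ["hub_rank", "short_module"])
    return pd.concat(frames)


def gs_kwithin_scatter(
    stats_table: pd.DataFrame,
    gs_p_cutoff: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-module (kWithin, GS) table of genes passing the GS p cutoff.

    Returns the filtered table plus the per-module count of passing genes.
    """
    required = {"module", "kWithin", "GS", "GS_p"}
    if not required.issubset(stats_table.columns):
        raise ValueError(f"stats table needs columns {sorted(required)}")
    passing = stats_table[
        (stats_table["GS_p"] <= gs_p_cutoff) & (stats_table["module"] != GREY)
    ].copy()
    counts = passing.groupby("module").size()
    counts.name = "n_passing"
    return passing[["module", "kWithin", "GS", "GS_p"]], counts
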