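"""Paired control-vs-case network comparison.

Modules are detected in the reference (control) network and their labels
copied onto the same genes in the test (case) network, so "the same module"
can be interrogated in both conditions.  Two complementary analyses follow:

* **Connectivity rank change** -- genes are ranked by intramodular
  connectivity in each network (1 = most connected); ``delta_rank =
  rank_ref - rank_test`` is positive when a gene gains connectivity in the
  test condition.  Modules are ordered by their median member delta.
* **Module preservation (Zsummary)** -- for each reference module, a density
  statistic (mean within-module test adjacency) and a connectivity statistic
  (correlation of member kWithin between networks) are compared against the
  same statistics on random gene sets of equal size; the permutation Z
  scores average into Zsummary.  Zsummary < 2 means no preservation,
  2-10 weak-to-moderate, > 10 strong.  A "gold" module of random genes is
  reported alongside as a calibration baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexnet.network import (
    GOLD,
    GREY,
    adjacency,
    correlation_matrix,
    detect_modules,
    tom_similarity,
)

__all__ = [
    "PairedNetworks",
    "RankChangeResult",
    "PreservationResult",
    "build_paired_networks",
    "rank_connectivity",
    "rank_change",
    "preservation_zsummary",
    "classify_preservation",
]


@dataclass
class PairedNetworks:
    """Reference and test adjacency over an identical gene universe.

    Module labels are detected in the reference network and shared."""

    adjacency_ref: pd.DataFrame
    adjacency_test: pd.DataFrame
    assignment: pd.Series
    beta: float

    def __post_init__(self) -> None:
        if not self.adjacency_ref.index.equals(self.adjacency_test.index):
            raise ValueError("reference and test networks must share one gene universe")


@dataclass
class RankChangeResult:
    per_gene: pd.DataFrame  # rank_ref, rank_test, delta_rank, module
    per_module: pd.DataFrame  # median_delta, n_gain, n_loss, size, classification


@dataclass
class PreservationResult:
    per_module: pd.DataFrame  # size, density/connectivity obs + null moments, Z*, class
    n_permutations: int
    gold_size: int


def build_paired_networks(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    beta: float = 10.0,
    method: str = "bicor",
    min_module_size: int = 50,
    assignment: pd.Series | None = None,
) -> PairedNetworks:
    """Build both networks at the same power with reference-derived modules.

    The gene universe is the intersection of the two matrices (mismatches
    dropped with a warning).  If ``assignment`` is given it is used verbatim
    (e.g. planted truth in simulations); otherwise modules are detected in
    the reference network via TOM clustering.
    """
    shared = expr_ref.index.intersection(expr_test.index)
    dropped = len(expr_ref.index.union(expr_test.index)) - len(shared)
    if dropped:
        warnings.warn(f"dropping {dropped} genes absent from one of the matrices", stacklevel=2)
    if len(shared) < 50:
        raise ValueError("fewer than 50 shared genes: paired comparison is meaningless")
    expr_ref = expr_ref.loc[shared]
    expr_test = expr_test.loc[shared]
    adj_ref = adjacency(correlation_matrix(expr_ref, method=method), beta)
    adj_test = adjacency(correlation_matrix(expr_test, method=method), beta)
    if assignment is None:
        assignment = detect_modules(tom_similarity(adj_ref), min_module_size=min_module_size)
    else:
        assignment = assignment.reindex(shared)
        if assignment.isna().any():
            raise ValueError("supplied assignment does not cover the shared gene universe")
    return PairedNetworks(adj_ref, adj_test, assignment, float(beta))


def rank_connectivity(stats_table: pd.DataFrame) -> pd.Series:
    """Dense ranks over all non-grey genes by kWithin, 1 = most connected.

    Ties break deterministically by gene id.
    """
    sub = stats_table[stats_table["module"] != GREY]
    order = np.lexsort((sub.index.to_numpy(), -sub["kWithin"].to_numpy()))
    ranks = pd.Series(0, index=sub.index[order], name="rank", dtype=int)
    ranks[:] = np.arange(1, len(sub) + 1)
    return ranks.reindex(sub.index)


def rank_change(
    ranks_ref: pd.Series,
    ranks_test: pd.Series,
    assignment: pd.Series,
) -> RankChangeResult:
    """Per-gene and per-module connectivity rank changes between networks.

    ``delta_rank = rank_ref - rank_test``; positive values mean the gene is
    better connected (lower rank number) in the test network, i.e. a gain of
    connectivity.  Modules are ordered by median member delta; the sign of
    the median classifies gain vs loss, and the count of gaining genes is
    reported alongside.
    """
    if not set(ranks_ref.index) == set(ranks_test.index):
        raise ValueError("rank change requires identical ranked gene sets")
    ranks_test = ranks_test.reindex(ranks_ref.index)
    delta = ranks_ref - ranks_test
    per_gene = pd.DataFrame(
        {
            "rank_ref": ranks_ref,
            "rank_test": ranks_test,
            "delta_rank": delta,
            "module": assignment.reindex(ranks_ref.index),
        }
    )
    rows = []
    for module, sub in per_gene.groupby("module"):
        median_delta = float(sub["delta_rank"].median())
        rows.append(
            {
                "module": module,
                "size": len(sub),
                "median_delta": median_delta,
                "n_gain": int((sub["delta_rank"] > 0).sum()),
                "n_loss": int((sub["delta_rank"] < 0).sum()),
                "classification": "gain" if median_delta > 0 else ("loss" if median_delta < 0 else "unchanged"),
            }
        )
    per_module = (
        pd.DataFrame(rows).set_index("module").sort_values("median_delta", ascending=False)
    )
    return RankChangeResult(per_gene=per_gene, per_module=per_module)


def classify_preservation(zsummary: float) -> str:
    """Standard Zsummary bands: <2 none, 2-10 weak/moderate, >10 strong."""
    if not np.isfinite(zsummary):
        return "strong" if zsummary > 0 else "none"
    if zsummary < 2:
        return "none"
    if zsummary > 10:
        return "strong"
    return "weak_moderate"


def _module_stats(
    members: np.ndarray,
    adj_ref: np.ndarray,
    adj_test: np.ndarray,
) -> tuple[float, float]:
    """(density, connectivity) preservation statistics for one gene set.

    Density is the mean off-diagonal test adjacency within the set;
    connectivity is the Pearson correlation between member intramodular
    connectivities in the reference and test networks.
    """
    sub_test = adj_test[np.ix_(members, members)]
    s = len(members)
    density = sub_test.sum() / (s * (s - 1))  # diagonals are zero
    k_ref = adj_ref[np.ix_(members, members)].sum(axis=1)
    k_test = sub_test.sum(axis=1)
    sd_ref, sd_test = k_ref.std(), k_test.std()
    if sd_ref == 0 or sd_test == 0:
        connectivity = 0.0
    else:
        connectivity = float(np.corrcoef(k_ref, k_test)[0, 1])
    return float(density), connectivity


def preservation_zsummary(
    paired: PairedNetworks,
    n_permutations: int = 100,
    gold_size: int = 1000,
    seed: int = 0,
) -> PreservationResult:
    """Permutation Z scores for module density and connectivity preservation.

    For each non-grey reference module of size ``s``, the observed density
    and connectivity statistics are compared with their distribution over
    ``n_permutations`` random gene sets of size ``s`` drawn from the shared
    universe; ``Z = (obs - null mean) / null SD`` and ``Zsummary`` is the
    mean of the two Z scores.  A gold module of ``gold_size`` random genes
    is evaluated the same way as a baseline.  Modules smaller than 3 genes
    are skipped; a zero null SD yields an infinite Z with a flag.
    """
    if n_permutations < 50:
        raise ValueError("need at least 50 permutations")
    genes = paired.adjacency_ref.index
    n_genes = len(genes)
    if gold_size > n_genes:
        raise ValueError("gold_size cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    adj_ref = paired.adjacency_ref.to_numpy(dtype=float)
    adj_test = paired.adjacency_test.to_numpy(dtype=float)
    labels = paired.assignment.reindex(genes)

    modules = [m for m in labels.unique() if m != GREY]
    rows = []
    evaluated: list[tuple[str, np.ndarray]] = []
    for module in modules:
        members = np.flatnonzero((labels == module).to_numpy())
        if len(members) < 3:
            warnings.warn(f"module {module!r} has fewer than 3 genes: skipped", stacklevel=2)
            continue
        evaluated.append((module, members))
    gold_members = rng.choice(n_genes, size=gold_size, replace=False)
    evaluated.append((GOLD, gold_members))

    for module, members in evaluated:
        s = len(members)
        obs_density, obs_connectivity = _module_stats(members, adj_ref, adj_test)
        null_d = np.empty(n_permutations)
        null_c = np.empty(n_permutations)
        # null sets are drawn from the whole gene universe: the null asks
        # "how would an arbitrary same-sized gene set score", not "an
        # arbitrary subset of module genes"
        for b in range(n_permutations):
            random_set = rng.choice(n_genes, size=s, replace=False)
            null_d[b], null_c[b] = _module_stats(random_set, adj_ref, adj_test)
        sd_d, sd_c = null_d.std(ddof=1), null_c.std(ddof=1)

        def z_score(obs, mean, sd):
            if sd > 0:
                return (obs - mean) / sd
            return 0.0 if obs == mean else np.inf * np.sign(obs - mean)

        z_density = z_score(obs_density, null_d.mean(), sd_d)
        z_connectivity = z_score(obs_connectivity, null_c.mean(), sd_c)
        zsummary = (z_density + z_connectivity) / 2.0
        rows.append(
            {
                "module": module,
                "size": s,
                "density_obs": obs_density,
                "density_null_mean": null_d.mean(),
                "density_null_sd": sd_d,
                "connectivity_obs": obs_connectivity,
                "connectivity_null_mean": null_c.mean(),
                "connectivity_null_sd": sd_c,
                "Zdensity": z_density,
                "Zconnectivity": z_connectivity,
                "Zsummary": zsummary,
                "degenerate_null": bool(sd_d == 0 or sd_c == 0),
                "class": classify_preservation(zsummary),
            }
        )
    per_module = pd.DataFrame(rows).set_index("module")
    return PreservationResult(
        per_module=per_module, n_permutations=n_permutations, gold_size=gold_size
    )
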