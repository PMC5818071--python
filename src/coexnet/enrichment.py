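"""Over-representation analysis of gene lists against GMT gene-set collections.

One-sided hypergeometric tests with the reporting convention used
throughout the pipeline: a set is called significant only when the raw
p-value is at or below 0.05 AND the overlap contains at least three genes.
No multiple-testing correction is applied (the raw-p filter is the
convention the downstream reports use).  Because a hypergeometric test
needs a gene universe, the default universe is the union of all collection
members; callers can pass their own (e.g. the filtered network genes).
"""

from __future__ import annotations

import os
import warnings
from collections.abc import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["read_gmt", "write_gmt", "overrepresentation", "function_gene_counts"]

P_CUTOFF = 0.05
MIN_OVERLAP = 3


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Parse a GMT file: name TAB description TAB member genes.

    Duplicate members within a set are de-duplicated; malformed lines raise
    with their line number.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, ""] + sorted(set(members))) + "\n")


def overrepresentation(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene list in each set.

    ``P(X >= k)`` for overlap ``k`` between the query and the set, drawing
    ``|query|`` genes from a universe of size ``N`` containing ``|set|``
    successes.  Results are sorted by p-value; the ``significant`` flag
    requires both p <= 0.05 and overlap >= 3.
    """
    query = set(query)
    if universe is None:
        universe = set().union(*(set(m) for m in sets.values()))
    else:
        universe = set(universe)
    outside = query - universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query genes outside the universe", stacklevel=2
        )
        query &= universe
    if not query:
        return pd.DataFrame(
            columns=["set", "set_size", "overlap", "p_value", "significant", "overlap_genes"]
        ).set_index("set")
    n_universe = len(universe)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        overlap = query & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, n_universe, len(members), len(query))) if members else 1.0
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "p_value": min(p, 1.0),
                "significant": (p <= P_CUTOFF) and (k >= MIN_OVERLAP),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    return pd.DataFrame(rows).set_index("set").sort_values("p_value")


def function_gene_counts(
    results: pd.DataFrame,
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Gene counts and percentages per function group (pie-chart table).

    ``grouping`` maps set names to function-group labels; only significant
    results contribute.  Each group counts the union of its sets' overlap
    genes, so a gene shared by two groups is counted once per group;
    percentages are over the total of the group counts.
    """
    sig = results[results["significant"]]
    if sig.empty:
        raise ValueError("no significant enrichment results to summarise")
    genes_by_group: dict[str, set[str]] = {}
    for name, row in sig.iterrows():
        group = grouping.get(str(name))
        if group is None:
            continue
        genes_by_group.setdefault(group, set()).update(
            g for g in str(row["overlap_genes"]).split(",") if g
        )
    counts = {g: len(v) for g, v in genes_by_group.items()}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("grouping matched no significant sets")
    table = pd.DataFrame(
        {
            "gene_count": pd.Series(counts),
            "percentage": pd.Series({g: 100.0 * c / total for g, c in counts.items()}),
        }
    )
    table.index.name = "function_group"
    return table.sort_values("gene_count", ascending=False)
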