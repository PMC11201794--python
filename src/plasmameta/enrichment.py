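"""Hypergeometric pathway over-representation and hierarchy roll-up.

Gene sets are tested against a measured-gene universe with the inclusive
upper hypergeometric tail P(X >= overlap); enriched pathways can then be
aggregated to the top-level ancestors of a child->parent pathway hierarchy
(a Reactome-style relations table read from a local file), and pathway
significance can be counted across cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .cohort_de import bh_adjust

logger = logging.getLogger(__name__)

#: Reserved root for enriched pathways that do not appear in the hierarchy.
UNCLASSIFIED = "unclassified"


@dataclass
class PathwayCatalog:
    """Named gene sets plus an optional child->parent hierarchy.

    ``sets`` maps pathway id to ``(name, member gene set)``.  ``hierarchy``
    is a list of (child_id, parent_id) edges forming a forest or DAG; roots
    are nodes that never appear as a child of anything.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    hierarchy: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has an empty member set")

    def parents_of(self, node: str) -> list[str]:
        if self.hierarchy is None:
            return []
        return [p for c, p in self.hierarchy if c == node]

    def root_ancestors(self, node: str) -> set[str]:
        """All top-level ancestors reachable from ``node`` (itself if a root)."""
        if self.hierarchy is None:
            return set()
        parent_map: dict[str, list[str]] = {}
        known: set[str] = set()
        for c, p in self.hierarchy:
            parent_map.setdefault(c, []).append(p)
            known.update((c, p))
        if node not in known:
            return set()
        roots: set[str] = set()
        seen: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            parents = parent_map.get(cur, [])
            if not parents:
                roots.add(cur)
            else:
                stack.extend(parents)
        return roots


def hypergeom_ora(
    query: Iterable[str],
    catalog: PathwayCatalog,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of a query gene set against each pathway.

    For each pathway with at least one gene overlapping the query,
    ``p_raw = P(X >= overlap)`` under Hypergeometric(universe_size,
    set_size, query_size); pathway members are intersected with the
    universe before testing.  BH correction is applied across the tested
    pathways and results are sorted by adjusted then raw p.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query gene set")
    outside = query_set - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query_set &= universe_set
        if not query_set:
            raise ValueError("no query gene lies in the universe")

    M, n_query = len(universe_set), len(query_set)
    rows = []
    for pid, (name, members) in catalog.sets.items():
        in_universe = members & universe_set
        overlap = query_set & in_universe
        if not overlap:
            continue
        K = len(in_universe)
        p = float(hypergeom.sf(len(overlap) - 1, M, K, n_query))
        rows.append(
            {
                "pathway_id": pid,
                "name": name,
                "overlap_count": len(overlap),
                "set_size": K,
                "query_size": n_query,
                "universe_size": M,
                "p_raw": min(p, 1.0),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "name", "overlap_count", "set_size", "query_size",
            "universe_size", "p_raw", "overlap_genes",
        ],
    )
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
        result = result.sort_values(
            ["p_adj", "p_raw", "pathway_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result


def rollup_ancestors(
    results: pd.DataFrame, catalog: PathwayCatalog
) -> pd.DataFrame:
    """Aggregate enriched pathways to their top-level hierarchy ancestors.

    Each enriched pathway is mapped to every root reachable by upward
    traversal (a pathway under multiple roots counts once per root).
    Pathways absent from the hierarchy land under the reserved root
    ``"unclassified"`` with a warning.
    """
    if catalog.hierarchy is None:
        raise ValueError("catalog has no hierarchy to roll up against")
    counts: dict[str, list[str]] = {}
    for pid in results["pathway_id"]:
        roots = catalog.root_ancestors(pid)
        if not roots:
            logger.warning("pathway %r absent from hierarchy; assigned to %s",
                           pid, UNCLASSIFIED)
            roots = {UNCLASSIFIED}
        for root in roots:
            counts.setdefault(root, []).append(pid)
    rows = [
        {"ancestor_id": root, "n_pathways": len(pids), "pathways": ",".join(sorted(pids))}
        for root, pids in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["ancestor_id", "n_pathways", "pathways"])
    return out.sort_values(
        ["n_pathways", "ancestor_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def cross_cohort_pathway_counts(
    per_cohort_results: Sequence[tuple[str, pd.DataFrame]],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Count, per pathway, the cohorts where it is significant at ``fdr_max``."""
    if len(per_cohort_results) < 2:
        raise ValueError("need enrichment results from at least 2 cohorts")
    counts: dict[str, int] = {}
    for _, res in per_cohort_results:
        if not len(res):
            continue
        sig = res[res["p_adj"] <= fdr_max]
        for pid in sig["pathway_id"]:
            counts[pid] = counts.get(pid, 0) + 1
    for _, res in per_cohort_results:
        for pid in res["pathway_id"]:
            counts.setdefault(pid, 0)
    out = pd.DataFrame(
        {"pathway_id": list(counts), "n_cohorts_significant": list(counts.values())}
    )
    return out.sort_values(
        ["n_cohorts_significant", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
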