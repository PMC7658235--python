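"""Fisher's-exact over-representation analysis and gene-set overlap networks.

Over-representation of a DEG list in GO-like gene sets is tested with a
one-sided (enrichment) Fisher's exact test against a stated gene
universe, Bonferroni-corrected over the sets actually testable in that
universe. Significant categories are then summarized as a network whose
edges mark set pairs sharing significantly many DEGs — the overlap test
uses the DEG list itself as its universe, so an edge means the two
categories tag overlapping parts of the differential signal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "OraResult",
    "OverlapNetwork",
    "fisher_ora",
    "pairwise_overlap_network",
    "overlap_network",
]


@dataclass
class OraResult:
    """Per-set over-representation results.

    ``table`` columns: overlap_count, set_size (within universe),
    universe_size, deg_count, odds_ratio, p_value (one-sided greater),
    p_bonferroni, significant_flag.
    """

    table: pd.DataFrame
    degs: list[str]
    # set name -> members within the universe (drives the overlap network)
    sets_in_universe: dict[str, frozenset[str]]
    alpha: float

    @property
    def significant_sets(self) -> list[str]:
        return list(self.table.index[self.table["significant_flag"]])


def fisher_hypergeom_p(
    overlap: int, set_size: int, deg_count: int, universe_size: int
) -> float:
    """One-sided Fisher p: P(X >= overlap), X ~ Hypergeom(N, K, n)."""
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, set_size, deg_count)
    )


def fisher_ora(
    degs: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    alpha: float = 0.05,
) -> OraResult:
    """One-sided Fisher's exact over-representation of ``degs`` in each set.

    Sets are intersected with the universe first; the Bonferroni factor is
    the number of sets with a nonzero intersection. DEGs must be a
    nonempty subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not degs:
        raise ValueError("empty DEG list")
    uni = set(universe)
    stray = [g for g in degs if g not in uni]
    if stray:
        raise ValueError(f"DEGs outside the universe: {stray[:5]}")
    deg_set = set(degs)
    n_universe, n_deg = len(uni), len(deg_set)

    members: dict[str, frozenset[str]] = {}
    rows = []
    for gs in sets:
        in_uni = frozenset(g for g in gs.genes if g in uni)
        if not in_uni:
            logger.info("set %r has no genes in the universe; skipped", gs.name)
            continue
        members[gs.name] = in_uni
        overlap = len(in_uni & deg_set)
        k = len(in_uni)
        p = fisher_hypergeom_p(overlap, k, n_deg, n_universe)
        a = overlap
        b = n_deg - overlap
        c = k - overlap
        d = n_universe - n_deg - k + overlap
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((gs.name, overlap, k, n_universe, n_deg, odds, p))
    if not rows:
        raise ValueError("no gene set intersects the universe")
    m = len(rows)
    table = pd.DataFrame(
        rows,
        columns=[
            "set", "overlap_count", "set_size", "universe_size",
            "deg_count", "odds_ratio", "p_value",
        ],
    ).set_index("set")
    table["p_bonferroni"] = np.minimum(1.0, m * table["p_value"])
    table["significant_flag"] = table["p_bonferroni"] < alpha
    return OraResult(table=table, degs=sorted(deg_set),
                     sets_in_universe=members, alpha=alpha)


@dataclass
class OverlapNetwork:
    """Gene-set overlap significance network.

    Nodes are gene sets (attribute ``n_genes``); an edge connects two sets
    whose shared members within the universe are more numerous than
    expected under independence (one-sided Fisher p below the threshold),
    annotated with the shared gene list and the p-value.
    """

    graph: nx.Graph
    universe_size: int
    edge_p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["p_value"], ";".join(d["shared_genes"]))
            for (a, b), d in (
                ((tuple(sorted(e))), self.graph.edges[e]) for e in self.graph.edges
            )
        ]
        return pd.DataFrame(
            rows, columns=["set_a", "set_b", "p_value", "shared_genes"]
        ).sort_values(["set_a", "set_b"]).reset_index(drop=True)

    def node_table(self) -> pd.DataFrame:
        rows = [(n, d.get("n_genes", 0)) for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows, columns=["set", "n_genes"]).set_index("set")


def overlap_network(
    sets: dict[str, frozenset[str]],
    universe: set[str],
    edge_p_threshold: float | None = None,
) -> OverlapNetwork:
    """Pairwise overlap-significance network over arbitrary gene sets.

    For each pair the 2x2 table counts universe genes by membership in
    each set; default edge threshold is 0.05 Bonferroni-corrected over
    the number of pairs.
    """
    names = sorted(sets)
    n_pairs = len(names) * (len(names) - 1) // 2
    if edge_p_threshold is None:
        edge_p_threshold = 0.05 / n_pairs if n_pairs else 0.05
    graph = nx.Graph()
    restricted = {n: frozenset(sets[n] & universe) for n in names}
    for n in names:
        graph.add_node(n, n_genes=len(restricted[n]))
    n_uni = len(universe)
    for a, b in itertools.combinations(names, 2):
        sa, sb = restricted[a], restricted[b]
        shared = sa & sb
        p = fisher_hypergeom_p(len(shared), len(sa), len(sb), n_uni)
        if p < edge_p_threshold:
            graph.add_edge(a, b, p_value=p, shared_genes=sorted(shared))
    return OverlapNetwork(graph=graph, universe_size=n_uni,
                          edge_p_threshold=edge_p_threshold)


def pairwise_overlap_network(
    ora: OraResult,
    degs: list[str] | None = None,
    edge_p_threshold: float | None = None,
) -> OverlapNetwork:
    """Overlap network among the significant ORA sets, restricted to DEGs.

    The universe of the pairwise Fisher tests is the DEG list itself, so
    edges report significant sharing of differential genes between
    categories. Shared-gene annotations are therefore DEGs in both sets.
    """
    if degs is None:
        degs = ora.degs
    deg_set = set(degs)
    significant = ora.significant_sets
    sets = {name: ora.sets_in_universe[name] for name in significant}
    return overlap_network(sets, deg_set, edge_p_threshold)
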