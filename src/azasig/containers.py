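"""Core in-memory containers shared by every pipeline stage.

All statistics in this package operate on the log2(value + 1) view of an
FPKM-like non-negative expression matrix; the raw values are kept so that
on-disk round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "GeneSet",
    "GeneSetCollection",
    "RegulatoryNetwork",
    "RESPONDER",
    "NON_RESPONDER",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


class ValidationError(ValueError):
    """Raised when a container or file violates its contract."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of non-negative FPKM-like expression values.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
        Values must be non-negative and finite; missing values are not
        permitted (the pipeline performs no imputation).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene ID {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            gi, si = map(int, np.argwhere(np.isnan(values))[0])
            raise ValidationError(
                f"missing value for gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        if (values < 0).any():
            gi, si = map(int, np.argwhere(values < 0)[0])
            raise ValidationError(
                f"negative value for gene {idx[gi]!r}, sample {cols[si]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def log2(self) -> pd.DataFrame:
        """log2(value + 1) view used by all downstream statistics."""
        return np.log2(self.data + 1.0)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class PhenotypeTable:
    """Per-sample response group and (optional) right-censored survival.

    ``group`` is ``responder`` / ``non_responder`` / ``unknown``; ``time``
    is survival in months and ``event`` is 1 for an observed death, 0 for
    censoring. Time and event are optional but must come in pairs.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        if "group" not in df.columns:
            raise ValidationError("phenotype table lacks a 'group' column")
        bad = set(df["group"]) - {RESPONDER, NON_RESPONDER, "unknown"}
        if bad:
            raise ValidationError(f"unrecognized group label {sorted(bad)[0]!r}")
        if "event" in df.columns:
            ev = df["event"].dropna()
            if not ev.isin([0, 1]).all():
                sample = ev[~ev.isin([0, 1])].index[0]
                raise ValidationError(
                    f"event for sample {sample!r} must be 0 or 1"
                )
            if "time" not in df.columns:
                raise ValidationError("event present without time column")
            times = df.loc[ev.index, "time"]
            if times.isna().any():
                sample = times[times.isna()].index[0]
                raise ValidationError(f"sample {sample!r} has event but no time")
            if (times.dropna() < 0).any():
                raise ValidationError("negative survival time")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])

    def group_counts(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    @property
    def has_survival(self) -> bool:
        return {"time", "event"} <= set(self.data.columns)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate genes within set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        uni = set(universe)
        return GeneSet(
            self.name, self.description, tuple(g for g in self.genes if g in uni)
        )


@dataclass
class GeneSetCollection:
    """Ordered, uniquely named gene sets (GMT-backed)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in out:
                raise ValidationError(f"duplicate set name {gs.name!r}")
            out[gs.name] = gs
        return cls(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValidationError(f"duplicate set name {gs.name!r}")
        self.sets[gs.name] = gs

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection.from_sets(self.sets[n] for n in names)


@dataclass
class RegulatoryNetwork:
    """Simple undirected gene–gene interaction graph."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] | None = None,
    ) -> "RegulatoryNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if nodes is not None and (u not in g or v not in g):
                missing = u if u not in g else v
                raise ValidationError(f"edge references unknown node {missing!r}")
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> list[str]:
        return list(self.graph.neighbors(gene))


def intersect_samples(
    matrix: ExpressionMatrix, phenotypes: PhenotypeTable, logger=None
) -> tuple[ExpressionMatrix, PhenotypeTable]:
    """Align a matrix and a phenotype table on their common sample IDs.

    Samples present in only one of the two are discarded (and logged);
    order follows the expression matrix.
    """
    common = [s for s in matrix.sample_ids if s in set(phenotypes.sample_ids)]
    dropped = (set(matrix.sample_ids) | set(phenotypes.sample_ids)) - set(common)
    if not common:
        raise ValidationError("no samples shared between expression and phenotypes")
    if dropped and logger is not None:
        logger.warning("discarding %d unmatched sample IDs: %s",
                       len(dropped), sorted(dropped)[:10])
    return (
        matrix.subset_samples(common),
        PhenotypeTable(phenotypes.data.loc[common]),
    )
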