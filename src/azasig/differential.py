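"""Per-gene two-sample testing, DEG selection and two-way clustering.

Testing follows the discovery analysis: an unadjusted two-sided Welch
t-test per gene on the log2(FPKM + 1) view, with differentially expressed
genes (DEGs) called at p < 0.01. The DEG submatrix is then clustered in
both dimensions with average linkage on 1 - Pearson correlation distance,
and the sample dendrogram is cut at k = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import (
    NON_RESPONDER,
    RESPONDER,
    ExpressionMatrix,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DegResult",
    "ClusterResult",
    "filter_low_expression",
    "t_test_per_gene",
    "select_degs",
    "hierarchical_cluster",
    "linkage_to_newick",
]


@dataclass
class DegResult:
    """Per-gene Welch t-test results on the log2 view.

    ``table`` columns: mean_responder, mean_nonresponder, log2_fold_change
    (responder minus non-responder), t_statistic, p_value, deg_flag, rank
    (ascending p, ties broken by gene ID).
    """

    table: pd.DataFrame
    p_threshold: float

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def degs(self) -> list[str]:
        return select_degs(self, self.p_threshold)


def filter_low_expression(
    matrix: ExpressionMatrix, max_zero_fraction: float = 0.9
) -> ExpressionMatrix:
    """Drop genes whose expression is zero in >= ``max_zero_fraction`` samples.

    Set ``max_zero_fraction`` above 1 to disable the filter.
    """
    zero_frac = (matrix.data.to_numpy() == 0).mean(axis=1)
    keep = zero_frac < max_zero_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("low-expression filter dropped %d of %d genes",
                    dropped, matrix.shape[0])
    return ExpressionMatrix(matrix.data.loc[keep])


def _group_columns(
    matrix: ExpressionMatrix, phenotypes: PhenotypeTable
) -> tuple[list[str], list[str]]:
    in_matrix = set(matrix.sample_ids)
    resp = [s for s in phenotypes.samples_in_group(RESPONDER) if s in in_matrix]
    nonresp = [
        s for s in phenotypes.samples_in_group(NON_RESPONDER) if s in in_matrix
    ]
    for label, cols in ((RESPONDER, resp), (NON_RESPONDER, nonresp)):
        if len(cols) < 2:
            raise ValueError(
                f"group {label!r} has {len(cols)} samples in the matrix; "
                "need at least 2"
            )
    return resp, nonresp


def t_test_per_gene(
    matrix: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    p_threshold: float = 0.01,
) -> DegResult:
    """Two-sided Welch (unequal-variance) t-test per gene, log2 view.

    Genes constant across all samples get t = 0, p = 1 so downstream DEG
    counts stay well defined.
    """
    resp, nonresp = _group_columns(matrix, phenotypes)
    log2 = matrix.log2
    a = log2[resp].to_numpy()
    b = log2[nonresp].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    mean_r = a.mean(axis=1)
    mean_nr = b.mean(axis=1)
    # zero variance in both groups: equal means -> no evidence (t=0, p=1);
    # unequal means -> infinitely strong evidence under the model
    degenerate = np.isnan(t)
    equal = degenerate & np.isclose(mean_r, mean_nr)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    unequal = degenerate & ~equal
    with np.errstate(invalid="ignore"):
        t = np.where(unequal, np.sign(mean_r - mean_nr) * np.inf, t)
    p = np.where(unequal, 0.0, p)

    table = pd.DataFrame(
        {
            "mean_responder": mean_r,
            "mean_nonresponder": mean_nr,
            "log2_fold_change": mean_r - mean_nr,
            "t_statistic": t,
            "p_value": p,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    table["deg_flag"] = table["p_value"] < p_threshold
    # rank: ascending p, ties by gene ID
    ranked = table.reset_index().sort_values(["p_value", "gene"]).set_index("gene")
    table["rank"] = pd.Series(
        np.arange(1, len(table) + 1), index=ranked.index
    ).reindex(table.index)
    return DegResult(table=table, p_threshold=p_threshold)


def select_degs(result: DegResult, p_threshold: float | None = None) -> list[str]:
    """Genes with p strictly below threshold, by ascending p then gene ID."""
    thr = result.p_threshold if p_threshold is None else p_threshold
    if not 0 < thr < 1:
        raise ValueError("p_threshold must lie in (0, 1)")
    hits = result.table[result.table["p_value"] < thr]
    ordered = hits.reset_index().sort_values(["p_value", "gene"])
    return list(ordered["gene"])


@dataclass
class ClusterResult:
    """Two-way hierarchical clustering of a DEG submatrix."""

    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_partition: pd.Series  # sample -> {1, 2}
    dropped_genes: list[str] = field(default_factory=list)

    def gene_newick(self) -> str:
        return linkage_to_newick(self.gene_linkage, self.gene_ids)

    def sample_newick(self) -> str:
        return linkage_to_newick(self.sample_linkage, self.sample_ids)

    def partition_agreement(self, groups: pd.Series) -> float:
        """Best 2-cluster agreement with known binary labels, in [0, 1]."""
        labels = groups.reindex(self.sample_partition.index)
        values = sorted(set(labels))
        if len(values) != 2:
            raise ValueError("partition agreement needs exactly two known groups")
        truth = (labels == values[0]).to_numpy()
        part = (self.sample_partition == 1).to_numpy()
        agree = (truth == part).mean()
        return float(max(agree, 1 - agree))


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    d = pdist(rows, metric="correlation")
    # numerical noise can push 1 - r marginally outside [0, 2]
    return np.clip(d, 0.0, 2.0)


def hierarchical_cluster(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> ClusterResult:
    """Average-linkage clustering on 1 - Pearson distance, both ways.

    Gene rows are z-scored first; constant rows are dropped with a
    warning. The sample dendrogram is cut at k = 2.
    """
    sub = matrix if genes is None else matrix.subset_genes(genes)
    log2 = sub.log2
    values = log2.to_numpy()
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = [g for g, k in zip(sub.gene_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant gene rows before clustering",
                       len(dropped))
    values = values[keep]
    gene_ids = [g for g, k in zip(sub.gene_ids, keep) if k]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 samples")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[keep][:, None]

    gene_linkage = hierarchy.average(_correlation_distance(z))
    sample_linkage = hierarchy.average(_correlation_distance(z.T))
    flat = hierarchy.fcluster(sample_linkage, t=2, criterion="maxclust")
    partition = pd.Series(flat, index=sub.sample_ids, name="cluster")
    return ClusterResult(
        gene_linkage=gene_linkage,
        sample_linkage=sample_linkage,
        gene_ids=gene_ids,
        sample_ids=sub.sample_ids,
        sample_partition=partition,
        dropped_genes=dropped,
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
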