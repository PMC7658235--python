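import numpy as np
import pandas as pd
import pytest

from azasig.containers import ExpressionMatrix, PhenotypeTable
from azasig.differential import (
    filter_low_expression,
    hierarchical_cluster,
    select_degs,
    t_test_per_gene,
)
from azasig.simulate import simulate_discovery_cohort
from tests.conftest import small_config


def test_welch_t_matches_hand_computed_example(tiny_matrix, tiny_phenotypes):
    """log2 groups (1,2,3) vs (4,5,6): t = -3.674235, df = 4, p = 0.021312."""
    result = t_test_per_gene(tiny_matrix, tiny_phenotypes)
    row = result.table.loc["gA"]
    assert row["t_statistic"] == pytest.approx(-3.674235, abs=1e-5)
    assert row["p_value"] == pytest.approx(0.021312, abs=1e-5)
    assert row["log2_fold_change"] == pytest.approx(-3.0)


def test_constant_gene_gets_t_zero_p_one(tiny_matrix, tiny_phenotypes):
    result = t_test_per_gene(tiny_matrix, tiny_phenotypes)
    for gene in ("gConst", "gFlat"):
        assert result.table.loc[gene, "t_statistic"] == 0.0
        assert result.table.loc[gene, "p_value"] == 1.0


def test_label_swap_negates_t_keeps_p(tiny_matrix, tiny_phenotypes):
    swapped = PhenotypeTable(
        tiny_phenotypes.data.assign(
            group=lambda df: df["group"].map(
                {"responder": "non_responder", "non_responder": "responder"}
            )
        )
    )
    a = t_test_per_gene(tiny_matrix, tiny_phenotypes).table
    b = t_test_per_gene(tiny_matrix, swapped).table
    np.testing.assert_allclose(a["t_statistic"], -b["t_statistic"])
    np.testing.assert_allclose(a["p_value"], b["p_value"])
    # sign(t) always tracks sign(log2 fold change)
    nonzero = a["t_statistic"] != 0
    assert (
        np.sign(a.loc[nonzero, "t_statistic"])
        == np.sign(a.loc[nonzero, "log2_fold_change"])
    ).all()


def test_group_below_two_samples_rejected(tiny_matrix, tiny_phenotypes):
    pheno = PhenotypeTable(tiny_phenotypes.data.iloc[[0, 1, 2, 3]])
    with pytest.raises(ValueError, match="at least 2"):
        t_test_per_gene(tiny_matrix.subset_samples(["s1", "s2", "s3", "s4"]),
                        pheno)


def test_select_degs_threshold_monotone_and_tie_ordered(planted_cohort):
    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs_strict = set(select_degs(result, 0.001))
    degs_loose = set(select_degs(result, 0.05))
    assert degs_strict <= degs_loose
    assert degs_loose <= set(result.genes)
    ordered = select_degs(result, 0.05)
    ps = result.table.loc[ordered, "p_value"].to_numpy()
    assert np.all(np.diff(ps) >= 0)


def test_select_degs_empty_when_all_p_one():
    table = pd.DataFrame(
        {
            "mean_responder": [1.0],
            "mean_nonresponder": [1.0],
            "log2_fold_change": [0.0],
            "t_statistic": [0.0],
            "p_value": [1.0],
            "deg_flag": [False],
            "rank": [1],
        },
        index=pd.Index(["g1"], name="gene"),
    )
    from azasig.differential import DegResult

    assert select_degs(DegResult(table, 0.01)) == []


def test_deg_sensitivity_on_planted_cohort(planted_cohort):
    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs = set(select_degs(result))
    planted = set(planted_cohort.truth.index[planted_cohort.truth["is_de"]])
    sensitivity = len(degs & planted) / len(planted)
    assert sensitivity >= 0.9


def test_low_expression_filter_drops_mostly_zero_genes():
    frame = pd.DataFrame(
        {
            f"s{i}": [0.0, 5.0] for i in range(10)
        },
        index=["gZero", "gExpr"],
    )
    frame.loc["gZero", "s1"] = 2.0  # expressed in 1/10 samples
    filtered = filter_low_expression(ExpressionMatrix(frame), 0.9)
    assert filtered.gene_ids == ["gExpr"]


def test_identical_samples_merge_first():
    log2 = pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 1.0],
            "b": [1.0, 2.0, 3.0, 1.0],
            "c": [3.0, 0.5, 1.0, 4.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    matrix = ExpressionMatrix(np.exp2(log2) - 1.0)
    result = hierarchical_cluster(matrix)
    part = result.sample_partition
    assert part["a"] == part["b"]
    assert part["a"] != part["c"]


def test_cluster_partition_invariant_to_sample_order(planted_cohort):
    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs = select_degs(result)
    base = hierarchical_cluster(planted_cohort.expression, degs)
    rng = np.random.default_rng(0)
    shuffled_samples = list(
        rng.permutation(planted_cohort.expression.sample_ids)
    )
    shuffled = hierarchical_cluster(
        planted_cohort.expression.subset_samples(shuffled_samples), degs
    )
    a = base.sample_partition
    b = shuffled.sample_partition.reindex(a.index)
    same = (a == b).all()
    flipped = (a != b).all()
    assert same or flipped


def test_cluster_invariant_to_positive_affine_gene_transform(planted_cohort):
    """Correlation distance ignores per-gene shift and positive scale."""
    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs = select_degs(result)[:40]
    base = hierarchical_cluster(planted_cohort.expression, degs)
    log2 = planted_cohort.expression.log2.loc[degs]
    rng = np.random.default_rng(1)
    scale = rng.uniform(0.5, 2.0, size=(len(degs), 1))
    shift = rng.uniform(0.0, 3.0, size=(len(degs), 1))
    transformed = ExpressionMatrix(
        pd.DataFrame(
            np.exp2(log2.to_numpy() * scale + shift) - 1.0,
            index=degs,
            columns=planted_cohort.expression.sample_ids,
        )
    )
    other = hierarchical_cluster(transformed)
    a, b = base.sample_partition, other.sample_partition.reindex(
        base.sample_partition.index
    )
    assert (a == b).all() or (a != b).all()


def test_cluster_recovers_response_groups(planted_cohort):
    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs = select_degs(result)
    clustered = hierarchical_cluster(planted_cohort.expression, degs)
    agreement = clustered.partition_agreement(planted_cohort.phenotypes.groups)
    assert agreement >= 21 / 23


def test_constant_gene_rows_dropped_with_warning(caplog):
    log2 = pd.DataFrame(
        {
            "a": [1.0, 2.0, 2.0],
            "b": [2.0, 2.0, 1.0],
            "c": [3.0, 2.0, 3.0],
            "d": [1.5, 2.0, 2.5],
        },
        index=["g1", "gConst", "g3"],
    )
    matrix = ExpressionMatrix(np.exp2(log2) - 1.0)
    with caplog.at_level("WARNING"):
        result = hierarchical_cluster(matrix)
    assert result.dropped_genes == ["gConst"]
    assert "gConst" not in result.gene_ids


def test_newick_export_parses_with_all_leaves(planted_cohort):
    import dendropy

    result = t_test_per_gene(planted_cohort.expression, planted_cohort.phenotypes)
    degs = select_degs(result)[:20]
    clustered = hierarchical_cluster(planted_cohort.expression, degs)
    tree = dendropy.Tree.get(data=clustered.sample_newick(), schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert leaves == set(planted_cohort.expression.sample_ids)
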