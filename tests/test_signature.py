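import warnings

import numpy as np
import pandas as pd
import pytest

from azasig.containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
)
from azasig.signature import (
    SignatureScoreMatrix,
    classify_cohort,
    logrank_compare,
    prediction_accuracy,
    score_samples,
)
from azasig.simulate import simulate_discovery_cohort, simulate_validation_cohort
from tests.conftest import small_config


def expr_from_log2(log2: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(np.exp2(log2) - 1.0)


def test_single_gene_set_score_equals_gene_value():
    log2 = pd.DataFrame({"s1": [2.0], "s2": [4.0]}, index=["g1"])
    matrix = expr_from_log2(log2)
    sets = GeneSetCollection.from_sets([GeneSet("S", "d", ("g1",))])
    scores = score_samples(matrix, sets, {"S": "responder_up"})
    np.testing.assert_allclose(scores.raw["S"], [2.0, 4.0])
    assert scores.coverage["S"] == 1.0


def test_two_gene_set_score_is_arithmetic_mean():
    log2 = pd.DataFrame({"s1": [2.0, 4.0]}, index=["g1", "g2"])
    matrix = expr_from_log2(log2)
    sets = GeneSetCollection.from_sets([GeneSet("S", "d", ("g1", "g2"))])
    scores = score_samples(matrix, sets, {"S": "responder_up"})
    assert scores.raw.loc["s1", "S"] == pytest.approx(3.0)


def test_score_coverage_and_missing_set_error(caplog):
    log2 = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
    matrix = expr_from_log2(log2)
    partial = GeneSetCollection.from_sets(
        [GeneSet("S", "d", ("g1", "gMissing", "gAlso", "gGone"))]
    )
    with caplog.at_level("WARNING"):
        scores = score_samples(matrix, partial, {"S": "responder_up"})
    assert scores.coverage["S"] == pytest.approx(0.25)
    assert any("coverage" in r.message for r in caplog.records)

    absent = GeneSetCollection.from_sets([GeneSet("T", "d", ("gNope",))])
    with pytest.raises(ValueError, match="T"):
        score_samples(matrix, absent, {"T": "responder_up"})


def test_score_invariant_to_gene_order():
    rng = np.random.default_rng(0)
    log2 = pd.DataFrame(
        rng.uniform(1, 5, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    matrix = expr_from_log2(log2)
    fwd = GeneSetCollection.from_sets([GeneSet("S", "d", ("g0", "g2", "g4"))])
    rev = GeneSetCollection.from_sets([GeneSet("S", "d", ("g4", "g2", "g0"))])
    a = score_samples(matrix, fwd, {"S": "responder_up"})
    b = score_samples(matrix, rev, {"S": "responder_up"})
    pd.testing.assert_frame_equal(a.raw, b.raw)


def _blob_scores(n_per_blob=10, seed=0):
    rng = np.random.default_rng(seed)
    high = rng.normal(1.5, 0.2, size=(n_per_blob, 2))
    low = rng.normal(-1.5, 0.2, size=(n_per_blob, 2))
    raw = pd.DataFrame(
        np.vstack([high, low]),
        index=[f"s{i}" for i in range(2 * n_per_blob)],
        columns=["R", "N"],
    )
    raw["N"] = -raw["N"]  # anti-correlated nonresponder-up set
    z = (raw - raw.mean()) / raw.std(ddof=0)
    return SignatureScoreMatrix(
        raw=raw,
        zscores=z,
        coverage=pd.Series(1.0, index=raw.columns),
        directions={"R": "responder_up", "N": "nonresponder_up"},
    )


def test_classifier_recovers_constructed_blobs():
    scores = _blob_scores()
    partition = classify_cohort(scores)
    labels = partition.labels
    first_half = {labels[f"s{i}"] for i in range(10)}
    second_half = {labels[f"s{i}"] for i in range(10, 20)}
    assert first_half == {"responder_like"}
    assert second_half == {"non_responder_like"}


def test_direction_flip_swaps_names_not_partition():
    scores = _blob_scores()
    flipped = SignatureScoreMatrix(
        raw=scores.raw,
        zscores=scores.zscores,
        coverage=scores.coverage,
        directions={"R": "nonresponder_up", "N": "responder_up"},
    )
    a = classify_cohort(scores).labels
    b = classify_cohort(flipped).labels
    assert (a != b).all()  # same two clusters, names exchanged


def test_classifier_accuracy_on_planted_validation_cohort():
    config = small_config(seed=23, n_validation_samples=100)
    disc = simulate_discovery_cohort(config)
    val = simulate_validation_cohort(
        config, disc.gene_sets.subset(["RESPIRATION", "APOPTOSIS", "WNT"])
    )
    dirs = {
        "RESPIRATION": "responder_up",
        "APOPTOSIS": "responder_up",
        "WNT": "nonresponder_up",
    }
    scores = score_samples(val.expression, val.gene_sets, dirs)
    partition = classify_cohort(scores)
    acc = prediction_accuracy(partition, val.truth["latent_label"])
    assert acc >= 0.85


def test_prediction_accuracy_identities():
    labels = pd.Series(
        ["responder_like"] * 3 + ["non_responder_like"] * 3,
        index=[f"s{i}" for i in range(6)],
    )
    from azasig.signature import CohortPartition

    part = CohortPartition(labels=labels, orientation=pd.Series(0.0, index=labels.index))
    truth = pd.Series(
        ["responder"] * 3 + ["non_responder"] * 3, index=labels.index
    )
    assert prediction_accuracy(part, truth) == 1.0
    inverted = truth.map(
        {"responder": "non_responder", "non_responder": "responder"}
    )
    assert prediction_accuracy(part, inverted) == 0.0
    with pytest.raises(ValueError, match="missing"):
        prediction_accuracy(part, truth.iloc[:4])


def test_random_scores_give_chance_level_accuracy():
    """Permutation oracle: oriented accuracy of noise concentrates at 1/2."""
    rng = np.random.default_rng(42)
    truth = pd.Series(
        ["responder"] * 13 + ["non_responder"] * 19,
        index=[f"s{i}" for i in range(32)],
    )
    accs = []
    for _ in range(100):
        raw = pd.DataFrame(
            rng.normal(size=(32, 4)),
            index=truth.index,
            columns=list("ABCD"),
        )
        z = (raw - raw.mean()) / raw.std(ddof=0)
        sm = SignatureScoreMatrix(
            raw=raw, zscores=z,
            coverage=pd.Series(1.0, index=raw.columns),
            directions={"A": "responder_up", "B": "responder_up",
                        "C": "nonresponder_up", "D": "nonresponder_up"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            accs.append(prediction_accuracy(classify_cohort(sm), truth))
    assert abs(np.mean(accs) - 0.5) < 0.06


def _survival_phenotypes(times1, events1, times2, events2):
    n1, n2 = len(times1), len(times2)
    frame = pd.DataFrame(
        {
            "group": ["unknown"] * (n1 + n2),
            "time": list(times1) + list(times2),
            "event": list(events1) + list(events2),
        },
        index=pd.Index([f"s{i}" for i in range(n1 + n2)], name="sample_id"),
    )
    labels = pd.Series(
        ["responder_like"] * n1 + ["non_responder_like"] * n2,
        index=frame.index,
    )
    from azasig.signature import CohortPartition

    return PhenotypeTable(frame), CohortPartition(
        labels=labels, orientation=pd.Series(0.0, index=frame.index)
    )


def test_logrank_identical_groups_gives_zero_statistic():
    times = [3.0, 5.0, 8.0, 12.0]
    events = [1, 0, 1, 1]
    pheno, part = _survival_phenotypes(times, events, times, events)
    comp = logrank_compare(pheno, part)
    assert comp.statistic == pytest.approx(0.0, abs=1e-12)
    assert comp.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_computed_table():
    """(1,2) events vs (3,4) events: O-E table gives 2.882353, p 0.089555."""
    pheno, part = _survival_phenotypes([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
    comp = logrank_compare(pheno, part)
    assert comp.statistic == pytest.approx(2.882353, abs=1e-5)
    assert comp.p_value == pytest.approx(0.089555, abs=1e-5)


def test_logrank_invariant_under_group_exchange():
    rng = np.random.default_rng(7)
    t1, t2 = rng.exponential(10, 12), rng.exponential(5, 15)
    e1, e2 = rng.integers(0, 2, 12), rng.integers(0, 2, 15)
    e1[0] = 1  # ensure at least one event
    pheno_a, part_a = _survival_phenotypes(t1, e1, t2, e2)
    pheno_b, part_b = _survival_phenotypes(t2, e2, t1, e1)
    a = logrank_compare(pheno_a, part_a)
    b = logrank_compare(pheno_b, part_b)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-9)


def test_logrank_requires_events():
    pheno, part = _survival_phenotypes([1.0, 2.0], [0, 0], [3.0, 4.0], [0, 0])
    with pytest.raises(ValueError, match="no observed events"):
        logrank_compare(pheno, part)
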