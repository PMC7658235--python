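import numpy as np
import pytest
from scipy import stats

from azasig.containers import (
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
)
from azasig.gsea import (
    RankedList,
    enrichment_score,
    leading_edge,
    permute_and_normalize,
    rank_genes,
    signal_to_noise,
)
from azasig.simulate import simulate_discovery_cohort
from tests.conftest import small_config


def brute_force_es(ranked: RankedList, members: set, weight_p: float = 1.0):
    """Independent pure-python running-sum oracle."""
    hits = [g in members for g in ranked.genes]
    k = sum(hits)
    n = len(ranked.genes)
    weights = [abs(s) ** weight_p if h else 0.0
               for s, h in zip(ranked.scores, hits)]
    total = sum(weights) or float(k)
    if total == float(k) and sum(weights) == 0:
        weights = [1.0 if h else 0.0 for h in hits]
    running, best_hi, best_lo = 0.0, -np.inf, np.inf
    for h, w in zip(hits, weights):
        running += w / total if h else -1.0 / (n - k)
        best_hi = max(best_hi, running)
        best_lo = min(best_lo, running)
    return best_hi if best_hi >= -best_lo else best_lo


def make_ranked(scores, names=None):
    scores = np.asarray(scores, dtype=float)
    names = names or [f"g{i}" for i in range(len(scores))]
    return RankedList(genes=list(names), scores=scores)


def test_signal_to_noise_hand_value():
    """mu 2 vs 1, sd 0.5 each (above the floor) -> score exactly 1."""
    half = 0.5 / np.sqrt(2)
    a = np.array([2 - half, 2 + half])
    b = np.array([1 - half, 1 + half])
    assert signal_to_noise(a, b) == pytest.approx(1.0)
    # equal groups -> zero
    assert signal_to_noise(a, a) == pytest.approx(0.0)


def test_rank_genes_antisymmetric_under_label_swap(planted_cohort):
    ranked = rank_genes(planted_cohort.expression, planted_cohort.phenotypes)
    swapped = PhenotypeTable(
        planted_cohort.phenotypes.data.assign(
            group=lambda df: df["group"].map(
                {"responder": "non_responder", "non_responder": "responder"}
            )
        )
    )
    reverse = rank_genes(planted_cohort.expression, swapped)
    assert reverse.genes == ranked.genes[::-1]
    np.testing.assert_allclose(reverse.scores, -ranked.scores[::-1], atol=1e-12)


def test_es_top_gene_only():
    ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
    es, profile, peak = enrichment_score(ranked, {"g0"})
    assert es == pytest.approx(1.0)
    assert peak == 1
    assert leading_edge(ranked, {"g0"}, es, peak) == ["g0"]


def test_es_bottom_gene_hand_profile():
    """|r| = (4,3,2,1), set = bottom gene: profile -1/3, -2/3, -1, 0."""
    ranked = make_ranked([4.0, 3.0, 2.0, 1.0])
    es, profile, peak = enrichment_score(ranked, {"g3"})
    np.testing.assert_allclose(profile, [-1 / 3, -2 / 3, -1.0, 0.0])
    assert es == pytest.approx(-1.0)
    assert peak == 3
    # members at ranks >= peak: only the bottom gene
    assert leading_edge(ranked, {"g3"}, es, peak) == ["g3"]


def test_es_whole_list_is_one():
    ranked = make_ranked([3.0, 2.0, 1.0])
    es, _, _ = enrichment_score(ranked, set(ranked.genes))
    assert es == pytest.approx(1.0)


def test_es_empty_intersection_rejected():
    ranked = make_ranked([1.0, 0.5])
    with pytest.raises(ValueError, match="no genes"):
        enrichment_score(ranked, {"absent"})


def test_es_matches_brute_force_oracle():
    rng = np.random.default_rng(8)
    scores = np.sort(rng.normal(size=8))[::-1]
    ranked = make_ranked(scores)
    import itertools

    for k in (1, 2, 3):
        for combo in itertools.combinations(ranked.genes, k):
            es, _, _ = enrichment_score(ranked, set(combo))
            assert es == pytest.approx(
                brute_force_es(ranked, set(combo)), abs=1e-12
            )


def test_es_scale_invariant():
    rng = np.random.default_rng(9)
    scores = np.sort(rng.normal(size=20))[::-1]
    ranked = make_ranked(scores)
    scaled = make_ranked(scores * 7.3)
    members = set(rng.choice(ranked.genes, size=6, replace=False))
    es1, _, _ = enrichment_score(ranked, members)
    es2, _, _ = enrichment_score(scaled, members)
    assert es1 == pytest.approx(es2, abs=1e-12)


def test_reversal_preserves_magnitude_and_flips_sign_off_ties():
    rng = np.random.default_rng(10)
    for _ in range(100):
        n = int(rng.integers(6, 25))
        scores = np.sort(rng.normal(size=n))[::-1]
        ranked = make_ranked(scores)
        reversed_list = make_ranked(
            -scores[::-1], names=ranked.genes[::-1]
        )
        k = int(rng.integers(2, n))
        members = set(rng.choice(ranked.genes, size=k, replace=False))
        es_fwd, prof, _ = enrichment_score(ranked, members)
        es_rev, _, _ = enrichment_score(reversed_list, members)
        assert abs(es_rev) == pytest.approx(abs(es_fwd), abs=1e-9)
        if abs(prof.max() + prof.min()) > 1e-9:  # extremes not tied
            assert es_rev == pytest.approx(-es_fwd, abs=1e-9)


def test_unweighted_es_equals_classical_ks_statistic():
    rng = np.random.default_rng(11)
    n = 60
    scores = np.sort(rng.normal(size=n))[::-1]
    ranked = make_ranked(scores)
    for _ in range(100):
        k = int(rng.integers(3, 20))
        members = set(rng.choice(ranked.genes, size=k, replace=False))
        es, _, _ = enrichment_score(ranked, members, weight_p=0.0)
        positions = np.array(
            [i for i, g in enumerate(ranked.genes) if g in members]
        )
        others = np.array(
            [i for i, g in enumerate(ranked.genes) if g not in members]
        )
        ks = stats.ks_2samp(positions, others).statistic
        assert abs(es) == pytest.approx(ks, abs=1e-12)


def test_leading_edge_contained_in_set():
    rng = np.random.default_rng(12)
    scores = np.sort(rng.normal(size=40))[::-1]
    ranked = make_ranked(scores)
    for _ in range(200):
        k = int(rng.integers(1, 15))
        members = set(rng.choice(ranked.genes, size=k, replace=False))
        es, _, peak = enrichment_score(ranked, members)
        edge = leading_edge(ranked, members, es, peak)
        assert set(edge) <= members
        assert edge  # nonzero ES always yields at least one gene
    assert leading_edge(ranked, {"g0"}, 0.0, 5) == []


@pytest.fixture(scope="module")
def planted_gsea():
    cohort = simulate_discovery_cohort(small_config(seed=17))
    result = permute_and_normalize(
        cohort.expression, cohort.phenotypes, cohort.gene_sets,
        n_perm=200, seed=17, min_size=10,
    )
    return cohort, result


def test_permutation_results_reproducible_and_order_invariant(planted_gsea):
    cohort, result = planted_gsea
    again = permute_and_normalize(
        cohort.expression, cohort.phenotypes, cohort.gene_sets,
        n_perm=200, seed=17, min_size=10,
    )
    assert result.table.equals(again.table)
    reordered = GeneSetCollection.from_sets(
        [cohort.gene_sets[n] for n in reversed(cohort.gene_sets.names)]
    )
    shuffled = permute_and_normalize(
        cohort.expression, cohort.phenotypes, reordered,
        n_perm=200, seed=17, min_size=10,
    )
    assert shuffled.table.equals(result.table)


def test_planted_modules_attain_extreme_nes(planted_gsea):
    cohort, result = planted_gsea
    table = result.table.sort_values("nes", ascending=False)
    assert {"RESPIRATION", "APOPTOSIS"} <= set(table.index[:3])
    assert table.index[-1] == "WNT"
    assert (result.table["es"].abs() <= 1.0 + 1e-12).all()
    valid = result.table["nes"].dropna()
    assert (np.sign(valid) == np.sign(result.table.loc[valid.index, "es"])).all()
    for col in ("p_value", "fdr", "fwer"):
        vals = result.table[col].dropna()
        assert ((0 <= vals) & (vals <= 1)).all()


def test_leading_edges_contained_and_directional(planted_gsea):
    cohort, result = planted_gsea
    for name, genes in result.leading_edges.items():
        assert set(genes) <= set(cohort.gene_sets[name].genes)
    assert result.directions["RESPIRATION"] == "responder_up"
    assert result.directions["WNT"] == "nonresponder_up"


def test_tiny_cohort_enumerates_all_label_assignments():
    """4+3 samples -> C(7,3) = 35 distinct assignments, all enumerated."""
    cohort = simulate_discovery_cohort(
        small_config(seed=19, n_responders=4, n_nonresponders=3, n_genes=120,
                     modules=(), n_decoy_sets=4,
                     decoy_set_size_range=(15, 25))
    )
    result = permute_and_normalize(
        cohort.expression, cohort.phenotypes, cohort.gene_sets,
        n_perm=100, seed=19, min_size=5,
    )
    assert result.n_permutations == 35


def test_set_size_filters_logged(planted_gsea):
    cohort, _ = planted_gsea
    result = permute_and_normalize(
        cohort.expression, cohort.phenotypes, cohort.gene_sets,
        n_perm=200, seed=17, min_size=26, max_size=70,
    )
    assert "APOPTOSIS" in result.skipped_sets  # size 10 < 26
    assert "WNT" not in result.table.index or len(
        cohort.gene_sets["WNT"]
    ) <= 70
    assert all(26 <= s <= 70 for s in result.table["size"])


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    raw=st.lists(
        st.floats(-5, 5, allow_nan=False, allow_infinity=False),
        min_size=4, max_size=20,
    ),
    mask_seed=st.integers(0, 2**16),
)
def test_es_bounds_and_leading_edge_containment(raw, mask_seed):
    """|ES| <= 1 and the leading edge is a subset of the gene set, for
    arbitrary score vectors and arbitrary nonempty member subsets."""
    scores = np.sort(np.asarray(raw, dtype=float))[::-1]
    ranked = make_ranked(scores)
    rng = np.random.default_rng(mask_seed)
    k = int(rng.integers(1, len(scores) + 1))
    members = set(rng.choice(ranked.genes, size=k, replace=False))
    es, profile, peak = enrichment_score(ranked, members)
    assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
    assert 1 <= peak <= len(scores)
    assert np.all(np.abs(profile) <= 1.0 + 1e-9)
    edge = leading_edge(ranked, members, es, peak)
    assert set(edge) <= members
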