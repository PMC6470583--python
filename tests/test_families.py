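import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teneigh.families import (
    PAIR_CELLS,
    assign_age_class,
    attach_qvalues,
    bh_adjust,
    chisq_gof,
    expected_pair_probs,
    kruskal_wallis,
    ks_two_sample,
    monte_carlo_pvalue,
    pair_context_counts,
    same_environment_partition,
    within_family_correlation,
)
from teneigh.intervals import FamilyRecord
from teneigh.reference import (
    DUPLICATED_CATEGORY_COUNTS,
    PAIR_CONTEXT_COUNTS,
    duplicated_marginals,
    pair_context_vector,
)
from teneigh.te_environment import CATEGORIES


class TestAgeClass:
    @pytest.mark.parametrize(
        "ds, expected",
        [
            (0.5, "young"),
            (1.5, "middle-age"),
            (2.5, "old"),
            (0.999, "young"),
            (1.0, "middle-age"),
            (2.0, "old"),
        ],
    )
    def test_thresholds(self, ds, expected):
        assert assign_age_class(ds) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_age_class(-0.1)


def _families_with_categories(cat_pairs):
    families, categories = [], {}
    for k, (c1, c2) in enumerate(cat_pairs):
        g1, g2 = f"g{2 * k}", f"g{2 * k + 1}"
        families.append(FamilyRecord(f"F{k}", g1, g2, dS=1.0, dN=0.1))
        categories[g1], categories[g2] = c1, c2
    return families, categories


class TestPairContextCounts:
    def test_reconstructs_published_table(self):
        pairs = []
        for (c1, c2), count in PAIR_CONTEXT_COUNTS.items():
            pairs.extend([(c1, c2)] * count)
        families, categories = _families_with_categories(pairs)
        table = pair_context_counts(families, categories)
        assert table.n == 1420
        assert np.array_equal(table.counts, pair_context_vector())
        assert table.diagonal_fraction == pytest.approx(453 / 1420)

    def test_single_te_free_family(self):
        families, categories = _families_with_categories([("TE-free", "TE-free")])
        table = pair_context_counts(families, categories)
        assert table.counts[0] == 1 and table.counts.sum() == 1

    def test_unordered_member_swap_invariance(self):
        pairs = [("TE-poor", "TE-rich"), ("TE-free", "TE-very-rich")]
        f1, c1 = _families_with_categories(pairs)
        f2, c2 = _families_with_categories([(b, a) for a, b in pairs])
        t1 = pair_context_counts(f1, c1)
        t2 = pair_context_counts(f2, c2)
        assert np.array_equal(t1.counts, t2.counts)

    def test_missing_category_names_gene(self):
        families, categories = _families_with_categories([("TE-free", "TE-free")])
        del categories["g1"]
        with pytest.raises(ValueError, match="g1"):
            pair_context_counts(families, categories)


class TestExpectedPairProbs:
    def test_two_equal_categories(self):
        q = expected_pair_probs([1, 1, 0, 0, 0])
        by_cell = dict(zip(PAIR_CELLS, q))
        assert by_cell[(0, 0)] == pytest.approx(0.25)
        assert by_cell[(0, 1)] == pytest.approx(0.5)
        assert by_cell[(1, 1)] == pytest.approx(0.25)
        assert sum(v for k, v in by_cell.items() if k not in {(0, 0), (0, 1), (1, 1)}) == 0

    def test_degenerate_single_category(self):
        q = expected_pair_probs([0, 0, 5, 0, 0])
        by_cell = dict(zip(PAIR_CELLS, q))
        assert by_cell[(2, 2)] == pytest.approx(1.0)

    def test_probs_sum_to_one_for_published_marginals(self):
        assert expected_pair_probs(duplicated_marginals()).sum() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            expected_pair_probs([0, 0, 0, 0, 0])


class TestChisqGof:
    def test_perfect_fit_is_zero(self):
        q = expected_pair_probs(duplicated_marginals())
        assert chisq_gof(1000 * q, q) == pytest.approx(0.0)

    def test_three_cell_toy(self):
        assert chisq_gof([30, 40, 30], [0.25, 0.5, 0.25]) == pytest.approx(4.0)

    def test_zero_probability_cell_with_observation_rejected(self):
        with pytest.raises(ValueError, match="zero-probability"):
            chisq_gof([5, 5], [1.0, 0.0])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = rng.dirichlet(np.ones(15))
            obs = rng.multinomial(500, q)
            expected = 500 * q
            brute = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
            assert chisq_gof(obs, q) == pytest.approx(brute, abs=1e-9)


class TestMonteCarloPvalue:
    def test_zero_statistic_gives_p_one(self):
        q = np.full(4, 0.25)
        assert monte_carlo_pvalue(250 * q, q, B=200, seed=0) == 1.0

    def test_p_on_lattice_and_reproducible(self):
        q = expected_pair_probs(duplicated_marginals())
        rng = np.random.default_rng(8)
        obs = rng.multinomial(1420, q)
        p1 = monte_carlo_pvalue(obs, q, B=999, seed=4)
        p2 = monte_carlo_pvalue(obs, q, B=999, seed=4)
        assert p1 == p2
        assert round(p1 * 1000) == pytest.approx(p1 * 1000)  # k / (B + 1) lattice
        assert 0 < p1 <= 1


class TestSameEnvironmentPartition:
    def test_fraction_equals_table_diagonal(self):
        pairs = [("TE-free", "TE-free"), ("TE-poor", "TE-poor"), ("TE-poor", "TE-rich")]
        families, categories = _families_with_categories(pairs)
        labels, frac = same_environment_partition(families, categories)
        assert frac == pytest.approx(2 / 3)
        assert labels["F0"] == "same" and labels["F2"] == "different"
        table = pair_context_counts(families, categories)
        assert frac == pytest.approx(table.diagonal_fraction)


class TestWithinFamilyCorrelation:
    def test_identical_values_give_rho_one(self):
        families, _ = _families_with_categories([("x", "x")] * 10)
        values = {}
        for k, fam in enumerate(families):
            values[fam.gene1_id] = float(k)
            values[fam.gene2_id] = float(k)
        res = within_family_correlation(values, families, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_negated_values_give_rho_minus_one(self):
        families, _ = _families_with_categories([("x", "x")] * 10)
        values = {}
        for k, fam in enumerate(families):
            values[fam.gene1_id] = float(k + 1)
            values[fam.gene2_id] = -float(k + 1)
        res = within_family_correlation(values, families, seed=0)
        assert res.rho == pytest.approx(-1.0)

    def test_fewer_than_three_pairs_not_computable(self):
        families, _ = _families_with_categories([("x", "x")] * 2)
        values = {g: 1.0 for fam in families for g in (fam.gene1_id, fam.gene2_id)}
        res = within_family_correlation(values, families, seed=0)
        assert not res.computable

    def test_missing_values_dropped(self):
        families, _ = _families_with_categories([("x", "x")] * 5)
        values = {}
        for k, fam in enumerate(families):
            values[fam.gene1_id] = float(k)
            values[fam.gene2_id] = float(k) if k != 2 else np.nan
        res = within_family_correlation(values, families, seed=0)
        assert res.n == 4


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_uniform_grid_collapses(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_step_up_two_values(self):
        assert bh_adjust([0.005, 0.1]) == pytest.approx([0.01, 0.1])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20))
    def test_q_at_least_p_and_monotone_on_sorted(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_attach_qvalues_skips_not_computable(self):
        families, _ = _families_with_categories([("x", "x")] * 5)
        values = {g: float(i) for i, fam in enumerate(families) for g in (fam.gene1_id, fam.gene2_id)}
        good = within_family_correlation(values, families, seed=0)
        bad = within_family_correlation({}, families, seed=0)
        out = attach_qvalues([good, bad])
        assert np.isfinite(out[0].q)
        assert np.isnan(out[1].q)


class TestDistributionComparisons:
    def test_identical_samples_ks_zero(self):
        x = np.arange(50, dtype=float)
        res = ks_two_sample(x, x)
        assert res["D"] == pytest.approx(0.0)

    def test_disjoint_supports_ks_one(self):
        res = ks_two_sample(np.arange(50.0), 100.0 + np.arange(50.0))
        assert res["D"] == pytest.approx(1.0)

    def test_kruskal_identical_groups_high_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        res = kruskal_wallis({"a": x[:100], "b": x[100:200], "c": x[200:]})
        assert res["df"] == 2
        assert res["p"] > 1e-4

    def test_small_group_not_computable(self):
        assert not kruskal_wallis({"a": [1.0], "b": [1.0, 2.0]})["computable"]
        assert not ks_two_sample([1.0], [1.0, 2.0])["computable"]
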