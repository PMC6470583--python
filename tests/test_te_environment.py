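import numpy as np
import pytest

from teneigh.intervals import GeneRecord, GenomicInterval, TEInsertion
from teneigh.te_environment import (
    CATEGORIES,
    CLUSTERED_CATEGORIES,
    CategoryModel,
    assign_categories,
    assign_category,
    category_distribution,
    compute_te_metrics,
    exhaustive_kmedoids_objective,
    fit_category_model,
)


def brute_metrics(gene, tes, flank=2000, chrom_end=None):
    """Per-base oracle for density and coverage."""
    start = max(0, gene.interval.start - flank)
    end = gene.interval.end + flank
    if chrom_end is not None:
        end = min(end, chrom_end)
    n = 0
    covered = np.zeros(end - start, dtype=bool)
    for te in tes:
        iv = te.interval
        if iv.chrom != gene.interval.chrom:
            continue
        lo, hi = max(iv.start, start), min(iv.end, end)
        if hi > lo:
            n += 1
            covered[lo - start : hi - start] = True
    length = end - start
    return n / length, covered.sum() / length


GENE = GeneRecord("g", GenomicInterval("chr1", 10_000, 11_000))


class TestComputeTEMetrics:
    def test_no_tes_is_te_free_point(self):
        env = compute_te_metrics(GENE, [])
        assert (env.density, env.coverage) == (0.0, 0.0)
        assert env.region.start == 8_000 and env.region.end == 13_000

    def test_two_disjoint_insertions(self):
        tes = [
            TEInsertion("t1", GenomicInterval("chr1", 8_500, 9_000)),
            TEInsertion("t2", GenomicInterval("chr1", 12_000, 12_500)),
        ]
        env = compute_te_metrics(GENE, tes)
        assert env.density == pytest.approx(4.0e-4)
        assert env.coverage == pytest.approx(0.2)
        assert (env.density, env.coverage) == pytest.approx(brute_metrics(GENE, tes))

    def test_overlapping_insertions_crossing_region_edge(self):
        tes = [
            TEInsertion("t1", GenomicInterval("chr1", 7_500, 8_500)),
            TEInsertion("t2", GenomicInterval("chr1", 8_400, 8_600)),
        ]
        env = compute_te_metrics(GENE, tes)
        assert env.density == pytest.approx(4.0e-4)
        assert env.coverage == pytest.approx(0.12)
        assert (env.density, env.coverage) == pytest.approx(brute_metrics(GENE, tes))

    def test_region_clipped_at_zero_and_chromosome_end(self):
        gene = GeneRecord("g", GenomicInterval("chr1", 500, 1_500))
        env = compute_te_metrics(gene, [], flank=2000, chrom_sizes={"chr1": 2_000})
        assert env.region.start == 0 and env.region.end == 2_000

    def test_adding_insertion_never_decreases_metrics(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tes = [
                TEInsertion(f"t{i}", GenomicInterval("chr1", int(s), int(s) + int(l)))
                for i, (s, l) in enumerate(
                    zip(rng.integers(0, 14_000, 5), rng.integers(1, 800, 5))
                )
            ]
            base = compute_te_metrics(GENE, tes)
            extra_start = int(rng.integers(8_000, 12_900))
            extra = TEInsertion("x", GenomicInterval("chr1", extra_start, extra_start + 50))
            more = compute_te_metrics(GENE, tes + [extra])
            assert more.density >= base.density
            assert more.coverage >= base.coverage

    def test_coverage_capped_at_one_with_nested_insertions(self):
        tes = [
            TEInsertion("t1", GenomicInterval("chr1", 0, 20_000)),
            TEInsertion("t2", GenomicInterval("chr1", 9_000, 12_000)),
        ]
        env = compute_te_metrics(GENE, tes)
        assert env.coverage == pytest.approx(1.0)


def blob_points():
    """Four well-separated (density, coverage) blobs of three points each."""
    centers = [(0.0003, 0.08), (0.0008, 0.20), (0.0014, 0.30), (0.0026, 0.42)]
    pts = []
    for cx, cy in centers:
        for dx, dy in ((0, 0), (0.00002, 0.004), (-0.00002, -0.004)):
            pts.append((cx + dx, cy + dy))
    return np.array(pts)


class TestCategoryModel:
    def test_separated_blobs_recover_density_ordering(self):
        model = fit_category_model(blob_points(), k=4, seed=0)
        assert model.labels == CLUSTERED_CATEGORIES
        assert np.all(np.diff(model.medoids[:, 0]) > 0)
        assert model.objective == pytest.approx(
            exhaustive_kmedoids_objective(blob_points(), 4)
        )

    def test_duplicated_points_make_distinct_points_medoids(self):
        # 12 points with only 4 distinct values -> those values are the
        # medoids and the objective is 0, as brute force confirms
        base = np.array([(0.0001, 0.05), (0.0005, 0.15), (0.001, 0.3), (0.002, 0.45)])
        pts = np.vstack([base, base, base])
        model = fit_category_model(pts, k=4, seed=0)
        assert model.objective == pytest.approx(0.0)
        assert exhaustive_kmedoids_objective(pts, 4) == pytest.approx(0.0)
        assert {tuple(m) for m in model.medoids} == {tuple(p) for p in base}

    def test_deterministic_given_points(self):
        m1 = fit_category_model(blob_points(), k=4, seed=0)
        m2 = fit_category_model(blob_points(), k=4, seed=0)
        assert np.array_equal(m1.medoids, m2.medoids)
        assert m1.objective == m2.objective

    def test_too_few_distinct_points_rejected(self):
        pts = np.array([(0.1, 0.1)] * 6 + [(0.2, 0.2)] * 6)
        with pytest.raises(ValueError, match="distinct"):
            fit_category_model(pts, k=4)

    def test_model_json_roundtrip(self, tmp_path):
        model = fit_category_model(blob_points(), k=4, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CategoryModel.from_json(path)
        assert np.allclose(back.medoids, model.medoids)
        assert back.labels == model.labels


class TestAssignCategory:
    def _model(self):
        return fit_category_model(blob_points(), k=4, seed=0)

    def test_zero_point_is_te_free_without_model(self):
        from teneigh.intervals import GenomicInterval as GI

        env = compute_te_metrics(GENE, [])
        assert assign_category(env, self._model()).category == "TE-free"

    def test_point_on_medoid_gets_that_label(self):
        model = self._model()
        env = compute_te_metrics(GENE, [])
        probe = env.__class__(
            gene_id="g", region=env.region,
            density=model.medoids[2, 0], coverage=model.medoids[2, 1],
            n_insertions=1,
        )
        assert assign_category(probe, model).category == model.labels[2]

    def test_equidistant_tie_goes_to_lower_label_index(self):
        model = CategoryModel(
            k=4,
            medoids=np.array([(0.001, 0.1), (0.003, 0.1), (0.005, 0.5), (0.007, 0.9)]),
            labels=CLUSTERED_CATEGORIES,
            objective=0.0,
        )
        env = compute_te_metrics(GENE, [])
        probe = env.__class__(
            gene_id="g", region=env.region, density=0.002, coverage=0.1, n_insertions=1
        )
        assert assign_category(probe, model).category == "TE-very-poor"


class TestCategoryDistribution:
    def _envs_with_counts(self, counts):
        env0 = compute_te_metrics(GENE, [])
        envs = []
        for cat, cnt in zip(CATEGORIES, counts):
            for _ in range(cnt):
                envs.append(env0.__class__(
                    gene_id="g", region=env0.region, density=0.0, coverage=0.0,
                    n_insertions=0, category=cat,
                ))
        return envs

    def test_published_duplicated_gene_percentages(self):
        df = category_distribution(self._envs_with_counts((109, 713, 915, 729, 374)))
        assert df["count"].sum() == 2840
        assert list(df["percent"].round(2)) == [3.84, 25.11, 32.22, 25.67, 13.17]

    def test_single_te_free_gene(self):
        df = category_distribution(self._envs_with_counts((1, 0, 0, 0, 0)))
        assert list(df["count"]) == [1, 0, 0, 0, 0]

    def test_order_invariance(self):
        envs = self._envs_with_counts((2, 3, 1, 0, 4))
        df1 = category_distribution(envs)
        df2 = category_distribution(list(reversed(envs)))
        assert list(df1["count"]) == list(df2["count"])

    def test_unassigned_category_rejected(self):
        env = compute_te_metrics(GENE, [])
        with pytest.raises(ValueError, match="category not assigned"):
            category_distribution([env])
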