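import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbstx import (
    MISSING,
    AlleleCountMatrix,
    FilterConfig,
    FilterReport,
    GenotypeMatrix,
    MatrixError,
    SampleMap,
    consolidate_lists,
    drop_sparse_samples,
    filter_loci,
    maf,
    mask_low_support,
    population_filter,
    site_alt_support,
)
from conftest import random_genotype_matrix


def _counts_matrix(loci, samples, ref, alt):
    return AlleleCountMatrix(loci, samples, np.array(ref), np.array(alt))


class TestMaskLowSupport:
    def test_entry_rules(self):
        gm = GenotypeMatrix(["c:1"], ["a", "b", "c"], np.array([[0, 1, 1]]))
        cm = _counts_matrix(["c:1"], ["a", "b", "c"], [[4, 2, 6]], [[0, 3, 4]])
        out = mask_low_support(gm, cm, FilterConfig())
        # depth 4 < 5 -> missing even for hom-ref
        assert out.data[0, 0] == MISSING
        # het on 3 alt reads (< 4) -> missing
        assert out.data[0, 1] == MISSING
        # depth 10, 4 alt reads: both thresholds met at the boundary
        assert out.data[0, 2] == 1

    def test_hom_ref_needs_only_depth(self):
        gm = GenotypeMatrix(["c:1"], ["a"], np.array([[0]]))
        cm = _counts_matrix(["c:1"], ["a"], [[8]], [[0]])
        assert mask_low_support(gm, cm).data[0, 0] == 0

    def test_axis_mismatch_rejected(self):
        gm = GenotypeMatrix(["c:1"], ["a"], np.array([[0]]))
        cm = _counts_matrix(["c:2"], ["a"], [[8]], [[0]])
        with pytest.raises(MatrixError, match="axes"):
            mask_low_support(gm, cm)

    def test_site_level_discovery_support(self):
        cm = _counts_matrix(
            ["c:1", "c:2"], ["a", "b"], [[10, 10], [10, 10]], [[2, 1], [2, 2]]
        )
        assert site_alt_support(cm, 4).tolist() == [False, True]


class TestMaf:
    def test_direct_count(self):
        col = np.array([0] * 8 + [1] + [2])
        assert maf(col) == pytest.approx(3 / 20)

    def test_monomorphic_is_zero(self):
        assert maf(np.zeros(10, dtype=int)) == 0.0

    def test_missing_excluded_from_both_sides(self):
        col = np.array([1] * 5 + [MISSING] * 5)
        assert maf(col) == pytest.approx(0.5)

    def test_all_missing_is_error(self):
        with pytest.raises(MatrixError, match="no data"):
            maf(np.full(4, MISSING))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=40))
    def test_maf_bounded(self, calls):
        if all(c == MISSING for c in calls):
            return
        assert 0.0 <= maf(np.array(calls)) <= 0.5


class TestFilterLoci:
    def test_missingness_then_maf_boundaries(self):
        data = np.array(
            [
                [0, 1, MISSING, MISSING, MISSING],  # 60% missing -> removed
                [0, 0, 0, 0, 1],                    # maf 0.1 -> kept at 0.02
                [0, 0, 0, 0, 0],                    # maf 0 -> removed
            ]
        )
        gm = GenotypeMatrix(["c:1", "c:2", "c:3"], list("abcde"), data)
        out, report = filter_loci(gm, FilterConfig())
        assert out.loci == ["c:2"]
        assert [s.name for s in report.stages] == ["locus_missingness", "maf"]
        assert report.stages[0].n_removed == 1 and report.stages[1].n_removed == 1

    def test_maf_threshold_is_inclusive(self):
        # 25 samples, 1 het -> maf exactly 0.02
        data = np.array([[1] + [0] * 24])
        gm = GenotypeMatrix(["c:1"], [f"s{i}" for i in range(25)], data)
        out, _ = filter_loci(gm, FilterConfig(maf_threshold=0.02))
        assert out.loci == ["c:1"]

    def test_empty_matrix_rejected(self):
        gm = GenotypeMatrix([], [], np.empty((0, 0), dtype=int))
        with pytest.raises(MatrixError, match="empty"):
            filter_loci(gm)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_idempotence(self, seed):
        gm = random_genotype_matrix(np.random.default_rng(seed))
        once, _ = filter_loci(gm, FilterConfig())
        twice, _ = filter_loci(once, FilterConfig()) if once.n_loci else (once, None)
        assert twice == once


class TestPopulationFilter:
    def test_retained_if_any_population_passes(self):
        # fixed in pop A, maf 0.10 in pop B
        data = np.array([[0, 0, 0, 0, 0, 1, 0, 0, 0, 0]])
        gm = GenotypeMatrix(["c:1"], [f"s{i}" for i in range(10)], data)
        popmap = SampleMap(population={f"s{i}": "A" if i < 5 else "B" for i in range(10)})
        retained, report = population_filter(gm, popmap, FilterConfig(maf_threshold=0.05))
        assert retained == ["c:1"]
        assert report.details["per_locus_populations"]["c:1"] == ["B"]

    def test_removed_when_all_populations_fail(self):
        # overall maf 0.03 but 0.025 in each of two equal populations
        col = [1] + [0] * 19 + [1] + [0] * 19
        gm = GenotypeMatrix(["c:1"], [f"s{i}" for i in range(40)], np.array([col]))
        popmap = SampleMap(population={f"s{i}": "A" if i < 20 else "B" for i in range(40)})
        retained, _ = population_filter(gm, popmap, FilterConfig(maf_threshold=0.05))
        assert retained == []

    def test_unmapped_sample_named(self, small_genotypes):
        popmap = SampleMap(population={s: "A" for s in small_genotypes.samples[:-1]})
        with pytest.raises(MatrixError, match="s4"):
            population_filter(small_genotypes, popmap)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_single_population_equals_global_filter(self, seed):
        gm = random_genotype_matrix(np.random.default_rng(seed))
        cfg = FilterConfig(maf_threshold=0.05)
        popmap = SampleMap(population={s: "only" for s in gm.samples})
        retained, _ = population_filter(gm, popmap, cfg)
        global_out, _ = filter_loci(gm, cfg)
        assert set(retained) == set(global_out.loci)


class TestConsolidateLists:
    def test_disjoint_union(self):
        merged, n = consolidate_lists({"x:1": ("G", "T")}, {"y:2": ("C", "A")})
        assert merged == {"x:1": ("G", "T"), "y:2": ("C", "A")} and n == 0

    def test_triallelic_across_groups_removed(self):
        merged, n = consolidate_lists({"x:1": ("G", "T")}, {"x:1": ("G", "A")})
        assert merged == {} and n == 1

    def test_idempotent_on_identical_lists(self):
        a = {"x:1": ("G", "T"), "y:2": ("C", "A")}
        merged, n = consolidate_lists(a, dict(a))
        assert merged == a and n == 0

    def test_reference_mismatch_rejected(self):
        with pytest.raises(MatrixError, match="reference mismatch"):
            consolidate_lists({"x:1": ("G", "T")}, {"x:1": ("C", "T")})


class TestDropSparseSamples:
    def test_thresholds(self, small_genotypes):
        data = small_genotypes.data.copy()
        data[:, 0] = MISSING
        gm = GenotypeMatrix(small_genotypes.loci, small_genotypes.samples, data)
        out, removed = drop_sparse_samples(gm, 0.9)
        assert removed == ["s0"]
        assert out.n_loci == gm.n_loci  # loci untouched
        out2, removed2 = drop_sparse_samples(gm, 1.0)
        assert removed2 == []

    def test_all_removed_is_error(self):
        gm = GenotypeMatrix(["c:1"], ["a"], np.array([[MISSING]]))
        with pytest.raises(MatrixError, match="all samples"):
            drop_sparse_samples(gm, 0.5)


class TestFilterReport:
    def test_counts_reconcile_and_chain(self):
        report = FilterReport()
        report.add_stage("a", 10, 4)
        stage = report.add_stage("b", 6, 1)
        assert stage.n_out == 5
        with pytest.raises(ValueError, match="chain"):
            report.add_stage("c", 99, 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(maf_threshold=1.5)
        with pytest.raises(ValueError):
            FilterConfig(min_depth=-1)
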