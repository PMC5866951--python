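import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gbstx import (
    MISSING,
    DosageMatrix,
    GenotypeMatrix,
    MatrixError,
    SampleMap,
    allele_freq_profile,
    ase_detection_prob,
    ase_table,
    distance_matrix,
    missingness_vs_reads,
    nei_distance,
    nj_tree,
    to_newick,
)

from tree_oracle import (
    TAXA,
    additive_matrix,
    five_taxon_topologies,
    tree_splits,
    true_splits,
)


class TestProfiles:
    def test_call_over_ploidy(self):
        assert allele_freq_profile(np.array([1]), 2)[0] == 0.5
        assert allele_freq_profile(np.array([3]), 4)[0] == 0.75
        assert np.isnan(allele_freq_profile(np.array([MISSING]), 2)[0])


class TestNeiDistance:
    def test_identical_profiles_are_zero(self):
        x = np.array([0.0, 0.5, 1.0, 0.25])
        assert nei_distance(x, x) == pytest.approx(0.0)

    def test_opposite_fixation_is_infinite(self):
        assert nei_distance(np.array([1.0]), np.array([0.0])) == math.inf

    def test_single_locus_closed_form(self):
        # x het (0.5), y fixed ref: D = -ln(0.5 / sqrt(0.5 * 1))
        d = nei_distance(np.array([0.5]), np.array([0.0]))
        assert d == pytest.approx(0.346574, abs=1e-6)

    def test_symmetry_and_pairwise_deletion(self, rng):
        for _ in range(20):
            x = rng.random(30)
            y = rng.random(30)
            x[rng.random(30) < 0.3] = np.nan
            y[rng.random(30) < 0.3] = np.nan
            if not (~np.isnan(x) & ~np.isnan(y)).any():
                continue
            assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))
            assert nei_distance(x, y) >= -1e-12

    def test_no_shared_loci_rejected(self):
        x = np.array([0.5, np.nan])
        y = np.array([np.nan, 0.5])
        with pytest.raises(MatrixError, match="no shared"):
            nei_distance(x, y)

    def test_distance_matrix_symmetric_zero_diagonal(self, rng):
        data = rng.integers(0, 3, size=(40, 6)).astype(np.int16)
        gm = GenotypeMatrix([f"c:{i}" for i in range(40)], [f"s{j}" for j in range(6)], data)
        d = distance_matrix(gm, ploidy=2)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_population_distances_use_mean_frequencies(self):
        data = np.array([[0, 0, 2, 2], [0, 0, 2, 2]])
        gm = GenotypeMatrix(["c:1", "c:2"], list("abcd"), data)
        pm = SampleMap(population={"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
        d = distance_matrix(gm, 2, pm)
        assert list(d.index) == ["P1", "P2"]
        assert d.loc["P1", "P2"] == math.inf  # fixed opposite in the two pops


class TestNJ:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("abc"), columns=list("abc")
        )
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}

    def test_recovers_additive_topology_and_distances(self, rng):
        topologies = five_taxon_topologies()
        assert len(topologies) == 15
        for k in range(20):
            cherry1, cherry2 = topologies[k % 15]
            lengths = rng.uniform(0.5, 2.0, size=7)
            d = additive_matrix(cherry1, cherry2, lengths)
            tree = nj_tree(d)
            assert tree_splits(tree, TAXA) == true_splits(cherry1, cherry2)
            # path metric reproduces the additive input
            for x, y in itertools.combinations(TAXA, 2):
                got = tree.find(x).distance(tree.find(y))
                assert got == pytest.approx(d.loc[x, y], abs=1e-9)

    def test_infinite_entries_rejected_with_guidance(self):
        d = pd.DataFrame(
            [[0, math.inf, 1], [math.inf, 0, 1], [1, 1, 0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.raises(ValueError, match="cap infinite"):
            nj_tree(d)

    def test_newick_serialization_round_trips_leaves(self):
        d = pd.DataFrame(
            [[0, 2, 3, 4], [2, 0, 3, 4], [3, 3, 0, 2], [4, 4, 2, 0]],
            index=list("wxyz"), columns=list("wxyz"),
        )
        nwk = to_newick(nj_tree(d))
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "wxyz")


class TestASE:
    def test_published_working_values(self):
        assert round(ase_detection_prob(0.9, 10), 2) == 0.65
        assert round(ase_detection_prob(0.9, 20), 2) == 0.88

    def test_degenerate_cases(self):
        assert ase_detection_prob(1.0, 50) == 0.0
        assert ase_detection_prob(0.3, 1) == 0.0
        assert ase_detection_prob(0.5, 0) == 0.0

    def test_maximized_at_balanced_expression_and_monotone_in_depth(self):
        for n in (2, 5, 10, 40):
            probs = [ase_detection_prob(p, n) for p in np.linspace(0, 1, 21)]
            assert max(probs) == pytest.approx(ase_detection_prob(0.5, n))
        for p in (0.1, 0.5, 0.9):
            vals = [ase_detection_prob(p, n) for n in range(1, 60)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo(self, rng):
        n, p, reps = 10, 0.9, 100_000
        draws = rng.binomial(n, p, size=reps)
        emp = np.mean((draws > 0) & (draws < n))
        se = (emp * (1 - emp) / reps) ** 0.5
        assert abs(emp - ase_detection_prob(p, n)) < 3 * se

    def test_table_layout(self):
        t = ase_table((0.9,), (10, 20))
        assert t.loc["90:10", 10] == pytest.approx(0.6513, abs=1e-4)
        assert t.loc["90:10", 20] == pytest.approx(0.8784, abs=1e-4)


class TestMissingnessVsReads:
    def test_sorted_summary(self):
        gm = GenotypeMatrix(
            ["c:1", "c:2"], ["hi", "lo"], np.array([[0, MISSING], [1, MISSING]])
        )
        df = missingness_vs_reads(gm, {"hi": 5000, "lo": 100})
        assert df["sample"].tolist() == ["lo", "hi"]
        assert df["missing_fraction"].tolist() == [1.0, 0.0]

    def test_unmatched_sample_rejected(self):
        gm = GenotypeMatrix(["c:1"], ["a"], np.array([[0]]))
        with pytest.raises(MatrixError, match="read counts"):
            missingness_vs_reads(gm, {})

    def test_monotone_trend_under_depth_driven_missingness(self):
        """When per-sample depth drives call probability, samples with more
        reads should show less missing data."""
        from gbstx.simulate import call_genotypes_from_counts, sample_reads

        rng = np.random.default_rng(9)
        truth = rng.integers(0, 3, size=(400, 12)).astype(np.int16)
        depths = np.linspace(0.5, 8, 12)
        ref = np.empty_like(truth, dtype=np.int32)
        alt = np.empty_like(truth, dtype=np.int32)
        for j, md in enumerate(depths):
            r, a = sample_reads(truth[:, [j]], 2, md, rng)
            ref[:, [j]], alt[:, [j]] = r, a
        gm = GenotypeMatrix(
            [f"c:{i}" for i in range(400)],
            [f"s{j}" for j in range(12)],
            call_genotypes_from_counts(ref, alt),
        )
        reads = {f"s{j}": int((ref + alt)[:, j].sum()) for j in range(12)}
        df = missingness_vs_reads(gm, reads)
        # the decay is nonlinear, so check the monotone (rank) association
        assert df["missing_fraction"].iloc[0] > df["missing_fraction"].iloc[-1]
        from scipy.stats import spearmanr

        rho = spearmanr(df["reads"], df["missing_fraction"]).statistic
        assert rho < -0.8
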