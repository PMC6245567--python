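"""Regional profiles, correlation-distance MDS, permutation nulls, Mantel R^2."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import rxscape as rx
from conftest import toy_matrix
from rxscape.containers import DistanceMatrix, RegionProfileMatrix
from rxscape.errors import ValidationError


def region_annotations(regions, providers):
    return pd.DataFrame(
        {
            "specialty": ["A"] * len(providers),
            "state": ["MA"] * len(providers),
            "county_fips": ["25025"] * len(providers),
            "cbsa": regions,
            "total_claims": [100] * len(providers),
        },
        index=pd.Index(providers, name="npi"),
    )


def make_region_profiles(values, regions, enrollees=None):
    values = np.asarray(values, dtype=float)
    enrollees = enrollees or {r: 1000.0 for r in regions}
    return RegionProfileMatrix(
        values=values,
        regions=pd.Index(regions, name="region"),
        features=pd.Index([f"f{j}" for j in range(values.shape[1])]),
        enrollees=pd.Series(enrollees),
    )


class TestRegionProfiles:
    def test_claims_per_enrollee_arithmetic(self):
        m = toy_matrix([[500]])
        ann = region_annotations(["X"], list(m.providers))
        prof = rx.region_profiles(m, ann, pd.Series({"X": 100.0}))
        assert prof.values[0, 0] == pytest.approx(5.0)

    def test_threshold_above_everything_is_error(self):
        m = toy_matrix([[500]])
        ann = region_annotations(["X"], list(m.providers))
        with pytest.raises(ValidationError, match="min_national_claims"):
            rx.region_profiles(m, ann, pd.Series({"X": 100.0}),
                               min_national_claims=10_000)

    def test_column_sums_match_groupby(self, trimmed_population):
        cfg, matrix, ann, _, _ = trimmed_population
        enr = rx.make_enrollee_table(cfg).set_index("region")["enrollees"]
        prof = rx.region_profiles(matrix, ann, enr)
        dense = matrix.to_dense()
        cols = matrix.drugs.get_indexer(prof.features)
        labels = ann["cbsa"].to_numpy()
        for i, r in enumerate(prof.regions):
            expect = dense[labels == r][:, cols].sum(axis=0) / enr[r]
            np.testing.assert_allclose(prof.values[i], expect)

    def test_strictly_greater_filter(self):
        m = toy_matrix([[100, 101]])
        ann = region_annotations(["X"], list(m.providers))
        prof = rx.region_profiles(m, ann, pd.Series({"X": 10.0}),
                                  min_national_claims=100)
        assert prof.values.shape[1] == 1  # only the 101-claim drug survives


class TestCorrelationDistance:
    def test_identical_rows_distance_zero(self):
        prof = make_region_profiles([[1, 2, 3], [1, 2, 3]], ["A", "B"])
        d = rx.correlation_distance(prof)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_distance_two(self):
        prof = make_region_profiles([[1, 2, 3], [3, 2, 1]], ["A", "B"])
        assert rx.correlation_distance(prof).values[0, 1] == pytest.approx(2.0)

    def test_hand_computed_pearson(self):
        prof = make_region_profiles([[1, 0, 0], [0, 1, 0]], ["A", "B"])
        assert rx.correlation_distance(prof).values[0, 1] == pytest.approx(1.5)

    def test_zero_variance_row_names_region(self):
        prof = make_region_profiles([[1, 1, 1], [1, 2, 3]], ["FLAT", "B"])
        with pytest.raises(ValidationError, match="FLAT"):
            rx.correlation_distance(prof)

    def test_invariants_on_random_profiles(self):
        rng = np.random.default_rng(0)
        prof = make_region_profiles(rng.random((6, 10)),
                                    [f"R{i}" for i in range(6)])
        d = rx.correlation_distance(prof).values
        assert np.allclose(np.diag(d), 0, atol=1e-12)
        assert np.allclose(d, d.T, atol=1e-12)
        assert (d >= 0).all() and (d <= 2).all()


class TestClassicalMds:
    def test_right_triangle_distances_recovered(self):
        D = DistanceMatrix(np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]]),
                           ["a", "b", "c"], "euclidean")
        coords, _ = rx.classical_mds(D, k=2)
        np.testing.assert_allclose(squareform(pdist(coords)), D.values, atol=1e-9)

    def test_equilateral_configuration(self):
        D = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"], "d")
        coords, _ = rx.classical_mds(D, k=2)
        dists = pdist(coords)
        np.testing.assert_allclose(dists, dists[0], atol=1e-9)

    def test_euclidean_point_sets_recovered(self):
        """Classical MDS exactly recovers distances from genuine point sets."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            X = rng.normal(size=(8, 3))
            D = DistanceMatrix(squareform(pdist(X)), list(range(8)), "euclidean")
            coords, _ = rx.classical_mds(D, k=3)
            np.testing.assert_allclose(squareform(pdist(coords)), D.values,
                                       atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(7, 2))
        D = squareform(pdist(X))
        perm = rng.permutation(7)
        a, _ = rx.classical_mds(DistanceMatrix(D, list(range(7)), "e"), k=2)
        b, _ = rx.classical_mds(
            DistanceMatrix(D[np.ix_(perm, perm)], list(range(7)), "e"), k=2
        )
        np.testing.assert_allclose(squareform(pdist(b)),
                                   squareform(pdist(a[perm])), atol=1e-9)


class TestPermutationNull:
    def test_permutation_preserves_counts_and_claims(self, trimmed_population):
        cfg, matrix, ann, _, _ = trimmed_population
        enr = rx.make_enrollee_table(cfg).set_index("region")["enrollees"]
        null = rx.permutation_null(matrix, ann, enr, n_perm=3, seed=1)
        # region set unchanged (counts preserved) and claims conserved
        assert set(null.regions) <= set(ann["cbsa"])
        assert null.permuted_coords.shape == (3, len(null.regions), 2)
        assert null.real_dispersion > 0

    def test_nperm_zero_rejected(self, trimmed_population):
        cfg, matrix, ann, _, _ = trimmed_population
        enr = rx.make_enrollee_table(cfg).set_index("region")["enrollees"]
        with pytest.raises(ValidationError):
            rx.permutation_null(matrix, ann, enr, n_perm=0)


class TestPairwiseRegionCompare:
    def test_fold_flagging(self):
        prof = make_region_profiles([[10.0, 10.0], [1.0, 10.0]], ["A", "B"])
        out = rx.pairwise_region_compare(prof, "A", "B", fold=5)
        assert out["flagged"].tolist() == [True, False]

    def test_planted_eightfold_effect_flagged_exactly(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(1, 2, size=10)
        other = base.copy()
        other[4] *= 8.0
        prof = make_region_profiles(np.vstack([base, other]), ["A", "B"])
        out = rx.pairwise_region_compare(prof, "A", "B", fold=5)
        assert out["flagged"].to_numpy().nonzero()[0].tolist() == [4]

    def test_zero_rates_excluded_unless_pseudocount(self):
        prof = make_region_profiles([[0.0, 2.0], [1.0, 2.0]], ["A", "B"])
        out = rx.pairwise_region_compare(prof, "A", "B")
        assert len(out) == 1
        out_pc = rx.pairwise_region_compare(prof, "A", "B", pseudocount=0.01)
        assert len(out_pc) == 2

    def test_unknown_region_is_error(self):
        prof = make_region_profiles([[1.0], [2.0]], ["A", "B"])
        with pytest.raises(ValidationError, match="nope"):
            rx.pairwise_region_compare(prof, "A", "nope")


class TestStateDistanceCorrelation:
    def test_affine_image_gives_r2_one(self):
        rng = np.random.default_rng(13)
        prev = pd.DataFrame(rng.random((8, 13)),
                            index=[f"S{i}" for i in range(8)])
        rx_df = prev * 3.0 + 1.0  # exact affine image: distances proportional
        _, _, r2 = rx.state_distance_correlation(rx_df, prev)
        assert r2 == pytest.approx(1.0)

    def test_three_state_closed_form(self):
        presc = pd.DataFrame([[0.0, 0], [1, 0], [0, 2]], index=["a", "b", "c"])
        prev = pd.DataFrame([[0.0, 0], [2, 0], [0, 1]], index=["a", "b", "c"])
        d_rx, d_dz, r2 = rx.state_distance_correlation(presc, prev)
        a, b = d_rx.condensed(), d_dz.condensed()
        expect = np.corrcoef(a, b)[0, 1] ** 2
        assert r2 == pytest.approx(expect)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(17)
        presc = pd.DataFrame(rng.random((6, 5)))
        prev = pd.DataFrame(rng.random((6, 4)))
        _, _, r2 = rx.state_distance_correlation(presc, prev)
        _, _, r2_scaled = rx.state_distance_correlation(presc * 7.0, prev * 0.2)
        assert r2_scaled == pytest.approx(r2)

    def test_identical_prevalence_is_error(self):
        presc = pd.DataFrame(np.random.default_rng(0).random((4, 3)))
        prev = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValidationError, match="zero variance"):
            rx.state_distance_correlation(presc, prev)

    def test_too_few_states_is_error(self):
        df = pd.DataFrame(np.eye(2))
        with pytest.raises(ValidationError):
            rx.state_distance_correlation(df, df)


def mannwhitney_oracle_p(a, b):
    """Two-sided exact p by enumerating all label assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    m = n1 * len(b) / 2.0
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    return float(np.mean([abs(u - m) >= abs(u_obs - m) - 1e-12 for u in us]))


class TestCompareRegionFractions:
    def test_identical_samples_p_one(self):
        _, p = rx.compare_region_fractions([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact(self):
        u, p = rx.compare_region_fractions([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 orderings

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(5)
        b = rng.random(6)
        _, p = rx.compare_region_fractions(a, b)
        assert p == pytest.approx(mannwhitney_oracle_p(a, b), abs=1e-12)

    def test_type_i_error_calibration(self):
        """Under the null the test rejects at ~alpha (Monte-Carlo check)."""
        rng = np.random.default_rng(19)
        rejections = 0
        trials = 400
        for _ in range(trials):
            a, b = rng.random(12), rng.random(12)
            _, p = rx.compare_region_fractions(a, b)
            rejections += p < 0.05
        rate = rejections / trials
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / trials)
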