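"""Ward clustering against independent oracles, dominance and region tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import rxscape as rx
from rxscape.containers import ProfileMatrix
from rxscape.errors import ValidationError


def make_profile(X, providers=None):
    X = np.asarray(X, dtype=float)
    if providers is None:
        providers = [f"p{i}" for i in range(len(X))]
    return ProfileMatrix(
        values=X,
        providers=pd.Index(providers, name="npi"),
        features=pd.Index([f"f{j}" for j in range(X.shape[1])]),
        normalized=False,
        totals=X.sum(axis=1),
    )


def annotate(providers, specialties, states=None):
    states = states or ["MA"] * len(providers)
    return pd.DataFrame(
        {
            "specialty": specialties,
            "state": states,
            "county_fips": ["25025"] * len(providers),
            "cbsa": [None] * len(providers),
            "total_claims": [100] * len(providers),
        },
        index=pd.Index(providers, name="npi"),
    )


def naive_ward_partitions(X):
    """Greedy Ward agglomeration via the cluster-mean increase formula.

    Independent of scipy: merges the pair whose union minimally increases
    total within-cluster variance, tracking the partition at every level.
    """
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    out = {len(clusters): {frozenset(c) for c in clusters}}
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = X[clusters[i]], X[clusters[j]]
            na, nb = len(a), len(b)
            d = na * nb / (na + nb) * np.sum((a.mean(0) - b.mean(0)) ** 2)
            if best is None or d < best[0]:
                best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        out[len(clusters)] = {frozenset(c) for c in clusters}
    return out


def brute_force_best_2partition(X):
    """Exhaustive minimum total within-cluster variance over all 2-partitions."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best = None
    for size in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), size):
            a = list(combo)
            b = [i for i in range(n) if i not in combo]
            cost = sum(((X[g] - X[g].mean(0)) ** 2).sum() for g in (a, b))
            if best is None or cost < best[0]:
                best = (cost, {frozenset(a), frozenset(b)})
    return best[1]


class TestWardCluster:
    def test_two_tight_pairs(self):
        """1-D points {0, 0.1, 10, 10.1}: the optimal 2-partition is recovered."""
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        assign = rx.ward_cluster(make_profile(X), n_clusters=2)
        got = {
            frozenset(np.flatnonzero(assign.labels.to_numpy() == c))
            for c in assign.labels.unique()
        }
        assert got == brute_force_best_2partition(X)

    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        assign = rx.ward_cluster(make_profile(X), n_clusters=6)
        assert assign.labels.nunique() == 6

    def test_duplicates_co_clustered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 3))
        X = np.vstack([base, base])
        assign = rx.ward_cluster(make_profile(X), n_clusters=5)
        labels = assign.labels.to_numpy()
        np.testing.assert_array_equal(labels[:5], labels[5:])

    def test_k_exceeding_n_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValidationError):
            rx.ward_cluster(make_profile(X), n_clusters=5)

    def test_merge_heights_non_decreasing(self, trimmed_population):
        _, matrix, _, _, _ = trimmed_population
        prof = rx.build_profiles(matrix)
        assign = rx.ward_cluster(prof, n_clusters=5)
        heights = assign.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_lance_williams_oracle(self, seed):
        """All flat cuts match a from-scratch greedy Ward agglomeration, n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        X = rng.normal(size=(n, 3))
        prof = make_profile(X)
        oracle = naive_ward_partitions(X)
        for k in range(1, n + 1):
            assign = rx.ward_cluster(prof, n_clusters=k)
            got = {
                frozenset(np.flatnonzero(assign.labels.to_numpy() == c))
                for c in assign.labels.unique()
            }
            assert got == oracle[k], f"n={n}, k={k}"

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        perm = rng.permutation(20)
        a = rx.ward_cluster(make_profile(X), n_clusters=4).labels.to_numpy()
        b = rx.ward_cluster(make_profile(X[perm]), n_clusters=4).labels.to_numpy()
        assert adjusted_rand_score(a[perm], b) == pytest.approx(1.0)


class TestClusterDominance:
    def _assignment(self, labels, providers):
        return rx.ClusterAssignment(
            labels=pd.Series(labels, index=pd.Index(providers, name="npi")),
            linkage_matrix=np.zeros((0, 4)),
            n_clusters=len(set(labels)),
            criterion="ward",
            metric="euclidean",
        )

    def test_dominant_fraction(self):
        providers = ["a", "b", "c", "d"]
        assign = self._assignment([1, 1, 1, 1], providers)
        ann = annotate(providers, ["A", "A", "A", "B"])
        rep = rx.cluster_dominance(assign, ann)
        row = rep.per_cluster.loc[1]
        assert row["dominant_specialty"] == "A"
        assert row["dominant_fraction"] == pytest.approx(0.75)
        assert row["second_specialty"] == "B"

    def test_single_specialty_population(self):
        providers = [f"p{i}" for i in range(6)]
        assign = self._assignment([1, 1, 2, 2, 3, 3], providers)
        rep = rx.cluster_dominance(assign, annotate(providers, ["A"] * 6))
        assert (rep.per_cluster["dominant_fraction"] == 1.0).all()
        assert rep.summary_fraction == 1.0

    def test_tie_flagged_and_lexicographic(self):
        providers = ["a", "b"]
        assign = self._assignment([1, 1], providers)
        rep = rx.cluster_dominance(assign, annotate(providers, ["B", "A"]))
        row = rep.per_cluster.loc[1]
        assert row["tie"]
        assert row["dominant_specialty"] == "A"

    def test_summary_monotone_in_threshold(self, trimmed_population):
        _, matrix, ann, _, _ = trimmed_population
        prof = rx.build_profiles(matrix)
        assign = rx.ward_cluster(prof, n_clusters=8)
        fracs = [
            rx.cluster_dominance(assign, ann, threshold=t).summary_fraction
            for t in (0.1, 0.3, 0.5, 0.9)
        ]
        assert fracs == sorted(fracs, reverse=True)

    def test_planted_specialties_dominate_clusters(self):
        """5-specialty generation, k=20: >= 90% of clusters specialty-dominated."""
        cfg = rx.default_config(n_providers=800, n_drugs=60, n_classes=12,
                                n_specialties=5, seed=37)
        matrix, ann, _, _ = rx.generate_population(cfg)
        matrix, _ = rx.drop_empty(matrix)
        prof = rx.build_profiles(matrix)
        assign = rx.ward_cluster(prof, n_clusters=20)
        rep = rx.cluster_dominance(assign, ann.loc[prof.providers], threshold=0.30)
        assert rep.summary_fraction >= 0.9


class TestClusterRegionCross:
    def test_single_region_population(self):
        providers = ["a", "b", "c"]
        assign = TestClusterDominance()._assignment([1, 1, 2], providers)
        ann = annotate(providers, ["A"] * 3, states=["MA"] * 3)
        table = rx.cluster_region_cross(assign, ann, "federal_region")
        assert list(table.columns) == ["Region 1"]
        assert (table["Region 1"] == 1.0).all()

    def test_rows_sum_to_one(self, trimmed_population):
        _, matrix, ann, _, _ = trimmed_population
        prof = rx.build_profiles(matrix)
        assign = rx.ward_cluster(prof, n_clusters=6)
        table = rx.cluster_region_cross(assign, ann, "state")
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_state_goes_to_unresolved(self):
        providers = ["a", "b"]
        assign = TestClusterDominance()._assignment([1, 1], providers)
        ann = annotate(providers, ["A", "A"], states=["MA", "ZZ"])
        table = rx.cluster_region_cross(assign, ann, "census_region")
        assert "unresolved" in table.columns

    def test_planted_region_effect_shows_in_composition(self):
        """With strong 2-region effects some cluster deviates from the global mix."""
        cfg = rx.default_config(n_providers=600, n_drugs=40, n_classes=8,
                                n_specialties=2, n_regions=2,
                                region_effect_sd=1.0, seed=41)
        matrix, ann, _, _ = rx.generate_population(cfg)
        matrix, _ = rx.drop_empty(matrix)
        ann = ann.loc[matrix.providers]
        prof = rx.build_profiles(matrix)
        assign = rx.ward_cluster(prof, n_clusters=8)
        table = rx.cluster_region_cross(assign, ann, "state")
        global_share = ann["state"].value_counts(normalize=True)
        sizes = assign.labels.value_counts()
        deviates = False
        for cid in table.index:
            n = sizes[cid]
            for st_code in table.columns:
                p = global_share.get(st_code, 0.0)
                sd = np.sqrt(p * (1 - p) / n)
                if abs(table.loc[cid, st_code] - p) > 2 * sd:
                    deviates = True
        assert deviates
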