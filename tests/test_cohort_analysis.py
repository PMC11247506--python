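import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnatriage import cohort_analysis as ca
from cnatriage.core_io import MutationRecord


class TestEncodeMutation:
    def test_full_published_scale_round_trips(self):
        expected = {
            "Missense Mutation": 2.0,
            "In-frame Insertion": 1.9,
            "In-frame Deletion": 1.8,
            "Nonstop Mutation": 1.7,
            "RNA Alteration": 1.6,
            "Splice Site mutation": 0.3,
            "Frameshift Insertion": 0.2,
            "Frameshift Deletion": 0.1,
            "Nonsense Mutation": 0.0,
        }
        assert ca.MUTATION_ENCODING == expected
        for label, value in expected.items():
            assert ca.encode_mutation(label) == value

    def test_canonical_maf_spellings_accepted(self):
        assert ca.encode_mutation("Missense_Mutation") == 2.0
        assert ca.encode_mutation("Frame_Shift_Del") == 0.1

    def test_absence_encodes_neutral(self):
        assert ca.encode_mutation(None) == 1.0

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(KeyError, match="Missense"):
            ca.encode_mutation("Telepathic Mutation")

    def test_multiple_mutations_farthest_from_neutral_wins(self):
        recs = [
            MutationRecord("S1", "G", "Missense_Mutation"),  # 2.0, |1.0| from neutral
            MutationRecord("S1", "G", "Splice_Site"),  # 0.3, |0.7|
        ]
        mat = ca.encode_mutation_matrix(recs, ["G"], ["S1"])
        assert mat.loc["S1", "G"] == 2.0

    def test_tie_prefers_loss(self):
        recs = [
            MutationRecord("S1", "G", "In_Frame_Del"),  # 1.8, |0.8|
            MutationRecord("S1", "G", "Frame_Shift_Ins"),  # 0.2, |0.8|
        ]
        mat = ca.encode_mutation_matrix(recs, ["G"], ["S1"])
        assert mat.loc["S1", "G"] == 0.2


class TestBuildFeatureMatrix:
    def test_joins_on_shared_samples(self):
        acn = pd.DataFrame({"R1": [1.0, 1.2], "R2": [0.8, 1.0]}, index=["S1", "S2"])
        mut = pd.DataFrame({"TP53": [2.0, 0.0]}, index=["S2", "S3"])
        joined, n_excluded = ca.build_feature_matrix(acn, mut)
        assert joined.shape == (1, 3)
        assert list(joined.index) == ["S2"]
        assert n_excluded == 2

    def test_empty_intersection_errors(self):
        acn = pd.DataFrame({"R1": [1.0]}, index=["S1"])
        mut = pd.DataFrame({"TP53": [2.0]}, index=["S9"])
        with pytest.raises(ValueError):
            ca.build_feature_matrix(acn, mut)


class TestGowerDistance:
    def test_identical_rows_are_zero(self):
        assert ca.gower_distance(
            [1.0, "a"], [1.0, "a"], ["numeric", "categorical"], [4.0, 0.0]
        ) == 0.0

    def test_one_categorical_mismatch_of_three(self):
        d = ca.gower_distance(
            ["a", "b", "c"], ["a", "b", "x"],
            ["categorical"] * 3, [0.0] * 3,
        )
        assert d == pytest.approx(1 / 3)

    def test_numeric_scaled_by_range(self):
        d = ca.gower_distance([2.0], [4.0], ["numeric"], [4.0])
        assert d == pytest.approx(0.5)

    def test_missing_features_renormalized(self):
        d = ca.gower_distance(
            [np.nan, "a"], [1.0, "b"], ["numeric", "categorical"], [2.0, 0.0]
        )
        assert d == 1.0  # only the mismatching categorical counts

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            ca.gower_distance([np.nan], [1.0], ["numeric"], [2.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.lists(st.floats(min_value=0, max_value=10), min_size=3, max_size=3),
        b=st.lists(st.floats(min_value=0, max_value=10), min_size=3, max_size=3),
    )
    def test_symmetric_and_bounded(self, a, b):
        kinds = ["numeric"] * 3
        ranges = [10.0] * 3
        d_ab = ca.gower_distance(a, b, kinds, ranges)
        d_ba = ca.gower_distance(b, a, kinds, ranges)
        assert d_ab == pytest.approx(d_ba)
        assert 0.0 <= d_ab <= 1.0


def brute_force_average_linkage(X: np.ndarray):
    """From-scratch agglomerative clustering oracle (average linkage).

    Returns the merge sequence as (frozenset_a, frozenset_b, height) using the
    mean pairwise inter-cluster Euclidean distance.
    """
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            a, b = clusters[i], clusters[j]
            d = np.mean([dist[p, q] for p in a for q in b])
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return merges


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        X = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]], index=list("abc"))
        res = ca.hierarchical_cluster(X)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 2}
        assert first[2] == pytest.approx(0.0)

    def test_pairwise_distances_match_double_loop(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        got = squareform(pdist(X))
        expected = np.array(
            [[np.sqrt(((r - s) ** 2).sum()) for s in X] for r in X]
        )
        assert np.allclose(got, expected)

    def test_matches_brute_force_oracle_merge_sequence(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        res = ca.hierarchical_cluster(pd.DataFrame(X), metric="euclidean")
        oracle = brute_force_average_linkage(X)
        # replay scipy's linkage into cluster sets
        clusters = {i: frozenset([i]) for i in range(8)}
        for step, row in enumerate(res.linkage):
            a, b, height = int(row[0]), int(row[1]), row[2]
            oa, ob, oh = oracle[step]
            assert {clusters[a], clusters[b]} == {oa, ob}
            assert height == pytest.approx(oh)
            clusters[8 + step] = clusters[a] | clusters[b]
        assert len(clusters[8 + len(oracle) - 1]) == 8

    def test_merge_heights_nondecreasing(self, default_cohort):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(12, 5)))
        res = ca.hierarchical_cluster(X)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_permuting_samples_preserves_heights(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(7, 3)), index=[f"s{i}" for i in range(7)])
        perm = X.sample(frac=1.0, random_state=1)
        h1 = np.sort(ca.hierarchical_cluster(X).linkage[:, 2])
        h2 = np.sort(ca.hierarchical_cluster(perm).linkage[:, 2])
        assert np.allclose(h1, h2)
        assert sorted(ca.hierarchical_cluster(perm).leaf_order) == sorted(X.index)

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError):
            ca.hierarchical_cluster(pd.DataFrame([[1.0]]))

    def test_gower_metric_tree_on_mixed_data(self):
        X = pd.DataFrame(
            {"acn": [1.0, 1.1, 2.0], "mut": ["a", "a", "b"]},
            index=list("xyz"),
        )
        res = ca.hierarchical_cluster(X, metric="gower")
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=[f"s{i}" for i in range(5)])
        nwk = ca.cluster_to_newick(ca.hierarchical_cluster(X))
        assert nwk.endswith(";")
        for name in X.index:
            assert name in nwk


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand-computed observed-vs-expected risk-set tally, chi-square 1 df."""
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.ones(len(times_a)), np.zeros(len(times_b))])
    O = E = V = 0.0
    for t in np.unique(all_times[all_events == 1]):
        at_risk = all_times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((all_times == t) & (all_events == 1)).sum()
        d1 = ((all_times == t) & (all_events == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestSurvival:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        stat, p = ca.logrank_test(t, e, t.copy(), e.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_set_tally_oracle(self):
        ta, ea = np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])
        tb, eb = np.array([4.0, 5.0, 6.0]), np.array([1, 1, 1])
        stat, _ = ca.logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_oracle_agreement_with_censoring(self):
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(10, 20), rng.exponential(14, 25)
        ea = (rng.random(20) < 0.7).astype(int)
        eb = (rng.random(25) < 0.7).astype(int)
        stat, _ = ca.logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_no_events_flagged(self):
        t = np.array([1.0, 2.0])
        z = np.array([0, 0])
        with pytest.raises(ValueError):
            ca.logrank_test(t, z, t, z)

    def test_km_starts_at_one_nonincreasing_matches_empirical(self):
        times = np.array([2.0, 4.0, 4.0, 7.0, 9.0])
        events = np.ones(5, dtype=int)
        km = ca.km_curve(times, events)
        surv = km["survival"].to_numpy()
        assert surv[0] == pytest.approx(1.0)
        assert np.all(np.diff(surv) <= 1e-12)
        # no censoring: KM equals the empirical survivor function
        for t, s in zip(km["time"], surv):
            assert s == pytest.approx((times > t).mean())

    def test_swapping_groups_inverts_hazard_ratio(self):
        rng = np.random.default_rng(9)
        n = 100
        grp = rng.random(n) < 0.5
        times = rng.exponential(np.where(grp, 5.0, 10.0))
        events = np.ones(n, dtype=int)
        hr = ca.cox_hazard_ratio(grp.astype(int), times, events)
        hr_swapped = ca.cox_hazard_ratio(1 - grp.astype(int), times, events)
        assert hr_swapped == pytest.approx(1.0 / hr, rel=1e-6)


class TestSurvivalStratify:
    def make_calls(self):
        return pd.DataFrame(
            {"S1": ["amp"], "S2": ["neutral"], "S3": ["amp"], "S4": ["del"]},
            index=["G"],
        )

    def records(self):
        from cnatriage.core_io import SurvivalRecord

        return [
            SurvivalRecord(f"S{i}", "OS", float(i * 100), True) for i in range(1, 5)
        ]

    def test_amplified_direction_defines_group_one(self):
        altered, other = ca.survival_stratify(
            self.make_calls(), "G", "amplified", self.records(), "OS"
        )
        assert set(altered["sample_id"]) == {"S1", "S3"}
        assert set(other["sample_id"]) == {"S2", "S4"}

    def test_deleted_direction_defines_group_one(self):
        altered, _ = ca.survival_stratify(
            self.make_calls(), "G", "deleted", self.records(), "OS"
        )
        assert set(altered["sample_id"]) == {"S4"}

    def test_never_altered_gene_flagged(self):
        calls = pd.DataFrame({"S1": ["neutral"], "S2": ["neutral"]}, index=["G"])
        res = ca.gene_survival_analysis(calls, "G", "amplified", self.records(), "OS")
        assert res.flagged and res.logrank_p is None

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError):
            ca.survival_stratify(self.make_calls(), "G", "amplified", self.records(), "DFS")
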