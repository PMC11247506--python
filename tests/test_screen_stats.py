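import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnatriage import screen_stats as ss


class TestElementaryRates:
    @pytest.mark.parametrize(
        "empty,uneclosed,expected", [(10, 0, 100.0), (0, 10, 0.0), (43, 7, 86.0)]
    )
    def test_eclosion_rate(self, empty, uneclosed, expected):
        assert ss.eclosion_rate(empty, uneclosed) == pytest.approx(expected)

    def test_eclosion_undefined_without_pupae(self):
        assert math.isnan(ss.eclosion_rate(0, 0))

    @pytest.mark.parametrize(
        "nontubby,tubby,expected", [(50, 100, 50.0), (100, 100, 100.0), (0, 100, 0.0)]
    )
    def test_relative_pupariation(self, nontubby, tubby, expected):
        assert ss.relative_pupariation(nontubby, tubby) == pytest.approx(expected)

    def test_relative_pupariation_can_exceed_hundred(self):
        assert ss.relative_pupariation(150, 100) == pytest.approx(150.0)

    def test_pupariation_undefined_for_balanced_stock(self):
        assert math.isnan(ss.relative_pupariation(10, 0))

    @pytest.mark.parametrize(
        "green,disc,expected", [(0, 1000, 0.0), (1000, 1000, 1.0), (250, 1000, 0.25)]
    )
    def test_overgrowth_ratio(self, green, disc, expected):
        assert ss.overgrowth_ratio(green, disc) == pytest.approx(expected)

    def test_green_exceeding_disc_rejected(self):
        with pytest.raises(ValueError):
            ss.overgrowth_ratio(1001, 1000)

    @settings(max_examples=50, derandomize=True)
    @given(
        empty=st.integers(1, 100),
        uneclosed=st.integers(0, 100),
        scale=st.integers(2, 20),
    )
    def test_rates_scale_invariant(self, empty, uneclosed, scale):
        assert ss.eclosion_rate(empty, uneclosed) == pytest.approx(
            ss.eclosion_rate(empty * scale, uneclosed * scale)
        )
        assert ss.overgrowth_ratio(empty, empty + uneclosed) == pytest.approx(
            ss.overgrowth_ratio(empty * scale, (empty + uneclosed) * scale)
        )


def mann_whitney_exact_oracle(a, b):
    """Two-sided exact Mann–Whitney p by enumeration of all assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_stat(group_idx):
        r = sum(ranks[pooled[i]] for i in group_idx)
        return r - n_a * (n_a + 1) / 2

    obs = u_stat(range(n_a))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    n = len(us)
    p_le = sum(u <= obs for u in us) / n
    p_ge = sum(u >= obs for u in us) / n
    return min(1.0, 2 * min(p_le, p_ge))


class TestCompareToControl:
    def test_identical_groups_p_one(self):
        _, p = ss.compare_to_control([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert p == 1.0

    def test_exact_rank_case_two_twentieths(self):
        test_used, p = ss.compare_to_control([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert test_used == "mann_whitney"
        assert p == pytest.approx(2 / 20)

    def test_small_groups_match_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        for n_a, n_b in [(3, 3), (4, 4), (5, 3), (7, 7), (2, 6), (6, 8), (8, 8)]:
            a = rng.normal(0, 1, n_a)
            b = rng.normal(1, 1, n_b)
            test_used, p = ss.compare_to_control(a, b)
            if test_used == "mann_whitney":  # n >= 8 groups may pass the gate
                assert p == pytest.approx(mann_whitney_exact_oracle(a, b), rel=1e-9)

    def test_large_normal_groups_use_t(self):
        rng = np.random.default_rng(11)
        test_used, _ = ss.compare_to_control(
            rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        )
        assert test_used == "student_t"

    def test_zero_variance_falls_back_to_ranks(self):
        test_used, _ = ss.compare_to_control([5.0] * 10, [5.0] * 9 + [6.0])
        assert test_used == "mann_whitney"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ss.compare_to_control([1.0], [2.0, 3.0])


class TestBhFdr:
    def brute_force_step_up(self, pvalues):
        m = len(pvalues)
        order = np.argsort(pvalues)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, pvalues[i] * m / rank_from_top)
            adj[i] = val
            prev = val
        return np.minimum(adj, 1.0)

    def test_published_style_example(self):
        assert np.allclose(
            ss.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_itself(self):
        assert ss.bh_fdr([0.037]) == pytest.approx([0.037])

    def test_matches_step_up_oracle_on_all_permutations(self):
        base = [0.001, 0.02, 0.049, 0.2, 0.51, 0.97]
        for size in range(1, 7):
            for perm in itertools.permutations(base[:size]):
                assert np.allclose(
                    ss.bh_fdr(list(perm)), self.brute_force_step_up(list(perm))
                )

    def test_sorted_input_gives_nondecreasing_output(self):
        p = sorted([0.001, 0.3, 0.02, 0.9, 0.04])
        adj = ss.bh_fdr(p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.bh_fdr([0.5, 1.2])


class TestHitRules:
    @pytest.mark.parametrize(
        "pvalues,expected",
        [([0.03, 0.04], True), ([0.03, 0.20], False), ([0.06], False), ([0.01, 0.2, 0.04], True)],
    )
    def test_lethality_needs_two_independent_experiments(self, pvalues, expected):
        assert ss.lethality_hit(pvalues) is expected

    @pytest.mark.parametrize(
        "p,fdr,expected",
        [(0.03, 0.05, True), (0.03, 0.15, False), (0.06, 0.05, False)],
    )
    def test_dual_phenotype_criterion(self, p, fdr, expected):
        assert ss.phenotype_hit(p, fdr) is expected

    @pytest.mark.parametrize(
        "lethality,trans,grow,expected",
        [
            (True, True, None, True),
            (True, False, True, True),
            (True, False, False, False),
            (False, True, True, False),
        ],
    )
    def test_driver_classification(self, lethality, trans, grow, expected):
        assert ss.classify_driver(lethality, trans, grow) is expected


class TestTally:
    def make_calls(self, spec):
        calls = []
        for group, n_tested, n_driver in spec:
            for i in range(n_tested):
                calls.append(
                    ss.ScreenCall(gene=f"{group}_{i}", group=group, driver=i < n_driver)
                )
        return calls

    def test_three_of_four_is_75_percent(self):
        tally = ss.tally_hit_rates(self.make_calls([("G1G", 4, 3)]))
        row = tally.iloc[0]
        assert row["n_tested"] == 4 and row["n_driver"] == 3
        assert row["percent"] == 75

    def test_zero_drivers_zero_percent(self):
        tally = ss.tally_hit_rates(self.make_calls([("G4", 3, 0)]))
        assert tally.iloc[0]["percent"] == 0

    def test_rounding_half_up(self):
        tally = ss.tally_hit_rates(self.make_calls([("G2I", 8, 3)]))  # 37.5 -> 38
        assert tally.iloc[0]["percent"] == 38

    def test_totals_conserved_across_groups(self):
        spec = [("G1I", 9, 5), ("G1G", 4, 3), ("G2G", 17, 13)]
        tally = ss.tally_hit_rates(self.make_calls(spec))
        assert tally["n_driver"].sum() == sum(d for _, _, d in spec)
        assert tally["n_tested"].sum() == sum(t for _, t, _ in spec)


class TestDrugRescue:
    def test_identical_arms_p_one(self):
        p, direction = ss.drug_rescue_test([50, 60, 70, 80], [80, 70, 60, 50])
        assert p == 1.0 and direction == "none"

    def test_exact_two_over_seventy(self):
        p, direction = ss.drug_rescue_test(
            [80.0, 82.0, 85.0, 88.0], [50.0, 52.0, 55.0, 58.0]
        )
        assert p == pytest.approx(2 / 70)
        assert direction == "rescue"

    def test_uniformly_lower_drug_is_worse(self):
        p, direction = ss.drug_rescue_test(
            [10.0, 12.0, 15.0, 18.0], [50.0, 52.0, 55.0, 58.0]
        )
        assert direction == "worse"

    def test_solvent_mismatch_rejected(self):
        with pytest.raises(ValueError, match="solvent"):
            ss.drug_rescue_test([1.0, 2.0], [3.0, 4.0], "water", "DMSO")


class TestScreenWorkflow:
    def test_planted_drivers_recovered_from_replicate_table(self, default_screen):
        table, line_truth = default_screen
        calls = ss.analyze_screen(table)
        truth_by_gene = line_truth[line_truth["gene"] != "w"].set_index("gene")
        drivers_called = {g for g, c in calls.items() if c.driver}
        planted = set(truth_by_gene.index[truth_by_gene["is_driver"]])
        non_planted = set(truth_by_gene.index[~truth_by_gene["is_driver"]])
        assert planted <= drivers_called | set()  # all planted drivers detected
        assert len(drivers_called & non_planted) <= max(1, len(non_planted) // 10)

    def test_overgrowth_only_drivers_need_the_conditional_assay(self, default_screen):
        table, line_truth = default_screen
        calls = ss.analyze_screen(table)
        grow_only = line_truth[
            (line_truth["mechanism"] == "overgrowth") & line_truth["is_driver"]
        ]["gene"]
        for gene in grow_only:
            assert calls[gene].overgrowth_tested
            assert calls[gene].driver

    def test_non_enhancing_lines_not_tested_one_sided(self):
        # a line whose mean is below control is never a phenotype candidate
        rng = np.random.default_rng(12)
        rows = []
        for gene, shift in [("w", 0.0), ("GX", -3.0)]:
            for exp in ("E1", "E2"):
                for rep in range(8):
                    rows.append(
                        dict(
                            line_id="L0" if gene == "w" else "L1",
                            gene=gene, group="control", direction="rnai",
                            experiment_id=exp, replicate_id=f"r{rep}",
                            assay="translocation",
                            empty_pupal_cases="", uneclosed_pupae="",
                            tubby_pupae="", nontubby_pupae="",
                            translocated_cells=max(0, round(rng.normal(5 + shift, 1))),
                            green_pixels="", disc_pixels="",
                        )
                    )
        import pandas as pd

        calls = ss.analyze_screen(pd.DataFrame(rows))
        assert not calls["GX"].translocation_hit
        assert calls["GX"].translocation_p == 1.0
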