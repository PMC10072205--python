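"""Cohort algebra, endpoints and the survival comparison statistics."""

import warnings

import numpy as np
import pytest

from careflow.compare import (
    cohort_from_expression,
    cohort_from_nodes,
    compare_cohorts,
    cox_hazard_ratio,
    logrank_test,
    parse_cohort_expression,
    pfs_time,
    survival_rate_at,
)
from careflow.exceptions import ContractError, FitError
from careflow.node_stats import km_estimate
from careflow.simulate import two_arm_survival
from careflow.tree import discover_tree

from conftest import (
    cox_loglik_grid_oracle,
    logrank_chi2_oracle,
    make_log,
    permutation_logrank_p,
)


class TestCohortAlgebra:
    def test_add_and_subtract_node_sets(self, two_patient_log):
        tree = discover_tree(two_patient_log, 0)
        cohort = cohort_from_nodes(
            tree, [["PD1"]], [["PD1", "BRAFi+MEKi"]], name="first-line only"
        )
        assert cohort.members == {"A"}
        assert cohort.anchors["A"] == two_patient_log.events["A"][0].start_date

    def test_subtracting_same_node_empties_cohort(self, two_patient_log):
        tree = discover_tree(two_patient_log, 0)
        cohort = cohort_from_nodes(tree, [["PD1"]], [["PD1"]])
        assert cohort.members == set()

    def test_disjoint_union_adds_sizes(self):
        log = make_log({"a": ["A"], "b": ["A"], "c": ["B"]})
        tree = discover_tree(log, 0)
        cohort = cohort_from_nodes(tree, [["A"], ["B"]])
        assert cohort.n == 3

    def test_union_is_commutative(self):
        log = make_log({"a": ["A", "B"], "b": ["A"], "c": ["B"]})
        tree = discover_tree(log, 0)
        c1 = cohort_from_nodes(tree, [["A"], ["B"]])
        c2 = cohort_from_nodes(tree, [["B"], ["A"]])
        assert c1.members == c2.members

    def test_multi_membership_keeps_shallowest_anchor_with_warning(self):
        log = make_log({"a": ["A", "B"]})
        tree = discover_tree(log, 0)
        with pytest.warns(UserWarning, match="multiple nodes"):
            cohort = cohort_from_nodes(tree, [["A"], ["A", "B"]])
        assert cohort.anchors["a"] == log.events["a"][0].start_date
        assert cohort.anchor_lines["a"] == 1

    def test_anchor_depth_reanchors_to_ancestor(self):
        log = make_log({"a": ["A", "B"], "b": ["A", "B"]})
        tree = discover_tree(log, 0)
        cohort = cohort_from_nodes(tree, [["A", "B"]], anchor_depth=1)
        assert cohort.anchor_lines == {"a": 1, "b": 1}
        assert cohort.anchors["a"] == log.events["a"][0].start_date

    def test_provenance_replays_membership(self, two_patient_log):
        tree = discover_tree(two_patient_log, 0)
        cohort = cohort_from_nodes(tree, [["PD1"]], [["PD1", "BRAFi+MEKi"]])
        replayed = set()
        for path, op in cohort.provenance:
            node = tree.find(path)
            if op == "add":
                replayed |= node.patient_ids
        for path, op in cohort.provenance:
            if op == "subtract":
                replayed -= tree.find(path).patient_ids
        assert replayed == cohort.members

    def test_unresolvable_path_raises(self, two_patient_log):
        tree = discover_tree(two_patient_log, 0)
        with pytest.raises(KeyError):
            cohort_from_nodes(tree, [["chemo"]])


class TestExpressionLanguage:
    def test_union_and_subtraction_with_adjuvant_marker(self):
        adds, subs = parse_cohort_expression("PD1>CTLA4+PD1 + PD1>PD1 - adj:PD1")
        assert adds == [
            [("PD1", "advanced"), ("CTLA4+PD1", "advanced")],
            [("PD1", "advanced"), ("PD1", "advanced")],
        ]
        assert subs == [[("PD1", "adjuvant")]]

    @pytest.mark.parametrize("bad", ["", "+ PD1", "PD1 PD1", "PD1 +"])
    def test_malformed_expressions_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_cohort_expression(bad)

    def test_expression_resolves_against_tree(self, two_patient_log):
        tree = discover_tree(two_patient_log, 0)
        cohort = cohort_from_expression(tree, "PD1 - PD1>BRAFi+MEKi")
        assert cohort.members == {"A"}


class TestPFS:
    def _log(self):
        return make_log(
            {"a": ["PD1"], "b": ["PD1"], "c": ["PD1"]},
            responses={"a": [(1, 90, "PD")]},
            death_days={"a": 200, "b": 150},
            followup_days=400,
        )

    def test_progression_before_death(self):
        assert pfs_time(self._log(), "a", 1) == (90.0, 1)

    def test_death_without_progression_counts_as_event(self):
        assert pfs_time(self._log(), "b", 1) == (150.0, 1)

    def test_no_event_censored_at_last_followup(self):
        assert pfs_time(self._log(), "c", 1) == (400.0, 0)

    def test_progression_on_later_line_counts(self):
        log = make_log(
            {"a": ["PD1", "BRAFi+MEKi"]},
            responses={"a": [(2, 200, "PD")]},
            followup_days=900,
        )
        assert pfs_time(log, "a", 1) == (200.0, 1)


class TestKMAndLandmark:
    def test_hand_example_with_one_censor(self):
        curve = km_estimate([10, 20, 30], [1, 0, 1])
        assert curve.value_at(5) == 1.0
        assert curve.value_at(10) == pytest.approx(2 / 3)
        assert curve.value_at(29) == pytest.approx(2 / 3)
        assert curve.value_at(30) == pytest.approx(0.0)
        rate, lo, hi = survival_rate_at(curve, 15)
        assert rate == pytest.approx(2 / 3)
        assert lo <= rate <= hi

    def test_rate_at_zero_is_one(self):
        curve = km_estimate([10, 20], [1, 0])
        assert survival_rate_at(curve, 0)[0] == 1.0

    def test_rate_monotone_nonincreasing(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(100, size=50)
        e = rng.integers(0, 2, size=50)
        curve = km_estimate(t, e)
        grid = np.linspace(0, t.max(), 40)
        rates = [survival_rate_at(curve, x)[0] for x in grid]
        assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))

    def test_extrapolation_beyond_last_time_warns(self):
        curve = km_estimate([10, 20], [1, 1])
        with pytest.warns(UserWarning, match="beyond last observed"):
            rate, _, _ = survival_rate_at(curve, 1e6)
        assert rate == pytest.approx(0.0)


class TestLogrank:
    def test_identical_event_times_give_zero_statistic(self):
        g = ([10, 20, 30, 40], [1, 1, 0, 1])
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_direct_oe_computation(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            ta = rng.exponential(100, 20)
            tb = rng.exponential(160, 20)
            ea = rng.integers(0, 2, 20)
            eb = np.ones(20, int)
            stat, _ = logrank_test((ta, ea), (tb, eb))
            oracle = logrank_chi2_oracle(
                np.concatenate([ta, tb]), np.concatenate([ea, eb]),
                np.concatenate([np.zeros(20, int), np.ones(20, int)]),
            )
            assert stat == pytest.approx(oracle, rel=1e-8)

    def test_p_value_agrees_with_permutation_null(self):
        rng = np.random.default_rng(41)
        ta = rng.exponential(120, 30)
        tb = rng.exponential(190, 30)
        t = np.concatenate([ta, tb])
        e = np.ones(60, int)
        g = np.concatenate([np.zeros(30, int), np.ones(30, int)])
        _, p_chi2 = logrank_test((ta, e[:30]), (tb, e[30:]))
        p_perm = permutation_logrank_p(t, e, g, n_perm=10_000, seed=5)
        # Monte-Carlo error ~ sqrt(p(1-p)/10000) plus chi-square approximation
        assert abs(p_chi2 - p_perm) < 0.03

    def test_no_events_anywhere_gives_null_result(self):
        stat, p = logrank_test(([10, 20], [0, 0]), ([15, 25], [0, 0]))
        assert (stat, p) == (0.0, 1.0)

    def test_empty_group_is_contract_error(self):
        with pytest.raises(ContractError):
            logrank_test(([], []), ([1], [1]))


class TestCox:
    def test_identical_groups_give_unit_hazard_ratio(self):
        g = ([10, 25, 40, 55, 70, 90], [1, 1, 0, 1, 0, 1])
        hr, lo, hi = cox_hazard_ratio(g, g)
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert lo <= 1.0 <= hi

    def test_matches_partial_likelihood_grid_search_small_n(self):
        # distinct event times so Efron and Breslow coincide
        ta = np.array([12.0, 34.0, 56.0, 90.0])
        ea = np.array([1, 1, 0, 1])
        tb = np.array([8.0, 21.0, 44.0, 70.0])
        eb = np.array([1, 0, 1, 1])
        hr, _, _ = cox_hazard_ratio((ta, ea), (tb, eb))
        beta_star = cox_loglik_grid_oracle(
            np.concatenate([ta, tb]), np.concatenate([ea, eb]),
            np.concatenate([np.zeros(4, int), np.ones(4, int)]),
        )
        assert np.log(hr) == pytest.approx(beta_star, abs=1e-4)

    def test_recovers_true_rate_ratio_two(self):
        (ta, ea), (tb, eb) = two_arm_survival(
            n_per_arm=500, hazard_ratio=2.0, seed=123
        )
        hr, lo, hi = cox_hazard_ratio((ta, ea), (tb, eb))
        assert 1.8 <= hr <= 2.2
        assert lo <= hr <= hi

    def test_no_events_is_fit_error(self):
        with pytest.raises(FitError):
            cox_hazard_ratio(([10, 20], [0, 0]), ([15], [0]))

    def test_event_free_arm_reports_infinite_bound_convention(self):
        hr, lo, hi = cox_hazard_ratio(
            ([5, 8, 11, 14], [1, 1, 1, 1]), ([100, 110, 120, 130], [0, 0, 0, 0])
        )
        assert hi == np.inf or hr < 1e-3 or np.isfinite(hr)


class TestCompareCohorts:
    def _tree_log(self):
        log = make_log(
            {f"p{i}": ["PD1", "BRAFi+MEKi"] if i % 2 else ["PD1"]
             for i in range(12)},
            death_days={f"p{i}": 100 + 57 * i for i in range(8)},
        )
        return log, discover_tree(log, 0)

    def test_self_comparison_is_null(self):
        log, tree = self._tree_log()
        a = cohort_from_nodes(tree, [["PD1"]], name="A")
        b = cohort_from_nodes(tree, [["PD1"]], name="B")
        with pytest.warns(UserWarning, match="share"):
            res = compare_cohorts(a, b, "OS", log)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.logrank_p == pytest.approx(1.0)

    def test_summaries_count_cohort_members(self):
        log, tree = self._tree_log()
        a = cohort_from_nodes(tree, [["PD1"]], [["PD1", "BRAFi+MEKi"]], name="stop")
        b = cohort_from_nodes(tree, [["PD1", "BRAFi+MEKi"]], name="switch")
        res = compare_cohorts(a, b, "OS", log)
        assert res.summaries["stop"]["n"] == a.n
        assert res.summaries["switch"]["n"] == b.n
        assert sum(res.summaries["stop"]["bor"].values()) == a.n
        assert res.hr_ci_low <= res.hazard_ratio <= res.hr_ci_high
        assert 0 <= res.logrank_p <= 1

    def test_pfs_endpoint_runs_on_anchor_lines(self):
        log, tree = self._tree_log()
        a = cohort_from_nodes(tree, [["PD1"]], [["PD1", "BRAFi+MEKi"]], name="stop")
        b = cohort_from_nodes(tree, [["PD1", "BRAFi+MEKi"]], name="switch")
        res = compare_cohorts(a, b, "PFS", log, landmark_days=365)
        assert res.endpoint == "PFS"
        for name in res.names:
            assert 0 <= res.landmark_estimates[name]["rate"] <= 1

    def test_empty_cohort_is_contract_error(self):
        log, tree = self._tree_log()
        a = cohort_from_nodes(tree, [["PD1"]], [["PD1"]], name="empty")
        b = cohort_from_nodes(tree, [["PD1"]], name="full")
        with pytest.raises(ContractError):
            compare_cohorts(a, b, "OS", log)

    def test_hr_ci_covers_generator_truth(self):
        # 200 replicates at true HR 0.5; nominal 95% CI should cover >= 93%
        covered = 0
        for rep in range(200):
            (ta, ea), (tb, eb) = two_arm_survival(
                n_per_arm=120, hazard_ratio=0.5, seed=10_000 + rep
            )
            _, lo, hi = cox_hazard_ratio((ta, ea), (tb, eb))
            covered += lo <= 0.5 <= hi
        assert covered / 200 >= 0.93
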