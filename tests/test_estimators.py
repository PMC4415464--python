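"""Point estimators: MLE, stage-wise, UMVCUE (vs enumeration), median-unbiased."""

import itertools

import numpy as np
import pytest

from twostagedx import (
    ScenarioSpec,
    TrialData,
    TrialStoppedError,
    TwoStageDesign,
    estimator_study,
    median_unbiased,
    mle,
    restricted_support,
    stage_estimates,
    sufficient_statistic,
    umvcue,
)
from conftest import SMALL_DESIGN_PANEL, enumerate_conditional_expectations


def _trial_k1(n1, c, n2, x, y):
    return TrialData(design=TwoStageDesign(n1=(n1,), c=(c,), n2=n2), x=(x,), y=y)


class TestNaiveEstimators:
    def test_mle_pools_both_stages(self):
        assert mle(_trial_k1(50, 0, 50, 35, 35)) == pytest.approx(0.70)
        assert mle(_trial_k1(26, 0, 22, 19, 14)) == pytest.approx(33 / 48)
        assert mle(_trial_k1(50, 0, 50, 0, 0)) == 0.0

    def test_stage_estimates(self):
        s1, s2 = stage_estimates(_trial_k1(50, 0, 50, 35, 25))
        assert s1 == pytest.approx(0.70) and s2 == pytest.approx(0.50)

    def test_stopped_trial_raises_typed_error(self):
        design = TwoStageDesign(n1=(10,), c=(5,), n2=5)
        trial = TrialData(design=design, x=(3,), y=None)
        for f in (mle, stage_estimates, umvcue):
            with pytest.raises(TrialStoppedError):
                f(trial)


class TestRestrictedSupport:
    def test_unrestricted_when_no_cutoff(self):
        trial = _trial_k1(50, 0, 50, 20, 20)  # z1 = 40
        supp = restricted_support(sufficient_statistic(trial), trial.design)
        assert supp.values == tuple(range(0, 41)) and supp.kind == "A'"

    def test_futility_bound_truncates(self):
        trial = _trial_k1(50, 35, 50, 36, 34)  # z1 = 70
        supp = restricted_support(sufficient_statistic(trial), trial.design)
        # lower: z1 - n1M = 20; upper: z1 - c_M = 35 < n2
        assert supp.values == tuple(range(20, 36))

    def test_tie_direction_sets_kind(self):
        design = TwoStageDesign(n1=(5, 5), c=(0, 0), n2=5)
        t_lead = TrialData(design=design, x=(4, 3), y=2)  # M=0 < runner 1
        t_trail = TrialData(design=design, x=(3, 4), y=2)  # M=1 > runner 0
        assert restricted_support(sufficient_statistic(t_lead), design).kind == "B"
        assert restricted_support(sufficient_statistic(t_trail), design).kind == "A"

    def test_runner_up_bound_matches_enumeration(self):
        # all (x_M, y) with x_M + y = z1 and x_M/5 >= 3/5 (tie admissible)
        design = TwoStageDesign(n1=(5, 5), c=(0, 0), n2=5)
        trial = TrialData(design=design, x=(4, 3), y=2)  # z1 = 6, runner count 3
        supp = restricted_support(sufficient_statistic(trial), design)
        expected = [
            y
            for y in range(design.n2 + 1)
            if 0 <= 6 - y <= 5 and (6 - y) / 5 >= 3 / 5
        ]
        assert list(supp.values) == expected

    def test_observed_y_always_member(self):
        for design in SMALL_DESIGN_PANEL:
            for key, (_, trial) in enumerate_conditional_expectations(
                design, (0.5,) * design.K
            ).items():
                supp = restricted_support(sufficient_statistic(trial), design)
                assert trial.y in supp


class TestUMVCUE:
    def test_reduces_to_mle_without_selection(self):
        design = TwoStageDesign(n1=(6,), c=(0,), n2=6)
        for x in range(7):
            for y in range(7):
                trial = TrialData(design=design, x=(x,), y=y)
                assert umvcue(trial) == pytest.approx(mle(trial), abs=1e-15)

    @pytest.mark.parametrize("design", SMALL_DESIGN_PANEL, ids=str)
    def test_equals_enumeration_oracle_and_s_invariant(self, design):
        """UMVCUE == E[Y/n2 | Z, Q] from brute force, for every reachable
        conditioning class, identically across the truth used to enumerate."""
        reference = None
        for s in (0.3, 0.5, 0.9):
            oracle = enumerate_conditional_expectations(design, (s,) * design.K)
            if reference is None:
                reference = {k: v for k, (v, _) in oracle.items()}
                for key, (expected, trial) in oracle.items():
                    got = umvcue(trial)
                    assert got == pytest.approx(expected, rel=1e-12, abs=1e-13)
            else:
                assert oracle.keys() == reference.keys()
                for key, (expected, _) in oracle.items():
                    assert expected == pytest.approx(
                        reference[key], rel=1e-9, abs=1e-11
                    )

    def test_equals_mle_when_support_reaches_n2(self):
        for design in SMALL_DESIGN_PANEL:
            for _, (_, trial) in enumerate_conditional_expectations(
                design, (0.5,) * design.K
            ).items():
                supp = restricted_support(sufficient_statistic(trial), design)
                if supp.hi == design.n2:
                    assert umvcue(trial) == pytest.approx(mle(trial), abs=1e-13)

    def test_single_point_support_returns_forced_value(self):
        # z1 = n1M + n2 forces x_M = n1M and y = n2
        trial = _trial_k1(10, 4, 8, 10, 8)
        supp = restricted_support(sufficient_statistic(trial), trial.design)
        assert supp.values == (8,)
        assert umvcue(trial) == pytest.approx(1.0)

    def test_range_and_convex_hull(self):
        for design in SMALL_DESIGN_PANEL:
            for _, (_, trial) in enumerate_conditional_expectations(
                design, (0.7,) * design.K
            ).items():
                u = umvcue(trial)
                supp = restricted_support(sufficient_statistic(trial), design)
                assert supp.lo / design.n2 - 1e-12 <= u <= supp.hi / design.n2 + 1e-12
                assert 0.0 <= u <= 1.0
                assert 0.0 <= mle(trial) <= 1.0

    def test_conditionally_unbiased_in_simulation(self):
        design = TwoStageDesign(n1=(50, 50), c=(35, 35), n2=50)
        res = estimator_study(
            ScenarioSpec(S=(0.5, 0.7), design=design, nsim=30_000, seed=2024)
        )
        umv = res.table.loc["umvcue"]
        assert abs(umv["bias"]) < 3 * umv["bias_se"]
        m = res.table.loc["mle"]
        assert m["bias"] > 3 * m["bias_se"]  # selection biases the MLE high


class TestMedianUnbiased:
    def test_vacuous_case_matches_binomial_median_estimate(self):
        trial = _trial_k1(50, 0, 50, 35, 35)
        est = median_unbiased(trial)
        assert 0.69 <= est <= 0.71

    def test_boundary_observation_saturates_upper_root(self):
        trial = _trial_k1(10, 4, 8, 10, 8)  # z1 = n1M + n2, top of the support
        est = median_unbiased(trial)
        # upper half-probability root saturates at 1; estimate stays in range
        # and above the MLE-scale value for a perfect observation
        assert 0.9 < est <= 1.0
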