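"""Screening decision tree: classification, strategy evaluation, reporting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glaucoma_cea import (
    ScreeningTest,
    StateRewards,
    Strategy,
    TransitionModel,
    ValidationError,
    classify,
    evaluate_strategy,
    per_patient_cost,
    time_savings_report,
)


def make_strategy(sens=0.865, spec=0.786, screen_cost=0.0, service=0.0, test=True):
    treated = TransitionModel.from_progression([0.1, 0.05, 0.05, 0.05], "treated")
    untreated = TransitionModel.from_progression([0.3, 0.3, 0.3, 0.3], "untreated")
    return Strategy(
        name="s",
        test=ScreeningTest(sens, spec, screen_cost) if test else None,
        treated_transitions=treated,
        untreated_transitions=untreated,
        annual_service_cost=service,
    )


REWARDS = StateRewards([1.0, 0.87, 0.79, 0.64, 0.5], [10.0, 30.0, 50.0, 80.0, 150.0])


class TestClassify:
    def test_perfect_test(self):
        c = classify(0.03, ScreeningTest(1.0, 1.0))
        assert c.p_true_positive == pytest.approx(0.03)
        assert c.p_true_negative == pytest.approx(0.97)
        assert c.p_false_positive == 0 and c.p_false_negative == 0

    def test_published_test_characteristics(self):
        c = classify(0.03, ScreeningTest(0.865, 0.786))
        assert c.p_true_positive == pytest.approx(0.02595)
        assert c.p_false_negative == pytest.approx(0.00405)
        assert c.p_false_positive == pytest.approx(0.20758)
        assert c.p_true_negative == pytest.approx(0.76242)

    def test_zero_prevalence(self):
        c = classify(0.0, ScreeningTest(0.8, 0.7))
        assert c.p_true_positive == 0 and c.p_false_negative == 0
        assert c.p_false_positive + c.p_true_negative == pytest.approx(1.0)

    def test_out_of_range_prevalence(self):
        with pytest.raises(ValidationError):
            classify(1.2, ScreeningTest(0.8, 0.7))

    @given(
        prevalence=st.floats(0, 1),
        sens=st.floats(0, 1),
        spec=st.floats(0, 1),
    )
    def test_probabilities_always_sum_to_one(self, prevalence, sens, spec):
        c = classify(prevalence, ScreeningTest(sens, spec))
        total = c.p_true_positive + c.p_false_negative + c.p_false_positive + c.p_true_negative
        assert total == pytest.approx(1.0, abs=1e-12)


class TestEvaluateStrategy:
    def test_zero_prevalence_degenerates_to_at_risk_branch(self):
        """With nobody diseased and a free screen, the strategy cost is the
        at-risk branch cost exactly (plus nothing else)."""
        strat = make_strategy(spec=1.0)
        out = evaluate_strategy(strat, 0.0, REWARDS, 10, 0.03)
        at_risk = out.component_traces["at_risk"]
        assert out.expected_cost == pytest.approx(at_risk.discounted_cost_cum)
        assert out.expected_qaly == pytest.approx(at_risk.discounted_qaly_cum)

    def test_zero_sensitivity_free_screen_equals_comparator(self):
        """sensitivity=0 with no screening cost is exactly a no-screening arm."""
        screened = make_strategy(sens=0.0, spec=1.0, screen_cost=0.0)
        comparator = make_strategy(test=False)
        a = evaluate_strategy(screened, 0.3, REWARDS, 20, 0.03)
        b = evaluate_strategy(comparator, 0.3, REWARDS, 20, 0.03)
        assert a.expected_cost == pytest.approx(b.expected_cost, abs=1e-12)
        assert a.expected_qaly == pytest.approx(b.expected_qaly, abs=1e-12)

    def test_branch_weights_follow_classification(self):
        out = evaluate_strategy(make_strategy(), 0.3, REWARDS, 10, 0.0)
        w = out.branch_weights
        assert w["treated"] == pytest.approx(0.3 * 0.865)
        assert w["untreated"] == pytest.approx(0.3 * 0.135)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_false_positives_pay_confirmatory_workup(self):
        strat = make_strategy(spec=0.786)
        base = evaluate_strategy(strat, 0.3, REWARDS, 10, 0.0, confirmatory_cost=0.0)
        conf = evaluate_strategy(strat, 0.3, REWARDS, 10, 0.0, confirmatory_cost=200.0)
        fp = conf.classification.p_false_positive
        assert conf.expected_cost - base.expected_cost == pytest.approx(200.0 * fp)
        assert conf.expected_qaly == pytest.approx(base.expected_qaly)

    @pytest.mark.parametrize("seed", range(20))
    def test_qaly_monotone_in_sensitivity(self, seed):
        """When treatment slows progression, catching more true cases never
        lowers expected QALYs."""
        rng = np.random.default_rng(seed)
        untreated_p = rng.uniform(0.05, 0.6, 4)
        treated_p = untreated_p * rng.uniform(0.2, 0.95, 4)
        prevalence = rng.uniform(0.05, 0.6)
        qalys = []
        for sens in (0.2, 0.5, 0.9):
            strat = Strategy(
                name="s",
                test=ScreeningTest(sens, 0.8),
                treated_transitions=TransitionModel.from_progression(treated_p, "treated"),
                untreated_transitions=TransitionModel.from_progression(
                    untreated_p, "untreated"
                ),
            )
            qalys.append(
                evaluate_strategy(strat, prevalence, REWARDS, 25, 0.03).expected_qaly
            )
        assert qalys[0] <= qalys[1] + 1e-12 <= qalys[2] + 2e-12

    def test_service_cost_applies_to_all_branches(self):
        plain = evaluate_strategy(make_strategy(service=0.0), 0.3, REWARDS, 10, 0.0)
        svc = evaluate_strategy(make_strategy(service=5.0), 0.3, REWARDS, 10, 0.0)
        # 11 accrual points x 5 CAD on every branch, undiscounted
        assert svc.expected_cost - plain.expected_cost == pytest.approx(55.0)


class TestReportingHelpers:
    def test_per_patient_cost(self):
        assert per_patient_cost(0, 300) == 0
        assert per_patient_cost(1000, 4) == 250
        with pytest.raises(ValidationError):
            per_patient_cost(1000, 0)

    @pytest.mark.parametrize(
        "tele, inperson, absolute, relative",
        [(78, 115, 37, 100 * 37 / 115), (60, 60, 0, 0), (115, 115, 0, 0)],
    )
    def test_time_savings(self, tele, inperson, absolute, relative):
        saving = time_savings_report(tele, inperson)
        assert saving.absolute_minutes == pytest.approx(absolute)
        assert saving.relative_percent == pytest.approx(relative)

    def test_time_savings_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            time_savings_report(0, 100)
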