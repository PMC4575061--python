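"""Screening decision layer over the Markov cohort engine.

A screening strategy classifies an at-risk population once at entry using
its test's sensitivity and specificity.  True positives enter the treated
Markov arm, false negatives the untreated (natural-history) arm, and
everyone without glaucoma — whether the test called them positive or not —
remains in the at-risk branch, where false positives additionally incur one
confirmatory in-person work-up.  Per-patient expected cost and effectiveness
are the probability-weighted totals over the branches plus the per-patient
screening cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .markov import (
    N_STATES,
    HealthState,
    StateRewards,
    TransitionModel,
    run_cohort,
)

__all__ = [
    "ScreeningTest",
    "Strategy",
    "ClassificationResult",
    "StrategyOutcome",
    "classify",
    "evaluate_strategy",
    "per_patient_cost",
    "time_savings_report",
    "TimeSavings",
]


@dataclass(frozen=True)
class ScreeningTest:
    """Test characteristics and program costs of a screening modality.

    ``cost_per_screen`` is the one-off per-patient cost of being screened;
    ``fixed_program_cost`` and ``capacity`` (patients per year) record the
    program-level figures it derives from (see :func:`per_patient_cost`).
    """

    sensitivity: float
    specificity: float
    cost_per_screen: float = 0.0
    fixed_program_cost: float = 0.0
    capacity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValidationError(f"sensitivity must lie in [0, 1], got {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValidationError(f"specificity must lie in [0, 1], got {self.specificity}")
        if self.cost_per_screen < 0 or self.fixed_program_cost < 0:
            raise ValidationError("screening costs must be >= 0")
        if self.capacity < 1:
            raise ValidationError(f"capacity must be >= 1, got {self.capacity}")


@dataclass(frozen=True)
class ClassificationResult:
    """Joint probabilities of disease status x test result."""

    p_true_positive: float
    p_false_negative: float
    p_false_positive: float
    p_true_negative: float

    def __post_init__(self) -> None:
        total = (
            self.p_true_positive
            + self.p_false_negative
            + self.p_false_positive
            + self.p_true_negative
        )
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"classification probabilities must sum to 1, got {total}")


def classify(prevalence: float, test: ScreeningTest) -> ClassificationResult:
    """Expand prevalence and test characteristics into joint probabilities.

    ``p_true_positive = prevalence * sensitivity`` and
    ``p_true_negative = (1 - prevalence) * specificity``; the complements
    fill the false-negative and false-positive cells.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValidationError(f"prevalence must lie in [0, 1], got {prevalence}")
    tp = prevalence * test.sensitivity
    fn = prevalence - tp
    tn = (1.0 - prevalence) * test.specificity
    fp = (1.0 - prevalence) - tn
    return ClassificationResult(tp, fn, fp, tn)


@dataclass(frozen=True)
class Strategy:
    """A screening arm, or the standard-of-care comparator when ``test`` is None.

    ``annual_service_cost`` is the recurring per-patient, per-year cost of
    delivering the strategy's care (monitoring visits, program running
    costs); it is added to every health state's annual cost in all branches.
    ``entry_state`` is where patients with glaucoma start their Markov arm;
    the reference set uses the glaucoma-suspect (at-risk) state so that the
    arm trace covers the pre-diagnostic phase.
    """

    name: str
    treated_transitions: TransitionModel
    untreated_transitions: TransitionModel
    test: Optional[ScreeningTest] = None
    annual_service_cost: float = 0.0
    entry_state: HealthState = HealthState.AT_RISK

    def __post_init__(self) -> None:
        if self.annual_service_cost < 0:
            raise ValidationError("annual service cost must be >= 0")

    @property
    def effective_test(self) -> ScreeningTest:
        """The comparator behaves as a zero-sensitivity, free, perfect-specificity test."""
        if self.test is not None:
            return self.test
        return ScreeningTest(sensitivity=0.0, specificity=1.0, cost_per_screen=0.0)


class TimeSavings(NamedTuple):
    absolute_minutes: float
    relative_percent: float


def per_patient_cost(total_program_cost: float, patients_served: int) -> float:
    """Divide a program-level cost across the patients it serves per year."""
    if patients_served < 1:
        raise ValidationError(f"patients_served must be >= 1, got {patients_served}")
    return float(total_program_cost) / float(patients_served)


def time_savings_report(tele_minutes: float, inperson_minutes: float) -> TimeSavings:
    """Absolute and relative visit-time savings of remote over in-person care."""
    if tele_minutes <= 0 or inperson_minutes <= 0:
        raise ValidationError("visit durations must be > 0 minutes")
    absolute = inperson_minutes - tele_minutes
    return TimeSavings(
        absolute_minutes=float(absolute),
        relative_percent=float(100.0 * absolute / inperson_minutes),
    )


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-patient expected discounted cost and QALYs with branch traces."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    classification: ClassificationResult
    component_traces: dict

    @property
    def branch_weights(self) -> dict:
        c = self.classification
        return {
            "treated": c.p_true_positive,
            "untreated": c.p_false_negative,
            "at_risk": c.p_false_positive + c.p_true_negative,
        }


def _entry_dist(state: HealthState) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[int(state)] = 1.0
    return v


_STAY_AT_RISK = TransitionModel(np.eye(N_STATES), arm_label="at_risk")


def evaluate_strategy(
    strategy: Strategy,
    prevalence: float,
    rewards: StateRewards,
    n_cycles: int,
    discount_rate: float,
    confirmatory_cost: float = 0.0,
    reward_timing: str = "start",
) -> StrategyOutcome:
    """Expected per-patient cost and QALYs of one strategy.

    Branches:

    * ``treated`` — true positives; the strategy's treated transition arm.
    * ``untreated`` — false negatives; natural-history transitions.
    * ``at_risk`` — all patients without glaucoma; they remain in the
      at-risk state and accrue its utility and cost.  False positives incur
      ``confirmatory_cost`` once, undiscounted, at entry.

    The recurring ``annual_service_cost`` is added to every state's annual
    cost in every branch, and ``cost_per_screen`` is charged once per
    patient screened.
    """
    if strategy.treated_transitions is None or strategy.untreated_transitions is None:
        raise ConfigurationError(f"strategy {strategy.name!r} is missing a transition arm")
    test = strategy.effective_test
    cls = classify(prevalence, test)
    branch_rewards = rewards.with_cost_offset(strategy.annual_service_cost)
    entry = _entry_dist(strategy.entry_state)

    traces = {
        "treated": run_cohort(
            entry, strategy.treated_transitions, branch_rewards,
            n_cycles, discount_rate, reward_timing,
        ),
        "untreated": run_cohort(
            entry, strategy.untreated_transitions, branch_rewards,
            n_cycles, discount_rate, reward_timing,
        ),
        "at_risk": run_cohort(
            _entry_dist(HealthState.AT_RISK), _STAY_AT_RISK, branch_rewards,
            n_cycles, discount_rate, reward_timing,
        ),
    }

    weights = {
        "treated": cls.p_true_positive,
        "untreated": cls.p_false_negative,
        "at_risk": cls.p_false_positive + cls.p_true_negative,
    }
    cost = test.cost_per_screen + cls.p_false_positive * confirmatory_cost
    effect = 0.0
    for branch, w in weights.items():
        cost += w * traces[branch].discounted_cost_cum
        effect += w * traces[branch].discounted_qaly_cum
    return StrategyOutcome(
        strategy=strategy.name,
        expected_cost=float(cost),
        expected_qaly=float(effect),
        classification=cls,
        component_traces=traces,
    )
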