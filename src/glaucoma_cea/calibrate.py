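"""Calibration of the reference parameter set.

The original analysis' full parameter file (per-state annual costs, treated
and untreated transition probabilities, screening program cost breakdown)
is not publicly available.  This module back-fills those values from the
published summary results instead of inventing point estimates:

* the teleglaucoma treated arm's per-cycle progression probabilities are
  fitted so its 30-year state occupancy matches the published cohort row;
* the in-person treated arm is fitted to its published cumulative
  discounted reward, the inferred 30-year blindness occupancy, and a fully
  depleted at-risk state;
* prevalence and the in-person test's sensitivity are solved in closed form
  from the published per-strategy effectiveness values;
* state costs, recurring service costs, per-screen costs and the
  confirmatory-exam cost are solved by bounded linear least squares so the
  published per-strategy and per-arm cumulative costs are met exactly,
  with weak priors pulling the under-determined directions toward
  plausible magnitudes.

Every value produced here is tagged ``source: calibrated`` in the emitted
configuration; values copied from the publication are ``source: reported``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .config import ModelConfig, run_base_case
from .exceptions import CalibrationError
from .markov import (
    HealthState,
    N_STATES,
    STATE_NAMES,
    StateRewards,
    TransitionModel,
    run_cohort,
)
from .screening import ScreeningTest, classify

__all__ = [
    "BENCHMARKS",
    "ArmStructure",
    "CalibrationResult",
    "calibrate_transitions",
    "calibrate_reference",
]

#: Published summary values the reference set is calibrated against
#: (per-patient discounted CAD and QALYs over the 30-year horizon, and the
#: teleglaucoma cohort's state occupancy after 30 cycles).  The in-person
#: 30-year blindness occupancy is not printed in the original tables; 0.89
#: is inferred from the reported 24% relative reduction in blindness and is
#: used only as a soft target.
BENCHMARKS: dict = {
    "strategy_cost": {"teleglaucoma": 871.54, "in_person": 4441.42},
    "strategy_effect": {"teleglaucoma": 18.32, "in_person": 18.19},
    "arm_cumulative_cost": {"teleglaucoma": 1155.45, "in_person": 4035.19},
    "arm_cumulative_qaly": {"teleglaucoma": 15.7, "in_person": 16.8},
    "tele_final_occupancy": (3.71e-5, 0.15, 0.10, 0.09, 0.65),
    "inperson_final_blind": 0.89,
}

#: Published model inputs used verbatim.
REPORTED = {
    "utilities": {"at_risk": 1.0, "mild": 0.87, "moderate": 0.79, "severe": 0.64, "blind": 0.5},
    "discount_rate": 0.03,
    "horizon": 30,
    "wtp": 40_000.0,
    "tele_sensitivity": 0.865,
    "tele_specificity": 0.786,
    "tele_capacity": 300,
    "inperson_capacity": 1379,
}

#: Untreated (natural-history) per-cycle stage progression once glaucoma is
#: manifest: roughly a two-year mean residence per stage.  The at-risk →
#: mild move is disease *incidence*, which treatment cannot alter, so the
#: untreated arm shares the calibrated treated-arm incidence and only these
#: three stage-progression probabilities are assumed.  A modelling choice
#: (no long-horizon untreated cohorts exist to fit against), tagged
#: ``assumption`` in the emitted configuration.
UNTREATED_STAGE_PROGRESSION = (0.45, 0.50, 0.55)

#: In-person examination is taken to be less sensitive and more specific
#: than teleglaucoma; its specificity is fixed here and its sensitivity is
#: solved from the published effectiveness values.
INPERSON_SPECIFICITY = 0.90

#: Weak priors (CAD) for the cost unknowns, in the order
#: (state costs at_risk..blind, service tele, service in-person,
#: per-screen tele, per-screen in-person, confirmatory exam).
_COST_PRIORS = np.array([15.0, 30.0, 45.0, 65.0, 150.0, 8.0, 140.0, 40.0, 300.0, 150.0])

_PROB_BOUNDS = (1e-9, 0.95)


@dataclass(frozen=True)
class ArmStructure:
    """Search space of a transition-arm calibration.

    Free parameters are the adjacent-progression probabilities (state ``i``
    to ``i + 1``); the cohort enters at ``entry_state`` and runs for
    ``horizon`` cycles.
    """

    entry_state: HealthState = HealthState.AT_RISK
    horizon: int = 30
    arm_label: str = "treated"


@dataclass(frozen=True)
class CalibrationResult:
    """A fitted transition arm with its fit diagnostics."""

    model: TransitionModel
    residual: float
    target: np.ndarray
    achieved: np.ndarray

    def __str__(self) -> str:  # diagnostics for error messages / logs
        return (
            f"CalibrationResult(arm={self.model.arm_label!r}, "
            f"residual={self.residual:.3e}, target={np.round(self.target, 5)}, "
            f"achieved={np.round(self.achieved, 5)})"
        )


def _entry_dist(state: HealthState) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[int(state)] = 1.0
    return v


def _final_occupancy(probs: np.ndarray, structure: ArmStructure) -> np.ndarray:
    m = TransitionModel.from_progression(probs, structure.arm_label)
    occ = _entry_dist(structure.entry_state)
    for _ in range(structure.horizon):
        occ = occ @ m.matrix
    return occ


def calibrate_transitions(
    target_cycle30_occupancy: Sequence[float],
    structure: ArmStructure = ArmStructure(),
    tolerance: float = 1e-3,
    x0: Optional[Sequence[float]] = None,
) -> CalibrationResult:
    """Fit per-cycle progression probabilities to an end-of-horizon occupancy.

    The target is normalized to a probability vector if it does not sum to
    one (published occupancy rows are rounded).  Raises
    :class:`CalibrationError` with diagnostics when the best fit leaves a
    Euclidean residual above ``tolerance``.

    Parameter recovery from an end-of-horizon occupancy alone is only
    well-posed while the occupancy retains information about each rate:
    once the entry state is essentially depleted (fast progression over a
    long horizon) distinct rate vectors produce end occupancies differing
    below any practical tolerance, and the fit returns one member of that
    near-degenerate set.
    """
    target = np.asarray(target_cycle30_occupancy, dtype=float)
    if target.shape != (N_STATES,) or np.any(target < 0) or target.sum() <= 0:
        raise CalibrationError(f"target must be a non-negative length-{N_STATES} vector")
    target = target / target.sum()

    # tiny ridge toward zero progression: pins down rates the occupancy
    # carries no information about (e.g. states no mass ever reaches)
    # without materially shifting identified fits
    ridge = np.sqrt(1e-8)

    def objective(p: np.ndarray) -> np.ndarray:
        return np.concatenate([_final_occupancy(p, structure) - target, ridge * p])

    starts = (
        [np.asarray(x0, dtype=float)]
        if x0 is not None
        else [np.full(N_STATES - 1, v) for v in (0.02, 0.2, 0.5)]
    )
    fit = None
    for start in starts:
        candidate = least_squares(
            objective, x0=start, bounds=_PROB_BOUNDS, method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if fit is None or candidate.cost < fit.cost:
            fit = candidate
    achieved = _final_occupancy(fit.x, structure)
    residual = float(np.linalg.norm(achieved - target))
    result = CalibrationResult(
        model=TransitionModel.from_progression(fit.x, structure.arm_label),
        residual=residual,
        target=target,
        achieved=achieved,
    )
    if not fit.success:
        raise CalibrationError(f"optimizer failed: {fit.message}; {result}")
    if residual > tolerance:
        raise CalibrationError(
            f"calibration residual {residual:.3e} exceeds tolerance {tolerance:.1e}; {result}"
        )
    return result


def _fit_arm_to_summary(
    target_qaly: float,
    target_blind: float,
    utilities: np.ndarray,
    discount_rate: float,
    horizon: int,
    arm_label: str,
    weights: tuple[float, float, float] = (0.5, 4.0, 2.0),
) -> TransitionModel:
    """Fit an arm to (cumulative discounted QALY, final blind occupancy,
    fully depleted at-risk state).

    The three targets are jointly infeasible for an adjacent-progression
    chain (a cohort cannot both accrue the published cumulative reward and
    reach the inferred blindness level), so this is an explicit compromise
    fit; the default weights favour the structural blindness-prevention
    contrast over the cumulative-reward cell.
    """
    rewards = StateRewards(utilities, np.zeros(N_STATES))
    entry = _entry_dist(HealthState.AT_RISK)
    w_q, w_b, w_a = weights

    def resid(p: np.ndarray) -> np.ndarray:
        trace = run_cohort(
            entry, TransitionModel.from_progression(p, arm_label), rewards,
            horizon, discount_rate,
        )
        final = trace.final_occupancy
        return np.array(
            [
                w_q * (trace.discounted_qaly_cum - target_qaly),
                w_b * (final[HealthState.BLIND] - target_blind),
                w_a * final[HealthState.AT_RISK],
            ]
        )

    best = None
    for x0 in ([0.08, 0.3, 0.3, 0.3], [0.05, 0.5, 0.5, 0.5], [0.12, 0.2, 0.2, 0.6]):
        fit = least_squares(resid, x0=x0, bounds=_PROB_BOUNDS, method="trf")
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None or not best.success:
        raise CalibrationError("in-person arm calibration failed to converge")
    return TransitionModel.from_progression(best.x, arm_label)


def _solve_mixture(q_treated_tele: float, q_treated_inp: float, q_untreated: float,
                   q_at_risk: float) -> tuple[float, float]:
    """Closed-form prevalence and in-person sensitivity from the published
    per-strategy effectiveness values."""
    b = BENCHMARKS["strategy_effect"]
    s_t = REPORTED["tele_sensitivity"]
    inner_tele = s_t * q_treated_tele + (1 - s_t) * q_untreated
    if inner_tele >= q_at_risk:
        raise CalibrationError("diseased branches must yield fewer QALYs than the at-risk branch")
    prevalence = (q_at_risk - b["teleglaucoma"]) / (q_at_risk - inner_tele)
    if not 0 < prevalence < 1:
        raise CalibrationError(f"calibrated prevalence {prevalence:.4f} outside (0, 1)")
    inner_inp = q_at_risk - (q_at_risk - b["in_person"]) / prevalence
    sens_inp = (inner_inp - q_untreated) / (q_treated_inp - q_untreated)
    if not 0 < sens_inp < s_t:
        raise CalibrationError(
            f"calibrated in-person sensitivity {sens_inp:.4f} outside (0, {s_t})"
        )
    return float(prevalence), float(sens_inp)


def _solve_costs(
    y_tele: np.ndarray,
    y_inp: np.ndarray,
    y_untreated: np.ndarray,
    disc_years_total: float,
    prevalence: float,
    sens_inp: float,
) -> np.ndarray:
    """Bounded linear least squares for the ten cost unknowns.

    Four exact constraints (per-arm cumulative costs, per-strategy expected
    costs) are given very large weights; weak relative priors regularize
    the remaining directions.  Returns
    ``(c_at_risk..c_blind, svc_tele, svc_inp, screen_tele, screen_inp, c_confirm)``.
    """
    b = BENCHMARKS
    n_x = len(_COST_PRIORS)
    tele_test = ScreeningTest(REPORTED["tele_sensitivity"], REPORTED["tele_specificity"])
    inp_test = ScreeningTest(sens_inp, INPERSON_SPECIFICITY)
    w_tele = classify(prevalence, tele_test)
    w_inp = classify(prevalence, inp_test)
    y_at_risk = np.zeros(N_STATES)
    y_at_risk[HealthState.AT_RISK] = disc_years_total

    def strategy_row(weights, y_treated, svc_idx, screen_idx):
        row = np.zeros(n_x)
        state_coeff = (
            weights.p_true_positive * y_treated
            + weights.p_false_negative * y_untreated
            + (weights.p_false_positive + weights.p_true_negative) * y_at_risk
        )
        row[:N_STATES] = state_coeff
        row[svc_idx] = disc_years_total
        row[screen_idx] = 1.0
        row[9] = weights.p_false_positive  # confirmatory exam
        return row

    rows, rhs = [], []
    # per-arm cumulative discounted costs
    for y, svc_idx, target in (
        (y_tele, 5, b["arm_cumulative_cost"]["teleglaucoma"]),
        (y_inp, 6, b["arm_cumulative_cost"]["in_person"]),
    ):
        row = np.zeros(n_x)
        row[:N_STATES] = y
        row[svc_idx] = disc_years_total
        rows.append(row)
        rhs.append(target)
    # per-strategy expected costs
    rows.append(strategy_row(w_tele, y_tele, svc_idx=5, screen_idx=7))
    rhs.append(b["strategy_cost"]["teleglaucoma"])
    rows.append(strategy_row(w_inp, y_inp, svc_idx=6, screen_idx=8))
    rhs.append(b["strategy_cost"]["in_person"])

    hard_weight = 1e6
    a_rows = [hard_weight * np.asarray(r) / t for r, t in zip(rows, rhs)]
    b_rows = [hard_weight] * len(rows)
    for i, prior in enumerate(_COST_PRIORS):
        prior_row = np.zeros(n_x)
        prior_row[i] = 1.0 / prior
        a_rows.append(prior_row)
        b_rows.append(1.0)
    solution = lsq_linear(
        np.vstack(a_rows), np.asarray(b_rows), bounds=(0.0, np.inf), method="bvls"
    )
    x = solution.x
    achieved = np.array([np.asarray(r) @ x for r in rows])
    rel = np.abs(achieved - np.asarray(rhs)) / np.asarray(rhs)
    if np.any(rel > 1e-6):
        raise CalibrationError(
            "cost identities not met exactly: relative residuals "
            f"{np.array2string(rel, precision=2)} for targets {rhs}"
        )
    return x


def calibrate_reference(psa_seed: int = 20150918) -> ModelConfig:
    """Run the full calibration pipeline and assemble the reference config."""
    utilities = np.array([REPORTED["utilities"][s] for s in STATE_NAMES])
    rate = REPORTED["discount_rate"]
    horizon = REPORTED["horizon"]

    tele_fit = calibrate_transitions(
        BENCHMARKS["tele_final_occupancy"],
        ArmStructure(HealthState.AT_RISK, horizon, "treated"),
        x0=[0.3, 0.1, 0.15, 0.25],
    )
    tele_treated = tele_fit.model
    untreated = TransitionModel.from_progression(
        (tele_treated.progression_probs[0], *UNTREATED_STAGE_PROGRESSION), "untreated"
    )
    inp_treated = _fit_arm_to_summary(
        BENCHMARKS["arm_cumulative_qaly"]["in_person"],
        BENCHMARKS["inperson_final_blind"],
        utilities,
        rate,
        horizon,
        "treated",
    )

    unit_rewards = StateRewards(utilities, np.zeros(N_STATES))
    entry = _entry_dist(HealthState.AT_RISK)
    traces = {
        "tele": run_cohort(entry, tele_treated, unit_rewards, horizon, rate),
        "inp": run_cohort(entry, inp_treated, unit_rewards, horizon, rate),
        "untreated": run_cohort(entry, untreated, unit_rewards, horizon, rate),
    }
    disc_total = float(((1 / (1 + rate)) ** np.arange(horizon + 1)).sum())
    q_at_risk = disc_total * utilities[HealthState.AT_RISK]

    prevalence, sens_inp = _solve_mixture(
        traces["tele"].discounted_qaly_cum,
        traces["inp"].discounted_qaly_cum,
        traces["untreated"].discounted_qaly_cum,
        q_at_risk,
    )
    x = _solve_costs(
        traces["tele"].discounted_state_years(),
        traces["inp"].discounted_state_years(),
        traces["untreated"].discounted_state_years(),
        disc_total,
        prevalence,
        sens_inp,
    )
    state_costs, svc_tele, svc_inp, screen_tele, screen_inp, c_confirm = (
        x[:N_STATES], x[5], x[6], x[7], x[8], x[9]
    )

    config = _assemble_config(
        utilities, state_costs, tele_treated, inp_treated, untreated,
        prevalence, sens_inp, svc_tele, svc_inp, screen_tele, screen_inp,
        c_confirm, psa_seed,
    )
    _verify_reproduction(config)
    return config


def _assemble_config(
    utilities, state_costs, tele_treated, inp_treated, untreated,
    prevalence, sens_inp, svc_tele, svc_inp, screen_tele, screen_inp,
    c_confirm, psa_seed,
) -> ModelConfig:
    def progression_doc(tm: TransitionModel, source: str) -> dict:
        from .config import PROGRESSION_EDGES

        return {
            "kind": "progression",
            "probs": {
                e: {"value": float(p), "source": source}
                for e, p in zip(PROGRESSION_EDGES, tm.progression_probs)
            },
        }

    def tagged(value, source):
        return {"value": value, "source": source}

    # Second-order uncertainty magnitudes are not published.  Prevalence in
    # an at-risk rural population is by far the least identified input
    # (population figures range from a few percent to half of referral
    # cohorts), while the transition probabilities are pinned down by the
    # occupancy calibration; the dispersions below encode that hierarchy
    # and put the PSA cost spreads on the published order of magnitude.
    psa_distributions = [
        {"name": "prevalence", "kind": "beta", "se": 0.10},
        {"name": "teleglaucoma.sensitivity", "kind": "beta", "se": 0.03},
        {"name": "teleglaucoma.specificity", "kind": "beta", "se": 0.03},
        {"name": "in_person.sensitivity", "kind": "beta", "se": 0.05},
        {"name": "in_person.specificity", "kind": "beta", "se": 0.03},
        *[
            {"name": f"utility.{s}", "kind": "beta", "se": 0.03}
            for s in STATE_NAMES[1:]
        ],
        *[
            {"name": f"cost.{s}", "kind": "gamma", "se": round(0.20 * c, 6)}
            for s, c in zip(STATE_NAMES, state_costs)
            if c > 0
        ],
        {"name": "teleglaucoma.annual_service_cost", "kind": "gamma",
         "se": round(0.20 * svc_tele, 6)},
        {"name": "in_person.annual_service_cost", "kind": "gamma",
         "se": round(0.30 * svc_inp, 6)},
        {"name": "teleglaucoma.cost_per_screen", "kind": "gamma",
         "se": round(0.20 * screen_tele, 6)},
        {"name": "in_person.cost_per_screen", "kind": "gamma",
         "se": round(0.40 * screen_inp, 6)},
        {"name": "confirmatory_exam_cost", "kind": "gamma",
         "se": round(0.20 * c_confirm, 6)},
        *[
            {"name": f"teleglaucoma.treated.{e}", "kind": "beta", "se": round(0.05 * p, 6)}
            for e, p in _edges(tele_treated)
        ],
        *[
            {"name": f"natural_history.{e}", "kind": "beta", "se": round(0.05 * p, 6)}
            for e, p in _edges(untreated)
        ],
    ]

    doc = {
        "meta": {
            "name": "reference-calibrated",
            "currency": "CAD",
            "price_year": 2014,
            "note": (
                "Costs are taken as already converted to 2014 CAD; foreign-"
                "currency conversion and the 2.05% inflation adjustment are "
                "upstream of this model. Transition probabilities, state "
                "costs and program costs are calibrated against the "
                "published 30-year summary results (see glaucoma_cea.calibrate)."
            ),
            "limitations": [
                "no background mortality / death state",
                "single treatment pathway; treatment variation not modelled",
            ],
        },
        "horizon": tagged(REPORTED["horizon"], "reported"),
        "discount_rate": tagged(REPORTED["discount_rate"], "reported"),
        "wtp": tagged(REPORTED["wtp"], "reported"),
        "prevalence": tagged(float(prevalence), "calibrated"),
        "confirmatory_exam_cost": tagged(float(c_confirm), "calibrated"),
        "reward_timing": "start",
        "utilities": {
            "at_risk": tagged(1.0, "assumption"),
            **{
                s: tagged(REPORTED["utilities"][s], "reported")
                for s in STATE_NAMES[1:]
            },
        },
        "state_costs": {
            s: tagged(float(c), "calibrated") for s, c in zip(STATE_NAMES, state_costs)
        },
        "reference_strategy": "teleglaucoma",
        "comparator_strategy": "in_person",
        "strategies": {
            "teleglaucoma": {
                "entry_state": "at_risk",
                "annual_service_cost": tagged(float(svc_tele), "calibrated"),
                "test": {
                    "sensitivity": tagged(REPORTED["tele_sensitivity"], "reported"),
                    "specificity": tagged(REPORTED["tele_specificity"], "reported"),
                    "cost_per_screen": tagged(float(screen_tele), "calibrated"),
                    "fixed_program_cost": tagged(
                        float(screen_tele * REPORTED["tele_capacity"]), "derived"
                    ),
                    "capacity": tagged(REPORTED["tele_capacity"], "reported"),
                },
                "treated_transitions": progression_doc(tele_treated, "calibrated"),
                "untreated_transitions": progression_doc(untreated, "assumption"),
            },
            "in_person": {
                "entry_state": "at_risk",
                "annual_service_cost": tagged(float(svc_inp), "calibrated"),
                "test": {
                    "sensitivity": tagged(float(sens_inp), "calibrated"),
                    "specificity": tagged(INPERSON_SPECIFICITY, "assumption"),
                    "cost_per_screen": tagged(float(screen_inp), "calibrated"),
                    "fixed_program_cost": tagged(
                        float(screen_inp * REPORTED["inperson_capacity"]), "derived"
                    ),
                    "capacity": tagged(REPORTED["inperson_capacity"], "reported"),
                },
                "treated_transitions": progression_doc(inp_treated, "calibrated"),
                "untreated_transitions": progression_doc(untreated, "assumption"),
            },
        },
        "dsa": {
            "relative_range": 0.2,
            "parameters": [
                "prevalence",
                "cost.blind",
                "teleglaucoma.treated.at_risk_to_mild",
                "teleglaucoma.treated.severe_to_blind",
                "natural_history.at_risk_to_mild",
                "natural_history.severe_to_blind",
            ],
        },
        "psa": {
            "n_samples": 1000,
            "seed": int(psa_seed),
            "distributions": psa_distributions,
        },
    }
    return ModelConfig.from_dict(doc)


def _edges(tm: TransitionModel):
    from .config import PROGRESSION_EDGES

    return list(zip(PROGRESSION_EDGES, tm.progression_probs))


def _verify_reproduction(config: ModelConfig) -> None:
    """Fail loudly if the calibrated set does not reproduce the benchmarks."""
    base = run_base_case(config)
    problems = []
    for name in ("teleglaucoma", "in_person"):
        o = base.outcomes[name]
        for kind, got in (("cost", o.expected_cost), ("effect", o.expected_qaly)):
            want = BENCHMARKS[f"strategy_{kind}"][name]
            if abs(got - want) / want > 0.01:
                problems.append(f"{name} {kind}: got {got:.2f}, benchmark {want:.2f}")
    occ = base.outcomes["teleglaucoma"].component_traces["treated"].final_occupancy
    target = np.asarray(BENCHMARKS["tele_final_occupancy"])
    target = target / target.sum()
    if np.any(np.abs(occ - target) > 0.01):
        problems.append(f"teleglaucoma final occupancy {np.round(occ, 4)} vs {np.round(target, 4)}")
    if problems:
        raise CalibrationError("benchmark reproduction failed: " + "; ".join(problems))
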