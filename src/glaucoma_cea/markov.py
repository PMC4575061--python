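"""Progressive glaucoma Markov cohort engine.

The disease is represented by five ordered health states — glaucoma suspect
(``AT_RISK``) followed by ``MILD``, ``MODERATE`` and ``SEVERE`` glaucoma and
finally ``BLIND`` — with annual cycles.  Glaucoma is irreversible, so a
cohort may only stay put or move toward more severe states, and blindness is
absorbing.  The engine propagates a state-occupancy vector through a
row-stochastic transition matrix and accrues per-cycle utilities (as QALYs)
and annual costs, discounted at a constant annual rate.

There is no death state: the cohort is closed and all-cause mortality is
deliberately outside the model, which reports results per patient entering
the screening pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "HealthState",
    "STATE_NAMES",
    "N_STATES",
    "TransitionModel",
    "StateRewards",
    "CohortTrace",
    "discount_factor",
    "qaly",
    "run_cohort",
]

#: Absolute tolerance for row-stochasticity checks.
ROW_SUM_TOL = 1e-9


class HealthState(IntEnum):
    """Ordered glaucoma severity states; the index is the severity rank."""

    AT_RISK = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    BLIND = 4


STATE_NAMES: tuple[str, ...] = tuple(s.name.lower() for s in HealthState)
N_STATES = len(STATE_NAMES)


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value multiplier ``1 / (1 + rate)**cycle``.

    Parameters
    ----------
    rate
        Annual discount rate as a proportion (e.g. ``0.03`` for 3%).
    cycle
        Cycle (year) index, a non-negative integer.  Cycle 0 is undiscounted.
    """
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if cycle < 0 or int(cycle) != cycle:
        raise ValidationError(f"cycle must be a non-negative integer, got {cycle}")
    return float(1.0 / (1.0 + rate) ** int(cycle))


def qaly(utility: float, years: float) -> float:
    """Quality-adjusted life years accrued by ``years`` at a utility weight.

    A utility of 1 is perfect health and 0 the worst state; one year lived at
    utility 0.5 (the blind state here) is worth half a quality-adjusted year.
    """
    if not 0.0 <= utility <= 1.0:
        raise ValidationError(f"utility must lie in [0, 1], got {utility}")
    if years < 0:
        raise ValidationError(f"years must be >= 0, got {years}")
    return float(utility * years)


def _as_state_vector(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_STATES,):
        raise ValidationError(f"{what} must have shape ({N_STATES},), got {arr.shape}")
    return arr


@dataclass(frozen=True)
class TransitionModel:
    """Per-cycle transition probabilities for one treatment arm.

    The matrix must be row-stochastic, upper-triangular (no recovery to a
    less severe state) and absorbing in ``BLIND``.
    """

    matrix: np.ndarray
    arm_label: str = "untreated"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValidationError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got {m.shape}"
            )
        if np.any(m < -1e-15) or np.any(m > 1 + 1e-12):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > ROW_SUM_TOL):
            raise ValidationError(
                f"transition rows must sum to 1 within {ROW_SUM_TOL}; sums are {rows}"
            )
        if np.any(np.abs(np.tril(m, k=-1)) > 0):
            raise ValidationError("recovery moves (below-diagonal entries) must be 0")
        blind = np.zeros(N_STATES)
        blind[HealthState.BLIND] = 1.0
        if not np.allclose(m[HealthState.BLIND], blind, atol=ROW_SUM_TOL):
            raise ValidationError("BLIND must be absorbing (identity row)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_progression(
        cls, probs: Sequence[float], arm_label: str = "untreated"
    ) -> "TransitionModel":
        """Adjacent-progression chain from four per-cycle move probabilities.

        ``probs[i]`` is the annual probability of moving from state ``i`` to
        state ``i + 1``; the remainder stays put.  This is the restricted
        structure used by the reference parameter set.
        """
        p = np.asarray(probs, dtype=float)
        if p.shape != (N_STATES - 1,):
            raise ValidationError(
                f"expected {N_STATES - 1} progression probabilities, got {p.shape}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("progression probabilities must lie in [0, 1]")
        m = np.eye(N_STATES)
        for i, pi in enumerate(p):
            m[i, i] = 1.0 - pi
            m[i, i + 1] = pi
        return cls(matrix=m, arm_label=arm_label)

    @property
    def progression_probs(self) -> np.ndarray:
        """The superdiagonal (state ``i`` → ``i + 1`` move probabilities)."""
        return np.diag(self.matrix, k=1).copy()


@dataclass(frozen=True)
class StateRewards:
    """Per-state annual utility weights and annual costs (CAD per year)."""

    utilities: np.ndarray
    annual_costs: np.ndarray

    def __post_init__(self) -> None:
        u = _as_state_vector(self.utilities, "utilities")
        c = _as_state_vector(self.annual_costs, "annual_costs")
        if np.any(u < 0) or np.any(u > 1):
            raise ValidationError("utilities must lie in [0, 1]")
        if np.any(np.diff(u) > 1e-12):
            raise ValidationError("utilities must be non-increasing with severity")
        if np.any(c < 0):
            raise ValidationError("annual state costs must be >= 0")
        object.__setattr__(self, "utilities", u)
        object.__setattr__(self, "annual_costs", c)

    @classmethod
    def from_mappings(
        cls,
        utility_per_state: Mapping[str, float],
        annual_cost_per_state: Mapping[str, float],
    ) -> "StateRewards":
        return cls(
            utilities=np.array([utility_per_state[s] for s in STATE_NAMES]),
            annual_costs=np.array([annual_cost_per_state[s] for s in STATE_NAMES]),
        )

    def with_cost_offset(self, offset: float) -> "StateRewards":
        """Rewards with a constant annual cost added to every state.

        Used to fold a strategy's recurring per-patient service cost into the
        cohort run.
        """
        return StateRewards(self.utilities, self.annual_costs + float(offset))


TRACE_CSV_COLUMNS = [
    "cycle",
    *STATE_NAMES,
    "cycle_cost",
    "cycle_qaly",
    "cum_disc_cost",
    "cum_disc_qaly",
]


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle cohort occupancy and accumulated rewards.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle 0 is the initial
    distribution).  ``per_cycle_cost`` / ``per_cycle_qaly`` are undiscounted
    accruals; the ``cum_disc_*`` arrays are running discounted totals and
    their final entries are exposed as ``discounted_cost_cum`` /
    ``discounted_qaly_cum``.
    """

    occupancy: np.ndarray
    per_cycle_cost: np.ndarray
    per_cycle_qaly: np.ndarray
    cum_disc_cost: np.ndarray
    cum_disc_qaly: np.ndarray
    discount_rate: float = 0.0
    reward_timing: str = "start"

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def discounted_cost_cum(self) -> float:
        return float(self.cum_disc_cost[-1])

    @property
    def discounted_qaly_cum(self) -> float:
        return float(self.cum_disc_qaly[-1])

    @property
    def final_occupancy(self) -> np.ndarray:
        return self.occupancy[-1].copy()

    def discounted_state_years(self) -> np.ndarray:
        """Discounted person-years spent in each state over the accrual span."""
        disc = (1.0 / (1.0 + self.discount_rate)) ** np.arange(len(self.occupancy))
        if self.reward_timing == "end":
            disc = disc.copy()
            disc[0] = 0.0
        return (self.occupancy * disc[:, None]).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        df.insert(0, "cycle", np.arange(len(df)))
        df["cycle_cost"] = self.per_cycle_cost
        df["cycle_qaly"] = self.per_cycle_qaly
        df["cum_disc_cost"] = self.cum_disc_cost
        df["cum_disc_qaly"] = self.cum_disc_qaly
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, columns=TRACE_CSV_COLUMNS)


def run_cohort(
    initial_dist: Iterable[float],
    transitions: TransitionModel,
    rewards: StateRewards,
    n_cycles: int,
    discount_rate: float = 0.0,
    reward_timing: str = "start",
) -> CohortTrace:
    """Propagate a cohort and accumulate discounted costs and QALYs.

    Rewards are accrued on the state occupancy at the *start* of each cycle,
    i.e. on rows 0..n_cycles inclusive, with no half-cycle correction; the
    reward at cycle ``t`` is discounted by ``1 / (1 + rate)**t``.  With
    ``reward_timing="end"`` accrual uses end-of-cycle occupancy instead
    (rows 1..n_cycles only).

    Parameters
    ----------
    initial_dist
        Length-5 probability vector over the health states at entry.
    transitions
        Validated transition model for the arm.
    rewards
        Per-state utilities and annual costs.
    n_cycles
        Number of one-year cycles (>= 1).
    discount_rate
        Annual discount rate applied to both costs and QALYs.
    reward_timing
        ``"start"`` (default) or ``"end"`` of cycle accrual.
    """
    init = _as_state_vector(initial_dist, "initial_dist")
    if np.any(init < 0) or abs(init.sum() - 1.0) > ROW_SUM_TOL:
        raise ValidationError("initial distribution must be a probability vector")
    if n_cycles < 1 or int(n_cycles) != n_cycles:
        raise ValidationError(f"n_cycles must be a positive integer, got {n_cycles}")
    if reward_timing not in ("start", "end"):
        raise ValidationError(f"reward_timing must be 'start' or 'end', got {reward_timing!r}")
    if discount_rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {discount_rate}")

    n_cycles = int(n_cycles)
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = init
    m = transitions.matrix
    for t in range(1, n_cycles + 1):
        occ[t] = occ[t - 1] @ m

    per_cost = occ @ rewards.annual_costs
    per_qaly = occ @ rewards.utilities
    disc = (1.0 / (1.0 + discount_rate)) ** np.arange(n_cycles + 1)
    if reward_timing == "end":
        per_cost = per_cost.copy()
        per_qaly = per_qaly.copy()
        per_cost[0] = 0.0
        per_qaly[0] = 0.0
    return CohortTrace(
        occupancy=occ,
        per_cycle_cost=per_cost,
        per_cycle_qaly=per_qaly,
        cum_disc_cost=np.cumsum(per_cost * disc),
        cum_disc_qaly=np.cumsum(per_qaly * disc),
        discount_rate=float(discount_rate),
        reward_timing=reward_timing,
    )
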