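"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis re-runs the whole model over a grid for a
single parameter; the tornado ranks parameters by the spread in incremental
net monetary benefit when each is swung to its low/high bound (default
+/-20% of the base value).  The probabilistic analysis is a second-order
Monte Carlo: each draw jointly resamples every uncertain parameter — gamma
for costs, beta for probabilities and utilities, both parameterized from
(mean, standard error) by the method of moments — re-evaluates both
strategies on the same draw, and the acceptability curve reports, per
willingness-to-pay value, the fraction of draws in which each strategy has
the higher net monetary benefit.

Draws are reproducible: draw ``i`` uses a child generator spawned from the
run seed with spawn key ``(i,)``, so enlarging ``n_samples`` extends the
sample without reshuffling earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cea import nmb
from .config import (
    DistributionSpec,
    ModelConfig,
    get_parameter,
    run_base_case,
    with_overrides,
)
from .exceptions import ConfigurationError
from .markov import STATE_NAMES

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "TornadoEntry",
    "moments_to_gamma",
    "moments_to_beta",
    "one_way_dsa",
    "tornado",
    "run_psa",
    "default_wtp_grid",
]


def moments_to_gamma(mean: float, standard_error: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) of a gamma with given mean and SE."""
    if mean <= 0:
        raise ConfigurationError(f"gamma requires mean > 0, got {mean}")
    if standard_error <= 0:
        raise ConfigurationError(f"gamma requires standard error > 0, got {standard_error}")
    var = standard_error**2
    return mean**2 / var, var / mean


def moments_to_beta(mean: float, standard_error: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) of a beta with given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(f"beta requires mean strictly in (0, 1), got {mean}")
    var = standard_error**2
    limit = mean * (1.0 - mean)
    if var <= 0:
        raise ConfigurationError(f"beta requires standard error > 0, got {standard_error}")
    if var >= limit:
        raise ConfigurationError(
            f"infeasible beta variance: se^2={var:.6g} must be below "
            f"mean*(1-mean)={limit:.6g} for mean={mean:.6g}"
        )
    nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class ParameterDistribution:
    """A sampleable second-order distribution around a parameter's mean."""

    name: str
    kind: str
    mean: float
    standard_error: float = 0.0
    bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "fixed"):
            raise ConfigurationError(f"{self.name}: unknown distribution kind {self.kind!r}")
        if self.kind != "fixed":
            # validate moment feasibility eagerly, before any sampling
            if self.kind == "gamma":
                moments_to_gamma(self.mean, self.standard_error)
            else:
                moments_to_beta(self.mean, self.standard_error)

    @classmethod
    def from_spec(cls, spec: DistributionSpec, mean: float) -> "ParameterDistribution":
        kind = "fixed" if spec.se == 0 else spec.kind
        return cls(name=spec.name, kind=kind, mean=mean, standard_error=spec.se)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return float(self.mean)
        if self.kind == "gamma":
            shape, scale = moments_to_gamma(self.mean, self.standard_error)
            value = rng.gamma(shape, scale)
        else:
            a, b = moments_to_beta(self.mean, self.standard_error)
            value = rng.beta(a, b)
        if self.bounds is not None:
            value = float(np.clip(value, *self.bounds))
        return float(value)


def _strategy_points(config: ModelConfig):
    base = run_base_case(config)
    ref = base.outcomes[config.reference_strategy]
    comp = base.outcomes[config.comparator_strategy]
    return base, ref, comp


def one_way_dsa(
    config: ModelConfig,
    parameter: str,
    relative_range: float = 0.2,
    grid_size: int = 11,
) -> pd.DataFrame:
    """Sweep one parameter over ``base*(1 +/- relative_range)``.

    Returns one row per grid point with both strategies' cost/effect, their
    average cost-effectiveness ratios, the incremental ICER and the
    incremental net monetary benefit at the configured willingness to pay.
    All other parameters stay at base values.
    """
    if relative_range < 0:
        raise ConfigurationError("relative_range must be >= 0")
    if grid_size < 1:
        raise ConfigurationError("grid_size must be >= 1")
    base_value = get_parameter(config, parameter)  # raises for unknown names
    lo, hi = base_value * (1 - relative_range), base_value * (1 + relative_range)
    grid = np.linspace(lo, hi, grid_size) if grid_size > 1 else np.array([base_value])
    rows = []
    for value in grid:
        cfg = with_overrides(config, {parameter: value})
        base, ref, comp = _strategy_points(cfg)
        rows.append(
            {
                "parameter": parameter,
                "value": float(value),
                "ref_cost": ref.expected_cost,
                "ref_effect": ref.expected_qaly,
                "comp_cost": comp.expected_cost,
                "comp_effect": comp.expected_qaly,
                "ref_cer": base.cea.ref_cer,
                "comp_cer": base.cea.comp_cer,
                "icer": base.cea.icer,
                "incremental_nmb": base.nmb(cfg.reference_strategy)
                - base.nmb(cfg.comparator_strategy),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TornadoEntry:
    """Incremental-NMB swing of one parameter between its low/high bounds."""

    parameter: str
    low_value: float
    high_value: float
    nmb_at_low: float
    nmb_at_high: float

    @property
    def range_width(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def tornado(
    config: ModelConfig,
    parameters: Optional[Sequence[str]] = None,
    wtp: Optional[float] = None,
    relative_range: Optional[float] = None,
) -> list[TornadoEntry]:
    """One-way swings of each parameter, ranked by incremental-NMB width.

    ``parameters`` defaults to the configuration's DSA parameter list.  A
    parameter with a declared second-order distribution is swung over its
    uncertainty interval (mean +/- 2 standard errors, clipped to the
    distribution's support); parameters without one use the relative swing
    (config default +/-20%), which a ``relative_range`` argument also
    forces for all parameters.  Entries are sorted by descending
    ``range_width`` (ties broken by parameter name for determinism).
    """
    params = list(parameters) if parameters is not None else list(config.dsa.parameters)
    if not params:
        raise ConfigurationError("tornado requires at least one parameter")
    swing = config.dsa.relative_range if relative_range is None else relative_range
    wtp_value = config.wtp if wtp is None else wtp
    declared = (
        {d.name: d for d in config.psa.distributions} if relative_range is None else {}
    )

    def bounds_for(name: str, base_value: float) -> tuple[float, float]:
        spec = declared.get(name)
        if spec is None or spec.se == 0 or spec.kind == "fixed":
            return base_value * (1 - swing), base_value * (1 + swing)
        lo, hi = base_value - 2 * spec.se, base_value + 2 * spec.se
        if spec.kind == "beta":
            return max(lo, 0.0), min(hi, 1.0)
        return max(lo, 0.0), hi

    def incremental_nmb(cfg: ModelConfig) -> float:
        _, ref, comp = _strategy_points(cfg)
        return nmb(ref.expected_cost, ref.expected_qaly, wtp_value) - nmb(
            comp.expected_cost, comp.expected_qaly, wtp_value
        )

    entries = []
    for p in params:
        base_value = get_parameter(config, p)
        lo, hi = bounds_for(p, base_value)
        entries.append(
            TornadoEntry(
                parameter=p,
                low_value=lo,
                high_value=hi,
                nmb_at_low=incremental_nmb(with_overrides(config, {p: lo})),
                nmb_at_high=incremental_nmb(with_overrides(config, {p: hi})),
            )
        )
    return sorted(entries, key=lambda e: (-e.range_width, e.parameter))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "nmb_low": e.nmb_at_low,
                "nmb_high": e.nmb_at_high,
                "width": e.range_width,
            }
            for e in entries
        ]
    )


def default_wtp_grid(upper: float = 100_000.0, steps: int = 2000) -> np.ndarray:
    """Willingness-to-pay grid for acceptability curves: 0..upper inclusive."""
    return np.linspace(0.0, upper, steps + 1)


@dataclass(frozen=True)
class PSAResult:
    """Second-order Monte Carlo output for the two compared strategies.

    ``costs`` and ``effects`` map strategy name to length-``n`` sample
    arrays (paired across strategies: entry ``i`` of each array comes from
    the same joint parameter draw).  ``ceac`` holds the acceptability curve.
    """

    seed: int
    costs: dict
    effects: dict
    ceac: pd.DataFrame
    parameter_samples: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.costs.values())))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.costs:
            rows.append(
                {
                    "strategy": name,
                    "mean_cost": float(np.mean(self.costs[name])),
                    "sd_cost": float(np.std(self.costs[name], ddof=1))
                    if self.n_samples > 1
                    else 0.0,
                    "mean_effect": float(np.mean(self.effects[name])),
                    "sd_effect": float(np.std(self.effects[name], ddof=1))
                    if self.n_samples > 1
                    else 0.0,
                }
            )
        return pd.DataFrame(rows).set_index("strategy")

    def samples_frame(self) -> pd.DataFrame:
        """Long-format draws: ``draw,strategy,cost,effect``."""
        frames = []
        for name in self.costs:
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(self.n_samples),
                        "strategy": name,
                        "cost": self.costs[name],
                        "effect": self.effects[name],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_psa(
    config: ModelConfig,
    n_samples: Optional[int] = None,
    seed: Optional[int] = None,
    wtp_grid: Optional[np.ndarray] = None,
    keep_parameter_samples: bool = False,
) -> PSAResult:
    """Second-order probabilistic sensitivity analysis with acceptability curve.

    Every distribution declared in ``config.psa`` is redrawn jointly per
    sample; both strategies are evaluated on the same draw.  ``CEAC(wtp)``
    is the fraction of draws in which a strategy attains the higher net
    monetary benefit (ties split evenly, so the two curves always sum to 1).
    """
    n = config.psa.n_samples if n_samples is None else int(n_samples)
    if n < 1:
        raise ConfigurationError("n_samples must be >= 1")
    run_seed = config.psa.seed if seed is None else int(seed)
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)

    # build (and eagerly validate) distributions before any sampling
    dists = [
        ParameterDistribution.from_spec(spec, mean=get_parameter(config, spec.name))
        for spec in config.psa.distributions
    ]

    ref_name, comp_name = config.reference_strategy, config.comparator_strategy
    costs = {ref_name: np.empty(n), comp_name: np.empty(n)}
    effects = {ref_name: np.empty(n), comp_name: np.empty(n)}
    param_rows = [] if keep_parameter_samples else None

    utility_params = sorted(
        (d.name for d in dists if d.name.startswith("utility.")),
        key=lambda name: STATE_NAMES.index(name.split(".", 1)[1]),
    )

    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(run_seed, spawn_key=(i,)))
        draw = {d.name: d.sample(rng) for d in dists}
        if len(utility_params) > 1:
            # monotone rearrangement: utilities must not increase with
            # severity, so severity-sort the sampled utility values
            ranked = sorted((draw[name] for name in utility_params), reverse=True)
            draw.update(zip(utility_params, ranked))
        cfg = with_overrides(config, draw) if draw else config
        base = run_base_case(cfg)
        for name in (ref_name, comp_name):
            costs[name][i] = base.outcomes[name].expected_cost
            effects[name][i] = base.outcomes[name].expected_qaly
        if param_rows is not None:
            param_rows.append(draw)

    nmb_ref = grid[:, None] * effects[ref_name][None, :] - costs[ref_name][None, :]
    nmb_comp = grid[:, None] * effects[comp_name][None, :] - costs[comp_name][None, :]
    wins = (nmb_ref > nmb_comp).mean(axis=1) + 0.5 * (nmb_ref == nmb_comp).mean(axis=1)
    ceac = pd.DataFrame(
        {"wtp": grid, f"p_{ref_name}": wins, f"p_{comp_name}": 1.0 - wins}
    )
    return PSAResult(
        seed=run_seed,
        costs=costs,
        effects=effects,
        ceac=ceac,
        parameter_samples=pd.DataFrame(param_rows) if param_rows is not None else None,
    )
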