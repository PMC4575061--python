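"""Model configuration: parameter set, serialization and base-case run.

A :class:`ModelConfig` bundles everything a cost-effectiveness run needs —
state rewards, the screening strategies with their transition arms,
prevalence, discounting, willingness to pay, horizon, and the deterministic
and probabilistic sensitivity-analysis specifications.  Configurations
round-trip losslessly through a YAML dialect in which every scalar carries a
``source`` tag (``reported`` for values taken from the published analysis,
``calibrated`` for values back-filled by the calibration routine,
``assumption`` / ``derived`` otherwise).

Every tunable scalar is addressable by a dotted path (``prevalence``,
``cost.blind``, ``teleglaucoma.sensitivity``,
``teleglaucoma.treated.at_risk_to_mild`` ...); sensitivity analyses operate
on these paths through :func:`get_parameter` / :func:`with_overrides`.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cea import CEAResult, icer, nmb
from .exceptions import ConfigurationError, ValidationError
from .markov import HealthState, STATE_NAMES, StateRewards, TransitionModel
from .screening import ScreeningTest, Strategy, evaluate_strategy

__all__ = [
    "DistributionSpec",
    "PSASpec",
    "DSASpec",
    "ModelConfig",
    "BaseCaseResult",
    "run_base_case",
    "reference_config",
    "random_scenario",
    "get_parameter",
    "with_overrides",
    "list_parameters",
]

#: Adjacent progression edges, in severity order; the addressable transitions.
PROGRESSION_EDGES = tuple(
    f"{STATE_NAMES[i]}_to_{STATE_NAMES[i + 1]}" for i in range(len(STATE_NAMES) - 1)
)

_REFERENCE_RESOURCE = "reference_config.yaml"


@dataclass(frozen=True)
class DistributionSpec:
    """Second-order uncertainty declaration for one parameter path.

    ``kind`` is ``gamma`` (non-negative quantities: costs), ``beta``
    (probabilities and utilities) or ``fixed``; ``se`` is the standard error
    around the configuration's base value, which acts as the mean.
    """

    name: str
    kind: str
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "fixed"):
            raise ConfigurationError(f"{self.name}: unknown distribution kind {self.kind!r}")
        if self.se < 0:
            raise ConfigurationError(f"{self.name}: standard error must be >= 0")


@dataclass
class PSASpec:
    n_samples: int = 1000
    seed: int = 0
    distributions: list[DistributionSpec] = field(default_factory=list)


@dataclass
class DSASpec:
    relative_range: float = 0.2
    parameters: list[str] = field(default_factory=list)


@dataclass
class ModelConfig:
    """Full parameterization of the screening cost-effectiveness model."""

    rewards: StateRewards
    strategies: dict[str, Strategy]
    prevalence: float
    discount_rate: float = 0.03
    wtp: float = 40_000.0
    horizon: int = 30
    reward_timing: str = "start"
    confirmatory_exam_cost: float = 0.0
    reference_strategy: str = ""
    comparator_strategy: str = ""
    dsa: DSASpec = field(default_factory=DSASpec)
    psa: PSASpec = field(default_factory=PSASpec)
    meta: dict = field(default_factory=dict)
    sources: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(f"prevalence: must lie in [0, 1], got {self.prevalence}")
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate: must be >= 0")
        if self.wtp < 0:
            raise ConfigurationError("wtp: must be >= 0")
        if self.horizon < 1 or int(self.horizon) != self.horizon:
            raise ConfigurationError("horizon: must be a positive integer number of cycles")
        if self.reward_timing not in ("start", "end"):
            raise ConfigurationError("reward_timing: must be 'start' or 'end'")
        if self.confirmatory_exam_cost < 0:
            raise ConfigurationError("confirmatory_exam_cost: must be >= 0")
        if not self.strategies:
            raise ConfigurationError("strategies: at least one strategy is required")
        for key in ("reference_strategy", "comparator_strategy"):
            name = getattr(self, key)
            if name and name not in self.strategies:
                raise ConfigurationError(f"{key}: {name!r} is not a defined strategy")
        for spec in self.psa.distributions:
            try:
                value = get_parameter(self, spec.name)
            except ConfigurationError as err:
                raise ConfigurationError(f"psa.distributions: {err}") from err
            if spec.kind == "beta" and not 0.0 < value < 1.0:
                raise ConfigurationError(
                    f"psa.distributions.{spec.name}: beta requires a mean strictly in "
                    f"(0, 1), base value is {value}"
                )
            if spec.kind == "gamma" and value <= 0 and spec.se > 0:
                raise ConfigurationError(
                    f"psa.distributions.{spec.name}: gamma requires a positive mean, "
                    f"base value is {value}"
                )
        names = [d.name for d in self.psa.distributions]
        if len(names) != len(set(names)):
            raise ConfigurationError("psa.distributions: parameter names must be unique")
        for p in self.dsa.parameters:
            get_parameter(self, p)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        """Plain nested-dict form (the YAML document layout)."""

        def tagged(path: str, value) -> dict:
            return {"value": value, "source": self.sources.get(path, "assumption")}

        strategies = {}
        for name, s in self.strategies.items():
            entry: dict = {
                "entry_state": STATE_NAMES[int(s.entry_state)],
                "annual_service_cost": tagged(
                    f"{name}.annual_service_cost", float(s.annual_service_cost)
                ),
                "treated_transitions": self._transitions_dict(name, "treated", s.treated_transitions),
                "untreated_transitions": self._transitions_dict(
                    name, "untreated", s.untreated_transitions
                ),
            }
            if s.test is not None:
                entry["test"] = {
                    "sensitivity": tagged(f"{name}.sensitivity", float(s.test.sensitivity)),
                    "specificity": tagged(f"{name}.specificity", float(s.test.specificity)),
                    "cost_per_screen": tagged(
                        f"{name}.cost_per_screen", float(s.test.cost_per_screen)
                    ),
                    "fixed_program_cost": tagged(
                        f"{name}.fixed_program_cost", float(s.test.fixed_program_cost)
                    ),
                    "capacity": tagged(f"{name}.capacity", int(s.test.capacity)),
                }
            strategies[name] = entry

        return {
            "meta": copy.deepcopy(self.meta),
            "horizon": tagged("horizon", int(self.horizon)),
            "discount_rate": tagged("discount_rate", float(self.discount_rate)),
            "wtp": tagged("wtp", float(self.wtp)),
            "prevalence": tagged("prevalence", float(self.prevalence)),
            "confirmatory_exam_cost": tagged(
                "confirmatory_exam_cost", float(self.confirmatory_exam_cost)
            ),
            "reward_timing": self.reward_timing,
            "utilities": {
                s: tagged(f"utility.{s}", float(u))
                for s, u in zip(STATE_NAMES, self.rewards.utilities)
            },
            "state_costs": {
                s: tagged(f"cost.{s}", float(c))
                for s, c in zip(STATE_NAMES, self.rewards.annual_costs)
            },
            "reference_strategy": self.reference_strategy,
            "comparator_strategy": self.comparator_strategy,
            "strategies": strategies,
            "dsa": {
                "relative_range": float(self.dsa.relative_range),
                "parameters": list(self.dsa.parameters),
            },
            "psa": {
                "n_samples": int(self.psa.n_samples),
                "seed": int(self.psa.seed),
                "distributions": [
                    {"name": d.name, "kind": d.kind, "se": float(d.se)}
                    for d in self.psa.distributions
                ],
            },
        }

    def _transitions_dict(self, strategy: str, arm: str, tm: TransitionModel) -> dict:
        m = tm.matrix
        chain = TransitionModel.from_progression(tm.progression_probs, tm.arm_label)
        if np.allclose(m, chain.matrix, atol=1e-15):
            return {
                "kind": "progression",
                "probs": {
                    edge: {
                        "value": float(p),
                        "source": self.sources.get(f"{strategy}.{arm}.{edge}", "assumption"),
                    }
                    for edge, p in zip(PROGRESSION_EDGES, tm.progression_probs)
                },
            }
        return {"kind": "matrix", "rows": [[float(v) for v in row] for row in m]}

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        sources: dict = {}

        def untag(path: str, node, default_source="assumption"):
            if isinstance(node, dict) and "value" in node:
                sources[path] = node.get("source", default_source)
                return node["value"]
            return node

        def require(mapping: dict, key: str, where: str):
            if key not in mapping:
                raise ConfigurationError(f"{where}: missing required key {key!r}")
            return mapping[key]

        try:
            utilities = {
                s: float(untag(f"utility.{s}", require(doc["utilities"], s, "utilities")))
                for s in STATE_NAMES
            }
            costs = {
                s: float(untag(f"cost.{s}", require(doc["state_costs"], s, "state_costs")))
                for s in STATE_NAMES
            }
            rewards = StateRewards.from_mappings(utilities, costs)

            strategies = {}
            for name, entry in doc["strategies"].items():
                test = None
                if "test" in entry and entry["test"] is not None:
                    t = entry["test"]
                    test = ScreeningTest(
                        sensitivity=float(untag(f"{name}.sensitivity", require(t, "sensitivity", f"strategies.{name}.test"))),
                        specificity=float(untag(f"{name}.specificity", require(t, "specificity", f"strategies.{name}.test"))),
                        cost_per_screen=float(untag(f"{name}.cost_per_screen", t.get("cost_per_screen", 0.0))),
                        fixed_program_cost=float(untag(f"{name}.fixed_program_cost", t.get("fixed_program_cost", 0.0))),
                        capacity=int(untag(f"{name}.capacity", t.get("capacity", 1))),
                    )
                strategies[name] = Strategy(
                    name=name,
                    test=test,
                    treated_transitions=cls._transitions_from_dict(
                        name, "treated", entry["treated_transitions"], untag
                    ),
                    untreated_transitions=cls._transitions_from_dict(
                        name, "untreated", entry["untreated_transitions"], untag
                    ),
                    annual_service_cost=float(
                        untag(f"{name}.annual_service_cost", entry.get("annual_service_cost", 0.0))
                    ),
                    entry_state=HealthState[entry.get("entry_state", "at_risk").upper()],
                )

            dsa_doc = doc.get("dsa", {})
            psa_doc = doc.get("psa", {})
            return cls(
                rewards=rewards,
                strategies=strategies,
                prevalence=float(untag("prevalence", doc["prevalence"])),
                discount_rate=float(untag("discount_rate", doc.get("discount_rate", 0.03))),
                wtp=float(untag("wtp", doc.get("wtp", 40_000.0))),
                horizon=int(untag("horizon", doc.get("horizon", 30))),
                reward_timing=doc.get("reward_timing", "start"),
                confirmatory_exam_cost=float(
                    untag("confirmatory_exam_cost", doc.get("confirmatory_exam_cost", 0.0))
                ),
                reference_strategy=doc.get("reference_strategy", ""),
                comparator_strategy=doc.get("comparator_strategy", ""),
                dsa=DSASpec(
                    relative_range=float(dsa_doc.get("relative_range", 0.2)),
                    parameters=list(dsa_doc.get("parameters", [])),
                ),
                psa=PSASpec(
                    n_samples=int(psa_doc.get("n_samples", 1000)),
                    seed=int(psa_doc.get("seed", 0)),
                    distributions=[
                        DistributionSpec(
                            name=d["name"], kind=d["kind"], se=float(d.get("se", 0.0))
                        )
                        for d in psa_doc.get("distributions", [])
                    ],
                ),
                meta=copy.deepcopy(doc.get("meta", {})),
                sources=sources,
            )
        except (KeyError, TypeError) as err:
            raise ConfigurationError(f"malformed configuration document: {err}") from err
        except ValidationError as err:
            raise ConfigurationError(str(err)) from err

    @staticmethod
    def _transitions_from_dict(strategy: str, arm: str, node: dict, untag) -> TransitionModel:
        kind = node.get("kind", "progression")
        if kind == "progression":
            probs = [
                float(untag(f"{strategy}.{arm}.{edge}", require_edge))
                for edge, require_edge in (
                    (e, node["probs"][e]) for e in PROGRESSION_EDGES
                )
            ]
            return TransitionModel.from_progression(probs, arm_label=arm)
        if kind == "matrix":
            return TransitionModel(np.asarray(node["rows"], dtype=float), arm_label=arm)
        raise ConfigurationError(
            f"strategies.{strategy}.{arm}_transitions: unknown kind {kind!r}"
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError("configuration document must be a YAML mapping")
        return cls.from_dict(doc)

    def config_hash(self) -> str:
        """Stable digest of the configuration content (for provenance files)."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# -- dotted-path parameter access --------------------------------------


def _parameter_accessors(config: ModelConfig):
    """Yield (path, getter) pairs for every addressable scalar."""
    yield "prevalence", lambda c: c.prevalence
    yield "discount_rate", lambda c: c.discount_rate
    yield "wtp", lambda c: c.wtp
    yield "confirmatory_exam_cost", lambda c: c.confirmatory_exam_cost
    for i, s in enumerate(STATE_NAMES):
        yield f"utility.{s}", (lambda c, i=i: float(c.rewards.utilities[i]))
        yield f"cost.{s}", (lambda c, i=i: float(c.rewards.annual_costs[i]))
    # shared natural-history edges: one alias that reads/writes the untreated
    # arm of every strategy at once (strategies share disease natural history)
    first = next(iter(config.strategies))
    for j, edge in enumerate(PROGRESSION_EDGES):
        yield f"natural_history.{edge}", (
            lambda c, f=first, j=j: float(
                c.strategies[f].untreated_transitions.progression_probs[j]
            )
        )
    for name, strat in config.strategies.items():
        if strat.test is not None:
            yield f"{name}.sensitivity", (lambda c, n=name: c.strategies[n].test.sensitivity)
            yield f"{name}.specificity", (lambda c, n=name: c.strategies[n].test.specificity)
            yield f"{name}.cost_per_screen", (
                lambda c, n=name: c.strategies[n].test.cost_per_screen
            )
        yield f"{name}.annual_service_cost", (
            lambda c, n=name: c.strategies[n].annual_service_cost
        )
        for arm in ("treated", "untreated"):
            for j, edge in enumerate(PROGRESSION_EDGES):
                yield f"{name}.{arm}.{edge}", (
                    lambda c, n=name, a=arm, j=j: float(
                        getattr(c.strategies[n], f"{a}_transitions").progression_probs[j]
                    )
                )


def list_parameters(config: ModelConfig) -> list[str]:
    """All dotted parameter paths addressable on this configuration."""
    return [path for path, _ in _parameter_accessors(config)]


def get_parameter(config: ModelConfig, path: str) -> float:
    for candidate, getter in _parameter_accessors(config):
        if candidate == path:
            return getter(config)
    raise ConfigurationError(f"unknown parameter path {path!r}")


def with_overrides(config: ModelConfig, overrides: dict) -> ModelConfig:
    """A new validated configuration with the given parameter values replaced."""
    known = set(list_parameters(config))
    unknown = set(overrides) - known
    if unknown:
        raise ConfigurationError(f"unknown parameter path(s): {sorted(unknown)}")
    doc = config.to_dict()

    def nodes_for(path: str) -> list:
        parts = path.split(".")
        if parts[0] == "utility":
            return [doc["utilities"][parts[1]]]
        if parts[0] == "cost":
            return [doc["state_costs"][parts[1]]]
        if parts[0] == "natural_history":
            return [
                entry["untreated_transitions"]["probs"][parts[1]]
                for entry in doc["strategies"].values()
            ]
        if len(parts) == 1:
            return [doc[parts[0]]]
        entry = doc["strategies"][parts[0]]
        if len(parts) == 2:
            if parts[1] in ("sensitivity", "specificity", "cost_per_screen"):
                return [entry["test"][parts[1]]]
            return [entry[parts[1]]]
        return [entry[f"{parts[1]}_transitions"]["probs"][parts[2]]]

    for path, value in overrides.items():
        for node in nodes_for(path):
            node["value"] = float(value)
    return ModelConfig.from_dict(doc)


# -- base case ----------------------------------------------------------


@dataclass(frozen=True)
class BaseCaseResult:
    """Deterministic per-strategy outcomes plus the incremental comparison."""

    outcomes: dict
    cea: CEAResult
    wtp: float

    def nmb(self, strategy: str) -> float:
        o = self.outcomes[strategy]
        return nmb(o.expected_cost, o.expected_qaly, self.wtp)

    def to_report(self) -> dict:
        return {
            "strategies": {
                name: {
                    "cost": o.expected_cost,
                    "effect": o.expected_qaly,
                    "cer": (o.expected_cost / o.expected_qaly) if o.expected_qaly else None,
                    "nmb_at_wtp": self.nmb(name),
                }
                for name, o in self.outcomes.items()
            },
            "incremental": self.cea.to_dict(),
            "wtp": self.wtp,
            "limitations": [
                "closed cohort without background mortality; results are per "
                "patient entering the screening pathway"
            ],
        }


def run_base_case(config: ModelConfig) -> BaseCaseResult:
    """Evaluate every strategy at base-case values and compare ref vs comp."""
    if not config.reference_strategy or not config.comparator_strategy:
        raise ConfigurationError(
            "run_base_case requires reference_strategy and comparator_strategy"
        )
    outcomes = {
        name: evaluate_strategy(
            strategy,
            prevalence=config.prevalence,
            rewards=config.rewards,
            n_cycles=config.horizon,
            discount_rate=config.discount_rate,
            confirmatory_cost=config.confirmatory_exam_cost,
            reward_timing=config.reward_timing,
        )
        for name, strategy in config.strategies.items()
    }
    ref = outcomes[config.reference_strategy]
    comp = outcomes[config.comparator_strategy]
    result = icer(
        ref.expected_cost,
        ref.expected_qaly,
        comp.expected_cost,
        comp.expected_qaly,
        ref_name=config.reference_strategy,
        comp_name=config.comparator_strategy,
    )
    return BaseCaseResult(outcomes=outcomes, cea=result, wtp=config.wtp)


# -- shipped reference set and random scenarios -------------------------


def reference_config() -> ModelConfig:
    """The shipped calibrated reference parameter set.

    Utilities and test characteristics are the published values; transition
    probabilities, state costs and program costs are calibrated so the
    30-year model reproduces the published per-strategy cost/effect summary
    and the teleglaucoma cohort's 30-year state occupancy (see
    :mod:`glaucoma_cea.calibrate`).
    """
    resource = importlib.resources.files("glaucoma_cea").joinpath(
        f"data/{_REFERENCE_RESOURCE}"
    )
    with resource.open() as fh:
        return ModelConfig.from_yaml(fh)


def random_scenario(seed: int) -> ModelConfig:
    """A random valid configuration for property-based testing.

    Scenarios have ordered utilities, non-negative costs, adjacent
    progression with the treated arm no faster than the untreated arm, and a
    two-strategy layout (screening vs no-screening comparator), so every
    engine invariant is exercisable on them.
    """
    rng = np.random.default_rng(seed)
    utilities = {"at_risk": 1.0}
    disease_u = np.sort(rng.uniform(0.3, 0.99, size=4))[::-1]
    for s, u in zip(STATE_NAMES[1:], disease_u):
        utilities[s] = float(u)
    costs = {
        s: float(c)
        for s, c in zip(STATE_NAMES, np.cumsum(rng.uniform(5.0, 300.0, size=5)))
    }
    untreated = rng.uniform(0.05, 0.6, size=4)
    treated = untreated * rng.uniform(0.2, 0.95, size=4)

    doc = {
        "meta": {"name": f"random-scenario-{seed}", "currency": "CAD"},
        "horizon": int(rng.integers(5, 36)),
        "discount_rate": float(rng.uniform(0.0, 0.05)),
        "wtp": float(rng.uniform(10_000, 100_000)),
        "prevalence": float(rng.uniform(0.02, 0.6)),
        "confirmatory_exam_cost": float(rng.uniform(0.0, 300.0)),
        "reward_timing": "start",
        "utilities": utilities,
        "state_costs": costs,
        "reference_strategy": "screening",
        "comparator_strategy": "no_screening",
        "strategies": {
            "screening": {
                "entry_state": "at_risk",
                "annual_service_cost": float(rng.uniform(0.0, 50.0)),
                "test": {
                    "sensitivity": float(rng.uniform(0.5, 1.0)),
                    "specificity": float(rng.uniform(0.5, 1.0)),
                    "cost_per_screen": float(rng.uniform(0.0, 200.0)),
                    "capacity": int(rng.integers(50, 2000)),
                },
                "treated_transitions": {
                    "kind": "progression",
                    "probs": {e: float(p) for e, p in zip(PROGRESSION_EDGES, treated)},
                },
                "untreated_transitions": {
                    "kind": "progression",
                    "probs": {e: float(p) for e, p in zip(PROGRESSION_EDGES, untreated)},
                },
            },
            "no_screening": {
                "entry_state": "at_risk",
                "annual_service_cost": float(rng.uniform(0.0, 200.0)),
                "treated_transitions": {
                    "kind": "progression",
                    "probs": {e: float(p) for e, p in zip(PROGRESSION_EDGES, treated)},
                },
                "untreated_transitions": {
                    "kind": "progression",
                    "probs": {e: float(p) for e, p in zip(PROGRESSION_EDGES, untreated)},
                },
            },
        },
        "dsa": {"relative_range": 0.2, "parameters": ["prevalence", "cost.blind"]},
        "psa": {
            "n_samples": 200,
            "seed": int(rng.integers(0, 2**31 - 1)),
            "distributions": [
                {"name": "prevalence", "kind": "beta", "se": 0.03},
                {"name": "cost.blind", "kind": "gamma", "se": float(costs["blind"] * 0.2)},
                {"name": "screening.sensitivity", "kind": "beta", "se": 0.02},
            ],
        },
    }
    return ModelConfig.from_dict(doc)
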