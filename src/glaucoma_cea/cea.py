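"""Incremental cost-effectiveness statistics.

Conventions: the *reference* strategy is the intervention of interest
(teleglaucoma in the shipped configuration) and the *comparator* is the
standard of care.  Incremental cost and effect are reported as
``comparator - reference`` (the comparator row of a league table), while
the headline ICER is ``(ref_cost - comp_cost) / (ref_effect - comp_effect)``
— the reference strategy's perspective — so a strategy that is cheaper and
more effective carries a negative ICER (savings per QALY gained) together
with a dominance flag.  The average cost-effectiveness ratio (CER,
cost/effect of each strategy alone) is reported alongside because league
tables conventionally print both.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

from .exceptions import ValidationError

__all__ = ["CEAResult", "icer", "nmb", "percent_cost_reduction"]


@dataclass(frozen=True)
class CEAResult:
    """Two-strategy incremental comparison.

    ``dominance`` describes the *comparator* relative to the reference:
    ``"dominated"`` when the comparator costs more and yields less,
    ``"dominant"`` when it costs less and yields more, else ``"none"``.
    ``icer`` is ``None`` (with ``icer_defined=False``) when the incremental
    effect is zero; dominance is still classified in that case.
    """

    ref_name: str
    comp_name: str
    ref_cost: float
    ref_effect: float
    comp_cost: float
    comp_effect: float
    incremental_cost: float
    incremental_effect: float
    icer: Optional[float]
    icer_defined: bool
    ref_cer: Optional[float]
    comp_cer: Optional[float]
    dominance: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        payload = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _cer(cost: float, effect: float) -> Optional[float]:
    return cost / effect if effect != 0 else None


def icer(
    ref_cost: float,
    ref_effect: float,
    comp_cost: float,
    comp_effect: float,
    ref_name: str = "reference",
    comp_name: str = "comparator",
) -> CEAResult:
    """Incremental cost-effectiveness of the reference versus the comparator."""
    for v in (ref_cost, ref_effect, comp_cost, comp_effect):
        if not (v == v and abs(v) != float("inf")):
            raise ValidationError("costs and effects must be finite")

    inc_cost = comp_cost - ref_cost
    inc_effect = comp_effect - ref_effect
    if inc_cost > 0 and inc_effect < 0:
        dominance = "dominated"
    elif inc_cost < 0 and inc_effect > 0:
        dominance = "dominant"
    else:
        dominance = "none"

    delta_effect = ref_effect - comp_effect
    if delta_effect == 0:
        ratio, defined = None, False
    else:
        ratio, defined = (ref_cost - comp_cost) / delta_effect, True
    return CEAResult(
        ref_name=ref_name,
        comp_name=comp_name,
        ref_cost=float(ref_cost),
        ref_effect=float(ref_effect),
        comp_cost=float(comp_cost),
        comp_effect=float(comp_effect),
        incremental_cost=float(inc_cost),
        incremental_effect=float(inc_effect),
        icer=ratio,
        icer_defined=defined,
        ref_cer=_cer(ref_cost, ref_effect),
        comp_cer=_cer(comp_cost, comp_effect),
        dominance=dominance,
    )


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * effect - cost`` at a willingness to pay.

    At any WTP the strategy with the higher NMB is exactly the one the
    ICER-threshold decision rule selects.
    """
    if wtp < 0:
        raise ValidationError(f"willingness to pay must be >= 0, got {wtp}")
    return float(wtp * effect - cost)


def percent_cost_reduction(ref_cost: float, comp_cost: float) -> float:
    """Percent by which the reference strategy undercuts the comparator's cost."""
    if comp_cost == 0:
        raise ValidationError("comparator cost must be non-zero")
    return float(100.0 * (comp_cost - ref_cost) / comp_cost)
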