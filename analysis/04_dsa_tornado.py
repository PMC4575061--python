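#!/usr/bin/env python
"""Deterministic sensitivity analysis: one-way sweeps and tornado diagram.

Sweeps the cost of blindness and the key transition probabilities +/-20%
around the base case, reports the direction of the ICER response, and
ranks the configured uncertain parameters by their incremental
net-monetary-benefit swing at the configured willingness to pay.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from glaucoma_cea import one_way_dsa, reference_config, tornado
from glaucoma_cea.sensitivity import tornado_frame

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dsa"

SWEPT = [
    "cost.blind",
    "teleglaucoma.treated.at_risk_to_mild",
    "teleglaucoma.treated.severe_to_blind",
    "natural_history.at_risk_to_mild",
    "natural_history.severe_to_blind",
]


def main() -> None:
    config = reference_config()
    OUT.mkdir(parents=True, exist_ok=True)

    curves = []
    for param in SWEPT:
        curve = one_way_dsa(config, param, relative_range=0.2, grid_size=9)
        curves.append(curve)
        lo, hi = curve.icer.iloc[0], curve.icer.iloc[-1]
        print(f"{param:45s} ICER {lo:12,.0f} -> {hi:12,.0f} CAD/QALY")
    pd.concat(curves, ignore_index=True).to_csv(OUT / "one_way_curves.csv", index=False)

    blind = curves[0]
    direction = "falls (more savings per QALY)" if blind.icer.iloc[-1] < blind.icer.iloc[0] \
        else "rises"
    print(f"\nas the cost of blindness rises, the teleglaucoma ICER {direction}")

    entries = tornado(config)
    frame = tornado_frame(entries)
    frame.to_csv(OUT / "tornado.csv", index=False)
    print("\ntornado (incremental NMB swing at configured WTP):")
    print(frame.round(1).to_string(index=False))

    fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1))
    base_nmb = None
    for i, e in enumerate(reversed(entries)):
        ax.barh(i, e.nmb_at_high - e.nmb_at_low, left=e.nmb_at_low, height=0.6)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in reversed(entries)], fontsize=8)
    ax.set_xlabel("incremental NMB (CAD), teleglaucoma vs in-person")
    fig.tight_layout()
    fig.savefig(OUT / "tornado.png", dpi=150)


if __name__ == "__main__":
    main()
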