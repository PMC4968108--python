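#!/usr/bin/env python
"""Exposure simulations: how a batch's initial attribute level shapes AUC.

Sweeps the initial modified fraction f for the deamidation and Man5 models
(published parameter sets, day 0-42 window), reporting attribute, total and
relative AUC per level — the deamidation total is constant (equal
clearance), while higher Man5 loads depress total exposure. Also draws the
simulated modified-form PK curves at each initial level.
"""

import dataclasses
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from qapk.exposure import calibrate_scale, relative_auc_sweep
from qapk.pk_model import reference_params, simulate

OUT = Path("results/exposure")
LEVELS = {"deamidation": [0.0, 5.6, 11.2, 27.8], "man5": [0.0, 3.0, 6.0, 14.9]}
REFERENCE_TOTAL = {"deamidation": 209.7, "man5": 212.8}  # h x mg/mL at 0% level


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    grid = np.linspace(0.0, 42.0, 300)
    for ax, (name, levels) in zip(axes, LEVELS.items()):
        params = reference_params(name)
        scale = calibrate_scale(params, REFERENCE_TOTAL[name], reference_f=0.0)
        for level, s in zip(levels, relative_auc_sweep(
            params, [lv / 100 for lv in levels], scale=scale
        )):
            rows.append((name, level, round(s.attribute_auc, 1), round(s.total_auc, 1),
                         round(s.relative_auc_pct, 1)))
            traj = simulate(dataclasses.replace(params, f=level / 100), grid)
            ax.plot(grid, scale * traj.cmod / 24.0, label=f"{level:g}%")
        ax.set_title(f"{name} (modified form)")
        ax.set_xlabel("time (days)")
        ax.set_yscale("log")
        ax.legend(title="initial level", fontsize=8)
    axes[0].set_ylabel("central concentration (scaled)")
    fig.tight_layout()
    fig.savefig(OUT / "simulated_pk_curves.png", dpi=120)

    table = pd.DataFrame(
        rows, columns=["attribute", "initial_level_pct", "attribute_auc_h_mg_ml",
                       "total_auc_h_mg_ml", "relative_auc_pct"]
    )
    table.to_csv(OUT / "exposure_table.csv", index=False)
    print(table.to_string(index=False))
    deam = table[table["attribute"] == "deamidation"]
    print("\ndeamidation: total AUC constant at "
          f"{deam['total_auc_h_mg_ml'].iloc[0]} h*mg/mL across initial levels; "
          "a 2x initial-level increase (5.6% -> 11.2%) raises the deamidated "
          f"share only {deam['relative_auc_pct'].iloc[1]}% -> "
          f"{deam['relative_auc_pct'].iloc[2]}% — conversion dominates.")
    man5 = table[table["attribute"] == "man5"]
    print("man5: relative AUC tracks the initial level "
          f"({man5['relative_auc_pct'].tolist()}% at {man5['initial_level_pct'].tolist()}%), "
          "and total exposure falls with higher initial load — clearance dominates.")


if __name__ == "__main__":
    main()
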