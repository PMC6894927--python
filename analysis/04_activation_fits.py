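#!/usr/bin/env python
"""Per-cell Boltzmann fits, mean activation, cAMP shift, kinetics, statistics.

Reads the activation CSVs and the current trace written by
01_simulate_inputs.py, fits each cell with I(V) = A/(1+exp((V-V1/2)/k)),
averages parameters per construct (mean ± SEM), measures the
cAMP-induced V1/2 shift, fits the exponential deactivation time
constant, and compares construct V1/2 groups by one-way ANOVA with
Fisher's LSD.

Writes results/ephys/: cell_fits.tsv, summary.tsv, comparison.txt.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from crankshaft.ephys import (
    ActivationDataset,
    camp_shift,
    compare_groups,
    fit_boltzmann,
    fit_exponential,
    mean_activation,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "results" / "inputs")
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "results" / "ephys")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    fit_rows, summaries = [], {}
    for csv in sorted(args.inputs.glob("activation_*.csv")):
        df = pd.read_csv(csv)
        fits = [fit_boltzmann(ds) for ds in ActivationDataset.from_frame(df)]
        key = (fits[0].construct, fits[0].condition)
        summaries[key] = mean_activation(fits)
        fit_rows += [{
            "construct": f.construct, "condition": f.condition,
            "cell_id": f.cell_id, "v_half_mV": f.v_half, "k_mV": f.k_slope,
            "amplitude_pA": f.amplitude} for f in fits]
    pd.DataFrame(fit_rows).to_csv(out / "cell_fits.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    pd.DataFrame([
        {"construct": c, "condition": cond, "n": s.n,
         "v_half_mean_mV": s.v_half_mean, "v_half_sem_mV": s.v_half_sem,
         "k_mean_mV": s.k_mean, "k_sem_mV": s.k_sem}
        for (c, cond), s in summaries.items()
    ]).to_csv(out / "summary.tsv", sep="\t", index=False,
              float_format="%.6g")
    for (c, cond), s in summaries.items():
        print(f"{c}/{cond}: V1/2 = {s.v_half_mean:.1f} ± {s.v_half_sem:.1f}"
              f" mV, k = {s.k_mean:.2f} ± {s.k_sem:.2f} mV (n={s.n})")

    shift, sem = camp_shift(summaries[("wt", "control")],
                            summaries[("wt", "cAMP")])
    print(f"cAMP-induced shift (wt): {shift:+.1f} ± {sem:.1f} mV")

    trace = pd.read_csv(args.inputs / "trace.csv")
    kin = fit_exponential(trace["time_s"].to_numpy(),
                          trace["current_pA"].to_numpy(), window=(0.0, 3.0))
    print(f"deactivation tau: {kin.tau * 1e3:.1f} ms "
          f"(mono-exponential, {kin.n_points} samples)")

    groups = {c: [r["v_half_mV"] for r in fit_rows
                  if r["construct"] == c and r["condition"] == "control"]
              for c, cond in summaries if cond == "control"}
    comparison = compare_groups(groups)
    lines = [f"{comparison.method}: statistic={comparison.statistic:.4g} "
             f"p={comparison.p_value:.3g} significant={comparison.significant}"]
    if comparison.pairwise:
        lines += [f"  {a} vs {b}: p={p:.3g}"
                  for (a, b), p in comparison.pairwise.items()]
    (out / "comparison.txt").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
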