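#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/:
  - coupled_assembly.pdb / coupled_assembly_severed.pdb — C4 toy
    tetramers (vsd/hcnd/linker domains annotated in domains.yaml)
  - activation_<construct>.csv — per-cell tail-current datasets for the
    four mutant-cycle constructs (HCN2 protocol, 2% amplitude noise)
  - activation_wt_cAMP.csv — wt dataset shifted +16.7 mV (cAMP on)
  - trace.csv — 5 kHz mono-exponential current trace (tau = 500 ms)
  - gas_frames.txt / shell_frames.txt — point trajectories for g(r)
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from crankshaft.ephys import ConstructEnergetics
from crankshaft.structures import write_morph
from crankshaft.synth import (
    make_activation_dataset,
    make_coupled_assembly,
    make_current_trace,
    make_energy_table,
    make_ideal_gas_traj,
    make_shell_traj,
)


def dump_cells(cells, path):
    rows = [
        {"cell_id": c.cell_id, "construct": c.construct,
         "condition": c.condition, "voltage_mV": v, "tail_pA": i}
        for c in cells for v, i in zip(c.voltage_mV, c.tail_pA)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def dump_traj(traj, path):
    lines = []
    for fi in range(traj.n_frames):
        for ai, (c, r, a) in enumerate(traj.atom_labels):
            x, y, z = traj.frames[fi, ai]
            lines.append(f"{fi} {traj.times[fi]} {c} {r} {a} "
                         f"{x:.4f} {y:.4f} {z:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "results" / "inputs")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # toy tetramers
    for severed, name in ((False, "coupled_assembly.pdb"),
                          (True, "coupled_assembly_severed.pdb")):
        asm = make_coupled_assembly(seed=args.seed, severed=severed)
        write_morph(asm.structure, np.zeros_like(asm.structure.coords),
                    n_frames=2, path=out / name)
        if not severed:
            (out / "domains.yaml").write_text(yaml.safe_dump({
                "sites": asm.sites,
                "domains": {k: f"{v.residue_range[0]}-{v.residue_range[1]}"
                            for k, v in asm.domains.items()}}))
    print(f"wrote toy tetramers (N = {asm.structure.n_beads} beads, "
          f"intact + severed)")

    # mutant-cycle activation datasets: wt anchored at the measured
    # V1/2 = -96.7 mV, k = 8 mV; -2.0 kcal/mol coupling dialled in
    table = make_energy_table(
        ConstructEnergetics("wt", -96.7, 8.0),
        dg_p1=1.4, dg_p2=-0.6, coupling=-2.0,
        labels=("R154A", "E478A", "R154A-E478A"))
    for ci, construct in enumerate(table):
        cells = make_activation_dataset(
            construct.v_half, construct.k_slope, amplitude=500.0,
            noise_frac=0.02, n_cells=20, seed=args.seed * 131 + ci,
            construct=construct.construct)
        safe = construct.construct.replace("/", "-")
        dump_cells(cells, out / f"activation_{safe}.csv")
    print("wrote 4 construct datasets "
          f"(true V1/2: {', '.join(f'{c.v_half:.1f}' for c in table)} mV)")

    camp = make_activation_dataset(
        -96.7 + 16.7, 8.0, 650.0, noise_frac=0.02, n_cells=20,
        seed=args.seed * 131 + 9, condition="cAMP")
    dump_cells(camp, out / "activation_wt_cAMP.csv")
    print("wrote wt + cAMP dataset (true shift +16.7 mV)")

    t, i = make_current_trace(i0=400.0, tau=0.5, duration=5.0, rate=5000.0,
                              noise=4.0, seed=args.seed)
    pd.DataFrame({"time_s": t, "current_pA": i}).to_csv(
        out / "trace.csv", index=False, float_format="%.8g")
    print(f"wrote current trace ({len(t)} samples at 5 kHz, tau = 500 ms)")

    dump_traj(make_ideal_gas_traj(0.05, [40, 40, 40], n_frames=150,
                                  seed=args.seed), out / "gas_frames.txt")
    dump_traj(make_shell_traj(shell_radius=3.1, n_shell=64, n_frames=25,
                              seed=args.seed), out / "shell_frames.txt")
    print("wrote g(r) trajectories (uniform gas, 3.1 Å shell)")


if __name__ == "__main__":
    main()
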