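#!/usr/bin/env python
"""Random-force perturbation experiment on the toy tetramer.

Protocol: 1000 uniformly random force directions applied C4-symmetrically
(magnitude 1600 a.u.) at the linker, hcnd and vsd sites of the coupled
assembly; responses clustered by linker ("shoulder") displacement with
elbow-selected k; best-matching clusters compared across sites by the
cosine similarity of their domain mean displacements.

A mechanically continuous assembly should move its domains the same way
no matter where the force is applied; the severed assembly should not.

Writes results/lrt/: per-site domain-motion tables, elbow tables,
concordance summary, and a morph PDB of the reference cluster response.
"""

import argparse
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from crankshaft.anm import build_anm
from crankshaft.perturbation import run_concordance
from crankshaft.structures import write_morph
from crankshaft.synth import make_coupled_assembly


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-samples", type=int, default=1000)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "results" / "lrt")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    for severed in (False, True):
        label = "severed" if severed else "intact"
        asm = make_coupled_assembly(seed=args.seed, severed=severed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = build_anm(asm.structure)  # 13 Å cutoff, uniform springs
        result = run_concordance(
            model, asm.sites, asm.domains["linker"], asm.domains,
            reference_site="linker", n_samples=args.n_samples,
            magnitude=1600.0, seed=args.seed)
        for site, report in result.reports.items():
            report.motion_table().to_csv(
                out / f"{label}_{site}_motions.tsv", sep="\t", index=False,
                float_format="%.6g")
            pd.DataFrame({
                "k": list(report.max_withinss_by_k),
                "log_max_withinss": list(report.max_withinss_by_k.values()),
            }).to_csv(out / f"{label}_{site}_elbow.tsv", sep="\t",
                      index=False, float_format="%.6g")
        for (a, b), sims in result.similarities.items():
            for domain, cos in sims.items():
                summary_rows.append({
                    "assembly": label, "site_a": a, "site_b": b,
                    "domain": domain, "cosine": cos})
        print(f"{label}: chosen k per site = "
              f"{ {s: r.chosen_k for s, r in result.reports.items()} }, "
              f"min cross-site cosine = {result.min_similarity:.3f}")
        if not severed:
            ref = result.reports["linker"].representative_responses[0]
            umax = float(np.abs(ref.displacements).max())
            write_morph(asm.structure, ref, scale=5.0 / umax, n_frames=11,
                        path=out / "reference_cluster_morph.pdb")

    pd.DataFrame(summary_rows).to_csv(out / "concordance.tsv", sep="\t",
                                      index=False, float_format="%.4f")
    intact = [r for r in summary_rows if r["assembly"] == "intact"]
    severed = [r for r in summary_rows if r["assembly"] == "severed"]
    print(f"intact assembly: all {len(intact)} site-pair/domain cosines "
          f">= {min(r['cosine'] for r in intact):.3f} -> one concerted "
          "rotation regardless of perturbation site")
    print(f"severed assembly: min cosine {min(r['cosine'] for r in severed):.3f}"
          " -> the mechanical path through the linker ring is required")


if __name__ == "__main__":
    main()
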