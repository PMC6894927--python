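"""Synthetic inputs with known ground truth.

Every generator is a pure function of its parameters and an explicit
seed, and emulates one class of input the pipeline consumes:

- C4-symmetric bead structures about the z-axis (the tetrameric channel
  geometry at coarse-grained scale);
- a "coupled assembly" toy whose three annotated domains per chain —
  vsd, hcnd and linker — form the mechanical path the channel study
  probes (inter-chain linker→hcnd contacts, intra-chain hcnd→vsd), with
  a severed variant whose linker ring is detached;
- Boltzmann-shaped activation datasets at the isoform voltage protocols
  with Gaussian amplitude noise;
- mono-exponential current traces at patch-clamp sampling rates;
- labelled Gaussian blobs (clustering oracle);
- four-construct energy tables with a dialled-in coupling energy;
- ideal-gas (uniform) point trajectories around a fixed reference atom
  (g(r) oracle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .anm import rotation_about_z
from .ephys import (
    ActivationDataset,
    ConstructEnergetics,
    VoltageProtocol,
    HCN2_PROTOCOL,
    delta_g_app,
    R_KCAL,
    DEFAULT_TEMPERATURE,
)
from .structures import CoarseGrainedStructure, ResidueSelection
from .traj import TrajectoryEnsemble

__all__ = [
    "make_c4_structure",
    "make_coupled_assembly",
    "CoupledAssembly",
    "make_activation_dataset",
    "make_current_trace",
    "make_cluster_blobs",
    "make_energy_table",
    "make_ideal_gas_traj",
    "make_shell_traj",
]

_CHAINS = ("A", "B", "C", "D")


def _c4_replicate(chain_a: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Replicate chain A beads as exact 90° z-rotation images on chains B-D."""
    coords, chains = [], []
    for k, label in enumerate(_CHAINS):
        rot = rotation_about_z(90.0 * k)
        coords.append(chain_a @ rot.T)
        chains.extend([label] * len(chain_a))
    return np.vstack(coords), chains


def make_c4_structure(n_res_per_chain: int = 50,
                      radius: float = 15.0,
                      pitch: float = 1.6,
                      seed: int = 0,
                      jitter: float = 0.4) -> CoarseGrainedStructure:
    """Four-chain helical bead structure with exact C4 symmetry about z.

    Chain A is a jittered helical trace (bead spacing set by ``pitch``
    and the angular step, roughly the 3.8 Å Cα-Cα distance scale); chains
    B-D are its exact Rz(90°/180°/270°) images, so rotating the
    coordinates by 90° about z and permuting chains A→B→C→D→A reproduces
    the structure to machine precision.
    """
    if n_res_per_chain < 10:
        raise ValueError("need at least 10 residues per chain")
    rng = np.random.default_rng(seed)
    t = np.arange(n_res_per_chain, dtype=float)
    u = t / (n_res_per_chain - 1)
    # radial coordinate ramps outward from near the symmetry axis, so the
    # four chains meet (within the spring cutoff) around the pore axis
    r = 4.0 + (radius - 4.0) * u
    angle = 0.22 * t                      # rad per residue along the helix
    chain_a = np.column_stack([
        r * np.cos(0.3 * angle),
        r * np.sin(0.3 * angle),
        pitch * t,
    ])
    chain_a = chain_a + rng.normal(0, jitter, (n_res_per_chain, 3))
    coords, chains = _c4_replicate(chain_a)
    n = n_res_per_chain
    return CoarseGrainedStructure(
        coords=coords,
        chain_ids=np.array(chains),
        residue_numbers=np.tile(np.arange(1, n + 1), 4),
        residue_names=np.full(4 * n, "ALA"),
        source=f"synthetic C4 helix (n={n_res_per_chain}, seed={seed})",
    )


@dataclass(frozen=True)
class CoupledAssembly:
    """Synthetic tetramer with annotated vsd/hcnd/linker domains.

    ``domains`` maps domain names to residue selections over all chains;
    ``sites`` names one representative perturbation residue per domain
    (mid-domain bead, present in all four chains).
    """

    structure: CoarseGrainedStructure
    domains: dict[str, ResidueSelection]
    sites: dict[str, int]
    severed: bool


def make_coupled_assembly(seed: int = 0, severed: bool = False,
                          n_per_domain: int = 10) -> CoupledAssembly:
    """Toy tetramer in which linker, hcnd and vsd form a mechanical path.

    Per chain, three bead segments stacked along z: "vsd" on top, "hcnd"
    in the middle (backbone-continuous with vsd), and a separate "linker"
    segment at the bottom that reaches azimuthally toward the *next*
    chain so its contact beads sit within the 13 Å spring cutoff of that
    chain's hcnd — an inter-subunit ring, as in the channel's gating
    ring. With ``severed=True`` the linker segments are displaced
    radially outward so every linker–hcnd contact is broken and the
    mechanical path through the ring disappears (the spring network then
    splits into components).
    """
    if n_per_domain < 4:
        raise ValueError("need at least 4 beads per domain")
    rng = np.random.default_rng(seed)
    m = n_per_domain
    radius = 16.0

    # vsd (top half) + hcnd (bottom half): one continuous α-helix-like
    # column winding about the chain axis at (radius, 0); the helical
    # geometry gives the column genuine transverse stiffness in the
    # spring network (a straight bead column would have zero-energy
    # bending modes).
    t = np.arange(2 * m, dtype=float)
    helix = np.column_stack([
        radius + 2.3 * np.cos(1.75 * t),
        2.3 * np.sin(1.75 * t),
        (2 * m - 1 - t) * 1.5 - 6.0,      # descends to z ~ -6 + 1.5
    ])
    vsd, hcnd = helix[:m], helix[m:]
    # linker: z- and radially-modulated arc below the hcnd, sweeping from
    # this chain's azimuth toward the next chain's (at +90°) so its last
    # beads contact the neighboring hcnd within the 13 Å cutoff
    sweep = np.linspace(0.30, 1.35, m)
    j = np.arange(m, dtype=float)
    r_arc = radius + 1.5 * np.sin(1.3 * j)
    z_arc = -10.0 + 1.2 * np.cos(2.2 * j)
    linker = np.column_stack([r_arc * np.cos(sweep), r_arc * np.sin(sweep),
                              z_arc])
    if severed:
        # push the ring outward: beyond cutoff of every hcnd, still a ring
        direction = linker[:, :2] / np.linalg.norm(linker[:, :2], axis=1,
                                                   keepdims=True)
        linker = linker.copy()
        linker[:, :2] += 30.0 * direction
    chain_a = np.vstack([vsd, hcnd, linker])
    chain_a = chain_a + rng.normal(0, 0.3, chain_a.shape)
    coords, chains = _c4_replicate(chain_a)
    n = 3 * m
    structure = CoarseGrainedStructure(
        coords=coords,
        chain_ids=np.array(chains),
        residue_numbers=np.tile(np.arange(1, n + 1), 4),
        residue_names=np.full(4 * n, "ALA"),
        source=("synthetic coupled assembly"
                + (" (severed)" if severed else "")
                + f" seed={seed}"),
    )
    domains = {
        "vsd": ResidueSelection.from_range(1, m),
        "hcnd": ResidueSelection.from_range(m + 1, 2 * m),
        "linker": ResidueSelection.from_range(2 * m + 1, 3 * m),
    }
    sites = {"vsd": m // 2, "hcnd": m + m // 2, "linker": 2 * m + m // 2}
    return CoupledAssembly(structure=structure, domains=domains, sites=sites,
                           severed=severed)


def make_activation_dataset(v_half: float,
                            k_slope: float,
                            amplitude: float,
                            protocol: VoltageProtocol = HCN2_PROTOCOL,
                            noise_frac: float = 0.02,
                            n_cells: int = 10,
                            seed: int = 0,
                            construct: str = "wt",
                            condition: str = "control"
                            ) -> list[ActivationDataset]:
    """Per-cell Boltzmann activation data with Gaussian amplitude noise.

    Each cell's tail amplitude at protocol voltage V is
    A/(1+exp((V−V1/2)/k)) plus N(0, (noise_frac·A)²) noise.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    v = protocol.voltages
    clean = amplitude / (1.0 + np.exp((v - v_half) / k_slope))
    out = []
    for c in range(n_cells):
        noise = rng.normal(0.0, noise_frac * amplitude, size=v.shape)
        out.append(ActivationDataset(
            cell_id=f"cell{c:03d}", construct=construct, condition=condition,
            voltage_mV=v, tail_pA=clean + noise,
        ))
    return out


def make_current_trace(i0: float = 500.0,
                       tau: float = 0.5,
                       duration: float = 5.0,
                       rate: float = 5000.0,
                       noise: float = 0.0,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled mono-exponential current I0·exp(−t/τ) + Gaussian noise.

    Times in seconds; default 5 kHz sampling. Returns (t, I) including
    both endpoints (duration·rate + 1 samples).
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    i = i0 * np.exp(-t / tau)
    if noise > 0:
        i = i + rng.normal(0.0, noise, size=n)
    return t, i


def make_cluster_blobs(k: int = 4,
                       dim: int = 3,
                       separation: float = 10.0,
                       spread: float = 1.0,
                       n_per: int = 50,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian blobs with centers ``separation`` apart.

    Centers are random directions scaled so that every pair is at least
    ``separation`` apart. Returns (points, ground-truth labels).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if separation == 0:
        centers = np.zeros((k, dim))
    else:
        centers = np.zeros((k, dim))
        for i in range(1, k):
            for _ in range(1000):
                cand = rng.normal(size=dim)
                cand = cand / np.linalg.norm(cand) * separation * (
                    1 + rng.uniform(0, 0.5))
                cand = centers[rng.integers(i)] + cand
                if np.all(np.linalg.norm(centers[:i] - cand, axis=1)
                          >= separation):
                    centers[i] = cand
                    break
            else:  # pragma: no cover - extremely unlikely
                raise RuntimeError("could not place blob centers")
    points = np.vstack([
        rng.normal(0, spread, (n_per, dim)) + c for c in centers
    ])
    labels = np.repeat(np.arange(k), n_per)
    return points, labels


def make_energy_table(wt: ConstructEnergetics,
                      dg_p1: float,
                      dg_p2: float,
                      coupling: float = 0.0,
                      labels: Sequence[str] = ("single1", "single2", "double"),
                      ) -> tuple[ConstructEnergetics, ConstructEnergetics,
                                 ConstructEnergetics, ConstructEnergetics]:
    """Four-construct energetics with a dialled-in coupling energy.

    Single mutants perturb the wt gating energy by ``dg_p1`` and
    ``dg_p2`` kcal/mol; the double mutant carries both perturbations plus
    ``coupling``, so the cycle's non-additivity ΔΔG equals ``coupling``
    exactly. Energies are back-solved into V1/2 at each construct's
    (here: the wt) inverse slope factor, exercising the same
    ΔGapp = (RT/k)·V1/2 arithmetic the analysis applies.
    """
    k = wt.k_slope
    temp = wt.temperature
    rt = R_KCAL * temp

    def construct(label: str, dg: float) -> ConstructEnergetics:
        v_half = dg * k / rt
        return ConstructEnergetics(label, v_half, k, temp)

    g_wt = wt.dg_app
    single1 = construct(labels[0], g_wt + dg_p1)
    single2 = construct(labels[1], g_wt + dg_p2)
    double = construct(labels[2], g_wt + dg_p1 + dg_p2 + coupling)
    return wt, single1, single2, double


def make_ideal_gas_traj(density: float,
                        box: Sequence[float],
                        n_frames: int = 100,
                        seed: int = 0) -> TrajectoryEnsemble:
    """Uniform (ideal-gas) target points around a fixed central reference atom.

    Per frame, round(density × volume) points are drawn uniformly in the
    box (the count is fixed across frames because a trajectory keeps a
    constant atom roster; the points remain exactly uniform). Atom 0 is
    the reference at the box center, labelled ("R", 1, "REF"); targets
    are ("W", i, "OW").
    """
    box = np.asarray(box, dtype=float)
    if density <= 0 or np.any(box <= 0):
        raise ValueError("density and box must be positive")
    rng = np.random.default_rng(seed)
    n_targets = max(1, int(round(density * float(np.prod(box)))))
    frames = np.empty((n_frames, n_targets + 1, 3))
    center = box / 2.0
    for f in range(n_frames):
        frames[f, 0] = center
        frames[f, 1:] = rng.uniform(0.0, 1.0, (n_targets, 3)) * box
    labels = [("R", 1, "REF")] + [("W", i + 1, "OW") for i in range(n_targets)]
    return TrajectoryEnsemble(frames=frames, atom_labels=tuple(labels),
                              times=np.arange(n_frames, dtype=float), box=box)


def make_shell_traj(shell_radius: float = 3.0,
                    n_shell: int = 64,
                    box_side: float = 40.0,
                    n_frames: int = 20,
                    seed: int = 0) -> TrajectoryEnsemble:
    """Targets placed exactly on a sphere of ``shell_radius`` around the reference.

    A hydration-shell toy: g(r) must show a single occupied bin at the
    shell radius and zero elsewhere within any r_max < box/2.
    """
    rng = np.random.default_rng(seed)
    box = np.full(3, float(box_side))
    center = box / 2.0
    frames = np.empty((n_frames, n_shell + 1, 3))
    for f in range(n_frames):
        v = rng.normal(size=(n_shell, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        frames[f, 0] = center
        frames[f, 1:] = center + shell_radius * v
    labels = [("R", 1, "REF")] + [("W", i + 1, "OW") for i in range(n_shell)]
    return TrajectoryEnsemble(frames=frames, atom_labels=tuple(labels),
                              times=np.arange(n_frames, dtype=float), box=box)
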