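"""Trajectory observables: minimum side-chain distances and solvent g(r).

Operates on in-memory frame ensembles (frames × atoms × 3). Input comes
from multi-model PDB files, plain whitespace tables, or any external
reader that can hand over arrays — binary MD formats are deliberately
not parsed here.

``min_distance_series`` reproduces the shortest-atom-pair distance trace
between two side chains, computed per subunit and averaged over the four
subunits with an SEM band. ``rdf`` computes the radial distribution
function of target atoms (e.g. water oxygens) around a reference group
(a side chain): for each target the distance to the *nearest* reference
atom is histogrammed and normalized per frame by the ideal-gas
expectation (shell volume × bulk target density), so g(r) → 1 in the
bulk for uniform targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

import biotite.structure.io.pdb as _pdb

__all__ = [
    "TrajectoryEnsemble",
    "DistanceSeries",
    "RDFProfile",
    "min_distance_series",
    "rdf",
]


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Ordered coordinate frames with constant atom labelling.

    Attributes
    ----------
    frames : (n_frames, n_atoms, 3) float array, Å
    atom_labels : sequence of (chain, residue_number, atom_name) tuples
    times : (n_frames,) float array, ns, strictly increasing
    box : optional (3,) orthorhombic box lengths, Å (enables the
        minimum-image convention and the bulk-density normalization)
    """

    frames: np.ndarray
    atom_labels: tuple[tuple[str, int, str], ...]
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if frames.shape[0] != times.shape[0]:
            raise ValueError("times length must match frame count")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        labels = tuple((str(c), int(r), str(a)) for c, r, a in self.atom_labels)
        if len(labels) != frames.shape[1]:
            raise ValueError("atom_labels length must match atom count")
        box = None if self.box is None else np.asarray(self.box, dtype=float)
        if box is not None and (box.shape != (3,) or np.any(box <= 0)):
            raise ValueError("box must be three positive lengths")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "atom_labels", labels)
        object.__setattr__(self, "box", box)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for c, _, _ in self.atom_labels:
            if c not in out:
                out.append(c)
        return out

    def select(self, chain: str | None = None,
               residue_number: int | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Indices of atoms matching all given label components."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for i, (c, r, a) in enumerate(self.atom_labels):
            if chain is not None and c != chain:
                mask[i] = False
            elif residue_number is not None and r != residue_number:
                mask[i] = False
            elif atom_name is not None and a != atom_name:
                mask[i] = False
        return np.flatnonzero(mask)

    @classmethod
    def from_multimodel_pdb(cls, path: str | Path,
                            times: Sequence[float] | None = None,
                            box: Sequence[float] | None = None
                            ) -> "TrajectoryEnsemble":
        """Load every MODEL of a PDB file as one frame (Å, times default 0,1,2... ns)."""
        pdbf = _pdb.PDBFile.read(str(path))
        stack = pdbf.get_structure(altloc="first")  # AtomArrayStack; labels shared
        coords = stack.coord
        if coords.ndim == 2:
            coords = coords[None]
        labels = tuple(zip(stack.chain_id.tolist(),
                           stack.res_id.tolist(),
                           stack.atom_name.tolist()))
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        return cls(frames=coords.astype(float), atom_labels=labels,
                   times=np.asarray(times, float),
                   box=None if box is None else np.asarray(box, float))

    @classmethod
    def from_table(cls, path: str | Path,
                   box: Sequence[float] | None = None) -> "TrajectoryEnsemble":
        """Load a plain whitespace table: frame time chain resid atom x y z."""
        import pandas as pd

        df = pd.read_csv(path, sep=r"\s+", comment="#",
                         names=["frame", "time", "chain", "resid", "atom",
                                "x", "y", "z"],
                         dtype={"chain": str, "atom": str})
        frames_ids = sorted(df["frame"].unique())
        first = df[df["frame"] == frames_ids[0]]
        labels = tuple(zip(first["chain"], first["resid"].astype(int),
                           first["atom"]))
        coords = np.stack([
            df[df["frame"] == f][["x", "y", "z"]].to_numpy(float)
            for f in frames_ids
        ])
        times = np.array([df[df["frame"] == f]["time"].iloc[0]
                          for f in frames_ids], dtype=float)
        return cls(frames=coords, atom_labels=labels, times=times,
                   box=None if box is None else np.asarray(box, float))


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame minimum inter-selection distances per subunit, with summary."""

    times: np.ndarray         # (n_frames,), ns
    per_subunit: np.ndarray   # (n_frames, n_subunits), Å
    subunits: tuple[str, ...]
    mean: np.ndarray          # (n_frames,), Å
    band: np.ndarray          # (n_frames,) SEM across subunits, Å


@dataclass(frozen=True)
class RDFProfile:
    """Radial distribution function on a uniform distance grid."""

    r_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    n_frames_used: int


def _pair_dist(a: np.ndarray, b: np.ndarray,
               box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) distances, minimum-image if an orthorhombic box is given."""
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def min_distance_series(traj: TrajectoryEnsemble,
                        sel_a: Mapping[str, Sequence[int]],
                        sel_b: Mapping[str, Sequence[int]]) -> DistanceSeries:
    """Minimum atom-pair distance between two selections, per subunit.

    ``sel_a``/``sel_b`` map subunit (chain) labels to atom-index lists;
    both must cover the same subunits and be nonempty in each. Per frame
    and subunit the minimum over all A×B pairs is taken; the mean and SEM
    across subunits summarize the tetramer.
    """
    subunits = tuple(sel_a)
    if set(sel_b) != set(subunits):
        raise ValueError("selections must cover the same subunits")
    for s in subunits:
        if len(sel_a[s]) == 0 or len(sel_b[s]) == 0:
            raise ValueError(f"empty selection in subunit {s!r}")
    out = np.empty((traj.n_frames, len(subunits)))
    for fi in range(traj.n_frames):
        frame = traj.frames[fi]
        for si, s in enumerate(subunits):
            d = _pair_dist(frame[np.asarray(sel_a[s], int)],
                           frame[np.asarray(sel_b[s], int)], traj.box)
            out[fi, si] = d.min()
    mean = out.mean(axis=1)
    n = len(subunits)
    band = out.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(traj.n_frames)
    return DistanceSeries(times=traj.times, per_subunit=out, subunits=subunits,
                          mean=mean, band=band)


def rdf(traj: TrajectoryEnsemble,
        reference: Sequence[int],
        targets: Sequence[int],
        r_max: float,
        bin_width: float,
        bulk_density: float | None = None) -> RDFProfile:
    """g(r) of target atoms around a reference group.

    For every target atom the distance to its nearest reference atom is
    histogrammed over [0, r_max] and normalized, per frame, by the
    ideal-gas count expectation: shell volume 4π r² dr times the bulk
    target number density (targets per box volume, or ``bulk_density``
    when no box is attached). Frames are averaged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")
    ref_idx = np.asarray(reference, dtype=int)
    tgt_idx = np.asarray(targets, dtype=int)
    if ref_idx.size == 0 or tgt_idx.size == 0:
        raise ValueError("reference and target selections must be nonempty")
    if bulk_density is None:
        if traj.box is None:
            raise ValueError(
                "g(r) normalization needs a box or an explicit bulk_density"
            )
        bulk_density = tgt_idx.size / float(np.prod(traj.box))
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if edges[-1] < r_max:
        edges = np.append(edges, edges[-1] + bin_width)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = shell_vol * bulk_density
    acc = np.zeros(edges.size - 1)
    for fi in range(traj.n_frames):
        frame = traj.frames[fi]
        d = _pair_dist(frame[tgt_idx], frame[ref_idx], traj.box).min(axis=1)
        counts, _ = np.histogram(d, bins=edges)
        acc += counts / expected
    g = acc / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(r_centers=centers, g=g, bin_width=float(bin_width),
                      n_frames_used=traj.n_frames)
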