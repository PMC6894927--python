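"""Coarse-grained structure I/O.

Reads PDB/mmCIF files, reduces them to one Cα bead per residue (the
substrate of the elastic-network model), resolves residue selections, and
writes multi-model PDB "morph" trajectories that interpolate between a
reference conformation and a displaced one.

Residue numbering is the author numbering of the source file and is never
remapped: downstream analyses address residues by those numbers (e.g. the
C-linker shoulder 446-465 of HCN1). Bead order is canonical — sorted by
chain label, then residue number — so that selections and force vectors
are reproducible across I/O round trips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb
import biotite.structure.io.pdbx as _pdbx

logger = logging.getLogger(__name__)

__all__ = [
    "CoarseGrainedStructure",
    "ResidueSelection",
    "MorphTrajectory",
    "StructureFormatError",
    "EmptyStructureError",
    "SelectionError",
    "read_structure",
    "resolve_selection",
    "write_morph",
]


class StructureFormatError(ValueError):
    """The input file could not be parsed as PDB or mmCIF."""


class EmptyStructureError(ValueError):
    """The input file contains no Cα atoms to coarse-grain."""


class SelectionError(ValueError):
    """A residue selection resolved to zero beads."""


@dataclass(frozen=True)
class CoarseGrainedStructure:
    """One Cα bead per residue, in canonical (chain, residue) order.

    Attributes
    ----------
    coords : (N, 3) float array, Å
    chain_ids : (N,) str array
    residue_numbers : (N,) int array — author numbering, preserved verbatim
    residue_names : (N,) str array — 3-letter codes
    source : str — free-text provenance
    """

    coords: np.ndarray
    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "chain_ids", np.asarray(self.chain_ids, dtype="U8"))
        object.__setattr__(
            self, "residue_numbers", np.asarray(self.residue_numbers, dtype=int)
        )
        object.__setattr__(
            self, "residue_names", np.asarray(self.residue_names, dtype="U8")
        )
        n = len(coords)
        for name in ("chain_ids", "residue_numbers", "residue_names"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords")
        pairs = list(zip(self.chain_ids.tolist(), self.residue_numbers.tolist()))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (chain, residue_number) pairs")
        if pairs != sorted(pairs):
            raise ValueError(
                "beads must be sorted by chain label, then residue number"
            )

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        """Distinct chain labels in bead order."""
        out: list[str] = []
        for c in self.chain_ids:
            if not out or out[-1] != c:
                out.append(str(c))
        return out

    def index_of(self, chain: str, residue_number: int) -> int:
        """Bead index of a (chain, residue) pair; raises SelectionError if absent."""
        hit = np.flatnonzero(
            (self.chain_ids == chain) & (self.residue_numbers == residue_number)
        )
        if hit.size == 0:
            raise SelectionError(
                f"residue {residue_number} not present in chain {chain!r}"
            )
        return int(hit[0])

    def with_coords(self, coords: np.ndarray, source: str | None = None
                    ) -> "CoarseGrainedStructure":
        return CoarseGrainedStructure(
            coords=np.asarray(coords, dtype=float),
            chain_ids=self.chain_ids,
            residue_numbers=self.residue_numbers,
            residue_names=self.residue_names,
            source=self.source if source is None else source,
        )


@dataclass(frozen=True)
class ResidueSelection:
    """Residue numbers (inclusive range or explicit list) on all or named chains.

    ``chains=None`` means every chain of the structure the selection is
    applied to. Resolution is deterministic and returns bead order.
    """

    residues: tuple[int, ...] = ()
    residue_range: tuple[int, int] | None = None
    chains: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"empty residue range {lo}-{hi}")
        if not self.residues and self.residue_range is None:
            raise ValueError("selection needs residues or a residue_range")
        object.__setattr__(self, "residues", tuple(int(r) for r in self.residues))
        if self.chains is not None:
            object.__setattr__(self, "chains", tuple(str(c) for c in self.chains))

    @classmethod
    def from_range(cls, start: int, stop: int,
                   chains: Sequence[str] | None = None) -> "ResidueSelection":
        return cls(residue_range=(int(start), int(stop)),
                   chains=None if chains is None else tuple(chains))

    @classmethod
    def from_residues(cls, residues: Sequence[int],
                      chains: Sequence[str] | None = None) -> "ResidueSelection":
        return cls(residues=tuple(int(r) for r in residues),
                   chains=None if chains is None else tuple(chains))

    @classmethod
    def parse(cls, text: str) -> "ResidueSelection":
        """Parse ``[CHAIN[,CHAIN...]:]START-STOP`` or ``[CHAINS:]N1,N2,...``.

        Examples: ``446-465`` (all chains), ``A:446-465``, ``A,B:425``.
        """
        chains: tuple[str, ...] | None = None
        body = text.strip()
        if ":" in body:
            chain_part, body = body.split(":", 1)
            chains = tuple(c.strip() for c in chain_part.split(",") if c.strip())
        body = body.strip()
        if "-" in body:
            lo, hi = body.split("-")
            return cls.from_range(int(lo), int(hi), chains)
        return cls.from_residues([int(t) for t in body.split(",") if t.strip()], chains)


def resolve_selection(structure: CoarseGrainedStructure,
                      sel: ResidueSelection) -> np.ndarray:
    """Resolve a selection to an ascending, duplicate-free bead-index array.

    Raises
    ------
    SelectionError
        If no bead of the structure matches, naming the residues and the
        chains that were searched.
    """
    if sel.chains is None:
        chain_mask = np.ones(structure.n_beads, dtype=bool)
        searched = "all chains"
    else:
        chain_mask = np.isin(structure.chain_ids, list(sel.chains))
        searched = f"chains {','.join(sel.chains)}"
    res = structure.residue_numbers
    res_mask = np.zeros(structure.n_beads, dtype=bool)
    if sel.residue_range is not None:
        lo, hi = sel.residue_range
        res_mask |= (res >= lo) & (res <= hi)
        what = f"residues {lo}-{hi}"
    else:
        res_mask |= np.isin(res, list(sel.residues))
        what = f"residues {','.join(map(str, sel.residues))}"
    idx = np.flatnonzero(chain_mask & res_mask)
    if idx.size == 0:
        raise SelectionError(f"{what} resolved to no beads on {searched}")
    return idx


@dataclass(frozen=True)
class MorphTrajectory:
    """Linear interpolation frames between a reference and displaced state."""

    frames: np.ndarray          # (n_frames, N, 3), Å
    frame_labels: np.ndarray    # (n_frames,) interpolation parameter in [0, 1]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        labels = np.asarray(self.frame_labels, dtype=float)
        if frames.ndim != 3 or frames.shape[0] != labels.shape[0]:
            raise ValueError("frames/labels shape mismatch")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_labels", labels)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _from_atom_array(atoms: struc.AtomArray, source: str) -> CoarseGrainedStructure:
    ca = atoms[atoms.atom_name == "CA"]
    # one bead per residue: count residues that have any atom but no CA
    all_pairs = set(zip(atoms.chain_id.tolist(), atoms.res_id.tolist()))
    ca_pairs = set(zip(ca.chain_id.tolist(), ca.res_id.tolist()))
    dropped = all_pairs - ca_pairs
    if dropped:
        msg = (f"{len(dropped)} residue(s) lack a CA atom and were dropped: "
               + ", ".join(f"{c}/{r}" for c, r in sorted(dropped)[:5])
               + ("..." if len(dropped) > 5 else ""))
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
    if ca.array_length() == 0:
        raise EmptyStructureError(f"no CA atoms found in {source}")
    order = np.lexsort((ca.res_id, ca.chain_id))
    ca = ca[order]
    # altloc: biotite's altloc="first" has already collapsed alternates; if
    # duplicates remain (e.g. insertion codes), keep the first occurrence
    pairs = np.array(list(zip(ca.chain_id, ca.res_id.astype(str))))
    _, first = np.unique(pairs, axis=0, return_index=True)
    keep = np.zeros(ca.array_length(), dtype=bool)
    keep[first] = True
    ca = ca[keep]
    return CoarseGrainedStructure(
        coords=ca.coord.astype(float),
        chain_ids=ca.chain_id,
        residue_numbers=ca.res_id,
        residue_names=ca.res_name,
        source=source,
    )


def read_structure(path: str | Path, model_index: int = 1) -> CoarseGrainedStructure:
    """Read a PDB or mmCIF file and coarse-grain it to Cα beads.

    Parameters
    ----------
    path : path to a ``.pdb``/``.ent`` or ``.cif``/``.mmcif`` file; the
        format is chosen by extension, falling back to PDB.
    model_index : 1-based model number (multi-model files).

    Returns
    -------
    CoarseGrainedStructure
        One bead per residue at its Cα position; residues lacking a Cα are
        dropped with a warning. Alternate locations resolve to the first.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            cif = _pdbx.CIFFile.read(str(path))
            atoms = _pdbx.get_structure(cif, model=model_index, altloc="first")
        else:
            pdbf = _pdb.PDBFile.read(str(path))
            atoms = pdbf.get_structure(model=model_index, altloc="first")
    except (EmptyStructureError, SelectionError):
        raise
    except Exception as exc:  # biotite raises format-specific errors
        if "0 models" in str(exc):
            raise EmptyStructureError(f"no atoms found in {path}") from exc
        raise StructureFormatError(
            f"could not parse {path} as {'mmCIF' if suffix in ('.cif', '.mmcif', '.pdbx') else 'PDB'}: {exc}"
        ) from exc
    return _from_atom_array(atoms, source=f"{path}#model{model_index}")


def _to_atom_array(structure: CoarseGrainedStructure,
                   coords: np.ndarray) -> struc.AtomArray:
    n = structure.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.residue_numbers
    arr.res_name = structure.residue_names.astype("U5")
    arr.atom_name = np.full(n, "CA", dtype="U6")
    arr.element = np.full(n, "C", dtype="U2")
    return arr


def write_morph(structure: CoarseGrainedStructure,
                response: "np.ndarray | object",
                scale: float = 1.0,
                n_frames: int = 11,
                path: str | Path | None = None) -> MorphTrajectory:
    """Interpolate linearly from the reference to reference + scale·response.

    ``response`` may be an (N, 3) displacement array or any object with a
    ``displacements`` attribute (a linear-response field). Frame 0 is the
    unperturbed structure; the last frame is fully displaced. If ``path``
    is given the frames are written as a multi-model PDB (MODEL/ENDMDL)
    viewable in any structure viewer.
    """
    disp = getattr(response, "displacements", response)
    disp = np.asarray(disp, dtype=float)
    if disp.shape != structure.coords.shape:
        raise ValueError(
            f"response shape {disp.shape} does not match structure "
            f"({structure.coords.shape})"
        )
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    t = np.linspace(0.0, 1.0, n_frames)
    frames = structure.coords[None, :, :] + t[:, None, None] * (scale * disp)[None, :, :]
    traj = MorphTrajectory(frames=frames, frame_labels=t)
    if path is not None:
        stack = struc.stack([_to_atom_array(structure, f) for f in frames])
        pdbf = _pdb.PDBFile()
        pdbf.set_structure(stack)
        pdbf.write(str(path))
    return traj
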