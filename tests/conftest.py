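"""Shared fixtures: tiny structures and deterministic random models."""

import numpy as np
import pytest

from crankshaft.anm import SpringModel, build_anm
from crankshaft.structures import CoarseGrainedStructure

# hand-written two-residue PDB: bead coordinates are the CA records verbatim
TWO_RESIDUE_PDB = (
    "ATOM      1  N   GLY A   1       0.100   0.200   0.300  1.00  0.00           N  \n"
    "ATOM      2  CA  GLY A   1       1.250   2.500   3.750  1.00  0.00           C  \n"
    "ATOM      3  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00           C  \n"
    "END\n"
)

# residue 2 carries only a CB atom and must be dropped with a warning
MISSING_CA_PDB = (
    "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
    "ATOM      2  CB  ALA A   2       3.800   0.000   0.000  1.00  0.00           C  \n"
    "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C  \n"
    "END\n"
)


@pytest.fixture
def two_residue_pdb(tmp_path):
    p = tmp_path / "two_res.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


@pytest.fixture
def missing_ca_pdb(tmp_path):
    p = tmp_path / "missing_ca.pdb"
    p.write_text(MISSING_CA_PDB)
    return p


def random_connected_structure(n_beads: int, seed: int) -> CoarseGrainedStructure:
    """Random bead cloud guaranteed connected and stiff under the 13 Å cutoff.

    Beads accrete onto a random existing bead at 4-7 Å (inside the
    cutoff, so the cloud is connected by construction) while keeping a
    3 Å clash distance; the resulting compact 3-D blob has no floppy
    collinear sub-chains, hence exactly six rigid modes.
    """
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_beads, 3))
    for i in range(1, n_beads):
        while True:
            anchor = coords[rng.integers(i)]
            step = rng.normal(size=3)
            step *= rng.uniform(4.0, 7.0) / np.linalg.norm(step)
            cand = anchor + step
            dists = np.linalg.norm(coords[:i] - cand, axis=1)
            # clash-free, and supported by >= 3 neighbors (no dangling
            # beads, which would leave zero-energy pivot modes)
            if dists.min() > 3.0 and (dists < 13.0).sum() >= min(i, 3):
                coords[i] = cand
                break
    return CoarseGrainedStructure(
        coords=coords,
        chain_ids=np.full(n_beads, "A"),
        residue_numbers=np.arange(1, n_beads + 1),
        residue_names=rng.choice(["ALA", "GLY", "SER", "LEU"], n_beads),
        source=f"random walk seed={seed}",
    )


def dimer_structure(distance: float = 5.0) -> CoarseGrainedStructure:
    return CoarseGrainedStructure(
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
        chain_ids=np.array(["A", "A"]),
        residue_numbers=np.array([1, 2]),
        residue_names=np.array(["GLY", "GLY"]),
        source="dimer",
    )


def brute_force_hessian(coords: np.ndarray, cutoff: float,
                        gamma: float = 1.0) -> np.ndarray:
    """Independent double-loop ANM Hessian (the test oracle)."""
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = coords[i] - coords[j]
            d2 = float(rij @ rij)
            if d2 > cutoff * cutoff:
                continue
            block = -gamma / d2 * np.outer(rij, rij)
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    return h


@pytest.fixture(scope="session")
def small_model():
    """A 30-bead connected ANM reused across response tests."""
    return build_anm(random_connected_structure(30, seed=42))
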