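"""Anisotropic network model and linear-response perturbation.

The channel structure, reduced to Cα beads, is modelled as a network of
harmonic springs connecting every bead pair within a distance cutoff
(default 13 Å). The Hessian of that network encodes its collective
mechanics; applying a static external force f and expanding to first
order gives the linear-response displacement field

    u = Σ_m (v_mᵀ f / λ_m) v_m

summed over the non-rigid eigenmodes (v_m, λ_m) of the Hessian — i.e. the
pseudo-inverse of the Hessian acting on the force. The six zero modes
(rigid translations and rotations) are excluded by an eigenvalue
threshold, so the response carries no net translation or rotation.

Spring constants are arbitrary units; displacements are reported in
arbitrary length units since only their directions are interpreted.
Forces are applied simultaneously on all four chains of the tetramer in
C4 fashion: the same residue on each chain, with the force direction
advanced by 90° about the z-axis from chain to chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structures import CoarseGrainedStructure, SelectionError

__all__ = [
    "SpringModel",
    "ANMModel",
    "ForcePerturbation",
    "ResponseField",
    "DisconnectedNetworkWarning",
    "build_anm",
    "lrt_response",
    "make_c4_perturbation",
    "rotation_about_z",
]

DEFAULT_CUTOFF = 13.0          # Å
DEFAULT_MAGNITUDE = 1600.0     # a.u.
RIGID_MODE_RTOL = 1e-8         # eigenvalue threshold relative to the largest


class DisconnectedNetworkWarning(UserWarning):
    """The spring network has more than one connected component."""


@dataclass(frozen=True)
class SpringModel:
    """Spring-constant assignment: uniform or a per-residue-name-pair table.

    ``pair_table`` maps frozenset-like sorted residue-name pairs, e.g.
    ``("ALA", "GLY")``, to constants; pairs absent from the table fall back
    to ``gamma``. All constants must be positive.
    """

    kind: str = "uniform"
    gamma: float = 1.0
    pair_table: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "pairwise-table"):
            raise ValueError(f"unknown spring model kind {self.kind!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kind == "pairwise-table":
            if not self.pair_table:
                raise ValueError("pairwise-table model needs a pair_table")
            if any(v <= 0 for v in self.pair_table.values()):
                raise ValueError("all spring constants must be positive")

    def constant(self, res_name_i: str, res_name_j: str) -> float:
        if self.kind == "uniform" or self.pair_table is None:
            return self.gamma
        key = tuple(sorted((res_name_i, res_name_j)))
        return self.pair_table.get(key, self.gamma)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ANMModel:
    """ANM Hessian with its stored eigendecomposition.

    ``eigenvalues`` ascend; the first ``n_rigid_modes`` fall below the
    rigid-mode threshold (exactly 6 for a connected network).
    """

    structure: CoarseGrainedStructure
    cutoff: float
    spring_model: SpringModel
    hessian: np.ndarray        # (3N, 3N), a.u. / Å²
    eigenvalues: np.ndarray    # (3N,), ascending
    eigenvectors: np.ndarray   # (3N, 3N), columns orthonormal
    n_rigid_modes: int

    @property
    def n_beads(self) -> int:
        return self.structure.n_beads


@dataclass(frozen=True)
class ForcePerturbation:
    """External forces on selected beads.

    ``targets`` holds (bead_index, unit_direction) pairs; every target
    receives a force of ``magnitude`` a.u. along its direction.
    ``symmetry_mode`` records whether the targets were constructed as
    successive 90° z-rotations on the four chains ("C4-about-z") or given
    directly ("as-given").
    """

    targets: tuple[tuple[int, np.ndarray], ...]
    magnitude: float = DEFAULT_MAGNITUDE
    symmetry_mode: str = "as-given"

    def __post_init__(self) -> None:
        if self.symmetry_mode not in ("as-given", "C4-about-z"):
            raise ValueError(f"unknown symmetry_mode {self.symmetry_mode!r}")
        norm_targets = []
        for idx, direction in self.targets:
            d = np.asarray(direction, dtype=float)
            if d.shape != (3,):
                raise ValueError("force directions must be 3-vectors")
            if abs(np.linalg.norm(d) - 1.0) > 1e-12:
                raise ValueError("force directions must be unit vectors")
            norm_targets.append((int(idx), d))
        object.__setattr__(self, "targets", tuple(norm_targets))

    def force_vector(self, n_beads: int) -> np.ndarray:
        """Assemble the flat 3N force vector (a.u.)."""
        f = np.zeros(3 * n_beads)
        for idx, direction in self.targets:
            if not 0 <= idx < n_beads:
                raise IndexError(f"target bead {idx} out of range (N={n_beads})")
            f[3 * idx: 3 * idx + 3] += self.magnitude * direction
        return f


@dataclass(frozen=True)
class ResponseField:
    """Per-bead displacement response to one force perturbation (a.u. lengths)."""

    displacements: np.ndarray          # (N, 3)
    perturbation: ForcePerturbation
    model_ref: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("displacements must be (N, 3)")
        if not np.all(np.isfinite(d)):
            raise ValueError("displacements must be finite")
        object.__setattr__(self, "displacements", d)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    """3×3 rotation matrix about +z (counter-clockwise seen from +z)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_anm(structure: CoarseGrainedStructure,
              cutoff: float = DEFAULT_CUTOFF,
              spring_model: SpringModel | None = None) -> ANMModel:
    """Build the anisotropic network model of a bead structure.

    The off-diagonal 3×3 super-block for a connected pair (i, j) is
    −γᵢⱼ/dᵢⱼ² · rᵢⱼ rᵢⱼᵀ; diagonal blocks are minus the sum of the row's
    off-diagonal blocks, which makes every 3×3 super-row sum to zero
    (translation invariance). The full symmetric eigendecomposition is
    computed and stored.

    Warns with :class:`DisconnectedNetworkWarning` if more than six
    eigenvalues fall below the rigid-mode threshold.
    """
    if structure.n_beads < 2:
        raise ValueError("ANM needs at least 2 beads")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    spring_model = spring_model or SpringModel()
    coords = structure.coords
    n = structure.n_beads

    diff = coords[:, None, :] - coords[None, :, :]          # r_i - r_j
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    within = dist2 <= cutoff * cutoff
    np.fill_diagonal(within, False)

    if spring_model.kind == "uniform":
        gamma = np.where(within, spring_model.gamma, 0.0)
    else:
        gamma = np.zeros((n, n))
        names = structure.residue_names
        ii, jj = np.nonzero(within)
        for i, j in zip(ii.tolist(), jj.tolist()):
            gamma[i, j] = spring_model.constant(names[i], names[j])

    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = np.where(within, -gamma / np.where(within, dist2, 1.0), 0.0)
    # blocks[i, j] = coeff[i, j] * outer(diff[i, j], diff[i, j])
    blocks = coeff[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    blocks[np.arange(n), np.arange(n)] = -blocks.sum(axis=1)
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    hessian = 0.5 * (hessian + hessian.T)  # enforce exact symmetry

    eigenvalues, eigenvectors = np.linalg.eigh(hessian)
    scale = max(eigenvalues[-1], 0.0)
    n_rigid = (int(np.sum(np.abs(eigenvalues) < RIGID_MODE_RTOL * scale))
               if scale > 0 else 3 * n)
    n_components = _count_components(within)
    if n_components > 1 or n_rigid > 6:
        warnings.warn(
            f"spring network is disconnected or floppy: {n_components} "
            f"component(s), {n_rigid} near-zero modes",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
    return ANMModel(
        structure=structure,
        cutoff=float(cutoff),
        spring_model=spring_model,
        hessian=hessian,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        n_rigid_modes=n_rigid,
    )


def _count_components(adjacency: np.ndarray) -> int:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    n_comp = 0
    for start in range(n):
        if seen[start]:
            continue
        n_comp += 1
        stack = [start]
        seen[start] = True
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adjacency[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
    return n_comp


def lrt_response(model: ANMModel, perturbation: ForcePerturbation) -> ResponseField:
    """Linear-response displacement field for an applied force.

    Computes u = Σ_m (v_mᵀ f / λ_m) v_m over non-rigid modes — the
    minimum-norm solution of H u = f with rigid modes projected out.
    The response is exactly linear in the force magnitude.
    """
    n = model.n_beads
    f = perturbation.force_vector(n)
    lam = model.eigenvalues
    live = np.arange(3 * n) >= model.n_rigid_modes
    if not np.any(live):
        raise np.linalg.LinAlgError("all modes are rigid; response undefined")
    v = model.eigenvectors[:, live]
    coeffs = (v.T @ f) / lam[live]
    u = v @ coeffs
    return ResponseField(
        displacements=u.reshape(n, 3),
        perturbation=perturbation,
        model_ref=model.structure.source,
    )


def response_operator(model: ANMModel) -> np.ndarray:
    """Dense (3N, 3N) pseudo-inverse response operator G with u = G f.

    Convenience for batch perturbation ensembles; equals the mode-sum of
    :func:`lrt_response` applied to unit forces.
    """
    lam = model.eigenvalues
    live = np.arange(lam.size) >= model.n_rigid_modes
    v = model.eigenvectors[:, live]
    return (v / lam[live]) @ v.T


def make_c4_perturbation(model: ANMModel,
                         residue_number: int,
                         base_direction: Sequence[float],
                         magnitude: float = DEFAULT_MAGNITUDE) -> ForcePerturbation:
    """Four-fold symmetric perturbation at one residue on every chain.

    Chain k (in z-rotation order, i.e. bead order for structures built or
    deposited with chains as successive 90° images) receives the base
    direction rotated by k·90° about z. Requires a 4-chain structure with
    the residue present in every chain.
    """
    structure = model.structure
    chains = structure.chains
    if len(chains) != 4:
        raise ValueError(
            f"C4 perturbation needs exactly 4 chains, found {len(chains)}"
        )
    d0 = np.asarray(base_direction, dtype=float)
    norm = np.linalg.norm(d0)
    if norm == 0:
        raise ValueError("base direction must be nonzero")
    d0 = d0 / norm
    targets = []
    for k, chain in enumerate(chains):
        idx = structure.index_of(chain, residue_number)  # SelectionError if absent
        direction = rotation_about_z(90.0 * k) @ d0
        targets.append((idx, direction / np.linalg.norm(direction)))
    return ForcePerturbation(
        targets=tuple(targets),
        magnitude=float(magnitude),
        symmetry_mode="C4-about-z",
    )
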