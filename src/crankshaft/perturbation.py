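"""Random-force perturbation experiments on the elastic network.

The protocol mirrors the channel study design: sample many (default
1000) uniformly random force directions, apply each in four-fold
symmetric fashion at a chosen residue (magnitude 1600 a.u.), compute the
linear-response displacement of every bead, and cluster the forces by
the displacement of the C-linker "shoulder" (residues 446-465 in HCN1
numbering, 20 residues × 4 chains). The number of clusters is chosen
from the log of the maximal within-cluster sum of squares as a function
of k (an elbow criterion), one representative force per cluster is the
member nearest the cluster centroid, and the motion of each annotated
domain under the representative response is summarized as a mean
displacement, its angle to the channel's z (symmetry) axis, and the
in-plane rotation about z (positive = counter-clockwise viewed from the
extracellular side, looking down +z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .anm import (
    ANMModel,
    ForcePerturbation,
    ResponseField,
    lrt_response,
    make_c4_perturbation,
    response_operator,
    rotation_about_z,
    DEFAULT_MAGNITUDE,
)
from .structures import CoarseGrainedStructure, ResidueSelection, resolve_selection

__all__ = [
    "ForceEnsemble",
    "ClusterResult",
    "DomainMotion",
    "ExperimentReport",
    "sample_force_directions",
    "shoulder_features",
    "kmeans_cluster",
    "elbow_select_k",
    "representative_force",
    "domain_motion",
    "run_perturbation_experiment",
]

#: floor used when taking logs of a vanishing within-cluster sum of squares
_LOG_FLOOR = 1e-30


def sample_force_directions(n: int, seed: int) -> np.ndarray:
    """Sample ``n`` unit vectors uniformly on the sphere (deterministic per seed)."""
    if n < 1:
        raise ValueError("need n >= 1 force directions")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1)
    # resample the (measure-zero) degenerate draws
    while np.any(norms < 1e-12):
        bad = norms < 1e-12
        v[bad] = rng.normal(size=(int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


@dataclass
class ForceEnsemble:
    """A reproducible ensemble of C4-applied random forces and their responses."""

    model: ANMModel
    residue_number: int
    n_samples: int = 1000
    magnitude: float = DEFAULT_MAGNITUDE
    seed: int = 0
    directions: np.ndarray = field(init=False)
    _responses: list[ResponseField] | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        self.directions = sample_force_directions(self.n_samples, self.seed)

    def perturbation(self, i: int) -> ForcePerturbation:
        return make_c4_perturbation(
            self.model, self.residue_number, self.directions[i], self.magnitude
        )

    @property
    def responses(self) -> list[ResponseField]:
        """Responses for every sampled direction (computed once, batched)."""
        if self._responses is None:
            g = response_operator(self.model)
            n = self.model.n_beads
            fields = []
            for i in range(self.n_samples):
                pert = self.perturbation(i)
                u = g @ pert.force_vector(n)
                fields.append(ResponseField(u.reshape(n, 3), pert,
                                            self.model.structure.source))
            self._responses = fields
        return self._responses


def shoulder_features(response: ResponseField,
                      shoulder_indices: np.ndarray) -> np.ndarray:
    """Flatten the shoulder-bead displacements into one feature vector.

    The feature is the concatenation of the selected beads' 3-vector
    displacements in bead order; length = 3 × n_selected. Extraction is
    linear in the response.
    """
    idx = np.asarray(shoulder_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty shoulder selection")
    return response.displacements[idx].reshape(-1)


@dataclass(frozen=True)
class ClusterResult:
    """k-means partition of perturbation samples by shoulder displacement."""

    k: int
    labels: np.ndarray                 # (n_samples,) in [0, k)
    centroids: np.ndarray              # (k, n_features)
    withinss: np.ndarray               # (k,) per-cluster sum of squares
    representative_index: np.ndarray   # (k,) sample nearest its centroid
    max_withinss_by_k: dict[int, float] | None = None


def _withinss(features: np.ndarray, labels: np.ndarray,
              centroids: np.ndarray) -> np.ndarray:
    k = centroids.shape[0]
    return np.array([
        float(((features[labels == i] - centroids[i]) ** 2).sum()) for i in range(k)
    ])


def kmeans_cluster(features: Sequence[np.ndarray] | np.ndarray,
                   k: int,
                   n_init: int = 10,
                   seed: int = 0) -> ClusterResult:
    """Cluster feature vectors with k-means (k-means++ seeding, best of n_init).

    Uses Lloyd's algorithm as implemented by scikit-learn; the returned
    result carries per-cluster within-cluster sums of squares and, per
    cluster, the index of the sample nearest the centroid.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        x = x.reshape(len(x), -1)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples ({x.shape[0]})")
    if k < 1:
        raise ValueError("k must be >= 1")
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        # duplicate points legitimately yield fewer distinct clusters;
        # handled by the compaction below
        _warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    labels = km.labels_.astype(int)
    centroids = km.cluster_centers_
    # degenerate inputs (fewer distinct points than k) can leave clusters
    # empty; compact to the occupied ones so every reported cluster is
    # non-empty and labels stay contiguous
    occupied = np.flatnonzero(np.bincount(labels, minlength=k) > 0)
    if occupied.size < k:
        remap = -np.ones(k, dtype=int)
        remap[occupied] = np.arange(occupied.size)
        labels = remap[labels]
        centroids = centroids[occupied]
        k = occupied.size
    wss = _withinss(x, labels, centroids)
    rep = np.empty(k, dtype=int)
    for i in range(k):
        members = np.flatnonzero(labels == i)
        d2 = ((x[members] - centroids[i]) ** 2).sum(axis=1)
        rep[i] = members[int(np.argmin(d2))]
    return ClusterResult(k=k, labels=labels, centroids=centroids,
                         withinss=wss, representative_index=rep)


def elbow_select_k(features: Sequence[np.ndarray] | np.ndarray,
                   k_candidates: Sequence[int] = range(1, 9),
                   n_init: int = 10,
                   seed: int = 0,
                   min_excess: float = 0.5) -> tuple[int, dict[int, float]]:
    """Choose the cluster count from the log max-withinss elbow.

    For each candidate k, records log(max per-cluster withinss). Splitting
    clusters shrinks the maximal withinss by roughly a factor k/(k+1) even
    for structureless data (cluster sizes halve), so the drop from k to
    k+1 is scored as its excess over that log((k+1)/k) baseline. The
    chosen k sits just after the largest excess drop; if no drop exceeds
    the baseline by ``min_excess`` (nats) there is no elbow and k = 1.

    Returns (chosen_k, {k: log_max_withinss}).
    """
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValueError("k_candidates must be nonempty")
    table: dict[int, float] = {}
    for k in ks:
        res = kmeans_cluster(features, k, n_init=n_init, seed=seed)
        table[k] = float(np.log(max(res.withinss.max(), _LOG_FLOOR)))
    if len(ks) == 1:
        return ks[0], table
    excesses = []
    for a, b in zip(ks[:-1], ks[1:]):
        drop = table[a] - table[b]
        baseline = np.log((a + 1) / a)  # size-effect expectation for one split
        excesses.append(drop - baseline)
    best = int(np.argmax(excesses))
    if excesses[best] < min_excess:
        return ks[0], table
    return ks[best + 1], table


def representative_force(cluster: ClusterResult,
                         ensemble: ForceEnsemble,
                         cluster_index: int) -> ForcePerturbation:
    """The sampled perturbation whose shoulder feature is nearest the centroid.

    An automated stand-in for picking a direction "from the cluster
    center" by eye: the Euclidean nearest member is unambiguous and
    reproducible.
    """
    if not 0 <= cluster_index < cluster.k:
        raise IndexError(f"cluster {cluster_index} out of range (k={cluster.k})")
    return ensemble.perturbation(int(cluster.representative_index[cluster_index]))


@dataclass(frozen=True)
class DomainMotion:
    """Mean displacement of a domain and its rotation geometry.

    ``angle_to_z`` is the angle (degrees, [0, 180]) between the mean
    displacement and +z; ``in_plane_rotation`` is the mean signed rotation
    (degrees) of the domain beads about the z-axis through the structure's
    center of mass, positive counter-clockwise viewed from +z. Both are
    NaN when flagged undefined (zero mean displacement).
    """

    domain: str
    mean_displacement: np.ndarray
    angle_to_z: float
    in_plane_rotation: float
    undefined: bool = False


def domain_motion(response: ResponseField,
                  structure: CoarseGrainedStructure,
                  domain_indices: np.ndarray,
                  domain_name: str = "") -> DomainMotion:
    """Summarize a domain's motion under one response field."""
    idx = np.asarray(domain_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty domain selection")
    disp = response.displacements[idx]
    mean_disp = disp.mean(axis=0)
    norm = np.linalg.norm(mean_disp)
    if norm < 1e-300 or not np.isfinite(norm):
        return DomainMotion(domain_name, mean_disp, float("nan"), float("nan"),
                            undefined=True)
    angle_to_z = float(np.degrees(np.arccos(np.clip(mean_disp[2] / norm, -1, 1))))
    com = structure.coords.mean(axis=0)
    rel = structure.coords[idx] - com
    moved = rel + disp
    a0 = np.arctan2(rel[:, 1], rel[:, 0])
    a1 = np.arctan2(moved[:, 1], moved[:, 0])
    dtheta = np.angle(np.exp(1j * (a1 - a0)))  # wrap to (-pi, pi]
    in_plane = float(np.degrees(dtheta.mean()))
    return DomainMotion(domain_name, mean_disp, angle_to_z, in_plane)


@dataclass(frozen=True)
class ExperimentReport:
    """Everything one perturbation-site experiment produced."""

    residue_number: int
    chosen_k: int
    max_withinss_by_k: dict[int, float]
    cluster: ClusterResult
    representatives: tuple[ForcePerturbation, ...]
    representative_responses: tuple[ResponseField, ...]
    motions: tuple[dict[str, DomainMotion], ...]   # per cluster: domain -> motion
    best_matching_cluster: int | None = None
    best_match_similarity: dict[str, float] | None = None

    def motion_table(self):
        """Long-format pandas table of per-cluster domain motions."""
        import pandas as pd

        rows = []
        for ci, motions in enumerate(self.motions):
            for name, m in motions.items():
                rows.append({
                    "cluster": ci,
                    "domain": name,
                    "mean_dx": m.mean_displacement[0],
                    "mean_dy": m.mean_displacement[1],
                    "mean_dz": m.mean_displacement[2],
                    "angle_to_z_deg": m.angle_to_z,
                    "in_plane_rotation_deg": m.in_plane_rotation,
                })
        return pd.DataFrame(rows)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def run_perturbation_experiment(
    model: ANMModel,
    residue_number: int,
    shoulder: ResidueSelection,
    domains: Mapping[str, ResidueSelection],
    n_samples: int = 1000,
    magnitude: float = DEFAULT_MAGNITUDE,
    k: int | None = None,
    k_candidates: Sequence[int] = range(1, 9),
    n_init: int = 10,
    seed: int = 0,
    reference: Mapping[str, DomainMotion] | None = None,
) -> ExperimentReport:
    """Run the full random-force perturbation protocol at one residue.

    Samples ``n_samples`` directions, applies each as a C4-symmetric force
    at ``residue_number``, clusters the responses by shoulder
    displacement (k chosen by the elbow criterion unless given), selects
    a representative force per cluster and summarizes each annotated
    domain's motion under it. If reference domain motions are supplied,
    the cluster whose motions best match them (mean cosine similarity of
    mean displacements over shared domains) is reported.
    """
    structure = model.structure
    shoulder_idx = resolve_selection(structure, shoulder)
    domain_idx = {name: resolve_selection(structure, sel)
                  for name, sel in domains.items()}

    ensemble = ForceEnsemble(model, residue_number, n_samples=n_samples,
                             magnitude=magnitude, seed=seed)
    feats = np.stack([shoulder_features(r, shoulder_idx)
                      for r in ensemble.responses])

    if k is None:
        chosen_k, table = elbow_select_k(feats, k_candidates, n_init=n_init,
                                         seed=seed)
    else:
        chosen_k, table = int(k), {}
    cluster = kmeans_cluster(feats, chosen_k, n_init=n_init, seed=seed)

    reps, rep_responses, motions = [], [], []
    for ci in range(chosen_k):
        pert = representative_force(cluster, ensemble, ci)
        resp = ensemble.responses[int(cluster.representative_index[ci])]
        reps.append(pert)
        rep_responses.append(resp)
        motions.append({
            name: domain_motion(resp, structure, idx, name)
            for name, idx in domain_idx.items()
        })

    best_cluster = None
    best_sims = None
    if reference is not None:
        shared = [d for d in reference if d in domain_idx]
        scores = []
        for ci in range(chosen_k):
            sims = {d: _cosine(motions[ci][d].mean_displacement,
                               reference[d].mean_displacement) for d in shared}
            scores.append((float(np.mean(list(sims.values()))), sims))
        best_cluster = int(np.argmax([s for s, _ in scores]))
        best_sims = scores[best_cluster][1]

    return ExperimentReport(
        residue_number=residue_number,
        chosen_k=chosen_k,
        max_withinss_by_k=table or {},
        cluster=ClusterResult(
            k=cluster.k, labels=cluster.labels, centroids=cluster.centroids,
            withinss=cluster.withinss,
            representative_index=cluster.representative_index,
            max_withinss_by_k=table or None,
        ),
        representatives=tuple(reps),
        representative_responses=tuple(rep_responses),
        motions=tuple(motions),
        best_matching_cluster=best_cluster,
        best_match_similarity=best_sims,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Cross-site agreement of the best-matching cluster motions.

    ``similarities`` holds, per ordered site pair and domain, the cosine
    similarity of the best-matching clusters' domain mean displacements;
    ``min_similarity`` is the minimum over all pairs and domains — the
    concordance score of the whole multi-site experiment.
    """

    reference_site: str
    reports: dict[str, ExperimentReport]
    best_motions: dict[str, dict[str, DomainMotion]]
    similarities: dict[tuple[str, str], dict[str, float]]
    min_similarity: float


def run_concordance(
    model: ANMModel,
    sites: Mapping[str, int],
    shoulder: ResidueSelection,
    domains: Mapping[str, ResidueSelection],
    reference_site: str,
    reference_cluster: int = 0,
    n_samples: int = 1000,
    magnitude: float = DEFAULT_MAGNITUDE,
    seed: int = 0,
    **experiment_kwargs,
) -> ConcordanceResult:
    """Do equivalent perturbations at different sites move the domains alike?

    Runs the full random-force experiment at the reference site, takes
    one of its clusters as the reference motion, then at every other
    site finds the cluster best matching that motion and scores the
    pairwise cosine similarity of the best clusters' domain mean
    displacements. A mechanically continuous assembly scores near 1; a
    severed one collapses toward (or below) zero.
    """
    if reference_site not in sites:
        raise KeyError(f"reference site {reference_site!r} not among sites")
    reports: dict[str, ExperimentReport] = {}
    ref_report = run_perturbation_experiment(
        model, sites[reference_site], shoulder, domains,
        n_samples=n_samples, magnitude=magnitude, seed=seed,
        **experiment_kwargs)
    reports[reference_site] = ref_report
    ref_motions = ref_report.motions[reference_cluster]
    best: dict[str, dict[str, DomainMotion]] = {reference_site: ref_motions}
    for name, residue in sites.items():
        if name == reference_site:
            continue
        rep = run_perturbation_experiment(
            model, residue, shoulder, domains,
            n_samples=n_samples, magnitude=magnitude, seed=seed,
            reference=ref_motions, **experiment_kwargs)
        reports[name] = rep
        best[name] = rep.motions[rep.best_matching_cluster]
    sims: dict[tuple[str, str], dict[str, float]] = {}
    site_names = list(best)
    min_sim = np.inf
    for i, a in enumerate(site_names):
        for b in site_names[i + 1:]:
            per_domain = {
                d: _cosine(best[a][d].mean_displacement,
                           best[b][d].mean_displacement)
                for d in domains
            }
            sims[(a, b)] = per_domain
            min_sim = min(min_sim, min(per_domain.values()))
    return ConcordanceResult(
        reference_site=reference_site,
        reports=reports,
        best_motions=best,
        similarities=sims,
        min_similarity=float(min_sim),
    )
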