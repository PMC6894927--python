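# Methods

## Coarse-grained structures

Structures (PDB or mmCIF, read through biotite) are reduced to one bead
per residue at the Cα position. Author residue numbering is preserved
verbatim — all downstream selections (shoulder 446–465, perturbation
sites 425/108/283 in HCN1 numbering) address residues by the numbers in
the source file. Residues without a Cα are dropped with a warning;
alternate locations resolve to the first listed. Bead order is canonical
(chain label, then residue number), which makes force vectors and
feature extractions reproducible across I/O round trips. Morph output is
a multi-model PDB with linear interpolation between the reference and
displaced coordinates; the interpolation is deliberately simple because
the linear-response amplitudes are qualitative (directions, not
magnitudes, are the read-out).

## Anisotropic network model and linear response

Springs connect bead pairs within a cutoff, default 13 Å. The 3N×3N
Hessian has off-diagonal super-blocks −γᵢⱼ/dᵢⱼ²·rᵢⱼrᵢⱼᵀ and diagonal
blocks equal to minus the row sum, so every super-row sums to zero
(translation invariance). Spring constants default to uniform γ = 1 in
arbitrary units, with a pluggable residue-name-pair table for
heterogeneous parameterizations. This uniform default is a documented
stand-in: every numerical parameter of the analysis (cutoff, force
count, force magnitude, cluster count) is independent of the spring
table, and the read-out — directions of domain motion — is robust to it.

The full symmetric eigendecomposition is computed and stored
(`numpy.linalg.eigh`; practical up to ~5000 beads, the supported scale).
Modes with eigenvalue below 1e−8 × the largest are classified rigid; a
connected network has exactly six (translations + rotations), and more
triggers a disconnection/floppiness warning with the component count.
The linear response to a force f is the mode sum u = Σ (v_mᵀf/λ_m)v_m
over non-rigid modes — the minimum-norm pseudo-inverse solution of
Hu = f. Because rigid modes are excluded, the response carries no net
translation or rotation; it is exactly linear in the force magnitude,
equivariant under global rotations, and reciprocal (the response
operator is symmetric). Tests verify all four properties plus equality
with a dense `numpy.linalg.pinv` oracle.

Forces are applied in C4 fashion: one target residue per chain, the base
direction rotated by k·90° about z for chain k. The z-axis of the input
frame is taken as the four-fold axis (true for the deposited channel
structure and for all synthetic structures by construction); no axis
auto-detection is attempted. Chains are assumed labelled in z-rotation
order. The default force magnitude is 1600 a.u.; since the response is
linear, direction results do not depend on it.

## Perturbation experiments and clustering

An experiment samples n (default 1000) force directions uniformly on the
sphere (normalized Gaussian triples, explicit integer seed), applies
each C4-symmetrically at the chosen residue, and computes all responses
through one precomputed response operator. The clustering feature of a
sample is the concatenated displacement 3-vectors of the shoulder beads
— the displacement of residues 446–465 over the tetramer gives a
240-dimensional feature. Clustering is k-means (scikit-learn: k-means++
seeding, best of n_init = 10 restarts).

**Elbow criterion.** The number of clusters is read from
L(k) = log(max per-cluster within-cluster sum of squares) over
candidates k = 1..8. Even structureless data drops L by roughly
log((k+1)/k) per split, simply because cluster sizes shrink; a genuine
elbow shows a drop far in excess of that baseline. Each drop
L(k)−L(k+1) is therefore scored as its excess over log((k+1)/k), and the
chosen k sits immediately after the largest excess, provided that excess
reaches min_excess (default 0.5 nats ≈ a 65% extra reduction); otherwise
there is no elbow and k = 1. On four well-separated synthetic blobs this
selects k = 4; on a single blob or identical points it selects k = 1
(zero within-cluster sums are floored before the log). The original
by-inspection comparison is thus automated with one interpretable
threshold.

**Representatives and domain motions.** Each cluster's representative
force is the member whose feature is Euclidean-nearest the centroid — a
deterministic stand-in for picking "from the cluster center" by eye.
Domain motion under the representative response is summarized as the
mean bead displacement, its angle to +z (arccos of the z-component over
the norm, in [0°, 180°]), and the mean signed in-plane rotation of the
domain beads about the z-axis through the structure's center of mass
(positive = counter-clockwise viewed from the extracellular side,
looking down +z). A zero mean displacement is flagged and the angles
reported as NaN.

**Concordance.** To ask whether perturbations at different sites move
the domains alike, the experiment is run at a reference site, one
reference cluster's motions are fixed, and at every other site the
cluster best matching them (highest mean cosine similarity of domain
mean displacements) is selected. The concordance score is the minimum
cosine over all site pairs and domains. On the synthetic coupled
assembly this is 1.0 intact and ≤ 0 severed.

## Trajectory observables

Trajectories are in-memory frame ensembles (constant atom roster,
strictly increasing times) read from multi-model PDB or a plain
whitespace table; binary MD formats are not parsed — the
`TrajectoryEnsemble` constructor is the adapter hook for external
readers. Distances are plain Euclidean, or minimum-image when an
orthorhombic box is attached.

The minimum-distance series takes, per frame and subunit, the minimum
over all A×B atom-pair distances, then reports mean and SEM across
subunits (SEM rather than SD, configurable, matching the error-band
convention for four-subunit averages).

g(r) uses a *group-minimum* convention: for each target atom the
distance to the nearest reference atom is histogrammed, normalized per
frame by shell volume × bulk target density (count/box volume, or an
explicit override when no box exists), and averaged over frames. Whether
the original analysis used group-minimum or per-atom-averaged distances
is not stated in its description; group-minimum matches "distance from
the side chain" read as proximity to the side chain as a whole, and the
choice only affects r ≲ the reference-group extent. Tests verify g = 1
within 5% in the bulk for uniform targets and that integrating
g·4πr²ρ dr recovers the mean in-range target count within 2%.

## Activation curves, kinetics, energetics

Per-cell tail-current amplitudes I(V) are fit with the three-parameter
Boltzmann A/(1+exp((V−V1/2)/k)) by nonlinear least squares
(`scipy.optimize.curve_fit`). V1/2 is stored signed (negative for
hyperpolarization-activated gating); magnitude display is offered at the
I/O layer since experimental tables usually print |V1/2|. Initialization:
V1/2 at the half-maximal observed amplitude, k from the 25–75% amplitude
voltage span ÷ 2.2, A from the maximum; |k| is bounded to (0.5, 50) mV.
Data without an inflection in the sampled window (e.g. all on a plateau)
are flagged with a saturated-data warning. Fits run on raw amplitudes
with free A rather than pre-normalized curves, matching the
amplitude-vs-voltage convention; normalized curves are derived output.
Construct summaries are per-cell-fit-then-average (mean ± SEM), not fits
to the mean curve. Kinetics: mono-exponential I0·exp(−t/τ) on a time
window (≥ 10 samples).

Energetics use ΔGapp = (RT/k)·V1/2 with R = 1.987×10⁻³ kcal/(mol·K) and
T = 298 K by default (room-temperature recordings); V1/2 and k in the
same voltage units make the ratio dimensionless. The double-mutant cycle
reports the perturbation energy ΔGp along each edge and the
non-additivity ΔΔG = ΔGapp(wt) + ΔGapp(double) − ΔGapp(single1) −
ΔGapp(single2); |ΔΔG| above a threshold (default 1 kcal/mol) flags the
sites as coupled. ΔΔG is invariant to adding a constant to all four
energies and to swapping the single mutants. The cycle uses mean
per-cell parameters per construct; whether the original analysis
averaged per-cell energies or fit mean curves is not stated, and the
choice is configurable.

Group comparisons: Student's t for two groups; one-way ANOVA for more,
with pairwise Fisher's-LSD p-values (t on the pooled within-group
variance) computed only after a significant ANOVA at α = 0.05. No
additional multiple-testing correction is applied — a documented
limitation that mirrors the LSD-after-ANOVA convention.

## Synthetic data

All generators are pure functions of (parameters, seed) with explicit
`numpy.random.default_rng` seeding; no global state.

- **C4 structures**: chain A is a jittered helical trace whose radial
  coordinate ramps outward from near the axis (so the four chains meet
  within the cutoff around the pore axis and the network is connected);
  chains B–D are exact 90°/180°/270° z-rotation images.
- **Coupled assembly**: per chain, an α-helix-like column (top half
  "vsd", bottom half "hcnd" — helical so the column has genuine
  transverse stiffness) plus a separate z- and radially-modulated
  "linker" arc that sweeps toward the next chain, contacting its hcnd
  within the 13 Å cutoff. The linker ring is the only inter-chain
  mechanical path. `severed=True` pushes the ring 30 Å radially outward,
  breaking every linker–hcnd contact (the network then decomposes into
  components and the build emits its disconnection warning — expected).
- **Activation datasets**: A/(1+exp((V−V1/2)/k)) at the isoform voltage
  protocols (HCN2 default: −40…−130 mV in 10 mV steps) plus Gaussian
  amplitude noise σ = noise_frac·A, default 2%.
- **Current traces**: I0·exp(−t/τ) sampled at 5 kHz.
- **Cluster blobs**: isotropic Gaussians with centers ≥ separation
  apart; ground-truth labels attached.
- **Energy tables**: single mutants perturb the wt gating energy by
  chosen ΔGp; the double carries both plus the coupling, back-solved
  into V1/2 at the wt slope factor — so the cycle's ΔΔG equals the
  dialled-in coupling exactly.
- **Ideal-gas / shell trajectories**: uniform points in a box around a
  fixed central reference (fixed count = round(density×volume), keeping
  the atom roster constant without biasing uniformity), or points on an
  exact sphere for the hydration-shell toy.

### What the synthetic data does and does not show

The toy assembly reproduces the *topology* of the channel's proposed
mechanical path (inter-subunit linker ring bridging HCND/VSD columns),
not its geometry, masses or heterogeneous stiffness; passing concordance
tests demonstrates that the pipeline detects mechanical continuity and
its loss, not that any particular channel is continuous. Activation
datasets have ideal Boltzmann shape with homoscedastic noise — no rundown,
leak, or liquid-junction artifacts — so fit-recovery results bound the
estimator's own bias, not experimental systematics. The g(r) fixtures
have no excluded volume or solvation structure beyond what is
constructed.

## Problem sizes and numerical choices

Default experiment sizes (1000 forces on a 120-bead toy, 20–100 cells
per construct, 150 trajectory frames) run in seconds on one core; they
were chosen as the smallest sizes at which the statistical checks have
clear power. The acceptance script averages the mutant-cycle ΔΔG over
eight replicate simulated experiments of 20 cells per construct because
one such experiment has a propagated ΔΔG SEM of ≈ 0.25 kcal/mol —
replication brings the reported mean to the one-decimal precision at
which the coupling energy is quoted. Ties in k-means are resolved by
scikit-learn's deterministic seeded restarts; zero within-cluster sums
are floored at 1e−30 before logs; rigid-mode classification uses a
relative eigenvalue threshold of 1e−8. Degenerate inputs (identical
points, empty clusters after duplicate collapse) compact to the occupied
clusters so reported clusters are always non-empty.

## Known limitations

- Uniform springs stand in for the cited heterogeneous parameterization;
  absolute response amplitudes are meaningless by design.
- The morph is linear interpolation, not a physical path.
- Only orthorhombic boxes; no binary trajectory formats.
- Fisher's LSD controls no family-wise error rate beyond the ANOVA gate.
- The elbow threshold (0.5 nats) is a heuristic; for ambiguous cluster
  structure, inspect the reported log-max-withinss table directly.
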