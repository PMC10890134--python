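# Methods

This note records the models, conventions, numerical choices and known
limitations behind `helixscope`. Units throughout: coordinates in Å,
times stored in ps and reported in ns, energies in kcal/mol, angles in
degrees. Residue numbering is the author/PDB `resid`, 1-based, never
renumbered — region defaults (TM domain 57–82, N-helix 10–30, C-helix
90–95, bend sites 71/74/77) are expressed in that numbering.

## Trajectory model and trimming

A `Trajectory` is an ordered list of frames over a fixed `Topology`; frame
`i` sits at `origin_time + i·frame_interval` ps. DCD files do not always
carry a trustworthy timestep, so `frame_interval` can be supplied by
config; when the CHARMM header carries a nonzero AKMA timestep and save
frequency, the reader uses timestep × save-frequency.

`trim_equilibration` removes frames earlier than a cutoff (default 15 ns):
membrane–protein systems relax for roughly that long after construction
restraints are released, and all statistics downstream assume the
production ensemble. The reference frame for superposition and essential
dynamics is the first post-trim frame.

## Superposition, RMSD, RMSF

`kabsch_fit` solves the weighted least-squares rigid superposition; the
implementation delegates the rotation to
`scipy.spatial.transform.Rotation.align_vectors` after weighted centering,
which performs the SVD-based Kabsch solution with the reflection corrected,
so the returned matrix is always a proper rotation (det = +1). Degenerate
inputs (< 3 points, collinear sets) are rejected because the rotation is
under-determined. Weights default to uniform; mass weighting is available
by passing masses. RMSD and RMSF default to Cα atoms — at Cα-trace
resolution "backbone" and Cα coincide, and on all-atom systems the
selection expression chooses.

For RMSD/RMSF each region is aligned *on itself* (fit selection =
measurement selection) unless told otherwise, so a floppy terminus is not
judged in the frame of the rigid TM helix. RMSF is reported per residue:
RMSF_i = sqrt(mean_f |r_i(f) − ⟨r_i⟩|²) after alignment.

## Bilayer geometry

The membrane normal is fixed to +Z; no per-frame normal re-estimation is
done (flat-bilayer assumption). The phosphate mass-density profile is a
mass-weighted histogram of z relative to the phosphate selection's own
mass-weighted center of mass. Bin centers sit on multiples of the bin
width (default 1 Å), symmetric about z = 0: leaflet peaks at ±w/2 then
fall on bin centers, and the grid is invariant under z → −z, which makes
delta-function leaflets and mirror tests exact. Peak positions are refined
by fitting a parabola through the three bins around each half-space
argmax — this removes bin-quantization bias so that width recovery beats
the bin resolution; ties between equal maxima break toward larger |z|
(logged). Width can be computed per frame, per window, or from the
whole-trajectory profile; the default is per frame.

`z_distance` is the signed z difference of two selections' mass-weighted
centers of mass, the membrane selection defining zero.

## Helix tilt and bending angle

The tilt estimator uses the dominant right-singular direction of the
centered Cα trace, sign-oriented from the N- to the C-terminal end, then
folds the angle to the membrane normal into [0°, 90°]. Terminal-vector and
gyration-tensor estimators are provided as alternatives for sensitivity
checks (`helix_axis(..., method=...)`). A discrete helix at 100°/residue
does not close a whole number of turns over 26 residues, so its principal
axis deviates from the ideal axis by a small fixed amount (0.78° for the
26-residue span) — this is a property of the geometry, not an estimator
error, and it bounds noise-free tilt recovery at about 0.8°.

The bending angle at an anchor residue is the angle between the vectors
from the anchor Cα to the Cαs three residues before and after it; 180°
means exactly collinear. On a *straight* canonical α-helix the ±3-residue
chords do not anti-align (300° of twist is 60° short of a full turn), so a
straight helix reads ≈ 153.7°, a constant geometric offset; series are
exported both as θ and as deviation 180° − θ. Frames with coincident bend
points yield NaN, are logged, and are excluded from summaries. The down
residue defaults to resid 77 (the site is labelled inconsistently in parts
of the literature; the residue number is what matters and is configurable
via `BendSpec`).

## Essential dynamics

The ensemble matrix holds each frame's selected Cα coordinates, flattened,
after Kabsch alignment onto the reference frame. PCA diagonalizes the
sample covariance of displacements from the *ensemble mean* (divisor F−1,
unbiased), implemented through an SVD of the centered ensemble
(λ_m = s_m²/(F−1)) for numerical stability; eigenvector orthonormality and
variance-fraction normalization are enforced as typed invariants of
`ModeSet`.

The DCCM is computed from the covariance filtered through the top k modes
(k = 2 by default): C_ij = Σ_{m≤k} λ_m v_{m,i}·v_{m,j}, normalized by the
filtered per-atom mean-square fluctuations, so entries describe
correlations *within* the retained essential subspace (+1 same direction,
−1 opposed). Atoms with no displacement in that subspace get zero
off-diagonals with a warning and a unit diagonal. Normalizing over all
modes instead is possible by passing a larger k.

One subtlety the synthetic generator exposes: its "rotation" mode is an
infinitesimal rigid rotation of the TM helix, which Kabsch alignment
removes almost entirely. Recovery tests therefore run PCA on the raw
(unaligned) ensemble — the generated trajectories contain no global rigid
motion, so alignment is unnecessary there — while the production pipeline
aligns, as is standard for real trajectories. Consequently the pipeline's
PC1 fraction on the default system is ≈ 99.9 % (stretch only), whereas
unaligned PCA recovers the planted 87/13 % split.

Mode b-factors are per-residue mean-square fluctuations contributed by one
mode, b_i = λ_m |v_{m,i}|² (Å²); the crystallographic 8π²/3 scaling is
optional. NMD export writes unit eigenvectors with sqrt(λ) scales and
round-trips to 1e-6.

## Nonbonded energetics

Pair energies use CHARMM conventions: V_LJ = ε_ij[(R_ij/r)¹² − 2(R_ij/r)⁶]
with ε_ij = √(ε_i ε_j) and R_ij = Rmin/2_i + Rmin/2_j (so V(R_ij) = −ε_ij
exactly), and V_C = 332.0636·q_i q_j/(ε_r r). Both are multiplied by the
CHARMM *energy*-switching factor, 1 below 10 Å, 0 above 12 Å and
(c²−r²)²(c²+2r²−3s²)/(c²−s²)³ between — C¹-continuous at both boundaries.

Electrostatics is deliberately a real-space switched cutoff, **not**
Ewald/PME: a reciprocal-space sum cannot be decomposed into the
region–region pair energies these series report, so absolute values are
not comparable to PME totals and the package does not claim otherwise.

Pair enumeration uses a k-d tree (periodic boxes handled via wrapped
coordinates and minimum-image displacements when a box is present);
`method="naive"` runs the O(N²) double loop and the two paths are asserted
equal to ~1e-10 relative in the tests. Internal energy excludes pairs
within the same segment closer than 3 residues — the Cα-trace analogue of
1-2/1-3 bonded exclusions; explicit bond-topology input (and 1-4 scaling)
is out of scope until bonded topologies exist.

## The synthetic generator

`SyntheticSystemSpec` defaults define the reference study conditions: a
103-residue Cα-trace chain, canonical α-helix constants (rise 1.5 Å/res,
twist 100°/res, radius 2.3 Å), TM span 57–82 with its midpoint residue
(69) at z = 0, leaflet phosphate pseudo-atoms at ±19 Å with Gaussian
spread σ = 1.5 Å (256 per leaflet over a 60 × 60 Å patch with a 6 Å
protein-excluded lateral zone, 3:1 zwitterionic/anionic lipid mixture with
the anionic headgroup carrying −1 e), planted TM modes of 8.7 Å² (stretch)
and 1.3 Å² (rotation), free termini (isotropic white noise, 1 Å² per
coordinate), a small lipid jitter (0.25 Å²), and 2000 frames at 100 ps —
a 200 ns production run recorded at the coarse end of common 20–100 ps
save intervals, trimmed by 15 ns before analysis.

Ground-truth conventions:

* **Tilt** is a rigid rotation of the whole protein about Y, so the TM
  axis makes exactly the requested angle with +Z.
* **Bend** is defined *through the estimator's own geometry*: `apply_bend`
  rigidly rotates the chain above the anchor about an in-plane axis chosen
  perpendicular to the sum of the two ±3-residue chords (which makes
  180° — exact anti-alignment — reachable), solving by bisection for the
  rotation that makes the three-point angle equal the requested value to
  1e-6°. On a collinear chain this reduces to the naive (180° − θ)
  rotation. A nominal arm-rotation definition would leave a ~26°
  discretization bias between "truth" and any three-point measurement;
  defining truth through the measurement geometry is what makes a ±2°
  recovery contract meaningful. `build_system` applies no bend at
  θ = 180° (straight means the untouched ideal helix, preserving exact
  tilt and Z-topology truth).
* **Modes** are orthonormalized (QR, sign-fixed against their raw
  patterns) over the TM Cα coordinates; amplitudes are i.i.d. Gaussian
  per frame with the prescribed variances — equal-time statistics only,
  no kinetics, because every analysis implemented here is an equal-time
  statistic. White-noise "modes" act per atom on a named scope (tmd,
  termini, protein, lipids, all).
* **Determinism**: the spec seed feeds two derived, independent streams
  (system build; trajectory noise), so identical spec + seed reproduces
  trajectories bit for bit, and changing only the seed changes phosphate
  placement but not the protein.

What the generator does *not* emulate: excluded volume (Gaussian
displacements can produce steric clashes, which makes nonbonded energy
series heavy-tailed — the pipeline's histogram stage therefore bins over a
robust IQR-based range when the raw range would exceed 10⁵ fixed-width
bins, dropping flagged outliers with a logged message), membrane
undulations and per-frame normal drift, lipid chains and solvent, and any
temporal correlation. Passing recovery tests on this generator validates
the *estimators*, not force-field realism.

## Pipeline and reporting

`run_analysis` executes the configured stages (trim → per-region
RMSD/RMSF → width → Z-distances → tilt → bend → PCA/DCCM/b-factors/NMD →
energies → histograms → tilt-vs-Z 2D density), records per-stage status in
a JSON manifest (config hash, package version, seed, frame counts), lets
independent stages continue past a failure, and exits nonzero from the CLI
if any stage failed. All outputs are plain CSV with fixed float formats,
so identical config + inputs reproduce the bundle byte for byte.

Histogram probabilities sum to 1 with bin edges anchored at the series
minimum; default bin widths follow common reporting practice for this
system class (0.047 Å for width — treated as Å, the conventional axis
unit, where the source convention is ambiguous — 9.4 kcal/mol for
region–lipid energies, 8.2 kcal/mol for internal energy; all
overridable). The 2D tilt-vs-Z grid is a normalized histogram (optional
Gaussian smoothing) integrating to 1.

## Problem sizes in tests

Recovery tests use the sizes at which their statistical tolerances are
meaningful: 10⁴ phosphates for width (±2 bins), 5000 frames for the
planted-PCA split (±0.02), 10⁴ frames for RMSF sampling theory (±5 %),
100 random rigid motions for Kabsch, 50 random fixtures for the
accelerated-vs-naive energy equality. The default 2000-frame system is
analyzed end to end twice in the determinism check.
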