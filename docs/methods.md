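# Methods

This note documents the models, conventions, numerical choices and
limitations behind `medoidspec`, in the spirit of a package methods page:
what is computed, under which assumptions, and what the synthetic test
battery does and does not demonstrate.

## Problem setting and assumptions

The package addresses band-shape simulation for chromophores whose
UV-Vis absorption at finite temperature is governed by conformational
freedom: floppy complexes, π-stacked charge-transfer dimers, solvated
transition-metal dyes. The working assumptions are

1. an MD trajectory provides a faithful Boltzmann sampling of the
   ground-state conformational ensemble;
2. vertical excitation energies and oscillator strengths are
   deterministic functions of the nuclear geometry (the classical
   Franck–Condon picture — no vibronic or non-adiabatic structure);
3. the conformational coordinates that matter for the electronic states
   are captured by a small set of geometric features.

Under these assumptions a small set of feature-space cluster
representatives, weighted by cluster populations, can stand in for the
full frame sampling in the double sum over frames and states that builds
the broadened spectrum.

## Feature construction

**Plane-pair features** (stacked dimers). Plane normals are the
smallest-variance directions of the centered atom selections (SVD); the
sign is fixed by the right-hand rule on the selection's first three
atoms, so the normal is a deterministic function of atom order. The
inter-plane angle is the un-folded arccos of the normals' dot product
(no absolute value: near-parallel and near-antiparallel stackings are
distinct). The rotation axis (normalized cross product of the normals)
and the center-to-center vector are expressed in a body-fixed frame
built from three user-chosen reference atoms (origin at atom 1, x toward
atom 2, z normal to the 1-2-3 plane, y = z × x); the same frame is used
for the spatial distribution function. These choices make every feature
exactly invariant under global rigid motion (verified to 1e-8 in the
suite). When the two planes are parallel the axis is undefined: the frame
keeps its angle, gets a zero-vector axis and a degeneracy flag, and stays
in the dataset — dropping frames would bias cluster populations.

**Dihedral features.** Signed dihedrals follow the sign convention of
the major MD analysis packages (mdtraj and MDAnalysis agree; checked
against both in the tests), mapped to (−180°, 180°] and encoded as
(cos φ, sin φ) pairs so that the feature-space metric is continuous
across the periodic boundary.

**C2 continuous symmetry measure.** The CSM is the minimized RMSD (in Å,
not a normalized percentage) between the centered selection and its
two-fold image generated by a user-supplied atom pairing (an involution,
element-preserving — validated). The optimal proper rotation comes from
Kabsch superposition (`scipy` `align_vectors`, det = +1 enforced). The
pairing permutation is mandatory configuration: which atom subset carries
the approximate C2 symmetry is system knowledge the package does not
guess. The measure is zero iff the selection is exactly symmetric under
the supplied pairing, and rigid-motion invariant.

**Standardization** uses population (1/N) standard deviations, matching
the 1/N covariance convention of the PCA stage. Zero-variance columns
cannot satisfy a unit-variance contract and are dropped with a logged
warning, recorded in the standardization parameters for the inverse
transform.

## K-medoids

PAM with *squared* Euclidean distances: the loss is the sum of squared
distances to the assigned medoid, matching the printed form of the
clustering objective (classic PAM uses unsquared distances; the squared
choice is deliberate and documented here). BUILD greedily seeds the K
medoids; SWAP accepts the first strictly-improving medoid/non-medoid
exchange scanning in index order, so the optimization is deterministic —
equal-loss swaps are rejected and ties in point assignment go to the
lowest medoid index, giving bit-reproducible runs. Strict decrease of a
loss with finitely many configurations guarantees termination. Default
`n_restarts = 8`: one BUILD start plus seven seeded random starts; the
best loss wins, ties broken by the lexicographically smallest medoid set.
N ≈ 500 makes the full N×N squared-distance matrix (2 MB) and exhaustive
SWAP scans cheap; no CLARA-style subsampling is needed or provided.

**Choosing K.** The scan reports inertia and the Calinski–Harabasz index
for each K. CH is computed with cluster *means* (the standard definition
of the index) even though the centers are medoids; a degenerate
clustering with zero within-cluster dispersion reports +inf. The default
chosen K is the CH argmax; the inertia-elbow location (maximum second
difference) is reported alongside for user override — the two diagnostics
are complementary and no principled precedence exists. The reported
inertia curve is forced non-increasing in K: if a scan step lands on a
worse local optimum than K−1, it is rerun warm-started from the K−1
medoids plus the worst-fit point.

## PCA

Population covariance C = XᵀX/N of the (already standardized, hence
centered) features, full symmetric eigendecomposition, eigenvector signs
fixed so each component's largest-magnitude entry is positive. PCA is
used for visualization only — never as a clustering preprocessor: the
feature spaces are already low-dimensional, and a 2-D projection can
visually overlap clusters that are separated in the full space (the
explained-variance fraction of the first two PCs is always reported so
apparent overlaps can be judged).

## Spectra

Lines are amplitude-normalized Gaussians: peak height equals the
oscillator strength, width parameter σ² = 0.001 eV² by default
(σ ≈ 0.032 eV), default grid 1.0–5.0 eV at 0.001 eV steps. The ensemble
spectrum divides the frame-and-state double sum by the number of frames
by default ("per-frame-mean"); the population-weighted medoid spectrum
needs no normalization since Σ p_k = 1. This makes the two constructions
identical under the trivial clustering where every frame is its own
medoid with p = 1/N — the algebraic anchor the test suite exercises
pointwise to 1e-12. A raw (unnormalized-sum) mode is kept behind a flag.
Stored spectra are never max-normalized; any rescaling for overlay plots
happens at the plotting layer only. Wavelength conversions use
hc = 1239.84193 eV·nm.

## Charge-transfer descriptors

Ω_AB sums the squared entries of the Löwdin-transformed transition
density S^{1/2} D S^{1/2} over hole basis functions on fragment A (rows)
and electron basis functions on fragment B (columns). The row = hole,
column = electron orientation is a package-level contract, stated in the
module docstring, since transition-density conventions differ between
electronic-structure codes. The overlap square root uses a symmetric
eigendecomposition; eigenvalues below −1e-8 are rejected as non-PSD and
near-zero ones floored to 1e-10 with a warning. D is analyzed as
supplied — no renormalization — with a warning if ΣΩ deviates from 1 by
more than 20% (single-excitation normalization heuristic). ω_CT computed
from a *partial* tabulation (not all fragment pairs supplied) uses the
supplied entries as the denominator and is flagged `partial` in reports.

## Synthetic generators: what they emulate

All inputs are generated programmatically, seeded, and byte-reproducible.

**Dimer trajectories.** A rigid planar 10-atom donor and rigid planar
6-atom acceptor; each planted cluster is a base acceptor orientation
(rotations spread over 10–170°, distinct axes) and stacking displacement
(~3.4 Å vertical, lateral offsets up to ±2.8 Å), sampled with Gaussian
jitter (defaults: 2° angular, 0.1 Å translational) and equal mixing
weights over 500 frames. Every frame then receives a random global rigid
motion, so lab-frame coordinates carry no planted signal — only the
body-frame features do. The defaults give well-separated clusters: these
are the standard study conditions for the recovery and spectrum-fidelity
tests.

**Excited-state tables.** Two states with base energies 2.0 and 2.9 eV —
the energy window of low-lying charge-transfer states of stacked organic
dimers. Energies couple linearly to the first two unit-variance principal
scores of the feature matrix with coefficients (0.05, 0)/(0.045, −0.015)
eV, plus 0.002 eV residual noise. The calibration targets two anchors of
the scenario being emulated: the energies of cluster-representative
structures should spread by ~0.15–0.2 eV (the published spread among
same-ring stacking conformers of the reference dimer), while the
within-cluster spread must stay below the σ ≈ 0.032 eV broadening —
which is exactly the regime in which a representative-frame spectrum can
reproduce the full sampling, as the reference system demonstrates. The
noise term stands for geometry dependence the features do not capture
and is kept small accordingly (assumption 2 above).

**Near-C2 structures.** An exactly two-fold-symmetric 8-atom template;
one atom of each symmetry pair is displaced by isotropic Gaussian noise
with per-atom RMS magnitude δ, giving a controlled, seed-averaged
monotone relation between δ and the CSM.

**Density/overlap pairs.** The overlap is identity plus a scaled random
symmetric part, eigen-floored to stay SPD; the *Löwdin-transformed*
density is constructed directly with squared mass `ct_weight` in the
off-diagonal fragment blocks and back-transformed, so the planted ω_CT
is exact. The generator's expected Ω comes from an independent route
(scipy `sqrtm` plus an explicit quadruple loop) and serves as the oracle
for the production implementation.

**What passing tests do not show.** The generators use rigid fragments,
isotropic noise, no solvent atoms, linear feature–energy response and
well-separated planted clusters. Success on them validates the
machinery — feature invariances, the PAM optimizer, the spectral algebra,
the Löwdin analysis — not the scientific adequacy of any particular
feature recipe for a real system, nor clustering performance when
conformational basins overlap or drift continuously.

## Problem sizes and runtime

The standard test conditions (500 frames, 7 features, K scans over 2–8
with 8 restarts, 2000-point spectral grids, 50-instance Ω batteries)
were chosen so the whole suite runs in well under a minute on one CPU
while keeping the clustering problem large enough for the K-selection
diagnostics to be meaningful.

## Known limitations

- Only singlet-type state tables are modeled; no triplets, vibronic
  progressions, Lorentzian/Voigt profiles or absolute absorptivity.
- The C2 pairing permutation and fragment definitions are user input;
  no automatic symmetry or fragment detection.
- The PDB reader is minimal (ATOM/HETATM symbols + coordinates, v3.3
  columns); no periodic-boundary handling or binary trajectory formats.
- K-medoids initialization/restart policy is a package choice (BUILD +
  seeded random restarts); other PAM variants may reach different local
  optima on hard instances.
- Uniform subsetting starts at frame 0 by default; equilibration
  discard is available via `skip` but is the user's responsibility.
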