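# medoidspec

Finite-temperature UV-Vis absorption spectra of flexible chromophores are
usually simulated by running excited-state (e.g. TD-DFT) calculations on
hundreds of snapshots drawn uniformly from a molecular-dynamics
trajectory. `medoidspec` implements the unsupervised alternative: cluster
the trajectory with K-medoids in a tailored geometric feature space, and
rebuild the ensemble spectrum and charge-transfer character from only the
K cluster-representative structures (the medoids), weighted by their
cluster populations — a 10–100× reduction in electronic-structure cost
with little loss in band shape.

It is aimed at computational chemists and molecular modellers who have an
MD trajectory (multi-frame XYZ or PDB) and per-frame excited-state tables,
and want representative conformers, reduced spectra and fragment
charge-transfer descriptors with full reproducibility.

## Method

**Features.** Each frame is mapped to a low-dimensional vector x ∈ R^d:
for stacked dimers, the inter-plane angle θ_r ∈ [0°, 180°] between the
least-squares plane normals of the two molecules, the rotation axis n̂_r
(normalized cross product of the normals) and the center-to-center vector
r⃗, the two vectors expressed in a body-fixed three-atom frame so every
feature is invariant under global rigid motion; for near-symmetric
complexes, torsional dihedrals φ encoded as (cos φ, sin φ) pairs to keep
the space metric across ±180°, plus a continuous symmetry measure (CSM)
of deviation from C2 symmetry — the Kabsch-minimized RMSD between the
structure and its two-fold image. Features are z-scored (population
standard deviation) before analysis.

**Clustering.** K-medoids by PAM (greedy BUILD seeding + first-improvement
SWAP) minimizing the squared-Euclidean loss

    L = Σ_i ‖x_i − c_k(i)‖²,   c_k ∈ {x_1 … x_N},

with the number of clusters chosen by scanning K and reading the inertia
elbow and the Calinski–Harabasz index (CH argmax wins on disagreement;
both are reported). PCA (population covariance C = XᵀX/N) projects the
partition to 2-D for visualization only.

**Spectra.** Every transition (frame l, state i) with vertical energy
ν_li and oscillator strength f_li contributes an amplitude-normalized
Gaussian f_li · exp(−(ν − ν_li)²/2σ²), σ² = 0.001 eV² by default. The
ensemble spectrum averages over all frames; the reduced spectrum sums
over medoids k weighted by cluster populations p_k = N_k/N:

    S(ν) = Σ_k p_k Σ_i S_ki(ν).

**Charge transfer.** From a transition density D (S_i ← S_0) and AO
overlap S, the Löwdin fragment populations are
Ω_AB = Σ_{μ∈A} Σ_{ν∈B} [S^1/2 D S^1/2]²_μν (rows = hole, columns =
electron), and ω_CT = Σ_{A≠B} Ω_AB / Σ_{A,B} Ω_AB is ≈1 for
charge-transfer states, ≈0 for local excitations.

## Worked example

Everything below runs from scratch — the synthetic generators produce all
inputs (a 500-frame dimer trajectory with 5 planted orientational
clusters and a matching excited-state table):

```python
import medoidspec as ms
from medoidspec import synthetic as syn
from medoidspec.trajectory import AtomSelection
from medoidspec.spectra import make_grid, spectrum_integral_deviation

traj, truth = syn.make_dimer_trajectory(syn.DimerGeneratorSpec(seed=3))
feat = ms.PlanePairFeaturizer(
    sel_a=AtomSelection("donor", syn.DIMER_DONOR_INDICES),
    sel_b=AtomSelection("acceptor", syn.DIMER_ACCEPTOR_INDICES),
    local_frame_atoms=syn.DIMER_LOCAL_FRAME,
)
std, _ = ms.standardize(feat.fit(traj).transform(traj).select_dtypes("number"))

report = ms.select_k(std, 2, 8, seed=7)
print("chosen K:", report.chosen_k, "| elbow at:", report.elbow_k)
sol = report.solutions[report.chosen_k]
print("medoid frames:", sol.medoid_indices.tolist())
print("populations:", [round(float(p), 3) for p in sol.populations])

table = syn.make_state_table(std, syn.StateModelSpec(seed=5))
grid = make_grid(1.5, 3.5, 0.001)
full = ms.ensemble_spectrum(table, grid=grid)
pops = {int(i): float(p) for i, p in zip(sol.medoid_indices, sol.populations)}
med = ms.medoid_spectrum(table.restrict(list(pops)), pops, grid=grid)
print("integrated |deviation| / integral:",
      round(spectrum_integral_deviation(med, full), 3))
```

Output:

```
chosen K: 5 | elbow at: 5
medoid frames: [4, 13, 39, 319, 445]
populations: [0.194, 0.198, 0.21, 0.222, 0.176]
integrated |deviation| / integral: 0.069
```

The K scan picks exactly the 5 planted clusters; the spectrum rebuilt
from 5 of 500 frames (a 100-fold cost reduction) deviates from the full
ensemble spectrum by under 7% of its integral.

The same pipeline runs from the shell:

```bash
medoidspec simulate states --seed 3 --out data/
medoidspec run --config run.yaml        # featurize → cluster → pca → spectra
medoidspec ctdesc --omega omega.tsv     # omega_CT from tabulated populations
```

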