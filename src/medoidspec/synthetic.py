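"""Seeded synthetic generators for every input the pipeline consumes.

Real inputs to this kind of analysis — ab initio MD trajectories and
TD-DFT excited-state runs — are expensive and system-specific, so the
package ships generators that emulate their statistical structure:

- a pi-stacked dimer trajectory with *planted orientational clusters*: a
  rigid planar donor plus a rigid planar acceptor whose orientation and
  displacement are drawn from K well-separated base configurations with
  Gaussian angular/translational jitter, then hit with a random global
  rigid motion per frame (so body-frame featurization has real work to do);
- near-C2-symmetric structures with controlled distortion magnitude;
- excited-state tables whose energies respond linearly to the geometric
  features (the physical premise of the whole method: conformation drives
  the electronic spectrum);
- transition-density/overlap matrix pairs with planted fragment-block
  charge-transfer weight, together with a brute-force reference Omega
  computed by an independent route (scipy matrix square root + explicit
  quadruple loop).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.transform import Rotation

from medoidspec.ct import OmegaMatrix, TransitionDensity
from medoidspec.features import c2_csm
from medoidspec.states import ExcitedStateTable
from medoidspec.trajectory import Frame, Trajectory

logger = logging.getLogger(__name__)

# Rigid planar 10-atom donor skeleton (naphthalene-like two fused hexagons,
# 1.4 A bonds, z = 0 plane). Chlorine-like substituent omitted: only the
# plane and center matter to the features.
_DONOR_TEMPLATE = np.array(
    [
        [0.000, 0.700, 0.0],
        [1.212, 1.400, 0.0],
        [2.425, 0.700, 0.0],
        [2.425, -0.700, 0.0],
        [1.212, -1.400, 0.0],
        [0.000, -0.700, 0.0],
        [-1.212, 1.400, 0.0],
        [-2.425, 0.700, 0.0],
        [-2.425, -0.700, 0.0],
        [-1.212, -1.400, 0.0],
    ]
)
_DONOR_SYMBOLS = ("C",) * 10

# Rigid planar 6-atom acceptor (ethylene core plus four nitrile nitrogens,
# tetracyanoethylene-like footprint, z = 0 plane, centered at the origin).
_ACCEPTOR_TEMPLATE = np.array(
    [
        [0.000, -0.670, 0.0],
        [0.000, 0.670, 0.0],
        [1.930, 1.780, 0.0],
        [-1.930, 1.780, 0.0],
        [1.930, -1.780, 0.0],
        [-1.930, -1.780, 0.0],
    ]
)
_ACCEPTOR_SYMBOLS = ("C", "C", "N", "N", "N", "N")

# Well-separated base orientations (angle deg, axis) and stack displacements
# (A) for up to 8 planted clusters: distinct tilt axes and lateral offsets at
# a ~3.4 A pi-stacking distance.
_BASE_ANGLES = [10.0, 50.0, 90.0, 130.0, 170.0, 30.0, 70.0, 110.0]
_BASE_AXES = [
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [1.0, 1.0, 0.0],
    [1.0, -1.0, 0.0],
    [0.0, 1.0, 1.0],
    [1.0, 0.0, 1.0],
    [1.0, 2.0, 0.0],
    [2.0, -1.0, 1.0],
]
_BASE_SHIFTS = [
    [0.0, 0.0, 3.4],
    [2.6, 0.0, 3.4],
    [-2.6, 1.4, 3.4],
    [0.0, -2.8, 3.5],
    [2.0, 2.0, 3.6],
    [-1.8, -1.8, 3.3],
    [1.4, -2.4, 3.5],
    [-2.8, 0.7, 3.6],
]


@dataclass
class DimerGeneratorSpec:
    """Planted-cluster dimer trajectory parameters.

    Defaults match the standard study conditions used throughout the test
    suite: 500 frames, 5 orientational clusters, 2 degrees of angular and
    0.1 A of translational jitter, equal mixing weights.
    """

    n_frames: int = 500
    n_clusters: int = 5
    angular_noise_deg: float = 2.0
    translational_noise: float = 0.1
    weights: list[float] | None = None
    seed: int = 0
    base_rotations: list[tuple[float, list[float]]] | None = None
    base_displacements: list[list[float]] | None = None

    def __post_init__(self) -> None:
        if self.angular_noise_deg < 0 or self.translational_noise < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.weights is not None:
            if len(self.weights) != self.n_clusters:
                raise ValueError("one weight per cluster required")
            if abs(sum(self.weights) - 1.0) > 1e-9 or any(w < 0 for w in self.weights):
                raise ValueError("weights must be non-negative and sum to 1")
        if self.base_rotations is None:
            if self.n_clusters > len(_BASE_ANGLES):
                raise ValueError(f"at most {len(_BASE_ANGLES)} default clusters")
            self.base_rotations = [
                (_BASE_ANGLES[k], _BASE_AXES[k]) for k in range(self.n_clusters)
            ]
            self.base_displacements = [_BASE_SHIFTS[k] for k in range(self.n_clusters)]


def make_dimer_trajectory(spec: DimerGeneratorSpec) -> tuple[Trajectory, np.ndarray]:
    """Generate a dimer trajectory with planted orientational clusters.

    Returns the trajectory (donor atoms 0-9, acceptor atoms 10-15) and the
    ground-truth cluster label of every frame. Each frame additionally
    receives a random global rigid motion, so nothing about the planted
    structure survives in raw lab-frame coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    weights = spec.weights or [1.0 / spec.n_clusters] * spec.n_clusters
    labels = rng.choice(spec.n_clusters, size=spec.n_frames, p=weights)
    base_rots = [
        Rotation.from_rotvec(np.radians(a) * np.asarray(ax) / np.linalg.norm(ax))
        for a, ax in spec.base_rotations
    ]
    base_disp = [np.asarray(d, dtype=float) for d in spec.base_displacements]
    symbols = _DONOR_SYMBOLS + _ACCEPTOR_SYMBOLS
    frames = []
    for i in range(spec.n_frames):
        k = int(labels[i])
        # angular jitter: small random rotation composed with the base one
        jitter_axis = rng.normal(size=3)
        jitter_axis /= np.linalg.norm(jitter_axis)
        jitter = Rotation.from_rotvec(
            np.radians(rng.normal(0.0, spec.angular_noise_deg)) * jitter_axis
        )
        rot = jitter * base_rots[k]
        shift = base_disp[k] + rng.normal(0.0, spec.translational_noise, size=3)
        acceptor = rot.apply(_ACCEPTOR_TEMPLATE) + shift
        coords = np.vstack([_DONOR_TEMPLATE, acceptor])
        # random global rigid motion of the whole dimer
        g = Rotation.random(random_state=int(rng.integers(2**31)))
        coords = g.apply(coords) + rng.uniform(-10.0, 10.0, size=3)
        frames.append(Frame(index=i, symbols=symbols, coords=coords))
    traj = Trajectory(frames=frames, metadata={"generator": "dimer", "seed": spec.seed})
    return traj, labels


#: selections for the generated dimer, usable directly with the featurizers
DIMER_DONOR_INDICES = tuple(range(10))
DIMER_ACCEPTOR_INDICES = tuple(range(10, 16))
DIMER_LOCAL_FRAME = (0, 2, 4)  # three non-collinear donor atoms spanning its plane


@dataclass
class C2GeneratorSpec:
    """Near-two-fold-symmetric structure generator.

    The default template is an 8-atom structure exactly symmetric under a
    180-degree rotation about z; ``permutation`` pairs each atom with its
    two-fold partner (an involution).
    """

    template: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.2, 0.4, 0.6],
                [2.1, -0.8, -0.3],
                [0.7, 1.9, 1.1],
                [1.6, 1.1, -0.9],
                [-1.2, -0.4, 0.6],
                [-2.1, 0.8, -0.3],
                [-0.7, -1.9, 1.1],
                [-1.6, -1.1, -0.9],
            ]
        )
    )
    permutation: tuple[int, ...] = (4, 5, 6, 7, 0, 1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation)
        if not np.array_equal(perm[perm], np.arange(len(perm))):
            raise ValueError("permutation must be an involution")
        if c2_csm(np.asarray(self.template, dtype=float), None, self.permutation) > 1e-10:
            raise ValueError("template is not exactly C2-symmetric under the permutation")


def make_c2_series(spec: C2GeneratorSpec, deltas) -> list[np.ndarray]:
    """One distorted copy of the template per delta (A).

    Half of the atom pairs (one member of each two-fold pair) are displaced
    by isotropic Gaussian noise with per-atom RMS magnitude delta, breaking
    the symmetry by a controlled amount.
    """
    rng = np.random.default_rng(spec.seed)
    half = sorted({min(i, int(spec.permutation[i])) for i in range(len(spec.permutation))})
    out = []
    for delta in deltas:
        if delta < 0:
            raise ValueError("delta must be >= 0")
        coords = np.asarray(spec.template, dtype=float).copy()
        if delta > 0:
            coords[half] += rng.normal(0.0, delta / np.sqrt(3.0), size=(len(half), 3))
        out.append(coords)
    return out


@dataclass
class StateModelSpec:
    """Feature-to-excited-state response model.

    State i has energy  base_i + (conformational coupling) + Gaussian
    noise, and oscillator strength f_base_i + noise, clipped at 0.

    By default the coupling acts along the *leading conformational modes*
    of the supplied feature matrix: the first two principal-component
    scores, normalized to unit variance, enter with the per-state
    coefficients ``mode_coupling_ev`` (eV per score standard deviation).
    Excitation energies of real chromophore ensembles track exactly these
    large-amplitude collective coordinates; the default coefficients put
    the spread of cluster-representative energies at ~0.15-0.2 eV — the
    scale separating the low-lying states of distinct stacking conformers
    — while the residual within-conformer scatter stays well below the
    spectral broadening width (vertical energies are deterministic given
    the geometry, so the small noise term stands only for geometry
    dependence the features do not capture). An explicit per-feature
    ``response`` matrix overrides the mode-coupling default.
    """

    base_energies_ev: tuple[float, ...] = (2.0, 2.9)
    response: np.ndarray | None = None  # (n_states, n_features) eV per feature unit
    mode_coupling_ev: tuple[tuple[float, float], ...] = ((0.05, 0.0), (0.045, -0.015))
    energy_noise_ev: float = 0.002
    base_strengths: tuple[float, ...] = (0.03, 0.06)
    strength_noise: float = 0.005
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.base_energies_ev)


_MIN_ENERGY_EV = 0.05


def make_state_table(features: pd.DataFrame, spec: StateModelSpec, frame_ids=None) -> ExcitedStateTable:
    """Excited-state table whose energies respond linearly to the features."""
    x = features.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    n_frames, n_feat = x.shape
    rng = np.random.default_rng(spec.seed)
    if spec.response is not None:
        resp = np.asarray(spec.response, dtype=float)
        if resp.shape != (spec.n_states, n_feat):
            raise ValueError(f"response must be ({spec.n_states}, {n_feat})")
        conf = x @ resp.T  # (n_frames, n_states)
    else:
        if len(spec.mode_coupling_ev) != spec.n_states:
            raise ValueError("one mode-coupling pair per state required")
        centered = x - x.mean(axis=0)
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        n_modes = min(2, vt.shape[0])
        scores = centered @ vt[:n_modes].T
        stds = scores.std(axis=0)
        stds[stds == 0] = 1.0
        scores = scores / stds
        coeffs = np.asarray(spec.mode_coupling_ev, dtype=float)[:, :n_modes]
        conf = scores @ coeffs.T  # (n_frames, n_states)
    if frame_ids is None:
        frame_ids = np.arange(n_frames)
    rows = []
    n_clipped = 0
    for l in range(n_frames):
        for i in range(spec.n_states):
            e = spec.base_energies_ev[i] + float(conf[l, i])
            e += rng.normal(0.0, spec.energy_noise_ev)
            if e < _MIN_ENERGY_EV:
                e = _MIN_ENERGY_EV
                n_clipped += 1
            f = max(spec.base_strengths[i] + rng.normal(0.0, spec.strength_noise), 0.0)
            rows.append((int(frame_ids[l]), i + 1, e, f))
    if n_clipped:
        logger.warning("clipped %d non-positive state energies to %.2f eV", n_clipped, _MIN_ENERGY_EV)
    return ExcitedStateTable(
        pd.DataFrame(rows, columns=["frame_id", "state", "energy_ev", "osc_strength"])
    )


def brute_force_omega(D: np.ndarray, S_ov: np.ndarray, frag_idx: np.ndarray, n_frags: int) -> np.ndarray:
    """Reference fragment populations by an independent route.

    Uses :func:`scipy.linalg.sqrtm` for the overlap square root and an
    explicit quadruple loop over fragment pairs and basis functions. Kept
    deliberately separate from the production implementation so it can
    serve as its oracle.
    """
    half = np.real(scipy.linalg.sqrtm(S_ov))
    m = half @ D @ half
    omega = np.zeros((n_frags, n_frags))
    n = len(frag_idx)
    for a in range(n_frags):
        for b in range(n_frags):
            for mu in range(n):
                if frag_idx[mu] != a:
                    continue
                for nu in range(n):
                    if frag_idx[nu] == b:
                        omega[a, b] += m[mu, nu] ** 2
    return omega


def make_transition_density(
    n_basis: int,
    fragment_sizes,
    ct_weight: float,
    seed: int = 0,
    overlap_scale: float = 0.1,
    fragment_names=None,
) -> tuple[TransitionDensity, OmegaMatrix]:
    """Random density/overlap pair with planted fragment-block CT weight.

    The Loewdin-transformed density M = S^(1/2) D S^(1/2) is constructed
    directly with squared mass ``ct_weight`` in the off-diagonal fragment
    blocks and ``1 - ct_weight`` in the diagonal ones (total 1), then
    back-transformed to D. The returned expected Omega matrix comes from
    the independent brute-force route, not from the production code.
    """
    fragment_sizes = list(fragment_sizes)
    if sum(fragment_sizes) != n_basis:
        raise ValueError("fragment sizes must sum to n_basis")
    if not 0.0 <= ct_weight <= 1.0:
        raise ValueError("ct_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if fragment_names is None:
        fragment_names = [chr(ord("A") + i) for i in range(len(fragment_sizes))]
    frag_idx = np.concatenate(
        [np.full(sz, i) for i, sz in enumerate(fragment_sizes)]
    )
    # SPD overlap: identity plus scaled random symmetric part, eigen-floored
    r = rng.standard_normal((n_basis, n_basis))
    s = np.eye(n_basis) + overlap_scale * (r + r.T) / 2.0
    w, v = np.linalg.eigh(s)
    s = (v * np.maximum(w, 0.2)) @ v.T
    # plant block masses in the Loewdin-transformed matrix M
    m = rng.standard_normal((n_basis, n_basis))
    diag_mask = frag_idx[:, None] == frag_idx[None, :]
    for mask, target in ((diag_mask, 1.0 - ct_weight), (~diag_mask, ct_weight)):
        block = m[mask]
        ss = float((block**2).sum())
        m[mask] = block * np.sqrt(target / ss) if ss > 0 and target > 0 else 0.0
    w, v = np.linalg.eigh(s)
    inv_half = (v / np.sqrt(w)) @ v.T
    d = inv_half @ m @ inv_half
    basis_to_atom = frag_idx.copy()  # one pseudo-atom per fragment suffices
    atom_to_fragment = {i: fragment_names[i] for i in range(len(fragment_sizes))}
    td = TransitionDensity(D=d, S_ov=s, basis_to_atom=basis_to_atom, atom_to_fragment=atom_to_fragment)
    expected = OmegaMatrix(
        fragments=list(fragment_names),
        values=brute_force_omega(d, s, frag_idx, len(fragment_sizes)),
    )
    return td, expected
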