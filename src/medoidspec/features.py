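"""Geometric featurization of trajectories.

Implements the tailored feature spaces used for conformational clustering:

- plane-pair orientation features for stacked dimers — the angle between the
  two molecular-plane normals, the rotation axis relating them, and the
  relative position vector of the two geometric centers, all expressed in a
  body-fixed frame of the reference molecule so they are invariant under
  global rigid motion;
- signed dihedral angles with periodic (cos, sin) encoding to keep the
  feature space metric across the +/-180 degree wrap;
- a continuous symmetry measure (CSM) of deviation from C2 symmetry, the
  minimized RMSD between a structure and its optimally superposed two-fold
  image;
- z-score standardization with population (1/N) scaling;
- body-frame spatial distribution functions (SDF) of a target site.

Featurizers follow the scikit-learn transformer protocol: ``fit`` is a
no-op that validates selections, ``transform`` maps a Trajectory to a
pandas DataFrame of named feature columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler

from medoidspec.trajectory import AtomSelection, Frame, Trajectory

logger = logging.getLogger(__name__)

_DEGENERATE_AXIS_TOL = 1e-8


@dataclass(frozen=True)
class PlaneFeatures:
    """Per-frame plane-pair descriptors.

    theta_r is the angle (degrees, [0, 180]) between the two plane normals;
    n_r the unit rotation axis relating them (zero vector when the planes
    are parallel and the axis is undefined); r_rel the vector between the
    two geometric centers. n_r and r_rel are given in the body-fixed frame.
    """

    theta_r: float
    n_r: np.ndarray
    r_rel: np.ndarray
    degenerate_axis: bool = False


@dataclass
class SDFGrid:
    """3-D occupancy histogram of a target site in a body-fixed frame."""

    counts: np.ndarray  # (nx, ny, nz)
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]  # bin edges, Angstrom

    @property
    def n_binned(self) -> int:
        return int(self.counts.sum())

    def density(self) -> np.ndarray:
        """Counts normalized to a probability mass function."""
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Least-squares plane normal of >=3 points with a deterministic sign.

    The normal is the smallest-variance direction of the centered points
    (last right singular vector). Its sign is fixed to have positive dot
    product with cross(p1 - p0, p2 - p0) of the first three points, so the
    same atom ordering always yields the same orientation.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[-2] - s[-1] <= 1e-9:
        raise ValueError("degenerate (collinear) point set: plane normal undefined")
    normal = vt[-1]
    ref = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    if np.dot(normal, ref) < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def _body_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Rotation matrix whose rows are the body-frame axes.

    Origin at p1, x toward p2, z normal to the p1-p2-p3 plane, y = z cross x.
    Apply as ``R @ v_lab`` to express a lab vector in the body frame.
    """
    x = p2 - p1
    nx = np.linalg.norm(x)
    z = np.cross(p2 - p1, p3 - p1)
    nz = np.linalg.norm(z)
    if nx < 1e-10 or nz < 1e-10:
        raise ValueError("collinear local-frame atoms: body frame undefined")
    x = x / nx
    z = z / nz
    y = np.cross(z, x)
    return np.stack([x, y, z])


def plane_pair_features(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    local_frame_atoms: tuple[int, int, int],
) -> list[PlaneFeatures]:
    """Per-frame plane-pair features for two molecular fragments.

    ``sel_a`` is the reference molecule (its plane normal n1 and the three
    ``local_frame_atoms`` defining the body frame); ``sel_b`` the partner.
    theta_r = arccos(n1 . n2) without absolute-value folding; the rotation
    axis is the normalized cross product of the normals. Both the axis and
    the center-to-center vector (centerB - centerA) are rotated into the
    body frame, making every component invariant under global rigid motion.
    Parallel planes leave the axis undefined: the frame is flagged and the
    axis emitted as the zero vector (a valid, clusterable feature point).
    """
    if traj.frames:
        sel_a.validate_against(traj.n_atoms)
        sel_b.validate_against(traj.n_atoms)
    ia = list(sel_a.indices)
    ib = list(sel_b.indices)
    f1, f2, f3 = local_frame_atoms
    out: list[PlaneFeatures] = []
    for fr in traj:
        pa = fr.coords[ia]
        pb = fr.coords[ib]
        n1 = plane_normal(pa)
        n2 = plane_normal(pb)
        cosang = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
        theta = math.degrees(math.acos(cosang))
        axis = np.cross(n1, n2)
        norm = np.linalg.norm(axis)
        degenerate = norm < _DEGENERATE_AXIS_TOL
        axis = np.zeros(3) if degenerate else axis / norm
        rot = _body_frame(fr.coords[f1], fr.coords[f2], fr.coords[f3])
        r_rel = rot @ (pb.mean(axis=0) - pa.mean(axis=0))
        n_r = axis if degenerate else rot @ axis
        out.append(PlaneFeatures(theta_r=theta, n_r=n_r, r_rel=r_rel, degenerate_axis=degenerate))
    n_flagged = sum(p.degenerate_axis for p in out)
    if n_flagged:
        logger.warning("%d frames with degenerate (parallel-plane) rotation axis", n_flagged)
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral angle in degrees, in (-180, 180].

    Right-hand rule about the p2 -> p3 axis; the cis (eclipsed) arrangement
    is 0 and trans is 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear atom triple: dihedral undefined")
    ang = math.degrees(
        math.atan2(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)), np.dot(n1, n2))
    )
    return 180.0 if ang == -180.0 else ang


def encode_periodic(phi_degrees: float) -> tuple[float, float]:
    """Map an angle to its (cos, sin) pair so +/-180 encode identically."""
    rad = math.radians(phi_degrees)
    return (math.cos(rad), math.sin(rad))


def c2_csm(frame: Frame | np.ndarray, selection: AtomSelection | None, permutation) -> float:
    """Continuous symmetry measure of deviation from C2 symmetry, in Angstrom.

    The selected coordinates are centered at their centroid, the supplied
    atom pairing (an involution mapping each atom to its two-fold partner)
    generates the C2 image, and the proper rotation best superposing the
    image onto the original (Kabsch, det = +1) is found. The minimized RMSD
    is returned: 0 for an exactly C2-symmetric structure, growing with
    distortion. The value is invariant under global rigid motion.
    """
    if isinstance(frame, Frame):
        coords = frame.coords
        symbols = frame.symbols
    else:
        coords = np.asarray(frame, dtype=float)
        symbols = None
    if selection is not None:
        idx = list(selection.indices)
        coords = coords[idx]
        if symbols is not None:
            symbols = tuple(symbols[i] for i in idx)
    perm = np.asarray(permutation, dtype=int)
    n = coords.shape[0]
    if perm.shape != (n,):
        raise ValueError(f"permutation length {perm.shape} != {n} selected atoms")
    if not np.array_equal(perm[perm], np.arange(n)):
        raise ValueError("permutation must be an involution (its own inverse)")
    if symbols is not None:
        for i, j in enumerate(perm):
            if symbols[i] != symbols[j]:
                raise ValueError(
                    f"permutation maps {symbols[i]} (atom {i}) onto {symbols[j]} (atom {j})"
                )
    x = coords - coords.mean(axis=0)
    y = x[perm]
    _, rssd = Rotation.align_vectors(x, y)
    return float(rssd) / math.sqrt(n)


@dataclass
class StandardizationParams:
    """Per-column centering/scaling record, including dropped constants."""

    columns: list[str]
    means: np.ndarray
    stds: np.ndarray
    dropped: list[str] = field(default_factory=list)


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score each column using population (1/N) standard deviation.

    Zero-variance columns cannot satisfy the unit-variance contract; they
    are dropped with a warning and recorded in the returned params.
    """
    scaler = FeatureStandardizer()
    out = scaler.fit_transform(features)
    return out, scaler.params_


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Column z-scoring transformer (population std, constant columns dropped).

    Thin wrapper over :class:`sklearn.preprocessing.StandardScaler` that
    keeps DataFrame column names, drops zero-variance columns (recorded in
    ``params_``) and exposes the exact inverse transform.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 rows to standardize")
        if not np.all(np.isfinite(X.to_numpy())):
            raise ValueError("non-finite feature values")
        variances = X.var(axis=0, ddof=0)
        dropped = list(variances.index[variances == 0.0])
        if dropped:
            logger.warning("dropping zero-variance columns: %s", dropped)
        kept = [c for c in X.columns if c not in dropped]
        self._scaler = StandardScaler()  # ddof=0: population std, per contract
        self._scaler.fit(X[kept].to_numpy())
        self.params_ = StandardizationParams(
            columns=kept,
            means=self._scaler.mean_.copy(),
            stds=self._scaler.scale_.copy(),
            dropped=dropped,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._as_frame(X)
        z = self._scaler.transform(X[self.params_.columns].to_numpy())
        return pd.DataFrame(z, columns=self.params_.columns, index=X.index)

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        Z = self._as_frame(Z)
        raw = self._scaler.inverse_transform(Z.to_numpy())
        return pd.DataFrame(raw, columns=self.params_.columns, index=Z.index)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


class PlanePairFeaturizer(TransformerMixin, BaseEstimator):
    """Trajectory -> DataFrame of plane-pair orientation features.

    Columns: theta_r (deg), nr_x/nr_y/nr_z (body-frame rotation-axis
    components), r_x/r_y/r_z (body-frame center-to-center vector, Angstrom),
    plus a boolean ``degenerate_axis`` flag column excluded from clustering
    by downstream consumers.
    """

    def __init__(
        self,
        sel_a: AtomSelection,
        sel_b: AtomSelection,
        local_frame_atoms: tuple[int, int, int],
    ):
        self.sel_a = sel_a
        self.sel_b = sel_b
        self.local_frame_atoms = local_frame_atoms

    def fit(self, X: Trajectory, y=None):
        if len(X):
            self.sel_a.validate_against(X.n_atoms)
            self.sel_b.validate_against(X.n_atoms)
        self.n_features_out_ = 7
        return self

    def transform(self, X: Trajectory) -> pd.DataFrame:
        feats = plane_pair_features(X, self.sel_a, self.sel_b, self.local_frame_atoms)
        rows = [
            (p.theta_r, *p.n_r, *p.r_rel, p.degenerate_axis)
            for p in feats
        ]
        return pd.DataFrame(
            rows,
            columns=["theta_r", "nr_x", "nr_y", "nr_z", "r_x", "r_y", "r_z", "degenerate_axis"],
        ).astype({"degenerate_axis": bool})


class C2SymmetryFeaturizer(TransformerMixin, BaseEstimator):
    """Trajectory -> DataFrame of dihedral (cos, sin) pairs plus the C2-CSM.

    ``dihedrals`` is a list of 4-tuples of atom indices; each angle phi
    contributes two columns cos_phi<i> and sin_phi<i>. ``csm_selection`` and
    ``csm_permutation`` define the atom subset and two-fold pairing for the
    continuous symmetry measure column.
    """

    def __init__(
        self,
        dihedrals: list[tuple[int, int, int, int]],
        csm_selection: AtomSelection | None = None,
        csm_permutation=None,
    ):
        self.dihedrals = dihedrals
        self.csm_selection = csm_selection
        self.csm_permutation = csm_permutation

    def fit(self, X: Trajectory, y=None):
        if len(X) and self.csm_selection is not None:
            self.csm_selection.validate_against(X.n_atoms)
        self.n_features_out_ = 2 * len(self.dihedrals) + (
            1 if self.csm_permutation is not None else 0
        )
        return self

    def transform(self, X: Trajectory) -> pd.DataFrame:
        cols: dict[str, list[float]] = {}
        for d, (i, j, k, l) in enumerate(self.dihedrals, start=1):
            cols[f"cos_phi{d}"] = []
            cols[f"sin_phi{d}"] = []
        if self.csm_permutation is not None:
            cols["c2_csm"] = []
        for fr in X:
            for d, (i, j, k, l) in enumerate(self.dihedrals, start=1):
                phi = dihedral(fr.coords[i], fr.coords[j], fr.coords[k], fr.coords[l])
                c, s = encode_periodic(phi)
                cols[f"cos_phi{d}"].append(c)
                cols[f"sin_phi{d}"].append(s)
            if self.csm_permutation is not None:
                cols["c2_csm"].append(c2_csm(fr, self.csm_selection, self.csm_permutation))
        return pd.DataFrame(cols)


def _atomic_mass(symbol: str) -> float:
    from mdtraj.core import element as _el

    return float(_el.get_by_symbol(symbol).mass)


def sdf(
    traj: Trajectory,
    local_frame_atoms: tuple[int, int, int],
    target_selection: AtomSelection,
    bin_width: float = 0.5,
    extent: float | None = None,
) -> SDFGrid:
    """Spatial distribution function of a target site in a body-fixed frame.

    Per frame, the mass-weighted center of the target selection is expressed
    in the three-point body frame of the reference molecule (origin at atom
    1, x toward atom 2, z normal to the 1-2-3 plane) and accumulated into a
    3-D histogram with cubic bins of ``bin_width`` Angstrom. ``extent``
    overrides the automatic (data-spanning) histogram range with a symmetric
    cube [-extent, extent]^3.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    target_selection.validate_against(traj.n_atoms)
    idx = list(target_selection.indices)
    masses = np.array([_atomic_mass(traj.symbols[i]) for i in idx])
    masses = masses / masses.sum()
    f1, f2, f3 = local_frame_atoms
    points = np.empty((len(traj), 3))
    for r, fr in enumerate(traj):
        rot = _body_frame(fr.coords[f1], fr.coords[f2], fr.coords[f3])
        com = masses @ fr.coords[idx]
        points[r] = rot @ (com - fr.coords[f1])
    if extent is None:
        lo = points.min(axis=0) - bin_width
        hi = points.max(axis=0) + bin_width
    else:
        lo = np.full(3, -extent)
        hi = np.full(3, extent)
    edges = [np.arange(lo[k], hi[k] + bin_width, bin_width) for k in range(3)]
    counts, final_edges = np.histogramdd(points, bins=edges)
    return SDFGrid(counts=counts.astype(int), edges=tuple(final_edges))
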