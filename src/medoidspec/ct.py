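"""Fragment-based Loewdin transition-density analysis and omega_CT.

Given the one-particle transition density matrix D (S_i <- S_0) in an
atomic-orbital basis and the AO overlap matrix S, the Loewdin-symmetrized
density M = S^(1/2) D S^(1/2) is partitioned over molecular fragments:

    Omega[A][B] = sum_{mu in A} sum_{nu in B} M_{mu nu}^2

Omega[A][B] is read as the weight of "hole on fragment A, electron on
fragment B": the row index of D is the hole (occupied) index and the
column index the electron (virtual) index. This orientation convention is
a package-level contract — swap the fragment roles if your upstream code
builds D transposed.

The charge-transfer descriptor is the off-diagonal fraction

    omega_CT = sum_{A != B} Omega[A][B] / sum_{A,B} Omega[A][B],

close to 1 for charge-transfer states and close to 0 for local
excitations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LE_CT_THRESHOLD = 0.5  # omega_CT above this => charge-transfer label


@dataclass
class TransitionDensity:
    """Transition density + overlap matrices with basis/fragment maps.

    ``basis_to_atom``: length-n array, AO index -> 0-based atom index.
    ``atom_to_fragment``: dict atom index -> fragment name; every atom
    carrying basis functions must be assigned to exactly one fragment.
    """

    D: np.ndarray
    S_ov: np.ndarray
    basis_to_atom: np.ndarray
    atom_to_fragment: dict[int, str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.S_ov = np.asarray(self.S_ov, dtype=float)
        self.basis_to_atom = np.asarray(self.basis_to_atom, dtype=int)
        n = self.D.shape[0]
        if self.D.shape != (n, n) or self.S_ov.shape != (n, n):
            raise ValueError("D and S must be square matrices of the same size")
        if len(self.basis_to_atom) != n:
            raise ValueError("basis_to_atom length must match the basis size")
        if np.abs(self.S_ov - self.S_ov.T).max() > 1e-10:
            raise ValueError("overlap matrix not symmetric")

    @property
    def fragments(self) -> list[str]:
        seen: list[str] = []
        for a in self.basis_to_atom:
            frag = self.atom_to_fragment.get(int(a))
            if frag is None:
                raise ValueError(f"atom {a} carries basis functions but has no fragment")
            if frag not in seen:
                seen.append(frag)
        return seen

    def fragment_of_basis(self) -> np.ndarray:
        """Fragment index (into ``fragments``) of each basis function."""
        frags = self.fragments
        lookup = {f: i for i, f in enumerate(frags)}
        return np.array([lookup[self.atom_to_fragment[int(a)]] for a in self.basis_to_atom])


@dataclass
class OmegaMatrix:
    """F x F fragment-pair weights, rows = hole fragment, cols = electron."""

    fragments: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        f = len(self.fragments)
        if self.values.shape != (f, f):
            raise ValueError("Omega shape must be (F, F)")
        if (self.values < 0).any():
            raise ValueError("negative Omega entry")

    def total(self) -> float:
        return float(self.values.sum())

    def as_records(self, id_=0, state=1) -> pd.DataFrame:
        rows = [
            (id_, state, a, b, self.values[i, j])
            for i, a in enumerate(self.fragments)
            for j, b in enumerate(self.fragments)
        ]
        return pd.DataFrame(rows, columns=["id", "state", "hole_frag", "elec_frag", "omega"])


def sym_sqrt(S_ov: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root via eigendecomposition.

    Eigenvalues below -1e-8 mean the input is not positive semi-definite
    and raise; tiny ones in [-1e-8, 1e-10] are floored to 1e-10 with a
    warning (near-singular overlaps from linear dependencies).
    """
    S_ov = np.asarray(S_ov, dtype=float)
    if np.abs(S_ov - S_ov.T).max() > 1e-10:
        raise ValueError("matrix not symmetric")
    w, v = np.linalg.eigh(S_ov)
    if w.min() < -1e-8:
        raise ValueError(f"matrix not positive semi-definite (min eigenvalue {w.min():.3e})")
    if w.min() < 1e-10:
        logger.warning("flooring %d near-zero overlap eigenvalues to 1e-10", int((w < 1e-10).sum()))
        w = np.maximum(w, 1e-10)
    return (v * np.sqrt(w)) @ v.T


def omega_matrix(td: TransitionDensity) -> OmegaMatrix:
    """Fragment-pair Loewdin populations of a transition density."""
    half = sym_sqrt(td.S_ov)
    m2 = (half @ td.D @ half) ** 2
    frag_idx = td.fragment_of_basis()
    frags = td.fragments
    f = len(frags)
    # indicator aggregation: Omega = I_h m2 I_e^T
    ind = np.zeros((f, len(frag_idx)))
    ind[frag_idx, np.arange(len(frag_idx))] = 1.0
    values = ind @ m2 @ ind.T
    total = values.sum()
    if abs(total - 1.0) > 0.2:
        logger.warning(
            "sum of Omega = %.3f deviates from 1 by >20%%: check the density normalization", total
        )
    return OmegaMatrix(fragments=frags, values=values)


def omega_ct(omega) -> float:
    """Charge-transfer fraction: off-diagonal Omega weight over the total.

    Accepts an :class:`OmegaMatrix` or a record table/dict of fragment-pair
    entries. For partial tabulations (not all F^2 pairs supplied) the
    denominator is the sum of the supplied entries only.
    """
    if isinstance(omega, OmegaMatrix):
        total = omega.total()
        if total <= 0:
            raise ValueError("all-zero Omega")
        off = total - float(np.trace(omega.values))
        return off / total
    if isinstance(omega, dict):
        items = [((a, b), float(v)) for (a, b), v in omega.items()]
    else:  # record DataFrame with hole_frag / elec_frag / omega columns
        items = [
            ((r.hole_frag, r.elec_frag), float(r.omega)) for r in omega.itertuples(index=False)
        ]
    if any(v < 0 for _, v in items):
        raise ValueError("negative Omega entry")
    total = sum(v for _, v in items)
    if total <= 0:
        raise ValueError("all-zero Omega")
    off = sum(v for (a, b), v in items if a != b)
    return off / total


def characterize_states(omega_records: pd.DataFrame, state_table=None) -> pd.DataFrame:
    """Per-state summary: omega_CT, dominant fragment pair, CT/LE label.

    ``omega_records`` is the long-format record table (id, state,
    hole_frag, elec_frag, omega); ``state_table`` optionally supplies
    energies and oscillator strengths joined on (id, state). The dominant
    pair is the argmax Omega entry (lowest-lexicographic tie-break); a
    state is labeled charge-transfer when omega_CT >= 0.5, else local
    excitation. Partial tabulations are flagged in the ``partial`` column.
    """
    if len(omega_records) == 0:
        raise ValueError("no omega records")
    n_frag_pairs = None
    all_frags = sorted(set(omega_records["hole_frag"]) | set(omega_records["elec_frag"]))
    n_frag_pairs = len(all_frags) ** 2
    rows = []
    for (id_, state), grp in omega_records.groupby(["id", "state"]):
        wct = omega_ct(grp[["hole_frag", "elec_frag", "omega"]])
        ordered = grp.sort_values(["hole_frag", "elec_frag"])
        best = ordered.loc[ordered["omega"].idxmax()]
        dominant = f"{best.hole_frag}->{best.elec_frag}"
        rows.append(
            {
                "id": id_,
                "state": state,
                "omega_ct": wct,
                "dominant_pair": dominant,
                "character": "CT" if wct >= LE_CT_THRESHOLD else "LE",
                "partial": len(grp) < n_frag_pairs,
            }
        )
    report = pd.DataFrame(rows)
    if state_table is not None:
        df = state_table.data if hasattr(state_table, "data") else state_table
        df = df.rename(columns={"frame_id": "id"})
        report = report.merge(
            df[["id", "state", "energy_ev", "osc_strength"]], on=["id", "state"], how="left"
        )
        if report["energy_ev"].isna().any():
            missing = report[report["energy_ev"].isna()][["id", "state"]].to_records(index=False)
            raise KeyError(f"states missing from the state table: {list(missing)}")
    return report.sort_values(["id", "state"]).reset_index(drop=True)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited n x n matrix with a one-line header (n, label)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    n = int(lines[0].split()[0])
    data = np.loadtxt(lines[1 : 1 + n])
    data = np.atleast_2d(data)
    if data.shape != (n, n):
        raise ValueError(f"{path}: expected {n}x{n} matrix, got {data.shape}")
    return data


def write_matrix(m: np.ndarray, path: str | Path, label: str = "") -> None:
    m = np.asarray(m, dtype=float)
    lines = [f"{m.shape[0]} {label}".rstrip()]
    lines += [" ".join(f"{x:.12e}" for x in row) for row in m]
    Path(path).write_text("\n".join(lines) + "\n")


def read_map_tsv(path: str | Path) -> dict[int, str]:
    """Two-column TSV (index, value) -> dict; used for basis and fragment maps."""
    out: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, val = line.split("\t")
        out[int(key)] = val.strip()
    return out


def load_transition_density(
    density_path, overlap_path, basis_map_path, frag_map_path
) -> TransitionDensity:
    """Assemble a TransitionDensity from the four on-disk pieces."""
    d = read_matrix(density_path)
    s = read_matrix(overlap_path)
    basis_map = read_map_tsv(basis_map_path)
    basis_to_atom = np.array([int(basis_map[i]) for i in range(len(basis_map))])
    frag_map = {int(k): v for k, v in read_map_tsv(frag_map_path).items()}
    return TransitionDensity(D=d, S_ov=s, basis_to_atom=basis_to_atom, atom_to_fragment=frag_map)
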