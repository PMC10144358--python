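"""Per-frame excited-state tables and fragment Omega records.

The package deliberately consumes excited-state results (vertical
excitation energies, oscillator strengths) and fragment transition-density
populations as plain TSV rather than parsing any quantum-chemistry
program's log files: the spectral reconstruction is agnostic to where the
electronic-structure numbers came from.

Dialects (tab-delimited, header mandatory, '#' comment lines allowed):

- ``states.tsv``: frame_id, state, energy_ev, osc_strength
- ``omega.tsv``:  id, state, hole_frag, elec_frag, omega
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HC_EV_NM = 1239.84193  # Planck constant x speed of light, eV * nm
EV_PER_INVCM = 1.0 / 8065.543937  # 1 cm^-1 in eV


@dataclass
class ExcitedStateTable:
    """Validated long-format table of per-frame excited states.

    Columns: frame_id (int), state (int >= 1, contiguous within each
    frame), energy_ev (> 0), osc_strength (>= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["frame_id", "state", "energy_ev", "osc_strength"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[required].copy()
        df["frame_id"] = df["frame_id"].astype(int)
        df["state"] = df["state"].astype(int)
        df[["energy_ev", "osc_strength"]] = df[["energy_ev", "osc_strength"]].astype(float)
        if df.duplicated(["frame_id", "state"]).any():
            raise ValueError("duplicate (frame_id, state) rows")
        if not np.all(np.isfinite(df["energy_ev"])):
            raise ValueError("non-finite excitation energy")
        if (df["energy_ev"] <= 0).any():
            raise ValueError("non-positive excitation energy")
        if (df["osc_strength"] < 0).any():
            raise ValueError("negative oscillator strength")
        for fid, grp in df.groupby("frame_id"):
            states = np.sort(grp["state"].to_numpy())
            if not np.array_equal(states, np.arange(1, len(states) + 1)):
                raise ValueError(
                    f"frame {fid}: states must be numbered 1..N contiguously, got {states.tolist()}"
                )
        self.data = df.sort_values(["frame_id", "state"]).reset_index(drop=True)

    @property
    def frame_ids(self) -> np.ndarray:
        return self.data["frame_id"].unique()

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def restrict(self, frame_ids) -> "ExcitedStateTable":
        """Sub-table containing only the given frames (e.g. the medoids)."""
        wanted = set(int(i) for i in frame_ids)
        missing = wanted - set(self.data["frame_id"].tolist())
        if missing:
            raise KeyError(f"frames not in table: {sorted(missing)}")
        sub = self.data[self.data["frame_id"].isin(wanted)]
        return ExcitedStateTable(sub.reset_index(drop=True))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.lstrip().startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t")


def read_states_tsv(path: str | Path, energy_unit: str = "ev") -> ExcitedStateTable:
    """Read a states.tsv file, optionally converting energies on the fly.

    ``energy_unit`` is one of ``ev`` (default), ``nm`` (wavelength) or
    ``cm-1`` (wavenumber); non-eV inputs are converted with
    hc = 1239.84193 eV nm.
    """
    df = _read_tsv(path)
    required = {"frame_id", "state", "energy_ev", "osc_strength"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    unit = energy_unit.lower()
    if unit == "nm":
        df["energy_ev"] = HC_EV_NM / df["energy_ev"].astype(float)
    elif unit in ("cm-1", "cm^-1", "wavenumber"):
        df["energy_ev"] = df["energy_ev"].astype(float) * EV_PER_INVCM
    elif unit != "ev":
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    table = ExcitedStateTable(df)
    logger.info("read %d state rows (%d frames) from %s", len(table.data), table.n_frames, path)
    return table


def write_states_tsv(table: ExcitedStateTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_omega_tsv(path: str | Path) -> pd.DataFrame:
    """Read fragment Omega records: (id, state, hole_frag, elec_frag, omega).

    Optional ``energy_ev`` / ``osc_strength`` columns are carried through.
    Negative omega values are rejected; an empty file yields an empty
    record set with a warning.
    """
    df = _read_tsv(path)
    required = {"id", "state", "hole_frag", "elec_frag", "omega"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    if len(df) == 0:
        logger.warning("%s: empty omega record file", path)
        return df
    df = df.copy()
    df["omega"] = df["omega"].astype(float)
    if (df["omega"] < 0).any():
        raise ValueError("negative omega value")
    if df.duplicated(["id", "state", "hole_frag", "elec_frag"]).any():
        raise ValueError("duplicate (id, state, hole, electron) omega record")
    logger.info("read %d omega records from %s", len(df), path)
    return df


def write_omega_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)
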