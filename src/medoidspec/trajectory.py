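"""Multi-frame molecular geometry I/O and the frame data model.

Every downstream module consumes the :class:`Trajectory` container defined
here: an ordered list of frames sharing one atom sequence, with coordinates
in Angstrom. Multi-frame XYZ is the canonical interchange format; PDB is
supported read-only for users whose snapshots come from solvated setups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_TIME_TAG = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


@dataclass(frozen=True)
class Frame:
    """A single snapshot: element symbols plus Cartesian coordinates (A).

    ``time`` is an optional timestamp in femtoseconds parsed from the XYZ
    comment line (``t=<float>``) when present.
    """

    index: int
    symbols: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom
    time: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise ValueError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass
class Trajectory:
    """Ordered frames with one shared atom sequence.

    Invariants: every frame carries the identical symbol tuple and frame
    indices are strictly increasing.
    """

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames:
            ref = self.frames[0].symbols
            for fr in self.frames[1:]:
                if fr.symbols != ref:
                    raise ValueError(
                        f"frame {fr.index}: element sequence differs from frame "
                        f"{self.frames[0].index}"
                    )
            idx = [fr.index for fr in self.frames]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def symbols(self) -> tuple[str, ...]:
        if not self.frames:
            raise ValueError("empty trajectory has no atom sequence")
        return self.frames[0].symbols

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def coords_array(self) -> np.ndarray:
        """Stack all coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    """A named set of 0-based atom indices (a fragment, a plane, a local frame)."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError(f"selection {self.name!r} is empty")
        if any(i < 0 for i in self.indices):
            raise ValueError(f"selection {self.name!r} has negative indices")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))

    def validate_against(self, n_atoms: int) -> None:
        bad = [i for i in self.indices if i >= n_atoms]
        if bad:
            raise ValueError(
                f"selection {self.name!r}: indices {bad} out of range for {n_atoms} atoms"
            )


def read_xyz(path: str | Path) -> Trajectory:
    """Read a multi-frame XYZ file.

    Each block is ``n_atoms`` / comment / ``n_atoms`` atom lines. A ``t=<float>``
    tag in the comment line is parsed as the frame time in femtoseconds.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}: expected atom count at line {pos + 1}, got {lines[pos]!r}"
            ) from exc
        if n < 0:
            raise ValueError(f"{path}: bad atom count {n} at line {pos + 1}")
        if pos + 2 + n > len(lines):
            raise ValueError(f"{path}: truncated frame starting at line {pos + 1}")
        comment = lines[pos + 1]
        m = _TIME_TAG.search(comment)
        time = float(m.group(1)) if m else None
        symbols: list[str] = []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[pos + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed atom line {pos + 3 + j}")
            symbols.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric coordinate at line {pos + 3 + j}"
                ) from exc
        frames.append(Frame(index=len(frames), symbols=tuple(symbols), coords=coords, time=time))
        pos += 2 + n
    traj = Trajectory(frames=frames, metadata={"source": str(path)})
    logger.info("read %d frames (%d atoms) from %s", len(frames), traj.n_atoms if frames else 0, path)
    return traj


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-frame XYZ with 8-decimal coordinates."""
    path = Path(path)
    if not traj.frames:
        logger.warning("writing empty trajectory to %s", path)
        path.write_text("")
        return
    out: list[str] = []
    for fr in traj.frames:
        out.append(str(fr.n_atoms))
        comment = f"frame {fr.index}"
        if fr.time is not None:
            comment += f" t={fr.time:.6f}"
        out.append(comment)
        for sym, (x, y, z) in zip(fr.symbols, fr.coords):
            out.append(f"{sym:<3s} {x:18.8f} {y:18.8f} {z:18.8f}")
    path.write_text("\n".join(out) + "\n")


# PDB v3.3 fixed columns for ATOM/HETATM records (0-based, half-open)
_PDB_X = slice(30, 38)
_PDB_Y = slice(38, 46)
_PDB_Z = slice(46, 54)
_PDB_ELEM = slice(76, 78)
_PDB_NAME = slice(12, 16)


def read_pdb(path: str | Path) -> Trajectory:
    """Minimal read-only PDB parser: ATOM/HETATM symbols and coordinates only.

    Multiple MODEL records become multiple frames. The element is taken from
    columns 77-78 when present, else inferred from the atom name.
    """
    path = Path(path)
    frames: list[Frame] = []
    symbols: list[str] = []
    coords: list[list[float]] = []

    def flush() -> None:
        nonlocal symbols, coords
        if symbols:
            frames.append(
                Frame(index=len(frames), symbols=tuple(symbols), coords=np.array(coords))
            )
            symbols, coords = [], []

    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            elem = line[_PDB_ELEM].strip() if len(line) >= 78 else ""
            if not elem:
                name = line[_PDB_NAME].strip()
                elem = "".join(c for c in name if c.isalpha())[:2].capitalize()
                if len(elem) == 2 and elem not in _TWO_LETTER:
                    elem = elem[0]
            else:
                elem = elem.capitalize()
            symbols.append(elem)
            coords.append([float(line[_PDB_X]), float(line[_PDB_Y]), float(line[_PDB_Z])])
        elif rec == "ENDMDL":
            flush()
    flush()
    return Trajectory(frames=frames, metadata={"source": str(path), "format": "pdb"})


_TWO_LETTER = frozenset(
    "He Li Be Ne Na Mg Al Si Cl Ar Ca Sc Ti Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba Pt Au Hg Tl Pb Bi".split()
)


def uniform_subset(
    traj: Trajectory,
    stride: int | None = None,
    target_count: int | None = None,
    skip: int = 0,
) -> Trajectory:
    """Take a uniformly strided frame subset, emulating "every n fs" sampling.

    Exactly one of ``stride`` / ``target_count`` must be given. With
    ``target_count``, stride = floor(N / target_count) and the first
    ``target_count`` frames of the strided sequence are kept (deterministic
    policy for N not divisible by the count). ``skip`` drops that many leading
    frames first (equilibration discard).
    """
    if (stride is None) == (target_count is None):
        raise ValueError("give exactly one of stride or target_count")
    frames = traj.frames[skip:]
    n = len(frames)
    if target_count is not None:
        if not 1 <= target_count <= n:
            raise ValueError(f"target_count {target_count} outside [1, {n}]")
        stride = max(n // target_count, 1)
        sub = frames[::stride][:target_count]
    else:
        if stride < 1:
            raise ValueError("stride must be >= 1")
        sub = frames[::stride]
    meta = dict(traj.metadata)
    meta.update({"subset_stride": stride, "subset_skip": skip})
    return Trajectory(frames=list(sub), metadata=meta)
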