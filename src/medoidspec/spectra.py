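"""Gaussian-broadened absorption spectra from excited-state tables.

Each electronic transition contributes an amplitude-normalized Gaussian
line: a peak of height f (the oscillator strength) centered at the
vertical excitation energy nu, with a fixed width parameter sigma
(default sigma^2 = 0.001 eV^2). The ensemble spectrum sums these lines
over every frame and state of a uniform trajectory sampling; the reduced
spectrum sums only over the cluster medoids, each weighted by its
cluster's population fraction p_k.

Normalization: the medoid spectrum's population weights sum to one, so
for comparability the ensemble sum is divided by the number of frames by
default (``per-frame-mean``). With the trivial clustering where every
frame is its own medoid (p_k = 1/N) the two constructions then coincide
exactly. ``raw`` mode keeps the plain double sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from medoidspec.states import HC_EV_NM, ExcitedStateTable

DEFAULT_SIGMA2 = 0.001  # eV^2
DEFAULT_GRID = (1.0, 5.0, 0.001)  # eV: lo, hi, step


@dataclass
class Spectrum:
    """Absorption spectrum on a uniform energy grid (eV, arbitrary units)."""

    grid: np.ndarray
    intensity: np.ndarray
    sigma2: float
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape:
            raise ValueError("grid/intensity shape mismatch")
        steps = np.diff(self.grid)
        if len(steps) and (steps.min() <= 0 or np.ptp(steps) > 1e-9):
            raise ValueError("grid must be strictly increasing and uniform")
        if (self.intensity < 0).any():
            raise ValueError("negative intensity")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        """Trapezoidal integral of the intensity over the grid (a.u. * eV)."""
        return float(np.trapezoid(self.intensity, self.grid))

    def argmax_energy(self) -> float:
        """Grid energy of the global intensity maximum."""
        return float(self.grid[int(np.argmax(self.intensity))])


def make_grid(lo: float = DEFAULT_GRID[0], hi: float = DEFAULT_GRID[1], step: float = DEFAULT_GRID[2]) -> np.ndarray:
    """Uniform energy grid including both endpoints."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def line_contribution(nu_grid: np.ndarray, nu: float, f: float, sigma2: float = DEFAULT_SIGMA2) -> np.ndarray:
    """One transition's Gaussian line: peak height f at energy nu.

    The line shape is amplitude-normalized (height f, not unit area); its
    integral is f * sigma * sqrt(2 pi).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if f < 0:
        raise ValueError("negative oscillator strength")
    nu_grid = np.asarray(nu_grid, dtype=float)
    return f * np.exp(-0.5 * (nu_grid - nu) ** 2 / sigma2)


def _sum_lines(nu_grid: np.ndarray, energies: np.ndarray, strengths: np.ndarray,
               weights: np.ndarray, sigma2: float) -> np.ndarray:
    # (n_lines, n_grid) broadcast; fine for <= ~2e4 lines x 4e3 points
    g = np.exp(-0.5 * (nu_grid[None, :] - energies[:, None]) ** 2 / sigma2)
    return (weights * strengths) @ g


def ensemble_spectrum(
    states: ExcitedStateTable,
    grid: np.ndarray | None = None,
    sigma2: float = DEFAULT_SIGMA2,
    normalization: str = "per-frame-mean",
) -> Spectrum:
    """Full-sampling spectrum: Gaussian sum over every frame and state."""
    if len(states.data) == 0:
        raise ValueError("empty state table")
    if normalization not in ("raw", "per-frame-mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    nu_grid = make_grid() if grid is None else np.asarray(grid, dtype=float)
    e = states.data["energy_ev"].to_numpy()
    f = states.data["osc_strength"].to_numpy()
    w = np.ones(len(e))
    if normalization == "per-frame-mean":
        w /= states.n_frames
    return Spectrum(nu_grid, _sum_lines(nu_grid, e, f, w, sigma2), sigma2, normalization)


def medoid_spectrum(
    medoid_states: ExcitedStateTable,
    populations,
    grid: np.ndarray | None = None,
    sigma2: float = DEFAULT_SIGMA2,
) -> Spectrum:
    """Reduced spectrum: population-weighted Gaussian sum over medoids only.

    ``populations`` maps one weight per medoid frame, ordered as
    ``medoid_states.frame_ids`` (or a dict frame_id -> p_k); weights must
    sum to 1.
    """
    fids = medoid_states.frame_ids
    if isinstance(populations, dict):
        p = np.array([populations[int(i)] for i in fids], dtype=float)
    else:
        p = np.asarray(populations, dtype=float)
    if len(p) != len(fids):
        raise ValueError(f"{len(p)} populations for {len(fids)} medoid frames")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"populations sum to {p.sum()}, expected 1")
    nu_grid = make_grid() if grid is None else np.asarray(grid, dtype=float)
    pop_of = dict(zip((int(i) for i in fids), p))
    df = medoid_states.data
    e = df["energy_ev"].to_numpy()
    f = df["osc_strength"].to_numpy()
    w = df["frame_id"].map(pop_of).to_numpy(dtype=float)
    return Spectrum(nu_grid, _sum_lines(nu_grid, e, f, w, sigma2), sigma2, "population-weighted")


def nm_to_ev(wavelength_nm: float) -> float:
    """Photon energy (eV) of a wavelength (nm): E = 1239.84193 / lambda."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    return HC_EV_NM / wavelength_nm


def ev_to_nm(energy_ev: float) -> float:
    if energy_ev <= 0:
        raise ValueError("energy must be > 0")
    return HC_EV_NM / energy_ev


def peak_report(spectrum: Spectrum, prominence: float = 0.0) -> list[tuple[float, float]]:
    """Local maxima above a prominence threshold, sorted by energy.

    Energies are reported at grid resolution. A maximum at the grid edge
    is included when it exceeds its inner neighbor.
    """
    y = spectrum.intensity
    idx, _ = find_peaks(y, prominence=prominence if prominence > 0 else None)
    peaks = [(float(spectrum.grid[i]), float(y[i])) for i in idx]
    # edge maxima are not found by find_peaks; report them when dominant
    if len(y) >= 2:
        for edge, inner in ((0, 1), (-1, -2)):
            if y[edge] > y[inner] and y[edge] >= prominence:
                peaks.append((float(spectrum.grid[edge]), float(y[edge])))
    return sorted(peaks)


def spectrum_integral_deviation(a: Spectrum, b: Spectrum) -> float:
    """Integrated absolute deviation of two spectra, relative to b's integral."""
    if a.grid.shape != b.grid.shape or np.abs(a.grid - b.grid).max() > 1e-12:
        raise ValueError("spectra must share the same grid")
    denom = b.integral()
    if denom <= 0:
        raise ValueError("reference spectrum has zero integral")
    return float(np.trapezoid(np.abs(a.intensity - b.intensity), a.grid)) / denom


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    lines = [
        f"# sigma2={spectrum.sigma2}",
        f"# normalization={spectrum.normalization}",
        "energy_ev\tintensity",
    ]
    lines += [f"{e:.6f}\t{i:.10e}" for e, i in zip(spectrum.grid, spectrum.intensity)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_tsv(path: str | Path) -> Spectrum:
    sigma2 = DEFAULT_SIGMA2
    normalization = "raw"
    grid, intens = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "sigma2":
                sigma2 = float(val)
            elif key.strip() == "normalization":
                normalization = val.strip()
        elif line and not line.startswith("energy_ev"):
            e, i = line.split("\t")
            grid.append(float(e))
            intens.append(float(i))
    return Spectrum(np.array(grid), np.array(intens), sigma2, normalization)
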