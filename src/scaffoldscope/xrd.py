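"""Bragg-law d-spacings and diffractogram peak analysis.

Wide-angle X-ray diffractograms of semicrystalline polysaccharide films show
broad maxima from "pseudocrystalline" ordered regions.  Each maximum at
scattering angle 2θ corresponds, through Bragg's law nλ = 2d·sinθ, to an
interplanar spacing d of the ordered regions.  This module converts between
2θ and d, detects diffractogram peaks, and quantifies the visual "reverse
similarity" between a film's spatial periodicity spectrum and its
diffractogram by correlating the two curves on normalized log-length axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .spectral import SpatialSpectrum

__all__ = [
    "CU_KALPHA1_A",
    "Diffractogram",
    "XrdPeak",
    "bragg_d",
    "two_theta_from_d",
    "find_xrd_peaks",
    "spectrum_similarity",
    "read_xy",
    "write_xy",
]

#: Cu Kα₁ wavelength in ångströms (default anode line).
CU_KALPHA1_A = 1.5406


@dataclass(frozen=True)
class Diffractogram:
    """Powder diffractogram: intensity vs scattering angle 2θ (degrees)."""

    two_theta_deg: np.ndarray
    intensity: np.ndarray
    wavelength_A: float = CU_KALPHA1_A

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta_deg, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if tt.shape != it.shape or tt.ndim != 1:
            raise ValueError("two_theta and intensity must be 1D of equal length")
        if tt.size and (tt.min() <= 0 or tt.max() >= 180):
            raise ValueError("2θ must lie in (0, 180) degrees")
        if tt.size > 1 and np.any(np.diff(tt) <= 0):
            raise ValueError("2θ must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensity must be non-negative")
        if self.wavelength_A <= 0:
            raise ValueError("wavelength must be positive")
        object.__setattr__(self, "two_theta_deg", tt)
        object.__setattr__(self, "intensity", it)


@dataclass(frozen=True)
class XrdPeak:
    two_theta_deg: float
    d_A: float
    intensity: float
    prominence: float


def bragg_d(two_theta_deg, wavelength_A: float = CU_KALPHA1_A, order: int = 1):
    """Interplanar spacing d = n·λ / (2·sin θ) in Å, with 2θ in degrees."""
    tt = np.asarray(two_theta_deg, dtype=float)
    if np.any(tt <= 0) or np.any(tt >= 180):
        raise ValueError("2θ must lie in (0, 180) degrees")
    if order < 1:
        raise ValueError("diffraction order must be ≥ 1")
    s = np.sin(np.deg2rad(tt) / 2.0)
    d = order * wavelength_A / (2.0 * s)
    return float(d) if np.ndim(two_theta_deg) == 0 else d


def two_theta_from_d(d_A, wavelength_A: float = CU_KALPHA1_A, order: int = 1):
    """Inverse Bragg mapping; errors when order·λ/(2d) exceeds 1."""
    d = np.asarray(d_A, dtype=float)
    arg = order * wavelength_A / (2.0 * d)
    if np.any(arg > 1):
        raise ValueError(
            f"no diffraction angle exists: order·λ/(2d) = {np.max(arg):g} > 1"
        )
    tt = 2.0 * np.rad2deg(np.arcsin(arg))
    return float(tt) if np.ndim(d_A) == 0 else tt


def _refine_parabolic(x: np.ndarray, y: np.ndarray, i: int) -> float:
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return x[i]
    h = 0.5 * (x[i + 1] - x[i - 1])
    return x[i] + np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0) * h


def find_xrd_peaks(dg: Diffractogram, prominence_frac: float = 0.1) -> list[XrdPeak]:
    """Diffractogram maxima with prominence ≥ frac of the intensity range.

    Peak angles are refined parabolically on the 2θ grid and annotated with
    their Bragg d-spacing.  Sorted by 2θ; an empty list is valid (flat or
    featureless trace).
    """
    if dg.two_theta_deg.size < 3:
        raise ValueError("diffractogram must have at least 3 points")
    span = dg.intensity.max() - dg.intensity.min()
    if span <= 0:
        return []
    idx, props = _scipy_find_peaks(dg.intensity, prominence=prominence_frac * span)
    peaks = []
    for j, prom in zip(idx, props["prominences"]):
        tt = float(_refine_parabolic(dg.two_theta_deg, dg.intensity, j))
        peaks.append(
            XrdPeak(tt, bragg_d(tt, dg.wavelength_A), float(dg.intensity[j]), float(prom))
        )
    return peaks


def spectrum_similarity(
    spec: SpatialSpectrum, dg: Diffractogram, n_points: int = 64
) -> float:
    """Pearson correlation of a spatial spectrum with a diffractogram.

    Both curves live on length-scale axes: the spectrum on spatial period
    (µm), the diffractogram on Bragg d-spacing (Å).  Since the two length
    ranges differ by four orders of magnitude, each log axis is affinely
    mapped to [0, 1] and both curves are resampled on a shared grid of
    ``n_points`` and z-scored before correlating.  Mirror-image peak layouts
    ("reverse" similarity) give values near −1.
    """
    periods = spec.periods_um
    power = spec.power
    finite = np.isfinite(power)
    if finite.sum() < 3 or dg.two_theta_deg.size < 3:
        raise ValueError("both curves need at least 3 usable points")
    periods, power = periods[finite], power[finite]
    if periods[0] > periods[-1]:
        periods, power = periods[::-1], power[::-1]

    d = bragg_d(dg.two_theta_deg, dg.wavelength_A)  # decreasing in 2θ
    d, inten = d[::-1], dg.intensity[::-1]

    def _normalized(xlog: np.ndarray) -> np.ndarray:
        span = xlog[-1] - xlog[0]
        if span <= 0:
            raise ValueError("degenerate length axis: zero log-span")
        return (xlog - xlog[0]) / span

    u = np.linspace(0.0, 1.0, n_points)
    a = np.interp(u, _normalized(np.log(periods)), power)
    b = np.interp(u, _normalized(np.log(d)), inten)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant curve: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def read_xy(path: str | Path, wavelength_A: float = CU_KALPHA1_A) -> Diffractogram:
    """Read a two-column whitespace- or comma-delimited XY diffractogram.

    Lines starting with ``#`` (the common .xy dialect) are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return Diffractogram(arr[:, 0], arr[:, 1], wavelength_A)


def write_xy(dg: Diffractogram, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([dg.two_theta_deg, dg.intensity]),
        fmt="%.6g",
        header=f"two_theta_deg intensity (wavelength_A={dg.wavelength_A})",
    )
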