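"""Integral spatial spectrum, peak detection, and multiscale ridge analysis.

Averaging the waveletgram modulus along the position axis gives the
*integral spatial spectrum* — power versus spatial period — whose pronounced
maxima identify the dominant periodicities of the section (e.g. banding at
10, 80 and 420 µm in a degrading film).  Ridge analysis then asks whether
those periodicities are *linked across scales*: chains of coefficient maxima
that stay in one narrow scale band ("grass" structures) indicate independent
periodicities, while chains spanning several octaves ("tree" structures)
indicate a cascade in which the scales are genetically related.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .mhat_cwt import Waveletgram

__all__ = [
    "SpatialSpectrum",
    "SpectrumPeak",
    "Ridge",
    "RidgeSet",
    "integral_spectrum",
    "find_peaks",
    "extract_ridges",
    "classify_structures",
]


@dataclass(frozen=True)
class SpatialSpectrum:
    """Power vs spatial period; NaN power marks scales fully outside the COI."""

    periods_um: np.ndarray
    power: np.ndarray
    stat: str

    def __post_init__(self) -> None:
        p = np.asarray(self.periods_um, dtype=float)
        w = np.asarray(self.power, dtype=float)
        if p.shape != w.shape or p.ndim != 1:
            raise ValueError("periods and power must be 1D of equal length")
        if np.any(w[np.isfinite(w)] < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "periods_um", p)
        object.__setattr__(self, "power", w)


@dataclass(frozen=True)
class SpectrumPeak:
    period_um: float
    power: float
    prominence: float


@dataclass(frozen=True)
class Ridge:
    """A chain of linked coefficient maxima across adjacent scales."""

    periods_um: np.ndarray
    positions_um: np.ndarray
    coeffs: np.ndarray
    label: str | None = None

    @property
    def span_octaves(self) -> float:
        return float(np.log2(self.periods_um.max() / self.periods_um.min()))


@dataclass(frozen=True)
class RidgeSet:
    ridges: tuple[Ridge, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.ridges)

    def with_label(self, label: str) -> tuple[Ridge, ...]:
        return tuple(r for r in self.ridges if r.label == label)


def integral_spectrum(
    wg: Waveletgram, stat: str = "mean_abs", use_coi: bool = True
) -> SpatialSpectrum:
    """Average the waveletgram along the position axis.

    ``stat="mean_abs"`` averages |coefficients| (the default: signed means
    cancel the oscillations and the spectrum should be everywhere positive);
    ``"mean_square"`` averages the squared coefficients.  With ``use_coi``
    only in-cone positions contribute; a scale with no in-cone position gets
    NaN power (flagged missing, not zero).
    """
    if stat not in ("mean_abs", "mean_square"):
        raise ValueError(f"stat must be 'mean_abs' or 'mean_square', got {stat!r}")
    vals = np.abs(wg.coeffs) if stat == "mean_abs" else wg.coeffs**2
    if use_coi:
        counts = wg.coi_mask.sum(axis=1)
        sums = np.where(wg.coi_mask, vals, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            power = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        power = vals.mean(axis=1)
    return SpatialSpectrum(wg.periods_um, power, stat)


def _refine_log_parabolic(logp: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (logp, y) at i−1, i, i+1."""
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not concave; keep the grid point
        return logp[i]
    # uniform log spacing assumed locally
    h = 0.5 * (logp[i + 1] - logp[i - 1])
    delta = 0.5 * (y0 - y2) / denom
    return logp[i] + np.clip(delta, -1.0, 1.0) * h


def find_peaks(spec: SpatialSpectrum, prominence_frac: float = 0.2) -> list[SpectrumPeak]:
    """Pronounced maxima of the spectrum.

    A peak is a strict local maximum (endpoints excluded) with topographic
    prominence at least ``prominence_frac`` of the global maximum power.
    Peak periods are refined by parabolic interpolation on the log-period
    axis; the list is sorted by period.
    """
    if not 0 < prominence_frac <= 1:
        raise ValueError("prominence_frac must be in (0, 1]")
    periods = spec.periods_um
    power = spec.power
    if periods.size < 3:
        raise ValueError("spectrum must have at least 3 points")
    if periods[0] > periods[-1]:  # normalize to increasing period
        periods, power = periods[::-1], power[::-1]
    finite = np.isfinite(power)
    if not finite.any() or np.nanmax(power) <= 0:
        return []
    threshold = prominence_frac * np.nanmax(power)

    logp = np.log(periods)
    peaks: list[SpectrumPeak] = []
    # peak-find each contiguous finite run so NaN scales never fake maxima
    for run in np.split(np.flatnonzero(finite), np.where(np.diff(np.flatnonzero(finite)) > 1)[0] + 1):
        if run.size < 3:
            continue
        seg = power[run]
        idx, props = _scipy_find_peaks(seg, prominence=threshold)
        for j, prom in zip(idx, props["prominences"]):
            i = run[j]
            if i == 0 or i == periods.size - 1:
                continue
            period = float(np.exp(_refine_log_parabolic(logp, power, i)))
            peaks.append(SpectrumPeak(period, float(power[i]), float(prom)))
    peaks.sort(key=lambda p: p.period_um)
    return peaks


def extract_ridges(
    wg: Waveletgram,
    max_drift_frac: float = 0.5,
    power_floor_frac: float = 0.15,
    use_coi: bool = True,
) -> RidgeSet:
    """Link per-scale coefficient maxima into cross-scale ridge chains.

    At each scale the strict local maxima (along position) of the *signed*
    coefficients are kept when they exceed ``power_floor_frac`` of the global
    maximum coefficient — positive maxima mark the bright bands, one per
    oscillation, so a pure tone of period λ yields ≈ length/λ ridges.
    Scanning scales from small to large period, a maximum is appended to an
    existing chain when its position drifts by at most
    ``max_drift_frac × period`` from the chain's current head (one-to-one,
    nearest first); otherwise it seeds a new chain.  Linking is
    deterministic given the waveletgram and parameters.
    """
    order = np.argsort(wg.periods_um)
    periods = wg.periods_um[order]
    coeffs = wg.coeffs[order]
    coi = wg.coi_mask[order]
    positions = wg.positions_um

    global_max = coeffs.max(initial=0.0)
    if global_max <= 0:
        return RidgeSet()
    floor = power_floor_frac * global_max

    # chains under construction: lists of (scale_idx, pos_idx)
    active: list[list[tuple[int, int]]] = []
    done: list[list[tuple[int, int]]] = []

    for i, period in enumerate(periods):
        row = coeffs[i]
        interior = (row[1:-1] > row[:-2]) & (row[1:-1] > row[2:]) & (row[1:-1] >= floor)
        cand = np.flatnonzero(interior) + 1
        if use_coi:
            cand = cand[coi[i][cand]]

        tol = max_drift_frac * period
        # greedy nearest-first one-to-one matching to chain heads
        pairs = []
        for ci, chain in enumerate(active):
            head_pos = positions[chain[-1][1]]
            for mj, j in enumerate(cand):
                d = abs(positions[j] - head_pos)
                if d <= tol:
                    pairs.append((d, ci, mj))
        pairs.sort(key=lambda t: t[0])
        used_chain: set[int] = set()
        used_max: set[int] = set()
        for d, ci, mj in pairs:
            if ci in used_chain or mj in used_max:
                continue
            active[ci].append((i, int(cand[mj])))
            used_chain.add(ci)
            used_max.add(mj)
        # close chains that found no continuation; start chains for new maxima
        still_active = []
        for ci, chain in enumerate(active):
            (still_active if ci in used_chain else done).append(chain)
        for mj, j in enumerate(cand):
            if mj not in used_max:
                still_active.append([(i, int(j))])
        active = still_active
    done.extend(active)

    ridges = tuple(
        Ridge(
            periods_um=np.array([periods[i] for i, _ in chain]),
            positions_um=np.array([positions[j] for _, j in chain]),
            coeffs=np.array([coeffs[i, j] for i, j in chain]),
        )
        for chain in done
        if chain
    )
    return RidgeSet(ridges)


def classify_structures(ridges: RidgeSet, tree_span_octaves: float = 3.5) -> RidgeSet:
    """Label each ridge "tree" or "grass" by its period span in octaves.

    A chain confined to one scale band is "grass" (an isolated periodicity);
    a chain spanning at least ``tree_span_octaves`` octaves is "tree"
    (cascade-linked scales).  The default threshold sits above the ≈3-octave
    band that a single pure tone's ridge occupies at a 10% coefficient floor
    — the Mexican hat's intrinsic scale bandwidth — so only genuinely linked
    multi-band chains qualify.
    """
    labelled = tuple(
        replace(r, label="tree" if r.span_octaves >= tree_span_octaves else "grass")
        for r in ridges.ridges
    )
    return RidgeSet(labelled)
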