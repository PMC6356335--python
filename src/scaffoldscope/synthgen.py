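"""Synthetic inputs with known ground truth for the whole pipeline.

No deposited images, diffractograms or NMR spectra accompany the analyses
this package implements, so every input is emulated here with its ground
truth recorded:

* stained-section profiles/images with periodic transverse striping at
  several linked scales plus Gaussian noise (the wavelet stage's input);
* porous-surface images built from non-overlapping disks with a controlled
  area fraction and diameter distribution (the morphometry input);
* diffractograms as Gaussian peak mixtures over a polynomial amorphous
  background (the XRD input);
* ¹H NMR integral sets generated forward from unit fractions, the exact
  inverse of :func:`scaffoldscope.chem_tables.compute_ds`.

All randomness flows through explicit integer seeds; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_tables import IntegralSet
from .profiles import IntensityProfile
from .xrd import Diffractogram

__all__ = [
    "NyquistError",
    "PorePackingError",
    "StripeComponent",
    "StripeSpec",
    "PoreImageSpec",
    "XrdSpec",
    "GroundTruth",
    "make_stripe_profile",
    "make_stripe_image",
    "make_pore_image",
    "pore_mask_from_truth",
    "make_diffractogram",
    "make_nmr_integrals",
    "histology_stripe_spec",
    "cascade_stripe_spec",
    "film_xrd_spec",
    "scaffold_pore_spec",
]


class NyquistError(ValueError):
    """A planted period is below twice the sampling interval."""


class PorePackingError(RuntimeError):
    """Target pore fraction unreachable by rejection placement."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"could not reach pore fraction {target:g}; achieved {achieved:.4f}"
        )


@dataclass(frozen=True)
class StripeComponent:
    period_um: float
    amplitude: float = 1.0
    phase_rad: float = 0.0


@dataclass(frozen=True)
class StripeSpec:
    """Recipe for a striped section-like profile.

    With ``cascade`` set, every shorter-period component is amplitude-
    modulated by the longest-period component — carrier × (1 + m·envelope)
    with modulation depth ``m`` — emulating a cascade in which the banding
    scales are genetically related rather than independent.
    """

    length_um: float
    sampling_um: float
    components: tuple[StripeComponent, ...]
    cascade: bool = False
    modulation_depth: float = 0.8
    noise_sigma: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, StripeComponent) else StripeComponent(*c)
            for c in self.components
        )
        object.__setattr__(self, "components", comps)
        if self.length_um <= 0 or self.sampling_um <= 0:
            raise ValueError("length_um and sampling_um must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for c in comps:
            if c.period_um <= 0 or c.amplitude < 0:
                raise ValueError("periods must be positive, amplitudes non-negative")
            if c.period_um < 2.0 * self.sampling_um:
                raise NyquistError(
                    f"period {c.period_um:g} µm below Nyquist bound "
                    f"2·sampling = {2 * self.sampling_um:g} µm"
                )
        if comps and self.length_um < 2.0 * max(c.period_um for c in comps):
            raise ValueError("length_um must be at least twice the longest period")

    @property
    def n_samples(self) -> int:
        return round(self.length_um / self.sampling_um)


@dataclass(frozen=True)
class PoreImageSpec:
    """Recipe for a porous-surface image of non-overlapping dark disks."""

    width_px: int = 384
    height_px: int = 384
    pixel_um: float = 0.5
    target_pore_fraction: float = 0.30
    diameter_mean_um: float = 4.5
    diameter_sd_um: float = 1.5
    allow_overlap: bool = False
    background_value: float = 200.0
    pore_value: float = 30.0
    blur_sigma_px: float = 0.0

    def __post_init__(self) -> None:
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("image must be at least 8×8 px")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if not 0 <= self.target_pore_fraction < 1:
            raise ValueError("target_pore_fraction must be in [0, 1)")
        if self.diameter_mean_um <= 0 or self.diameter_sd_um < 0:
            raise ValueError("diameter distribution must be positive")


@dataclass(frozen=True)
class XrdSpec:
    """Recipe for a diffractogram: Gaussian peaks + polynomial background.

    ``peaks`` entries are (center 2θ deg, height, FWHM deg); ``background``
    holds polynomial coefficients, highest degree first (numpy order).
    """

    peaks: tuple[tuple[float, float, float], ...]
    background: tuple[float, ...] = (0.0,)
    range_deg: tuple[float, float] = (5.0, 40.0)
    step_deg: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.range_deg
        if not lo < hi:
            raise ValueError("range_deg must satisfy lo < hi")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        for c, h, w in self.peaks:
            if not lo < c < hi:
                raise ValueError(f"peak center {c:g}° outside range [{lo}, {hi}]")
            if h < 0 or w <= 0:
                raise ValueError("peak heights must be ≥ 0 and FWHMs > 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, JSON-round-trippable.

    Field groups are optional: stripe profiles fill ``periods_um`` (and
    friends), pore images fill ``pores``/``achieved_fraction``,
    diffractograms ``peak_centers_deg``, NMR sets ``unit_fractions``.
    """

    periods_um: tuple[float, ...] | None = None
    amplitudes: tuple[float, ...] | None = None
    cascade: bool | None = None
    baseline: float | None = None
    pores: tuple[dict, ...] | None = None
    achieved_fraction: float | None = None
    pixel_um: float | None = None
    peak_centers_deg: tuple[float, ...] | None = None
    unit_fractions: dict | None = None
    seed: int | None = None

    def to_json(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, list):
                v = tuple(dict(e) if isinstance(e, dict) else e for e in v)
            kwargs[f.name] = v
        return cls(**kwargs)


def _stripe_values(spec: StripeSpec) -> np.ndarray:
    """Noiseless stripe signal on the spec's sample grid."""
    x = np.arange(spec.n_samples) * spec.sampling_um
    signal = np.full(x.size, float(spec.baseline))
    if not spec.components:
        return signal
    longest = max(spec.components, key=lambda c: c.period_um)
    envelope = np.cos(2.0 * np.pi * x / longest.period_um + longest.phase_rad)
    for c in spec.components:
        carrier = c.amplitude * np.cos(2.0 * np.pi * x / c.period_um + c.phase_rad)
        if spec.cascade and c.period_um < longest.period_um:
            carrier = carrier * (1.0 + spec.modulation_depth * envelope)
        signal += carrier
    return signal


def _stripe_truth(spec: StripeSpec, seed: int) -> GroundTruth:
    return GroundTruth(
        periods_um=tuple(c.period_um for c in spec.components),
        amplitudes=tuple(c.amplitude for c in spec.components),
        cascade=spec.cascade,
        baseline=spec.baseline,
        seed=seed,
    )


def make_stripe_profile(spec: StripeSpec, seed: int) -> tuple[IntensityProfile, GroundTruth]:
    """Striped 1D intensity profile plus the planted periods."""
    rng = np.random.default_rng(seed)
    values = _stripe_values(spec)
    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, values.size)
    positions = np.arange(spec.n_samples) * spec.sampling_um
    profile = IntensityProfile(positions, values, spec.sampling_um, "along")
    return profile, _stripe_truth(spec, seed)


def make_stripe_image(
    spec: StripeSpec, height_px: int, seed: int
) -> tuple[np.ndarray, float, GroundTruth]:
    """2D striped image: each row is the noiseless stripe signal plus
    independent per-pixel noise.  Returns (image, µm-per-pixel, truth);
    column means recover the profile to within noise/sqrt(height)."""
    if height_px < 1:
        raise ValueError("height_px must be ≥ 1")
    rng = np.random.default_rng(seed)
    base = _stripe_values(spec)
    image = np.tile(base, (height_px, 1))
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    return image, spec.sampling_um, _stripe_truth(spec, seed)


def _paint_disk(mask: np.ndarray, r0: float, c0: float, radius_px: float) -> None:
    h, w = mask.shape
    rlo = max(int(np.floor(r0 - radius_px)), 0)
    rhi = min(int(np.ceil(r0 + radius_px)) + 1, h)
    clo = max(int(np.floor(c0 - radius_px)), 0)
    chi = min(int(np.ceil(c0 + radius_px)) + 1, w)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    mask[rlo:rhi, clo:chi] |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2


def pore_mask_from_truth(truth: GroundTruth, width_px: int, height_px: int) -> np.ndarray:
    """Re-rasterize the exact pore mask from a pore GroundTruth."""
    if truth.pores is None or truth.pixel_um is None:
        raise ValueError("ground truth carries no pore records")
    mask = np.zeros((height_px, width_px), dtype=bool)
    for p in truth.pores:
        r0, c0 = p["center_px"]
        _paint_disk(mask, r0, c0, (p["diameter_um"] / 2.0) / truth.pixel_um)
    return mask


def make_pore_image(
    spec: PoreImageSpec,
    seed: int,
    position_attempts: int = 200,
    max_failed_disks: int = 50,
) -> tuple[np.ndarray, GroundTruth]:
    """Porous-surface image by rejection placement of disks.

    Disk diameters are drawn from a normal distribution truncated at
    2·pixel_um.  Each drawn disk keeps its diameter and tries up to
    ``position_attempts`` uniform positions (redrawing the diameter after a
    failed placement would bias the accepted disks small, since large disks
    collide more often).  With overlap disallowed (default) a position is
    accepted only when at least 1.5 px of matrix separates the disk from
    every earlier one, so 8-connected components map one-to-one onto planted
    disks and ground-truth diameters stay exact.  Placement stops when the
    mask fraction reaches the target; after ``max_failed_disks`` consecutive
    unplaceable disks a :class:`PorePackingError` reports the achieved
    fraction.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float, float]] = []  # r, c, radius_px, diam_um
    total_px = h * w
    min_diam = 2.0 * spec.pixel_um

    failed_disks = 0
    while mask.sum() / total_px < spec.target_pore_fraction:
        diam = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um)
        if diam <= min_diam:
            continue  # truncated distribution: redraw
        radius_px = (diam / 2.0) / spec.pixel_um
        if 2 * radius_px + 2 > min(h, w):
            continue
        for _ in range(position_attempts):
            r0 = rng.uniform(radius_px, h - 1 - radius_px)
            c0 = rng.uniform(radius_px, w - 1 - radius_px)
            if spec.allow_overlap or all(
                np.hypot(r0 - r, c0 - c) >= radius_px + rad + 1.5
                for r, c, rad, _ in placed
            ):
                _paint_disk(mask, r0, c0, radius_px)
                placed.append((r0, c0, radius_px, diam))
                failed_disks = 0
                break
        else:
            failed_disks += 1
            if failed_disks >= max_failed_disks:
                raise PorePackingError(spec.target_pore_fraction, mask.sum() / total_px)

    truth = GroundTruth(
        pores=tuple(
            {"center_px": [r, c], "diameter_um": d} for r, c, _, d in placed
        ),
        achieved_fraction=float(mask.mean()),
        pixel_um=spec.pixel_um,
        seed=seed,
    )
    image = np.where(mask, spec.pore_value, spec.background_value).astype(float)
    if spec.blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, spec.blur_sigma_px)
    return image, truth


def make_diffractogram(spec: XrdSpec, wavelength_A: float = 1.5406) -> tuple[Diffractogram, GroundTruth]:
    """Noiseless diffractogram: polynomial background + Gaussian peaks."""
    lo, hi = spec.range_deg
    tt = np.arange(lo, hi + spec.step_deg / 2.0, spec.step_deg)
    intensity = np.polyval(spec.background, tt)
    for center, height, fwhm in spec.peaks:
        sigma2 = fwhm**2 / (8.0 * np.log(2.0))
        intensity = intensity + height * np.exp(-((tt - center) ** 2) / (2.0 * sigma2))
    if np.any(intensity < 0):
        raise ValueError("background drives intensity negative; adjust coefficients")
    truth = GroundTruth(peak_centers_deg=tuple(c for c, _, _ in spec.peaks))
    return Diffractogram(tt, intensity, wavelength_A), truth


def make_nmr_integrals(
    x_n: float, x_o: float, da: float, scale: float = 1.0
) -> tuple[IntegralSet, GroundTruth]:
    """Forward NMR model from unit fractions.

    ``x_n``/``x_o`` are the fractions of units carrying N-/O-allyl groups,
    ``da`` the acetylated fraction.  Per 1 unit of polymer the integrals are
    I_H2 = 1·(1 − da − x_n), I_acetyl = 3·da, I_Nvinyl = 2·x_n,
    I_Ovinyl = 2·x_o (proton counts 1H/3H/2H/2H); any common positive scale
    leaves the inferred DS unchanged.
    """
    for name, v in (("x_n", x_n), ("x_o", x_o), ("da", da)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if x_n + da > 1:
        raise ValueError("x_n + da must not exceed 1 (unit fractions overlap)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    integrals = IntegralSet(
        i_h2=scale * (1.0 - da - x_n),
        i_acetyl=scale * 3.0 * da,
        i_n_vinyl=scale * 2.0 * x_n,
        i_o_vinyl=scale * 2.0 * x_o,
    )
    truth = GroundTruth(unit_fractions={"x_n": x_n, "x_o": x_o, "da": da})
    return integrals, truth


# ---------------------------------------------------------------------------
# Canonical study-condition specs

def histology_stripe_spec(
    noise_sigma: float = 0.2, length_um: float = 3000.0, sampling_um: float = 2.0
) -> StripeSpec:
    """Section-like profile with banding at 10, 80 and 420 µm.

    Equal unit amplitudes on a baseline of 120 intensity units with additive
    Gaussian noise; the three planted periods are the periodicities the
    integral spatial spectrum should recover as pronounced maxima.
    """
    return StripeSpec(
        length_um=length_um,
        sampling_um=sampling_um,
        components=(
            StripeComponent(10.0, 1.0, 0.0),
            StripeComponent(80.0, 1.0, 1.0),
            StripeComponent(420.0, 1.0, 2.0),
        ),
        noise_sigma=noise_sigma,
        baseline=120.0,
    )


def cascade_stripe_spec(length_um: float = 1600.0, sampling_um: float = 1.0) -> StripeSpec:
    """10 µm carrier amplitude-modulated by an 80 µm envelope (cascade on)."""
    return StripeSpec(
        length_um=length_um,
        sampling_um=sampling_um,
        components=(StripeComponent(80.0, 1.0, 0.0), StripeComponent(10.0, 1.0, 0.0)),
        cascade=True,
        noise_sigma=0.0,
        baseline=0.0,
    )


def film_xrd_spec() -> XrdSpec:
    """Diffractogram recipe for a semicrystalline film: broad maxima near
    2θ = 10°, 15° (weak) and 20° over a gently sloping amorphous background."""
    return XrdSpec(
        peaks=((10.0, 60.0, 2.5), (15.0, 25.0, 1.5), (20.0, 100.0, 3.5)),
        background=(-0.1, 8.0),
        range_deg=(5.0, 40.0),
        step_deg=0.05,
    )


def scaffold_pore_spec() -> PoreImageSpec:
    """Porous surface at 30% target pore fraction, diameters ≈ N(4.5, 1.5) µm
    (≈⅔ of pores in the 3–6 µm bin), 0.5 µm pixels."""
    return PoreImageSpec()
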