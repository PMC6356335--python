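"""Averaged-intensity profiles from stained section images.

A histological section of a biopolymer film is reduced to two calibrated
one-dimensional signals: the pixel intensities averaged along and across the
visible film surface.  These profiles are what the wavelet stage consumes;
everything downstream (waveletgram, spatial spectrum, ridge analysis) works
on an :class:`IntensityProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "IntensityProfile",
    "to_gray",
    "extract_profile",
    "detrend",
    "read_image",
    "read_profile_csv",
    "write_profile_csv",
]

#: Rec. 709 luma weights used for the "luminance" channel mode.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

_MIN_SAMPLES = 16


@dataclass(frozen=True)
class IntensityProfile:
    """Calibrated 1D sequence of averaged pixel intensities vs position.

    Parameters
    ----------
    positions_um
        Strictly increasing, uniformly spaced positions in micrometres,
        starting at 0 (pixel centres).
    values
        Intensity at each position, arbitrary units.
    sampling_um
        Spacing of the position grid (µm per sample).
    axis_label
        ``"along"`` or ``"across"`` the film surface.
    """

    positions_um: np.ndarray
    values: np.ndarray
    sampling_um: float
    axis_label: str = "along"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ValueError("positions and values must be 1D of equal length")
        if pos.size < _MIN_SAMPLES:
            raise ValueError(
                f"profile needs at least {_MIN_SAMPLES} samples, got {pos.size}"
            )
        if self.sampling_um <= 0:
            raise ValueError("sampling_um must be positive")
        steps = np.diff(pos)
        if steps.min() <= 0:
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, self.sampling_um, rtol=1e-9, atol=0.0):
            raise ValueError("positions must be uniform at sampling_um spacing")
        if self.axis_label not in ("along", "across"):
            raise ValueError(f"unknown axis_label {self.axis_label!r}")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "values", val)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def length_um(self) -> float:
        """Physical extent covered by the profile (n · sampling)."""
        return self.n * self.sampling_um


def to_gray(image: np.ndarray, mode: str = "luminance") -> np.ndarray:
    """Collapse an RGB(A) image to one channel.

    ``"luminance"`` is the Rec. 709 weighted sum; ``"red"``/``"green"``/
    ``"blue"`` select a single channel (useful when stain contrast lives in
    one channel, e.g. picrosirius red in the red channel).  A 2D input is
    returned unchanged for any mode.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ValueError(f"expected HxW or HxWx3/4 image, got shape {img.shape}")
    rgb = img[:, :, :3]
    if mode == "luminance":
        return rgb @ _LUMA_WEIGHTS
    channels = {"red": 0, "green": 1, "blue": 2}
    if mode not in channels:
        raise ValueError(f"unknown channel mode {mode!r}")
    return rgb[:, :, channels[mode]]


def extract_profile(
    gray: np.ndarray,
    pixel_um: float,
    axis: str = "along",
    orientation: str = "auto",
) -> IntensityProfile:
    """Average a grayscale image into a 1D calibrated profile.

    The film's long axis is taken to be the longer image dimension
    (``orientation="auto"``); ``"along"`` then profiles that direction by
    averaging perpendicular to it.  ``orientation="horizontal"`` forces the
    film to run left-right (so ``"along"`` = column means vs x), and
    ``"vertical"`` the converse.  Positions are pixel-centre based, 0-based,
    in µm.
    """
    img = np.asarray(gray, dtype=float)
    if img.ndim != 2:
        raise ValueError("extract_profile expects a 2D grayscale image")
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    if axis not in ("along", "across"):
        raise ValueError(f"axis must be 'along' or 'across', got {axis!r}")
    if orientation == "auto":
        film_horizontal = img.shape[1] >= img.shape[0]
    elif orientation in ("horizontal", "vertical"):
        film_horizontal = orientation == "horizontal"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    profile_columns = film_horizontal == (axis == "along")
    values = img.mean(axis=0) if profile_columns else img.mean(axis=1)
    if values.size < _MIN_SAMPLES:
        raise ValueError(
            f"image too small: {values.size} px in the profiled direction "
            f"(need ≥ {_MIN_SAMPLES})"
        )
    positions = np.arange(values.size) * pixel_um
    return IntensityProfile(positions, values, pixel_um, axis)


def detrend(profile: IntensityProfile, method: str = "linear") -> IntensityProfile:
    """Remove a constant ("mean") or least-squares line ("linear").

    The Mexican-hat transform is blind to constants but a strong linear
    trend leaks into the largest scales, so "linear" is the default for
    section profiles.
    """
    if method == "none":
        return profile
    if method == "mean":
        return replace(profile, values=profile.values - profile.values.mean())
    if method == "linear":
        coef = np.polyfit(profile.positions_um, profile.values, 1)
        trend = np.polyval(coef, profile.positions_um)
        return replace(profile, values=profile.values - trend)
    raise ValueError(f"unknown detrend method {method!r}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image into a float array (HxW or HxWxC)."""
    with Image.open(path) as im:
        return np.asarray(im, dtype=float)


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    arr = np.column_stack([profile.positions_um, profile.values])
    header = f"position_um,intensity  # axis={profile.axis_label}"
    np.savetxt(path, arr, delimiter=",", header=header, comments="# ")


def read_profile_csv(path: str | Path, axis_label: str = "along") -> IntensityProfile:
    arr = np.loadtxt(path, delimiter=",", comments="#")
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two-column CSV (position_um,intensity)")
    pos, val = arr[:, 0], arr[:, 1]
    sampling = float(np.median(np.diff(pos)))
    return IntensityProfile(pos, val, sampling, axis_label)
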