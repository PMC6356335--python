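"""Pore segmentation and morphometry for SEM-like scaffold surface images.

Freeze-dried / photo-crosslinked polysaccharide scaffolds carry a porous
surface; the quantities of interest are the fraction of the surface occupied
by pores and the distribution of pore sizes (equivalent-circle diameters).
Pores are segmented by thresholding (dark-pores convention), labelled as
8-connected components, and summarised into a per-pore table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = ["PoreTable", "segment_pores", "pore_stats", "size_fraction"]


@dataclass(frozen=True)
class PoreTable:
    """Per-pore records plus the image-level pore area fraction.

    ``pores`` columns: id, area_um2, equivalent_diameter_um, centroid_row_um,
    centroid_col_um.  ``pore_area_fraction`` is the masked-pixel fraction of
    the whole image, computed before any minimum-size filtering.
    """

    pores: pd.DataFrame
    pore_area_fraction: float
    pixel_um: float

    @property
    def n_pores(self) -> int:
        return len(self.pores)


def segment_pores(
    gray: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    pores_are_dark: bool = True,
) -> np.ndarray:
    """Threshold a grayscale image into a boolean pore mask.

    Pores are the below-threshold (dark) class by default; set
    ``pores_are_dark=False`` for bright pores on a dark matrix.  ``"fixed"``
    uses the supplied threshold, ``"otsu"`` picks it from the histogram
    (which requires a non-constant image).
    """
    img = np.asarray(gray, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_pores expects a 2D grayscale image")
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("Otsu thresholding undefined on a constant image")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return img < thr if pores_are_dark else img > thr


def pore_stats(mask: np.ndarray, pixel_um: float, min_area_px: int = 4) -> PoreTable:
    """Label 8-connected pores and tabulate per-pore geometry.

    Components smaller than ``min_area_px`` pixels are treated as noise and
    dropped from the table; the image-level area fraction is computed from
    the raw mask first, so tiny specks still count toward porosity.
    Equivalent diameter is 2·sqrt(area/π).
    """
    m = np.asarray(mask, dtype=bool)
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    fraction = float(m.mean()) if m.size else 0.0
    labels = label(m, connectivity=2)
    rows = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        area_um2 = region.area * pixel_um**2
        rows.append(
            {
                "id": region.label,
                "area_um2": area_um2,
                "equivalent_diameter_um": 2.0 * np.sqrt(area_um2 / np.pi),
                "centroid_row_um": region.centroid[0] * pixel_um,
                "centroid_col_um": region.centroid[1] * pixel_um,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "area_um2", "equivalent_diameter_um", "centroid_row_um", "centroid_col_um"],
    )
    return PoreTable(df, fraction, pixel_um)


def size_fraction(table: PoreTable, lo_um: float, hi_um: float) -> float:
    """Fraction of pores with equivalent diameter in the half-open bin [lo, hi)."""
    if not lo_um < hi_um:
        raise ValueError("size bin requires lo < hi")
    if table.n_pores == 0:
        raise ValueError("size fraction undefined for an empty pore table")
    d = table.pores["equivalent_diameter_um"].to_numpy()
    return float(np.mean((d >= lo_um) & (d < hi_um)))
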