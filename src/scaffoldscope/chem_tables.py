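"""Scalar chemistry analyses on tabulated data.

Two small but load-bearing computations live here:

* the degree of substitution (DS) of allyl-modified chitosan from the
  integrated intensities of four ¹H NMR signals — the ring H2 proton of
  free-amine units (3.0–3.2 ppm, 1H), the N-acetyl methyl (1.9 ppm, 3H),
  and the vinylidene protons of N- and O-allyl groups (5.3–5.5 and
  5.1–5.2 ppm, 2H each);
* elongation-at-break deltas of modified films relative to the unmodified
  chitosan reference, from a tensile-test table.

The DS model counts polymer units per proton: u = I / (protons per unit).
The unit total T = u_H2 + u_acetyl + u_N-allyl partitions the glucosamine
backbone into free-amine, N-acetylated and N-allylated units; O-allylation
is treated as an independent event on the same unit population (an O-allyl
group does not remove the H2 proton of its own unit), so DS_O = 100·u_O/T
may in principle approach 100 independently of DS_N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "IntegralSet",
    "DSResult",
    "MechRow",
    "ElongationDeltas",
    "ALLYLCHITOSAN_FILM_MECHANICS",
    "compute_ds",
    "elongation_deltas",
    "read_integrals_csv",
    "read_mech_csv",
]


@dataclass(frozen=True)
class IntegralSet:
    """Integrated ¹H NMR signal intensities on a common arbitrary scale."""

    i_h2: float        # >CH-NH2 ring proton, 3.0–3.2 ppm, 1H per unit
    i_acetyl: float    # H3C-CONH-, 1.9 ppm, 3H per unit
    i_n_vinyl: float   # H2C=CH-CH2-NH-, 5.3–5.5 ppm, 2H per group
    i_o_vinyl: float   # H2C=CH-CH2-O-, 5.1–5.2 ppm, 2H per group

    def __post_init__(self) -> None:
        vals = (self.i_h2, self.i_acetyl, self.i_n_vinyl, self.i_o_vinyl)
        if any(v < 0 for v in vals):
            raise ValueError("integrals must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("integral set must not be all zero")


@dataclass(frozen=True)
class DSResult:
    """Degrees of substitution / acetylation in mol% per 100 polymer units."""

    ds_n: float
    ds_o: float
    da: float

    @property
    def ds_total(self) -> float:
        return self.ds_n + self.ds_o


def compute_ds(integrals: IntegralSet) -> DSResult:
    """Degree of substitution from NMR integrals.

    Per-proton unit amounts u = I/protons; the unit total is
    T = u_H2 + u_acetyl + u_N (free-amine + N-acetyl + N-allyl units) and
    each mol% is 100·u/T.  The result is invariant to the common scale of
    the integrals.  DS_O is capped at 100 (multiple-O-substitution is out of
    scope) with a warning.
    """
    u_h2 = integrals.i_h2 / 1.0
    u_da = integrals.i_acetyl / 3.0
    u_n = integrals.i_n_vinyl / 2.0
    u_o = integrals.i_o_vinyl / 2.0
    total = u_h2 + u_da + u_n
    if total <= 0:
        raise ValueError("no backbone-unit signal: u_H2 + u_acetyl + u_N-allyl is zero")
    ds_o = 100.0 * u_o / total
    if ds_o > 100.0:
        warnings.warn(
            f"DS_O = {ds_o:.1f} mol% exceeds 100; capping (multiple O-substitution "
            "per unit is outside the model)",
            stacklevel=2,
        )
        ds_o = 100.0
    return DSResult(ds_n=100.0 * u_n / total, ds_o=ds_o, da=100.0 * u_da / total)


@dataclass(frozen=True)
class MechRow:
    """Tensile characteristics of one film sample, before and after UV curing.

    σ tensile strength (MPa), E Young's modulus (MPa), ε elongation at
    break (%); means only, reported uncertainties carried but unused.
    """

    sample: str
    ds_molpct: float
    sigma_mpa: float
    e_mpa: float
    eps_pct: float
    sigma_uv_mpa: float
    e_uv_mpa: float
    eps_uv_pct: float

    def __post_init__(self) -> None:
        for name in ("sigma_mpa", "e_mpa", "eps_pct", "sigma_uv_mpa", "e_uv_mpa", "eps_uv_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.sample}: {name} must be positive")


#: Bundled example dataset: tensile properties of solvent-cast chitosan and
#: allylchitosan films (AC2/AC4/AC5, DS 5/20/50 mol%) before and after UV.
ALLYLCHITOSAN_FILM_MECHANICS: tuple[MechRow, ...] = (
    MechRow("chitosan", 0, 37, 1800, 18, 39, 1900, 18),
    MechRow("AC2", 5, 37, 1800, 26, 41, 1900, 21),
    MechRow("AC4", 20, 38, 2100, 25, 38, 1800, 19),
    MechRow("AC5", 50, 33, 1900, 23, 33, 1400, 17),
)


@dataclass(frozen=True)
class ElongationDeltas:
    """Per-sample ε(before UV) deltas vs the reference, percentage points."""

    deltas: dict[str, float]
    min_delta: float
    max_delta: float


def elongation_deltas(rows: list[MechRow] | tuple[MechRow, ...], reference_id: str) -> ElongationDeltas:
    """Elongation-at-break gains of each sample over the reference film.

    Δε_i = ε_i − ε_ref (both before UV exposure), in percentage points;
    invariant to row order.  Raises if the reference sample is missing or is
    the only row.
    """
    ref = next((r for r in rows if r.sample == reference_id), None)
    if ref is None:
        raise ValueError(f"reference sample {reference_id!r} not found")
    deltas = {r.sample: r.eps_pct - ref.eps_pct for r in rows if r.sample != reference_id}
    if not deltas:
        raise ValueError("need at least one non-reference row")
    vals = list(deltas.values())
    return ElongationDeltas(deltas, min(vals), max(vals))


def read_integrals_csv(path: str | Path) -> IntegralSet:
    """CSV with columns i_h2, i_acetyl, i_n_vinyl, i_o_vinyl (one data row)."""
    df = pd.read_csv(path)
    row = df.iloc[0]
    return IntegralSet(
        float(row["i_h2"]), float(row["i_acetyl"]),
        float(row["i_n_vinyl"]), float(row["i_o_vinyl"]),
    )


def read_mech_csv(path: str | Path) -> list[MechRow]:
    """CSV with columns sample, ds_molpct, sigma_mpa, e_mpa, eps_pct,
    sigma_uv_mpa, e_uv_mpa, eps_uv_pct."""
    df = pd.read_csv(path)
    return [
        MechRow(
            str(r["sample"]), float(r["ds_molpct"]), float(r["sigma_mpa"]),
            float(r["e_mpa"]), float(r["eps_pct"]), float(r["sigma_uv_mpa"]),
            float(r["e_uv_mpa"]), float(r["eps_uv_pct"]),
        )
        for _, r in df.iterrows()
    ]
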