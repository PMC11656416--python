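"""From per-slice peak tables to fit-ready (10^-pH, 1/kappa) points.

kappa is the concentration of protons the acidic analyte has given up at a
slice: protons now sitting on the indicator plus those free in solution,

    kappa = f_H * C_indicator + [H+]_free,       [H+]_free = 10^-pH / gamma1.

The free-proton term matters for low-pKa analytes (phosphoric acid), where a
non-negligible share of the transferred protons stays unbound.  The analyte
concentration is taken as homogeneous across the sample; protonation of the
indicator by water is neglected (the indicators are weak bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    A_DEBYE,
    Indicator,
    ReferenceCompound,
    SliceMeasurement,
    SlicePoint,
    gamma1,
)
from .errors import DataError, DomainError, InsufficientDataError
from .ph import IonicContext, frac_protonated, ph_selfconsistent

#: Slices whose protonated fraction falls outside this band sit too close to
#: a limiting shift for the shift uncertainty to give a usable pH.
FRAC_MIN = 0.05
FRAC_MAX = 0.95

PEAK_TABLE_COLUMNS = [
    "height_mm",
    "delta_obs_ppm",
    "integral_indicator",
    "integral_reference",
]

POINTS_COLUMNS = [
    "height_mm",
    "pH",
    "ionic_strength_M",
    "C_indicator_M",
    "kappa_M",
    "inv_kappa",
    "aH",
]


def indicator_concentration(
    m: SliceMeasurement, ind: Indicator, ref: ReferenceCompound
) -> float:
    """Indicator concentration of a slice from the per-proton integral ratio.

    C_indicator = (integral_ind/n_ind) / (integral_ref/n_ref)
                  * ref.conc * ref.correction_factor
    """
    if m.integral_indicator <= 0 or m.integral_reference <= 0:
        raise DataError(
            f"slice at {m.height} mm: integrals must be positive "
            f"(indicator={m.integral_indicator}, reference={m.integral_reference})"
        )
    per_proton_ind = m.integral_indicator / ind.n_protons
    per_proton_ref = m.integral_reference / ref.n_protons
    return per_proton_ind / per_proton_ref * ref.conc * ref.correction_factor


def kappa(
    C_indicator: float,
    frac_protonated: float,
    pH: float,
    I: float = 0.0,
    A: float = A_DEBYE,
) -> float:
    """Proton-transfer concentration of a slice (mol/L).

    ``10^-pH`` is the proton activity; division by gamma1 converts it to the
    free-proton concentration that enters the proton count.
    """
    if C_indicator <= 0:
        raise DomainError(f"C_indicator must be > 0, got {C_indicator}")
    return frac_protonated * C_indicator + 10.0 ** (-pH) / gamma1(I, A)


@dataclass(frozen=True)
class Rejection:
    height: float
    reason: str


@dataclass
class PointSet:
    """Retained slice points plus the rejection log."""

    points: list[SlicePoint]
    rejections: list[Rejection]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "height_mm": p.height,
                    "pH": p.pH,
                    "ionic_strength_M": p.ionic_strength,
                    "C_indicator_M": p.C_indicator,
                    "kappa_M": p.kappa,
                    "inv_kappa": p.inv_kappa,
                    "aH": p.aH,
                }
                for p in self.points
            ],
            columns=POINTS_COLUMNS,
        )


def build_points(
    measurements: Sequence[SliceMeasurement],
    ind: Indicator,
    ref: ReferenceCompound,
    composition: IonicContext | None = None,
    A: float = A_DEBYE,
) -> PointSet:
    """Convert slice measurements to retained :class:`SlicePoint`s.

    Per slice: indicator concentration from integrals, pH from the shift with
    self-consistent ionic strength, then kappa.  Slices are rejected — with a
    logged reason, never silently — when the shift sits at or beyond a
    limiting shift, the protonated fraction is within the margin of a limit,
    the pH falls outside the indicator's validity window, or kappa is not
    positive.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 slices survive filtering.
    """
    if len(measurements) < 3:
        raise InsufficientDataError(
            f"need at least 3 slice measurements, got {len(measurements)}"
        )
    if composition is None:
        composition = IonicContext()

    points: list[SlicePoint] = []
    rejections: list[Rejection] = []
    lo, hi = sorted((ind.delta_H, ind.delta_L))
    for m in measurements:
        if not lo < m.delta_obs < hi:
            rejections.append(
                Rejection(m.height, f"shift {m.delta_obs:.4f} ppm outside limiting shifts")
            )
            continue
        try:
            C_ind = indicator_concentration(m, ind, ref)
        except DataError as exc:
            rejections.append(Rejection(m.height, str(exc)))
            continue
        fH = frac_protonated(m.delta_obs, ind)
        if not FRAC_MIN <= fH <= FRAC_MAX:
            rejections.append(
                Rejection(
                    m.height,
                    f"protonated fraction {fH:.3f} outside [{FRAC_MIN}, {FRAC_MAX}]",
                )
            )
            continue
        ctx = composition.with_indicator_conc(C_ind)
        res = ph_selfconsistent(m.delta_obs, ind, ctx, A=A)
        if not res.in_window:
            rejections.append(
                Rejection(
                    m.height,
                    f"pH {res.pH:.3f} outside {ind.name} window {ind.pH_window}",
                )
            )
            continue
        k = kappa(C_ind, fH, res.pH, res.I_used, A)
        if k <= 0 or not math.isfinite(1.0 / k):
            rejections.append(Rejection(m.height, f"kappa {k:.3e} M not positive"))
            continue
        points.append(
            SlicePoint(
                height=m.height,
                pH=res.pH,
                ionic_strength=res.I_used,
                C_indicator=C_ind,
                kappa=k,
            )
        )

    if len(points) < 3:
        raise InsufficientDataError(
            f"only {len(points)} of {len(measurements)} slices usable "
            f"(rejections: {[r.reason for r in rejections][:5]} ...)"
        )
    return PointSet(points=points, rejections=rejections)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_peak_table(path: str | Path) -> list[SliceMeasurement]:
    """Read a peak-table CSV (header required, dot-decimal, UTF-8)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot read peak table {path}: {exc}") from exc
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(
            f"peak table {path} missing columns {missing}; "
            f"expected header {PEAK_TABLE_COLUMNS}"
        )
    numeric = df[PEAK_TABLE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise DataError(f"peak table {path}: non-numeric or missing values at lines {rows}")
    df = numeric
    return [
        SliceMeasurement(
            height=float(r.height_mm),
            delta_obs=float(r.delta_obs_ppm),
            integral_indicator=float(r.integral_indicator),
            integral_reference=float(r.integral_reference),
        )
        for r in df.itertuples()
    ]


def write_peak_table(measurements: Sequence[SliceMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "height_mm": m.height,
                "delta_obs_ppm": m.delta_obs,
                "integral_indicator": m.integral_indicator,
                "integral_reference": m.integral_reference,
            }
            for m in measurements
        ],
        columns=PEAK_TABLE_COLUMNS,
    ).to_csv(path, index=False)


def write_points(pointset: PointSet, path: str | Path) -> None:
    pointset.to_frame().to_csv(path, index=False)
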