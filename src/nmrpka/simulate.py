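"""Forward simulation of a complete indicator-gradient experiment.

A solid basic indicator at the bottom of a 5 mm NMR tube (or a drop of
liquid base layered on top) dissolves and diffuses into the analyte
solution, establishing a concentration gradient.  The chemical-shift-imaging
readout divides the NMR-active region into 64 horizontal slices of 0.41 mm.
Per slice this module computes the indicator concentration from a
semi-infinite erfc diffusion profile, solves the exact acid-base equilibrium
with the speciation oracle, emits the indicator shift and integrals a
spectrometer would report, and adds seeded Gaussian noise.  Ground truth is
retained alongside, so every pipeline stage can be validated end to end
without any experimental data.

The erfc profile C(h) = C0*erfc(h / (2*sqrt(D*t))) is a deliberately simple
stand-in for the full gradient-development model used to predict optimal
run times on real samples; it reproduces the feature the analysis needs (a
smooth monotone sweep of the indicator through its pH window), not the
detailed hydrodynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc
from scipy.stats import linregress

from .core import (
    AcidSpecies,
    Indicator,
    INDICATORS,
    REFERENCES,
    ReferenceCompound,
    SliceMeasurement,
    solve_speciation,
)
from .errors import CalibrationError, DataError, DomainError
from .pipeline import indicator_concentration, write_peak_table

TRUTH_COLUMNS = [
    "height_mm",
    "pH_true",
    "C_ind_true_M",
    "kappa_true_M",
    "I_true_M",
    "delta_true_ppm",
    "frac_protonated_true",
    "deprot_analyte_M",
    "h_M",
    "oh_M",
]

#: DSS chemical-shift reference present in every stock solution (sodium salt).
DSS_CONC = 2.0e-4


@dataclass(frozen=True)
class TubeSystem:
    """Everything needed to simulate one gradient experiment."""

    analyte: AcidSpecies | None
    indicator: Indicator
    source_conc_C0: float  # mol/L at the diffusion source
    diffusion_coefficient_D: float = 1.0e-9  # m^2/s
    elapsed_time_t: float = 6.0e4  # s
    n_slices: int = 64
    slice_thickness: float = 0.41  # mm
    active_region_offset: float = 4.0  # mm, source to bottom of active region
    top_clearance: float = 4.0  # mm, top of active region to liquid surface
    source_location: str = "bottom"  # or "top" (base layered on the liquid)
    strong_cations: float = 0.0  # mol/L, fully dissociated (incl. DSS Na+)
    strong_anions: float = 0.0
    reference: ReferenceCompound = REFERENCES["dioxane"]
    noise_shift_sd: float = 0.002  # ppm
    noise_integral_rel_sd: float = 0.02  # fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source_conc_C0 <= 0:
            raise DomainError("source_conc_C0 must be positive")
        if self.source_location not in ("bottom", "top"):
            raise DomainError("source_location must be 'bottom' or 'top'")

    @property
    def extent(self) -> float:
        """Vertical extent of the NMR-active region in mm."""
        return self.n_slices * self.slice_thickness

    def slice_heights(self) -> np.ndarray:
        """Mid-heights of every slice, mm from the tube base."""
        return self.active_region_offset + (np.arange(self.n_slices) + 0.5) * (
            self.slice_thickness
        )


def gradient_profile(sys: TubeSystem, height: float) -> float:
    """Indicator concentration (mol/L) at ``height`` mm from the tube base.

    Semi-infinite diffusion from the source: C = C0*erfc(x / (2*sqrt(D*t)))
    with x the distance from the source plane.  Monotone non-increasing away
    from the source; equals C0 at the source.
    """
    if sys.elapsed_time_t <= 0:
        raise DomainError(f"elapsed_time_t must be positive, got {sys.elapsed_time_t}")
    if height < 0:
        raise DomainError("height must be >= 0")
    length_mm = 2.0 * math.sqrt(sys.diffusion_coefficient_D * sys.elapsed_time_t) * 1e3
    if sys.source_location == "bottom":
        x = height
    else:
        surface = sys.active_region_offset + sys.extent + sys.top_clearance
        x = surface - height
    x = max(x, 0.0)
    return sys.source_conc_C0 * float(erfc(x / length_mm))


@dataclass
class SimulationResult:
    system: TubeSystem
    measurements: list[SliceMeasurement]
    truth: pd.DataFrame

    def write_peaks(self, path: str | Path) -> None:
        write_peak_table(self.measurements, path)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, index=False)


def simulate_tube(sys: TubeSystem) -> SimulationResult:
    """Simulate every slice of a gradient experiment.

    Per slice: indicator concentration from the diffusion profile,
    equilibrium from the speciation oracle (activity corrections on),
    observed shift from the indicator's protonated fraction, and integrals
    scaled so the indicator:reference per-proton ratio encodes the indicator
    concentration through the declared correction factor.  Gaussian noise
    (shift sd in ppm, relative integral sd) is drawn from a generator seeded
    with ``sys.seed``; a fixed seed reproduces the output bitwise.
    """
    ind = sys.indicator
    ref = sys.reference
    rng = np.random.default_rng(sys.seed)
    acids = [sys.analyte] if sys.analyte is not None else []

    # sodium counter-ion accompanies a carboxylate-type indicator salt
    na_per_ind = 1.0 if ind.dz2 == -1 else 0.0

    measurements: list[SliceMeasurement] = []
    rows: list[dict] = []
    ref_area = 1000.0
    for h_mm in sys.slice_heights():
        C_ind = gradient_profile(sys, float(h_mm))
        state = solve_speciation(
            acids=acids,
            base=ind,
            base_conc=C_ind,
            strong_cations=sys.strong_cations + na_per_ind * C_ind,
            strong_anions=sys.strong_anions,
            use_activity=True,
        )
        fH = state.indicator_frac_protonated
        delta_true = ind.delta_L + fH * (ind.delta_H - ind.delta_L)
        kappa_true = fH * C_ind + state.h
        if sys.analyte is not None:
            species = state.species[sys.analyte.name]
            deprot = float(np.arange(species.size) @ species)
        else:
            deprot = float("nan")

        area_ind_true = (
            ref_area * (ind.n_protons / ref.n_protons)
            * C_ind / (ref.conc * ref.correction_factor)
        )
        delta_obs = delta_true + rng.normal(0.0, sys.noise_shift_sd)
        area_ind = area_ind_true * (1.0 + rng.normal(0.0, sys.noise_integral_rel_sd))
        area_ref = ref_area * (1.0 + rng.normal(0.0, sys.noise_integral_rel_sd))

        measurements.append(
            SliceMeasurement(
                height=float(h_mm),
                delta_obs=float(delta_obs),
                integral_indicator=max(float(area_ind), 1e-12),
                integral_reference=max(float(area_ref), 1e-12),
            )
        )
        rows.append(
            {
                "height_mm": float(h_mm),
                "pH_true": state.pH,
                "C_ind_true_M": C_ind,
                "kappa_true_M": kappa_true,
                "I_true_M": state.ionic_strength,
                "delta_true_ppm": delta_true,
                "frac_protonated_true": fH,
                "deprot_analyte_M": deprot,
                "h_M": state.h,
                "oh_M": state.oh,
            }
        )

    return SimulationResult(
        system=sys,
        measurements=measurements,
        truth=pd.DataFrame(rows, columns=TRUTH_COLUMNS),
    )


def simulate_calibration(
    strong_acid_conc: float,
    ind: Indicator,
    source_conc_C0: float | None = None,
    **geometry,
) -> SimulationResult:
    """Gradient of the indicator over a strong-acid solution of known
    concentration, used to calibrate the limiting shifts.

    Every proton of the strong acid is transferred (it is fully dissociated),
    so kappa is known a priori and equals ``strong_acid_conc``; the truth
    table's ``kappa_true_M`` is the simulated value, which matches to within
    the (negligible) free-hydroxide concentration.
    """
    if strong_acid_conc <= 0:
        raise DomainError("strong_acid_conc must be positive")
    if source_conc_C0 is None:
        source_conc_C0 = 5.0 * strong_acid_conc
    sys = TubeSystem(
        analyte=None,
        indicator=ind,
        source_conc_C0=source_conc_C0,
        strong_anions=strong_acid_conc,
        **geometry,
    )
    return simulate_tube(sys)


@dataclass(frozen=True)
class CalibrationResult:
    delta_H: float
    delta_L: float
    ci95_H: float
    ci95_L: float
    n_points: int
    ill_conditioned: bool


def calibrate_limits(
    measurements: Sequence[SliceMeasurement],
    ind: Indicator,
    ref: ReferenceCompound,
    kappa_known: float,
    A: float | None = None,
) -> CalibrationResult:
    """Estimate the limiting shifts from a known-kappa calibration gradient.

    With kappa fixed by a strong acid, the protonated fraction of each slice
    is ``f_H = (kappa_known - [H+]_free)/C_indicator``, where the free-proton
    concentration comes from solving the slice equilibrium with the
    indicator's literature pKa,0 (its limiting shifts are not needed).  A
    linear regression of delta_obs on f_H then yields delta_L (intercept)
    and delta_H (intercept + slope).

    The passed ``ind`` supplies pKa,0, dz2 and n_protons; its shift limits
    are ignored and may be placeholders.
    """
    if kappa_known <= 0:
        raise DomainError("kappa_known must be positive")
    na_per_ind = 1.0 if ind.dz2 == -1 else 0.0
    fHs: list[float] = []
    deltas: list[float] = []
    for m in measurements:
        C_ind = indicator_concentration(m, ind, ref)
        if C_ind <= 0:
            continue
        state = solve_speciation(
            base=ind,
            base_conc=C_ind,
            strong_cations=na_per_ind * C_ind,
            strong_anions=kappa_known,
            use_activity=True,
        )
        fH = (kappa_known - state.h) / C_ind
        if 0.0 < fH < 1.0:
            fHs.append(fH)
            deltas.append(m.delta_obs)
    if len(fHs) < 3:
        raise CalibrationError(
            "calibration impossible: fewer than 3 slices with protonated "
            "fraction inside (0, 1); is the base gradient present?"
        )
    fh = np.asarray(fHs)
    dl = np.asarray(deltas)
    ill = bool(fh.max() - fh.min() < 0.05)
    res = linregress(fh, dl)
    from scipy.stats import t as t_dist

    dof = len(fHs) - 2
    tcrit = float(t_dist.ppf(0.975, dof)) if dof > 0 else math.inf
    delta_L = float(res.intercept)
    delta_H = float(res.intercept + res.slope)
    ci_L = tcrit * float(res.intercept_stderr)
    ci_H = tcrit * float(math.hypot(res.intercept_stderr, res.stderr))
    return CalibrationResult(
        delta_H=delta_H,
        delta_L=delta_L,
        ci95_H=ci_H,
        ci95_L=ci_L,
        n_points=len(fHs),
        ill_conditioned=ill,
    )


def synthesize_spectrum(
    delta_indicator: float,
    integral_indicator: float,
    integral_reference: float,
    delta_reference: float = 3.751,
    integral_dss: float = 50.0,
    gamma: float = 0.001,
    ppm_min: float = -1.0,
    ppm_max: float = 10.5,
    n_points: int = 2 ** 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Optional demo: a stick-to-Lorentzian ¹H spectrum of one slice.

    Lorentzian lines (half-width ``gamma`` ppm) at the indicator shift, the
    integral-reference shift and DSS (0 ppm), with areas equal to the
    declared integrals.  Returns (ppm, intensity) arrays.
    """
    ppm = np.linspace(ppm_min, ppm_max, n_points)
    intensity = np.zeros_like(ppm)
    for x0, area in (
        (delta_indicator, integral_indicator),
        (delta_reference, integral_reference),
        (0.0, integral_dss),
    ):
        intensity += area * (gamma / math.pi) / ((ppm - x0) ** 2 + gamma**2)
    return ppm, intensity


# ---------------------------------------------------------------------------
# Scenario presets: the nine benchmark analytes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A named simulation scenario with its ground-truth fit targets."""

    name: str
    system: TubeSystem
    true_pKa0: float  # literature pKa,0 of the titrating site
    analyte_dz2: int  # charge-squared change of that site


def _std_system(
    analyte: AcidSpecies,
    indicator: str,
    extra_cations: float = 0.0,
    extra_anions: float = 0.0,
    source_location: str = "bottom",
    seed: int = 0,
    noise_shift_sd: float = 0.002,
    noise_integral_rel_sd: float = 0.02,
) -> TubeSystem:
    # DSS (sodium salt, 0.2 mM) is present in every stock solution
    return TubeSystem(
        analyte=analyte,
        indicator=INDICATORS[indicator],
        source_conc_C0=5.0 * analyte.total_conc,
        strong_cations=extra_cations + DSS_CONC,
        strong_anions=extra_anions + DSS_CONC,
        source_location=source_location,
        seed=seed,
        noise_shift_sd=noise_shift_sd,
        noise_integral_rel_sd=noise_integral_rel_sd,
    )


def _scenario_specs() -> dict[str, dict]:
    """Literature pKa,0 values, concentrations and paired indicators."""
    return {
        "glycine_hcl": dict(
            acid=AcidSpecies("glycinium", (2.35, 9.78), 0.010, +1),
            indicator="1,2,4-triazole",
            extra_anions=0.010,  # chloride of the hydrochloride salt
        ),
        "phosphoric_acid": dict(
            acid=AcidSpecies("phosphoric acid", (2.16, 7.21, 12.32), 0.060, 0),
            indicator="1,2,4-triazole",
        ),
        "sodium_dihydrogen_phosphate": dict(
            acid=AcidSpecies("dihydrogen phosphate", (7.21, 12.32), 0.010, -1),
            indicator="2-methylimidazole",
            extra_cations=0.010,  # sodium of the salt
        ),
        "4-cyanophenol": dict(
            acid=AcidSpecies("4-cyanophenol", (7.95,), 0.010, 0),
            indicator="2-methylimidazole",
        ),
        "boric_acid": dict(
            acid=AcidSpecies("boric acid", (9.19,), 0.010, 0),
            indicator="2-methylimidazole",
        ),
        "hydroxylammonium_chloride": dict(
            acid=AcidSpecies("hydroxylammonium", (5.94,), 0.010, +1),
            indicator="2,6-lutidine",
            extra_anions=0.010,
            source_location="top",  # 2,6-lutidine solution floats on the sample
        ),
        "ammonium_chloride": dict(
            acid=AcidSpecies("ammonium", (9.24,), 0.010, +1),
            indicator="2-methylimidazole",
            extra_anions=0.010,
        ),
        "benzoic_acid": dict(
            acid=AcidSpecies("benzoic acid", (4.20,), 0.010, 0),
            indicator="acetate",
        ),
        "glycolic_acid": dict(
            acid=AcidSpecies("glycolic acid", (3.89,), 0.010, 0),
            indicator="formate",
        ),
    }


SCENARIO_NAMES: tuple[str, ...] = tuple(_scenario_specs())


def scenario(
    name: str,
    seed: int = 0,
    noise_shift_sd: float = 0.002,
    noise_integral_rel_sd: float = 0.02,
) -> Scenario:
    """Build a named benchmark scenario (see :data:`SCENARIO_NAMES`)."""
    specs = _scenario_specs()
    if name not in specs:
        raise DomainError(f"unknown scenario {name!r}; available: {sorted(specs)}")
    spec = dict(specs[name])
    acid: AcidSpecies = spec.pop("acid")
    system = _std_system(
        acid,
        spec.pop("indicator"),
        seed=seed,
        noise_shift_sd=noise_shift_sd,
        noise_integral_rel_sd=noise_integral_rel_sd,
        **spec,
    )
    return Scenario(
        name=name,
        system=system,
        true_pKa0=acid.pKa0_list[0],
        analyte_dz2=acid.site_dz2(0),
    )
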