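"""Domain types and the exact acid-base speciation solver.

The solver is the package's brute-force oracle: given the full composition of
a slice (weak acids, the basic indicator, strong co-ions) it returns the
unique proton concentration satisfying charge balance with mass-action laws
for every dissociable site and for water.  Every higher-level quantity the
package computes (pH from a chemical shift, the proton-transfer concentration
kappa, the linearized titration fit) can be checked against it.

Conventions
-----------
* Thermodynamic (zero-ionic-strength) constants ``pKa,0`` are stored on the
  domain types.  At finite ionic strength they are converted to
  concentration quotients with Davies activity coefficients,
  ``log10 gamma_z = -A * z**2 * (sqrt(I)/(1+sqrt(I)) - 0.3*I)``.
* ``pH`` is the proton *activity* scale, ``pH = -log10(gamma_1 * [H+])``,
  when activity corrections are on; otherwise ``-log10([H+])``.
* Kw = 1.0e-14 is applied to concentrations directly (no activity
  correction on water autoionization; the working range is pH 1-10 where
  this refinement is negligible).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError

#: Debye-Hueckel A coefficient for water at 298 K (log10 basis).
A_DEBYE = 0.509

#: Ion product of water at 298 K, concentration basis.
KW = 1.0e-14


def davies_f(I: float) -> float:
    """Ionic-strength function of the Davies equation, sqrt(I)/(1+sqrt(I)) - 0.3*I.

    Parameters
    ----------
    I : float
        Ionic strength in mol/L; must be non-negative.
    """
    if I < 0:
        raise DomainError(f"ionic strength must be >= 0, got {I}")
    s = math.sqrt(I)
    return s / (1.0 + s) - 0.3 * I


def davies_log_gamma(z: int, I: float, A: float = A_DEBYE) -> float:
    """log10 of the single-ion activity coefficient of a charge-``z`` ion.

    Davies form: ``-A * z**2 * (sqrt(I)/(1+sqrt(I)) - 0.3*I)``.  Returns 0 for
    a neutral species or at zero ionic strength.
    """
    return -A * z * z * davies_f(I)


def gamma1(I: float, A: float = A_DEBYE) -> float:
    """Activity coefficient of a singly charged ion at ionic strength ``I``."""
    return 10.0 ** davies_log_gamma(1, I, A)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Indicator:
    """A basic NMR pH indicator.

    The indicator is a weak base whose observed ¹H shift interpolates between
    the fully protonated limit ``delta_H`` and the fully deprotonated limit
    ``delta_L``.  ``dz2`` is the difference of squared charges between the
    protonated and deprotonated forms: +1 for nitrogenous bases
    (BH⁺/B), -1 for carboxylate-type indicators (HA/A⁻).  ``pH_window`` is
    the pH range over which the shift is a usable pH probe; outside it the
    shift sits too close to a limit for the measurement uncertainty.
    """

    name: str
    pKa0: float
    delta_H: float
    delta_L: float
    dz2: int
    n_protons: int
    pH_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.delta_H == self.delta_L:
            raise DomainError(f"{self.name}: limiting shifts must differ")
        lo, hi = self.pH_window
        if not lo < hi:
            raise DomainError(f"{self.name}: pH_window must be (low, high)")
        if self.n_protons <= 0:
            raise DomainError(f"{self.name}: n_protons must be positive")

    @property
    def charge_protonated(self) -> int:
        """Charge of the protonated form (+1 nitrogenous, 0 carboxylate-type)."""
        return 1 if self.dz2 == 1 else 0

    def as_acid(self, conc: float) -> "AcidSpecies":
        """The indicator's conjugate acid as an :class:`AcidSpecies` at ``conc``."""
        return AcidSpecies(
            name=self.name,
            pKa0_list=(self.pKa0,),
            total_conc=conc,
            charge_fully_protonated=self.charge_protonated,
        )

    def in_window(self, pH: float) -> bool:
        lo, hi = self.pH_window
        return lo <= pH <= hi


@dataclass(frozen=True)
class AcidSpecies:
    """A (poly)protic acid with thermodynamic site constants.

    ``pKa0_list`` holds one pKa,0 per dissociable proton in increasing order;
    ``charge_fully_protonated`` is the charge of the species with all protons
    attached (e.g. 0 for H3PO4, +1 for glycinium, -1 for H2PO4⁻ supplied as
    its sodium salt).
    """

    name: str
    pKa0_list: tuple[float, ...]
    total_conc: float
    charge_fully_protonated: int = 0

    def __post_init__(self) -> None:
        if self.total_conc < 0:
            raise DomainError(f"{self.name}: total_conc must be >= 0")
        pk = tuple(self.pKa0_list)
        if len(pk) == 0:
            raise DomainError(f"{self.name}: at least one pKa required")
        if any(b <= a for a, b in zip(pk, pk[1:])):
            raise DomainError(f"{self.name}: pKa0_list must be strictly increasing")
        object.__setattr__(self, "pKa0_list", pk)

    @property
    def n_sites(self) -> int:
        return len(self.pKa0_list)

    def site_dz2(self, site: int) -> int:
        """Charge-squared change of deprotonation step ``site`` (0-based)."""
        z_h = self.charge_fully_protonated - site
        z_l = z_h - 1
        return z_h * z_h - z_l * z_l

    def species_charges(self) -> np.ndarray:
        """Charges of the n_sites+1 protonation states, most protonated first."""
        z0 = self.charge_fully_protonated
        return z0 - np.arange(self.n_sites + 1)


@dataclass(frozen=True)
class ReferenceCompound:
    """Inert integral-reference compound of known concentration.

    ``correction_factor`` rescales the per-proton integral ratio to a
    concentration ratio; it absorbs differential relaxation/saturation of the
    reference resonance and is determined on a solution of known base
    concentration.
    """

    name: str
    conc: float
    n_protons: int
    correction_factor: float = 1.0


@dataclass(frozen=True)
class SliceMeasurement:
    """Raw observables of one chemical-shift-imaging slice."""

    height: float  # mm from tube base
    delta_obs: float  # ppm
    integral_indicator: float  # arbitrary units
    integral_reference: float  # arbitrary units


@dataclass(frozen=True)
class SlicePoint:
    """Derived per-slice quantities ready for titration fitting."""

    height: float
    pH: float
    ionic_strength: float
    C_indicator: float
    kappa: float

    @property
    def inv_kappa(self) -> float:
        return 1.0 / self.kappa

    @property
    def aH(self) -> float:
        """Proton activity 10^-pH."""
        return 10.0 ** (-self.pH)


@dataclass(frozen=True)
class FitResult:
    """pKa,0 and analyte concentration with 95% confidence half-widths."""

    pKa0_fit: float
    C_analyte_fit: float
    ci95_pKa: float
    ci95_C: float
    r_squared: float
    n_points: int
    method: str  # "linear" or "nonlinear"
    residuals: tuple[float, ...]
    pKa_mixed: float = float("nan")
    I_median: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "pKa0": self.pKa0_fit,
            "pKa0_ci95": self.ci95_pKa,
            "C_analyte_M": self.C_analyte_fit,
            "C_ci95": self.ci95_C,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


# ---------------------------------------------------------------------------
# Speciation solver
# ---------------------------------------------------------------------------


@dataclass
class SpeciationState:
    """Equilibrium state returned by :func:`solve_speciation`."""

    pH: float
    h: float  # free proton concentration, mol/L
    oh: float  # free hydroxide concentration, mol/L
    ionic_strength: float
    gamma1: float
    species: dict[str, np.ndarray]  # name -> concentrations, most protonated first
    charge_residual: float
    iterations: int
    indicator_frac_protonated: float = float("nan")

    @property
    def aH(self) -> float:
        return 10.0 ** (-self.pH)


def _ladder_fractions(h: float, kc: np.ndarray) -> np.ndarray:
    """Fractions of the n+1 protonation states of a polyprotic acid.

    ``kc`` are concentration dissociation quotients of the successive sites.
    State ``j`` has ``j`` protons removed; relative weight prod(kc[:j])/h**j.
    """
    n = kc.size
    w = np.empty(n + 1)
    w[0] = 1.0
    for j in range(n):
        w[j + 1] = w[j] * kc[j] / h
    return w / w.sum()


def _conc_quotients(acid: AcidSpecies, I: float, A: float) -> np.ndarray:
    """Concentration dissociation quotients of every site at ionic strength I.

    pKc_j = pKa0_j - A*f(I)*(1 - dz2_j): gamma_H+ plus the gammas of the
    conjugate pair, all in the Davies approximation.
    """
    f = davies_f(I)
    pkc = np.array(
        [pk - A * f * (1 - acid.site_dz2(j)) for j, pk in enumerate(acid.pKa0_list)]
    )
    return 10.0 ** (-pkc)


def solve_speciation(
    acids: Sequence[AcidSpecies] = (),
    base: Indicator | None = None,
    base_conc: float = 0.0,
    strong_cations: float = 0.0,
    strong_anions: float = 0.0,
    use_activity: bool = True,
    A: float = A_DEBYE,
    tol_pH: float = 1e-9,
    max_iter: int = 200,
) -> SpeciationState:
    """Solve the full acid-base equilibrium of a slice composition.

    Parameters
    ----------
    acids
        Weak acids present (the analyte, possibly multiprotic).
    base, base_conc
        The indicator acting as a base at total concentration ``base_conc``
        (mol/L); internally treated through its conjugate acid.
    strong_cations, strong_anions
        Fully dissociated singly charged co-ions (Na⁺, Cl⁻, DSS⁻ ...), mol/L.
    use_activity
        If True, site constants are converted to concentration quotients with
        Davies coefficients and the ionic strength is iterated to
        self-consistency (|ΔpH| < ``tol_pH``); pH is then the activity scale
        -log10(gamma1*[H+]).

    Returns
    -------
    SpeciationState
        The unique equilibrium; ``species[name]`` lists the concentrations of
        each protonation state, most protonated first.

    Raises
    ------
    ConvergenceError
        If the charge balance cannot be bracketed or the ionic-strength
        fixed point does not settle within ``max_iter`` iterations.
    """
    for a in acids:
        if a.total_conc < 0:
            raise DomainError(f"{a.name}: negative concentration")
    if base_conc < 0 or strong_cations < 0 or strong_anions < 0:
        raise DomainError("concentrations must be >= 0")

    all_acids = list(acids)
    if base is not None and base_conc > 0:
        all_acids.append(base.as_acid(base_conc))

    charges = [a.species_charges() for a in all_acids]

    def solve_at(kcs: list[np.ndarray]) -> tuple[float, list[np.ndarray]]:
        def balance(h: float) -> float:
            q = h - KW / h + strong_cations - strong_anions
            for a, kc, z in zip(all_acids, kcs, charges):
                if a.total_conc > 0:
                    q += a.total_conc * float(_ladder_fractions(h, kc) @ z)
            return q

        lo, hi = 1e-14, 1.0
        f_lo, f_hi = balance(lo), balance(hi)
        if f_lo > 0 or f_hi < 0:
            raise ConvergenceError(
                f"charge balance not bracketed on [{lo}, {hi}] "
                f"(f(lo)={f_lo:.3e}, f(hi)={f_hi:.3e})"
            )
        x = brentq(lambda lg: balance(10.0**lg), -14.0, 0.0, xtol=1e-15, rtol=8.9e-16)
        h = 10.0**x
        # Newton polish on the linear scale for a tiny charge residual.
        for _ in range(3):
            fh = balance(h)
            dh = h * 1e-7
            dfdh = (balance(h + dh) - balance(h - dh)) / (2 * dh)
            if dfdh == 0:
                break
            step = fh / dfdh
            if not math.isfinite(step) or abs(step) > 0.5 * h:
                break
            h -= step
        fracs = [_ladder_fractions(h, kc) for kc in kcs]
        return h, fracs

    def ionic_strength(h: float, fracs: list[np.ndarray]) -> float:
        I = 0.5 * (h + KW / h + strong_cations + strong_anions)
        for a, fr, z in zip(all_acids, fracs, charges):
            if a.total_conc > 0:
                I += 0.5 * a.total_conc * float(fr @ (z * z))
        return I

    if not use_activity:
        kcs = [10.0 ** (-np.asarray(a.pKa0_list, dtype=float)) for a in all_acids]
        h, fracs = solve_at(kcs)
        I = ionic_strength(h, fracs)
        pH = -math.log10(h)
        g1 = 1.0
        iters = 1
    else:
        I = 0.0
        pH_prev = math.inf
        for iters in range(1, max_iter + 1):
            kcs = [_conc_quotients(a, I, A) for a in all_acids]
            h, fracs = solve_at(kcs)
            I_new = ionic_strength(h, fracs)
            g1 = gamma1(I_new, A)
            pH = -math.log10(g1 * h)
            if abs(pH - pH_prev) < tol_pH:
                I = I_new
                break
            pH_prev = pH
            # plain fixed point converges fast here; damp late just in case
            I = I_new if iters < 30 else 0.5 * (I + I_new)
        else:
            raise ConvergenceError(
                f"ionic-strength fixed point did not converge in {max_iter} "
                f"iterations (last pH {pH:.6f})"
            )

    species = {
        a.name: a.total_conc * fr for a, fr in zip(all_acids, fracs)
    }
    q = h - KW / h + strong_cations - strong_anions
    for a, fr, z in zip(all_acids, fracs, charges):
        q += a.total_conc * float(fr @ z)

    state = SpeciationState(
        pH=pH,
        h=h,
        oh=KW / h,
        ionic_strength=I,
        gamma1=g1,
        species=species,
        charge_residual=q,
        iterations=iters,
    )
    if base is not None and base_conc > 0:
        frac = species[base.name][0] / base_conc
        state.indicator_frac_protonated = float(frac)
    return state


# ---------------------------------------------------------------------------
# Packaged constants and JSON loading
# ---------------------------------------------------------------------------

#: The five basic indicators used throughout, with literature pKa,0 and
#: calibrated limiting shifts.  Note formate's delta_H < delta_L: the formula
#: handles either orientation through the shift ratio.
INDICATORS: dict[str, Indicator] = {
    ind.name: ind
    for ind in (
        Indicator("2-methylimidazole", 7.96, 7.270, 6.958, +1, 2, (7.0, 9.0)),
        Indicator("2,6-lutidine", 6.75, 2.707, 2.456, +1, 6, (6.0, 8.0)),
        Indicator("acetate", 4.76, 2.083, 1.906, -1, 3, (3.5, 5.5)),
        Indicator("formate", 3.75, 8.266, 8.441, -1, 1, (2.5, 4.5)),
        Indicator("1,2,4-triazole", 2.45, 9.193, 8.352, +1, 2, (1.0, 3.0)),
    )
}

#: Integral-reference compounds at their stock concentrations (0.01% v/v).
REFERENCES: dict[str, ReferenceCompound] = {
    "dioxane": ReferenceCompound("dioxane", 1.17e-3, 8, 1.0),
    "dmso": ReferenceCompound("dmso", 1.41e-3, 6, 1.0),
}


def indicator_from_dict(d: dict) -> Indicator:
    """Build an :class:`Indicator` from a JSON-style mapping."""
    return Indicator(
        name=d["name"],
        pKa0=float(d["pKa0"]),
        delta_H=float(d["delta_H"]),
        delta_L=float(d["delta_L"]),
        dz2=int(d["dz2"]),
        n_protons=int(d["n_protons"]),
        pH_window=tuple(float(x) for x in d["pH_window"]),  # type: ignore[arg-type]
    )


def acid_from_dict(d: dict) -> AcidSpecies:
    return AcidSpecies(
        name=d["name"],
        pKa0_list=tuple(float(x) for x in d["pKa0_list"]),
        total_conc=float(d["total_conc"]),
        charge_fully_protonated=int(d.get("charge_fully_protonated", 0)),
    )


def load_indicator(source: str | Path | dict) -> Indicator:
    """Resolve an indicator from a packaged name, a mapping, or a JSON file."""
    if isinstance(source, dict):
        return indicator_from_dict(source)
    key = str(source)
    if key in INDICATORS:
        return INDICATORS[key]
    p = Path(key)
    if p.suffix == ".json" and p.exists():
        return indicator_from_dict(json.loads(p.read_text()))
    raise DomainError(
        f"unknown indicator {key!r}; packaged indicators: {sorted(INDICATORS)}"
    )
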