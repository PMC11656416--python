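"""Chemical shift -> pH conversion with Davies ionic-strength correction.

The observed shift of a fast-exchange indicator is the population-weighted
average of its protonated and deprotonated limiting shifts, so the
protonated fraction is ``f_H = (delta_obs - delta_L)/(delta_H - delta_L)``
and

    pH = pKa,0 + dz2 * A * (sqrt(I)/(1+sqrt(I)) - 0.3*I)
              + log10((delta_H - delta_obs)/(delta_obs - delta_L))

where the middle term converts the thermodynamic pKa,0 to the mixed constant
(concentration ratio of the conjugate pair, activity of H+) at ionic
strength I.  The ratio form handles both shift orientations (formate has
delta_H < delta_L) without any sign gymnastics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import A_DEBYE, KW, AcidSpecies, Indicator, davies_f, gamma1
from .errors import ConvergenceError, DomainError


@dataclass(frozen=True)
class PhResult:
    pH: float
    frac_protonated: float
    I_used: float
    in_window: bool


def frac_protonated(delta_obs: float, ind: Indicator) -> float:
    """Protonated fraction from the observed shift; open-interval checked."""
    lo, hi = sorted((ind.delta_H, ind.delta_L))
    if not lo < delta_obs < hi:
        raise DomainError(
            f"delta_obs={delta_obs} ppm outside the open interval "
            f"({lo}, {hi}) of {ind.name}'s limiting shifts; slice unusable"
        )
    return (delta_obs - ind.delta_L) / (ind.delta_H - ind.delta_L)


def mixed_pKa(ind: Indicator, I: float, A: float = A_DEBYE) -> float:
    """Mixed (H+-activity) pKa of the indicator at ionic strength I."""
    return ind.pKa0 + ind.dz2 * A * davies_f(I)


def ph_from_shift(
    delta_obs: float, ind: Indicator, I: float = 0.0, A: float = A_DEBYE
) -> PhResult:
    """pH from an indicator shift at known ionic strength.

    At I = 0 and ``delta_obs`` midway between the limits the result is
    exactly ``pKa,0``.
    """
    fH = frac_protonated(delta_obs, ind)
    pH = mixed_pKa(ind, I, A) + math.log10((1.0 - fH) / fH)
    return PhResult(pH=pH, frac_protonated=fH, I_used=I, in_window=ind.in_window(pH))


def shift_from_ph(pH: float, ind: Indicator, I: float = 0.0, A: float = A_DEBYE) -> float:
    """Exact inverse of :func:`ph_from_shift`; saturates smoothly at the limits."""
    r = 10.0 ** (pH - mixed_pKa(ind, I, A))  # deprotonated/protonated ratio
    fH = 1.0 / (1.0 + r)
    return ind.delta_L + fH * (ind.delta_H - ind.delta_L)


@dataclass(frozen=True)
class IonicContext:
    """Composition knowledge needed to estimate a slice's ionic strength.

    ``strong_cations``/``strong_anions`` are fully dissociated singly charged
    co-ions declared by the experiment (analyte counter-ions, DSS).  When the
    indicator ships as a sodium salt (carboxylate-type, ``dz2 = -1``) the Na⁺
    accompanying ``C_indicator`` is added automatically.  If ``analyte`` is
    given, its ionization state is reconstructed from the charge-balance
    identity (protons transferred create one negative-charge unit each),
    using its *nominal* total concentration only — no pKa knowledge needed.
    """

    C_indicator: float = 0.0
    strong_cations: float = 0.0
    strong_anions: float = 0.0
    analyte: AcidSpecies | None = None

    def with_indicator_conc(self, C_indicator: float) -> "IonicContext":
        return IonicContext(
            C_indicator=C_indicator,
            strong_cations=self.strong_cations,
            strong_anions=self.strong_anions,
            analyte=self.analyte,
        )

    def ionic_strength(
        self, pH: float, fH: float, ind: Indicator, A: float = A_DEBYE
    ) -> float:
        """Estimate I at a given pH and indicator protonated fraction.

        The free-proton concentration is 10^-pH/gamma1, which itself depends
        on I; a short fixed-point iteration resolves that.
        """
        aH = 10.0 ** (-pH)
        cat = self.strong_cations
        if ind.dz2 == -1:
            cat += self.C_indicator  # sodium counter-ion of the indicator salt
        ind_charged = fH * self.C_indicator if ind.dz2 == 1 else (1 - fH) * self.C_indicator
        ind_net = fH * self.C_indicator if ind.dz2 == 1 else -(1 - fH) * self.C_indicator

        I = 0.0
        for _ in range(50):
            h = aH / gamma1(I, A)
            oh = KW / h
            I_new = 0.5 * (h + oh + cat + self.strong_anions + ind_charged)
            if self.analyte is not None:
                C = self.analyte.total_conc
                z0 = self.analyte.charge_fully_protonated
                # protons removed from the analyte, by charge balance
                d = h - oh + cat + ind_net - self.strong_anions + C * z0
                d = min(max(d, 0.0), C)
                z1 = z0 - 1
                I_new += 0.5 * ((C - d) * z0 * z0 + d * z1 * z1)
            if abs(I_new - I) < 1e-12:
                return I_new
            I = I_new
        return I


def ph_selfconsistent(
    delta_obs: float,
    ind: Indicator,
    context: IonicContext,
    A: float = A_DEBYE,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PhResult:
    """pH from a shift with ionic strength iterated to self-consistency.

    Fixed point: pH -> I(pH) from the composition context -> pH, until
    |ΔpH| < ``tol``.  With an empty context this reduces to
    :func:`ph_from_shift` at (essentially) zero ionic strength.
    """
    fH = frac_protonated(delta_obs, ind)
    I = 0.0
    pH_prev = math.inf
    for _ in range(max_iter):
        res = ph_from_shift(delta_obs, ind, I, A)
        if abs(res.pH - pH_prev) < tol:
            return PhResult(res.pH, fH, I, ind.in_window(res.pH))
        pH_prev = res.pH
        I = context.ionic_strength(res.pH, fH, ind, A)
    raise ConvergenceError(
        f"pH/ionic-strength fixed point did not converge in {max_iter} "
        f"iterations (last pH {pH_prev:.4f}, I {I:.3e} M)"
    )
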