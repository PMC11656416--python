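"""pKa,0 and analyte concentration from slice points.

The titration model for a single acid site is

    kappa = C_analyte * Ka / (Ka + 10^-pH)

with Ka the mixed dissociation constant (concentration ratio of the
conjugate pair, H+ activity).  Its reciprocal is linear in the proton
activity aH = 10^-pH,

    1/kappa = 1/C_analyte + aH / (Ka * C_analyte),

so ordinary least squares of 1/kappa on aH gives C_analyte = 1/intercept
and Ka = intercept/slope.  Because Ka here is the mixed constant, it drifts
with the ionic strength of each slice: pKa_mixed(I) = pKa,0 + dz2*A*f(I),
where dz2 is the charge-squared change of the titrating site (-1 for a
neutral acid HA/A⁻, +1 for a cationic acid BH⁺/B, -3 for H2PO4⁻/HPO4²⁻).
Substituting that into the linear form shows the regression is exactly
linear in the corrected abscissa

    x = aH * 10**(dz2 * A * f(I_slice)),

with slope 1/(Ka0*C) and intercept 1/C — so fitting against x returns the
thermodynamic pKa,0 directly with no after-the-fact correction.  (A single
median-I correction applied after an uncorrected fit leaves a small
curvature that the long extrapolation to the intercept amplifies into a
multi-hundredth pKa bias; the per-point form removes it.)  A nonlinear fit
of the un-inverted model is provided as a cross-check.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .core import A_DEBYE, FitResult, SlicePoint, davies_f
from .errors import (
    DomainError,
    InsufficientDataError,
    NoTitrationError,
    UnphysicalFitError,
)

#: Minimum factor by which the proton activity must vary across the points.
MIN_AH_SPREAD = 3.0


def _extract(
    points: Sequence[SlicePoint], analyte_dz2: int, A: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Corrected abscissa x = aH*10**(dz2*A*f(I)), kappa, and median I."""
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 points to fit, got {len(points)}")
    aH = np.array([p.aH for p in points])
    kap = np.array([p.kappa for p in points])
    Is = np.array([p.ionic_strength for p in points])
    I_med = float(np.median(Is))
    if aH.max() / aH.min() < MIN_AH_SPREAD:
        raise InsufficientDataError(
            f"proton activity spans only a factor {aH.max() / aH.min():.2f} "
            f"(need >= {MIN_AH_SPREAD}); gradient too shallow to titrate"
        )
    x = aH * 10.0 ** (analyte_dz2 * A * np.array([davies_f(i) for i in Is]))
    return x, kap, I_med


def fit_linear(
    points: Sequence[SlicePoint],
    analyte_dz2: int = -1,
    A: float = A_DEBYE,
) -> FitResult:
    """Linearized titration fit: OLS of 1/kappa on 10^-pH.

    Confidence intervals are 95% t-intervals (n-2 degrees of freedom);
    those of C_analyte = 1/intercept and pKa = -log10(intercept/slope) follow
    by first-order (delta-method) propagation from the (slope, intercept)
    covariance — approximate when the intercept nears zero.  The abscissa
    carries the per-point Davies correction, so the reported pKa is the
    thermodynamic pKa,0 (comparable to literature tables).

    Raises
    ------
    UnphysicalFitError
        If the intercept is <= 0 (no positive analyte concentration).
    NoTitrationError
        If the slope is <= 0 (kappa does not fall with proton activity).
    """
    x, kap, I_med = _extract(points, analyte_dz2, A)
    y = 1.0 / kap
    n = x.size

    X = np.column_stack([x, np.ones(n)])
    coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    if intercept <= 0:
        raise UnphysicalFitError(
            f"intercept {intercept:.4g} L/mol <= 0: fitted analyte concentration "
            f"is not positive (slope {slope:.4g}, n {n})"
        )
    if slope <= 0:
        raise NoTitrationError(
            f"slope {slope:.4g} <= 0: 1/kappa does not increase with 10^-pH; "
            "no titratable acid detected"
        )

    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    tcrit = float(stats.t.ppf(0.975, dof)) if dof > 0 else math.inf

    C = 1.0 / intercept
    Ka = intercept / slope
    # delta method: C = 1/b ; Ka = b/m
    var_C = cov[1, 1] / intercept**4
    grad_Ka = np.array([-intercept / slope**2, 1.0 / slope])
    var_Ka = float(grad_Ka @ cov @ grad_Ka)
    var_pKa = var_Ka / (Ka * math.log(10.0)) ** 2

    pKa0 = -math.log10(Ka)
    pKa_mixed = pKa0 + analyte_dz2 * A * davies_f(I_med)

    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0

    return FitResult(
        pKa0_fit=pKa0,
        C_analyte_fit=C,
        ci95_pKa=tcrit * math.sqrt(max(var_pKa, 0.0)),
        ci95_C=tcrit * math.sqrt(max(var_C, 0.0)),
        r_squared=max(0.0, min(1.0, r2)),
        n_points=n,
        method="linear",
        residuals=tuple(float(r) for r in resid),
        pKa_mixed=pKa_mixed,
        I_median=I_med,
    )


def fit_nonlinear(
    points: Sequence[SlicePoint],
    analyte_dz2: int = -1,
    A: float = A_DEBYE,
) -> FitResult:
    """Nonlinear least squares of kappa = C*Ka/(Ka + aH) over (Ka, C).

    Initial guesses come from :func:`fit_linear` when it succeeds, otherwise
    from (median aH, max kappa).  Confidence intervals are 95% t-intervals
    from the parameter covariance at the optimum.
    """
    x, kap, I_med = _extract(points, analyte_dz2, A)
    n = x.size

    try:
        lin = fit_linear(points, analyte_dz2, A)
        Ka_init = 10.0 ** (-lin.pKa0_fit)
        C_init = lin.C_analyte_fit
    except (UnphysicalFitError, NoTitrationError):
        Ka_init = float(np.median(x))
        C_init = float(kap.max())

    def model(x: np.ndarray, Ka: float, C: float) -> np.ndarray:
        return C * Ka / (Ka + x)

    try:
        popt, pcov = optimize.curve_fit(
            model, x, kap, p0=[Ka_init, C_init], maxfev=20000, absolute_sigma=False
        )
    except RuntimeError as exc:
        raise NoTitrationError(f"nonlinear fit did not converge: {exc}") from exc
    Ka, C = float(popt[0]), float(popt[1])
    if Ka <= 0 or C <= 0:
        raise UnphysicalFitError(f"nonlinear optimum unphysical: Ka={Ka:.3g}, C={C:.3g}")

    resid = kap - model(x, *popt)
    # flat model: Ka indistinguishable from infinity -> no titration signal
    ss_tot = float(((kap - kap.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    if ss_tot <= 0 or not np.all(np.isfinite(pcov)):
        raise NoTitrationError(
            "kappa shows no pH dependence; cannot determine a pKa"
        )

    dof = n - 2
    tcrit = float(stats.t.ppf(0.975, dof)) if dof > 0 else math.inf
    var_Ka = float(pcov[0, 0])
    var_C = float(pcov[1, 1])
    var_pKa = var_Ka / (Ka * math.log(10.0)) ** 2

    pKa0 = -math.log10(Ka)
    pKa_mixed = pKa0 + analyte_dz2 * A * davies_f(I_med)
    r2 = 1.0 - ss_res / ss_tot

    return FitResult(
        pKa0_fit=pKa0,
        C_analyte_fit=C,
        ci95_pKa=tcrit * math.sqrt(max(var_pKa, 0.0)),
        ci95_C=tcrit * math.sqrt(max(var_C, 0.0)),
        r_squared=max(0.0, min(1.0, r2)),
        n_points=n,
        method="nonlinear",
        residuals=tuple(float(r) for r in resid),
        pKa_mixed=pKa_mixed,
        I_median=I_med,
    )


def protein_molarity(mass_conc: float, mw: float) -> float:
    """Molar concentration from mass concentration (mg/mL == g/L) and MW (Da)."""
    if mass_conc <= 0 or mw <= 0:
        raise DomainError(
            f"mass_conc and mw must be positive (got {mass_conc}, {mw})"
        )
    return mass_conc / mw


class SitesPerMolecule(NamedTuple):
    value: float
    ci95: float


def sites_per_molecule(
    C_analyte: float, protein_molar: float, ci95_C: float = 0.0
) -> SitesPerMolecule:
    """Acidic sites per molecule: fitted acidic-group concentration over
    protein molarity, with the C_analyte confidence interval propagated.

    The value is returned unrounded; rounding to a whole number of sites is
    presentation, not computation.
    """
    if C_analyte <= 0 or protein_molar <= 0:
        raise DomainError(
            f"C_analyte and protein molarity must be positive "
            f"(got {C_analyte}, {protein_molar})"
        )
    return SitesPerMolecule(
        value=C_analyte / protein_molar, ci95=ci95_C / protein_molar
    )
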