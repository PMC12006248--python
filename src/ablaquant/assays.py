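"""Standard-curve quantification for qPCR and ELISA.

qPCR transcript abundance is read off a per-plate log-linear standard curve
(Cq versus log10 template quantity); the curve is usable only when R^2
exceeds 0.9, amplification efficiency is ``10^(-1/slope) - 1`` (a perfect
doubling per cycle gives slope -1/log10(2) = -3.3219), and target abundance
is normalized to the R18S housekeeping abundance of the same sample.

ELISA concentrations are interpolated from a four-parameter logistic (4PL)
standard curve and reported as pg of analyte per mg of source tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (FitError, GatedFitError, InsufficientStandardsError,
                     NormalizationError, OutOfRangeError)

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "FourPLFit",
    "SampleQuant",
    "fit_standard_curve",
    "quantify_qpcr",
    "fit_4pl",
    "invert_4pl",
    "normalize_per_mg",
    "QPCR_STANDARD_CONCENTRATIONS",
]

# default 7-point RNA dilution series (ug/ul) replicated on each plate
QPCR_STANDARD_CONCENTRATIONS = (2000.0, 1000.0, 500.0, 250.0, 125.0,
                                61.25, 31.125)

R_SQUARED_GATE = 0.9


@dataclass(frozen=True)
class DilutionSeries:
    """Calibration points: concentrations with measured responses."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != len(self.responses):
            raise InsufficientStandardsError(
                "concentrations and responses differ in length")
        if np.any(c <= 0):
            raise InsufficientStandardsError("concentrations must be positive")
        if not np.all(np.diff(c) < 0):
            raise InsufficientStandardsError(
                "concentrations must be strictly decreasing")


@dataclass(frozen=True)
class StandardCurveFit:
    """Log-linear qPCR calibration: Cq = slope * log10(conc) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def usable(self) -> bool:
        return self.r_squared > R_SQUARED_GATE

    def quantity(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass(frozen=True)
class FourPLFit:
    """4PL calibration y = d + (a - d) / (1 + (x / c)^b).

    ``a`` is the zero-dose asymptote, ``d`` the infinite-dose asymptote,
    ``c`` the inflection (EC50) and ``b`` the Hill slope.
    """

    a: float
    b: float
    c: float
    d: float
    rss: float

    def response(self, x):
        x = np.asarray(x, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)


@dataclass(frozen=True)
class SampleQuant:
    raw: float
    normalized: float | None
    flags: tuple[str, ...] = ()


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Least-squares line of response (Cq) against log10 concentration."""
    if len(series.concentrations) < 3:
        raise InsufficientStandardsError("need at least 3 standard points")
    x = np.log10(series.concentrations)
    y = np.asarray(series.responses, dtype=float)
    res = stats.linregress(x, y)
    return StandardCurveFit(float(res.slope), float(res.intercept),
                            float(res.rvalue) ** 2)


def quantify_qpcr(sample_cq: float, fit: StandardCurveFit,
                  reference_quantity: float | None = None,
                  standard_range: tuple[float, float] | None = None
                  ) -> SampleQuant:
    """Template quantity from a sample Cq, normalized to a reference.

    The fit must have passed the R^2 > 0.9 gate.  ``reference_quantity`` is
    the housekeeping (R18S) abundance of the same sample; pass None to skip
    normalization.  Samples whose Cq falls outside the standards' response
    range are flagged as extrapolated.
    """
    if not fit.usable:
        raise GatedFitError(
            f"standard curve R^2 = {fit.r_squared:.4f} fails the "
            f"> {R_SQUARED_GATE} usability gate")
    raw = fit.quantity(sample_cq)
    flags = []
    if standard_range is not None:
        lo, hi = sorted(standard_range)
        if not (lo <= sample_cq <= hi):
            flags.append("outside_standard_range")
    normalized = None
    if reference_quantity is not None:
        if not reference_quantity > 0 or math.isnan(reference_quantity):
            raise NormalizationError("reference abundance must be positive")
        normalized = raw / reference_quantity
    return SampleQuant(float(raw), normalized, tuple(flags))


def _fourpl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(series: DilutionSeries, weighting: str = "uniform") -> FourPLFit:
    """Nonlinear least-squares 4PL fit with heuristic initialization.

    Asymptotes start at the extreme responses, the inflection at the
    concentration whose response is nearest the midpoint, and the Hill
    slope sign from the response trend.  ``weighting`` may be "uniform" or
    "1/y^2" (inverse-variance for signals with constant CV).
    """
    x = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    if len(x) < 5:
        raise InsufficientStandardsError("need at least 5 points for a 4PL fit")
    # x is strictly decreasing: y[-1] is the low-dose response
    a0, d0 = y[-1], y[0]
    mid = (a0 + d0) / 2.0
    c0 = x[np.argmin(np.abs(y - mid))]
    b0 = 1.0 if d0 > a0 else -1.0
    sigma = None if weighting == "uniform" else np.abs(y) + 1e-12
    try:
        popt, _ = optimize.curve_fit(
            _fourpl, x, y, p0=(a0, b0, c0, d0), sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)) or popt[2] <= 0:
        raise FitError(f"4PL fit produced invalid parameters {popt}")
    rss = float(np.sum((y - _fourpl(x, *popt)) ** 2))
    return FourPLFit(float(popt[0]), float(popt[1]), float(popt[2]),
                     float(popt[3]), rss)


def invert_4pl(signal: float, fit: FourPLFit) -> SampleQuant:
    """Concentration for a measured signal via the closed-form 4PL inverse.

    Signals at or beyond the asymptotes have no finite inverse and come
    back flagged with a NaN concentration.
    """
    lo, hi = sorted((fit.a, fit.d))
    if not (lo < signal < hi):
        return SampleQuant(float("nan"), None, ("outside_asymptotes",))
    x = fit.c * ((fit.a - fit.d) / (signal - fit.d) - 1.0) ** (1.0 / fit.b)
    return SampleQuant(float(x), None, ())


def normalize_per_mg(concentration_pg_per_ml: float, eluate_volume_ml: float,
                     tissue_mass_mg: float) -> float:
    """pg analyte per mg tissue: concentration x eluate volume / mass."""
    if tissue_mass_mg <= 0:
        raise NormalizationError("tissue mass must be positive")
    if eluate_volume_ml <= 0:
        raise NormalizationError("eluate volume must be positive")
    if concentration_pg_per_ml < 0 or math.isnan(concentration_pg_per_ml):
        raise OutOfRangeError("concentration must be a non-negative number")
    return concentration_pg_per_ml * eluate_volume_ml / tissue_mass_mg
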