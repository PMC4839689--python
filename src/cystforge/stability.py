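"""Enzyme stability and kinetics arithmetic.

Fits and comparisons for the standard stability measures of an
engineered enzyme: first-order thermal-inactivation half-life (t1/2),
half-inactivation temperature (T50) by interpolation, optimal
temperature/pH profile normalization, Michaelis-Menten parameters via
the Lineweaver-Burk double-reciprocal fit, and percent/difference
comparisons of measured quantities (Tm, ΔG, half-lives).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AssaySeries",
    "StabilityResult",
    "ThermoRecord",
    "KineticsResult",
    "ProfileResult",
    "Comparison",
    "fit_half_life",
    "crossing_half_life",
    "interpolate_T50",
    "normalize_profile",
    "fit_lineweaver_burk",
    "compare",
]

ASSAY_KINDS = (
    "inactivation_time",
    "thermal_T50",
    "profile_temperature",
    "profile_pH",
    "kinetics_substrate",
)


@dataclass
class AssaySeries:
    """One assay curve: x (min | °C | pH | substrate conc) vs activity."""

    kind: str
    x: np.ndarray
    y: np.ndarray
    replicates: np.ndarray | None = None  # per-point spread (sd), optional
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.kind!r}")
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x values must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError("activities must be non-negative")


@dataclass
class StabilityResult:
    """Fitted kinetic-stability parameters; t_half = ln2 / k_inact."""

    t_half: float | None = None  # min
    k_inact: float | None = None  # 1/min
    T50: float | None = None  # °C
    fit_r2: float | None = None


@dataclass
class ThermoRecord:
    """DSC-measured thermodynamic parameters (inputs, not fitted here)."""

    label: str
    Tm: float  # °C
    dH: float  # kcal/mol
    dG: float  # kcal/mol


@dataclass
class KineticsResult:
    Km: float  # same units as substrate axis (conventionally μM)
    Vmax: float  # rate units of the input
    kcat: float | None = None  # 1/s, requires enzyme concentration
    kcat_over_Km: float | None = None  # 1/(s·mM) when Km is in μM
    fit_r2: float | None = None


@dataclass
class ProfileResult:
    series: AssaySeries  # normalized to max 100
    optimum: float  # x at maximum activity
    tied: bool  # True when the maximum was not unique


@dataclass
class Comparison:
    label_a: str
    label_b: str
    mode: str
    value_a: float
    value_b: float
    value: float  # percent change (1-decimal) or plain difference


def fit_half_life(series: AssaySeries) -> StabilityResult:
    """Half-life from a first-order inactivation fit.

    Fits a(t) = a0 * exp(-k t) by linear regression on log-activity and
    reports t1/2 = ln 2 / k. Zero-activity points cannot enter the log
    fit and are dropped with a warning. A non-decaying series (k <= 0)
    is an error.
    """
    if series.kind != "inactivation_time":
        raise ValueError("fit_half_life expects an inactivation_time series")
    keep = series.y > 0
    if not np.all(keep):
        warnings.warn("zero-activity points excluded from log-linear fit")
    t = series.x[keep]
    a = series.y[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 positive-activity points")
    res = stats.linregress(t, np.log(a))
    k = -res.slope
    if k <= 0:
        raise ValueError("no inactivation: activity does not decay")
    return StabilityResult(
        t_half=math.log(2) / k,
        k_inact=k,
        fit_r2=float(res.rvalue**2),
    )


def crossing_half_life(series: AssaySeries) -> float:
    """Half-life as the interpolated time of the 50%-of-initial crossing.

    Provided for comparison with :func:`fit_half_life`; for clean
    first-order decay the two coincide.
    """
    if series.kind != "inactivation_time":
        raise ValueError("crossing_half_life expects an inactivation_time series")
    target = series.y[0] / 2.0
    y = series.y
    for i in range(len(y) - 1):
        if y[i] >= target >= y[i + 1]:
            if y[i] == y[i + 1]:
                return float(series.x[i])
            frac = (y[i] - target) / (y[i] - y[i + 1])
            return float(series.x[i] + frac * (series.x[i + 1] - series.x[i]))
    raise ValueError("activity never falls to half of its initial value")


def _as_fraction(y: np.ndarray) -> np.ndarray:
    # residual activity given either as fraction or percent
    return y / 100.0 if np.max(y) > 1.5 else y


def interpolate_T50(series: AssaySeries, control: float | None = None) -> float:
    """Half-inactivation temperature by linear interpolation.

    The series holds residual activity after a fixed incubation at each
    temperature. With ``control`` (the untreated activity) the series is
    normalized by it; otherwise values are taken as fractions, or as
    percent when they exceed 1.5. T50 is the temperature of the first
    downward crossing of 50% residual activity; a non-monotone
    neighborhood triggers a warning and the first crossing is used.
    """
    if series.kind != "thermal_T50":
        raise ValueError("interpolate_T50 expects a thermal_T50 series")
    if control is not None:
        if control <= 0:
            raise ValueError("control activity must be positive")
        y = series.y / control
    else:
        y = _as_fraction(series.y)
    x = series.x
    if np.any(np.diff(y) > 0):
        warnings.warn("residual-activity series is not monotone; first crossing used")
    exact = np.where(np.isclose(y, 0.5))[0]
    for i in range(len(y) - 1):
        if np.isclose(y[i], 0.5):
            return float(x[i])
        if y[i] > 0.5 > y[i + 1]:
            frac = (y[i] - 0.5) / (y[i] - y[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    if len(exact) and exact[-1] == len(y) - 1:
        return float(x[-1])
    raise ValueError("residual activity never crosses 50%")


def normalize_profile(series: AssaySeries) -> ProfileResult:
    """Scale a temperature/pH activity profile so its maximum is 100%.

    Returns the scaled series plus the optimum (x at the maximum); a tie
    resolves to the lower x and is flagged.
    """
    if series.kind not in ("profile_temperature", "profile_pH"):
        raise ValueError("normalize_profile expects a profile_* series")
    if len(series.y) < 2:
        raise ValueError("need at least 2 points")
    ymax = float(np.max(series.y))
    if ymax == 0:
        raise ValueError("all-zero activities cannot be normalized")
    scaled = series.y * (100.0 / ymax)
    at_max = np.where(np.isclose(scaled, 100.0))[0]
    return ProfileResult(
        series=AssaySeries(series.kind, series.x, scaled, series.replicates, series.label),
        optimum=float(series.x[at_max[0]]),
        tied=len(at_max) > 1,
    )


def fit_lineweaver_burk(
    series: AssaySeries,
    enzyme_conc: float | None = None,
    km_to_mM: float = 1e-3,
) -> KineticsResult:
    """Km and Vmax by the Lineweaver-Burk double-reciprocal fit.

    A least-squares line on (1/[S], 1/v) gives Km = slope/intercept and
    Vmax = 1/intercept. With an enzyme concentration (same molar units
    as Vmax's numerator per time), kcat = Vmax/[E] and the specificity
    constant kcat/Km is also reported, with Km converted by ``km_to_mM``
    (default treats the substrate axis as μM and reports 1/(s·mM)).
    """
    if series.kind != "kinetics_substrate":
        raise ValueError("fit_lineweaver_burk expects a kinetics_substrate series")
    s = series.x
    v = series.y
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("substrate concentrations and rates must be positive")
    if len(s) < 3:
        raise ValueError("need at least 3 substrate concentrations")
    res = stats.linregress(1.0 / s, 1.0 / v)
    if res.intercept <= 0:
        raise ValueError("non-saturable data: double-reciprocal intercept <= 0")
    km = res.slope / res.intercept
    vmax = 1.0 / res.intercept
    kcat = None
    kcat_over_km = None
    if enzyme_conc is not None:
        if enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        kcat = vmax / enzyme_conc
        kcat_over_km = kcat / (km * km_to_mM)
    return KineticsResult(
        Km=float(km),
        Vmax=float(vmax),
        kcat=kcat,
        kcat_over_Km=kcat_over_km,
        fit_r2=float(res.rvalue**2),
    )


def compare(
    label_a: str,
    value_a: float,
    label_b: str,
    value_b: float,
    mode: str = "percent",
) -> Comparison:
    """Change of b relative to a: percent (1-decimal) or plain difference."""
    if not (math.isfinite(value_a) and math.isfinite(value_b)):
        raise ValueError("values must be finite")
    if mode == "percent":
        if value_a == 0:
            raise ValueError("zero baseline: percent change undefined")
        value = round(100.0 * (value_b - value_a) / value_a, 1)
    elif mode == "difference":
        value = value_b - value_a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Comparison(label_a, label_b, mode, value_a, value_b, value)
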