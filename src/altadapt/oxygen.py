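"""Hemoglobin oxygen-equilibrium analytics.

Hill plots linearise an O2 equilibrium curve as
log10(Y / (1 - Y)) versus log10(PO2): the slope at half saturation is the
cooperativity coefficient n50 and the x-intercept gives log10(P50), the
partial pressure at half saturation (lower P50 = higher O2 affinity).

From P50 values measured under different conditions the module derives

* the Bohr factor  Phi = d log10(P50) / d pH  (negative under the normal
  alkaline Bohr effect), and
* the Van't Hoff oxygenation enthalpy
  dH = 2.303 R * d log10(P50) / d(1/T)  with R = 8.314 J/mol/K and T in
  kelvin, plus dH' corrected by removing the heat of O2 dissolution
  (-12.6 kJ/mol O2), so dH' = dH + 12.6 kJ/mol identically.

Group comparisons (haplotype A vs B hemolysates) summarise replicate P50
fits as mean +/- SEM and test the difference with Welch's two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import OxygenEquilibriumCurve

__all__ = [
    "GAS_CONSTANT_R",
    "O2_SOLUTION_HEAT",
    "HillFit",
    "OxygenationThermo",
    "hill_transform",
    "fit_hill",
    "bohr_factor",
    "vant_hoff_enthalpy",
    "compare_haplotypes",
]

GAS_CONSTANT_R = 8.314  # J / mol / K
O2_SOLUTION_HEAT = -12_600.0  # J / mol O2, heat of O2 in solution
KELVIN_OFFSET = 273.15
SATURATION_WINDOW = (0.05, 0.95)  # linear Hill-plot region used for fitting


@dataclass(frozen=True)
class HillFit:
    """Hill-plot line fit for one curve under one condition."""

    P50: float
    n50: float
    r2: float
    ph: float = 7.4
    temp_c: float = 37.0
    condition: str = "stripped"
    n_points: int = 0


@dataclass(frozen=True)
class OxygenationThermo:
    """Van't Hoff oxygenation enthalpy, raw and solution-heat corrected."""

    delta_H: float  # J / mol O2
    delta_H_prime: float  # J / mol O2, = delta_H - O2_SOLUTION_HEAT


def hill_transform(Y):
    """Hill-plot ordinate log10(Y / (1 - Y)); Y must lie strictly in (0, 1)."""
    Y = np.asarray(Y, dtype=float)
    if np.any(Y <= 0) or np.any(Y >= 1):
        raise ValueError("saturation must be strictly inside (0, 1)")
    out = np.log10(Y / (1 - Y))
    return float(out) if out.ndim == 0 else out


def fit_hill(
    curve: OxygenEquilibriumCurve,
    saturation_window: tuple[float, float] = SATURATION_WINDOW,
) -> HillFit:
    """Least-squares Hill-plot line; n50 from the slope, P50 from the x-intercept.

    Points outside ``saturation_window`` are dropped before fitting (the
    Hill plot is linear only around half saturation); at least three points
    must remain.
    """
    lo, hi = saturation_window
    y = np.asarray(curve.saturation, dtype=float)
    po2 = np.asarray(curve.po2_torr, dtype=float)
    keep = (y > lo) & (y < hi)
    y, po2 = y[keep], po2[keep]
    if y.size < 3:
        raise ValueError("need >= 3 points inside the saturation window")
    x = np.log10(po2)
    if np.ptp(x) <= 0:
        raise ValueError("degenerate PO2 range")
    fit = stats.linregress(x, hill_transform(y))
    if fit.slope <= 0:
        raise ValueError("non-positive Hill slope; curve not fittable")
    p50 = 10 ** (-fit.intercept / fit.slope)
    return HillFit(
        float(p50),
        float(fit.slope),
        float(fit.rvalue**2),
        ph=curve.ph,
        temp_c=curve.temp_c,
        condition=curve.condition,
        n_points=int(y.size),
    )


def bohr_factor(fit_a: HillFit, fit_b: HillFit) -> float:
    """Bohr factor Phi = delta log10(P50) / delta pH between two fits.

    The two fits must share temperature and cofactor condition and differ
    in pH; ordering is normalised internally so the result is independent
    of argument order.
    """
    if fit_a.ph == fit_b.ph:
        raise ValueError("fits must be at distinct pH")
    if fit_a.temp_c != fit_b.temp_c or fit_a.condition != fit_b.condition:
        raise ValueError("fits must share temperature and cofactor condition")
    lo, hi = sorted((fit_a, fit_b), key=lambda f: f.ph)
    return (np.log10(hi.P50) - np.log10(lo.P50)) / (hi.ph - lo.ph)


def vant_hoff_enthalpy(fit_a: HillFit, fit_b: HillFit) -> OxygenationThermo:
    """Van't Hoff oxygenation enthalpy from P50 at two temperatures.

    dH = 2.303 R * [log10 P50(T2) - log10 P50(T1)] / (1/T2 - 1/T1) with
    T2 > T1 in kelvin; invariant to argument order.  dH' additionally
    removes the heat of O2 dissolution.
    """
    if fit_a.temp_c == fit_b.temp_c:
        raise ValueError("fits must be at distinct temperatures")
    if fit_a.ph != fit_b.ph or fit_a.condition != fit_b.condition:
        raise ValueError("fits must share pH and cofactor condition")
    lo, hi = sorted((fit_a, fit_b), key=lambda f: f.temp_c)
    t1 = lo.temp_c + KELVIN_OFFSET
    t2 = hi.temp_c + KELVIN_OFFSET
    dH = (
        2.303
        * GAS_CONSTANT_R
        * (np.log10(hi.P50) - np.log10(lo.P50))
        / (1.0 / t2 - 1.0 / t1)
    )
    return OxygenationThermo(float(dH), float(dH - O2_SOLUTION_HEAT))


def compare_haplotypes(fits_a: list[HillFit], fits_b: list[HillFit]) -> dict:
    """Replicate-level P50 comparison between two hemoglobin groups.

    Returns per-group mean and SEM of P50 and a Welch two-sample p value.
    Degenerate cases follow fixed conventions: identical replicate sets
    give p = 1; zero within-group variance with distinct means is exact
    separation, flagged and reported with p = 0.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need >= 2 replicate fits per group for a SEM")
    a = np.array([f.P50 for f in fits_a], dtype=float)
    b = np.array([f.P50 for f in fits_b], dtype=float)
    out = {
        "mean_a": float(a.mean()),
        "sem_a": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_b": float(b.mean()),
        "sem_b": float(b.std(ddof=1) / np.sqrt(b.size)),
        "difference": float(a.mean() - b.mean()),
        "exact_separation": False,
    }
    if a.size == b.size and np.allclose(np.sort(a), np.sort(b)):
        out["p"] = 1.0
        return out
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        out["exact_separation"] = a.mean() != b.mean()
        out["p"] = 0.0 if out["exact_separation"] else 1.0
        return out
    out["p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return out
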