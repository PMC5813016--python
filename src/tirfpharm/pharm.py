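"""Receptor pharmacology toolkit.

Covers the calculation layer of an agonist characterization campaign:

* HTRF-ratio -> cAMP interpolation through a monotone 4PL standard curve
  (inverted analytically; out-of-range ratios are flagged, never silently
  extrapolated).
* Four-parameter logistic (4PL) dose-response fits on log10 concentration,
  r = bottom + (top - bottom) / (1 + (EC50/c)^hill),
  giving EC50, the fitted maximum asymptote, and derived statistics.
* Percent efficacy (Emax as % of the plate's saturating full-agonist
  control), percent desensitization (percent decrease in challenge-evoked
  cAMP vs vehicle pretreatment), and delta-potency EC50(mut)/EC50(wt).
* Cheng-Prusoff Ki = IC50 / (1 + L/Kd) for competition binding,
  apparent Kb = IC50 / (1 + [A]/EC50_A) for functional antagonism, and
  receptor occupancy RO% = 100 * C / (C + Ki) at unbound brain
  concentration C = C_brain,total * fu,b.
* PK-driven occupancy profiles and an occupancy-matched dose scaler used
  to normalize two compounds with different Ki and kinetics to the same
  mean occupancy over a dosing interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .synthetic import four_pl

__all__ = [
    "FourPLFit",
    "StandardCurve",
    "InterpolationResult",
    "PotencyShift",
    "OccupancyPoint",
    "fit_4pl",
    "interpolate_camp",
    "percent_efficacy",
    "percent_desensitization",
    "delta_potency",
    "cheng_prusoff_ki",
    "apparent_kb",
    "receptor_occupancy",
    "occupancy_profile",
    "match_occupancy_dose",
]


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n_points: int
    status: str = "ok"          # ok | no_response | failed
    message: str = ""

    def predict(self, conc):
        return four_pl(conc, self.bottom, self.top, self.ec50, self.hill)


def _init_4pl(logc: np.ndarray, resp: np.ndarray) -> np.ndarray:
    bottom = float(resp.min())
    top = float(resp.max())
    half = 0.5 * (bottom + top)
    ec50_log = float(logc[np.argmin(np.abs(resp - half))])
    return np.array([bottom, top, ec50_log, 1.0])


def fit_4pl(conc, response) -> FourPLFit:
    """Least-squares 4PL fit on log10 concentration.

    Deterministic: initialization is bottom=min, top=max, EC50 at the
    concentration whose response is nearest half-range, hill=1; the hill
    slope is bounded to [0.1, 10].  Flat data are flagged "no_response"
    rather than fitted.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("conc and response must have the same shape")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    logc = np.log10(conc)

    span = resp.max() - resp.min()
    scale = max(abs(resp.max()), abs(resp.min()), 1e-12)
    if span <= 1e-6 * scale:
        return FourPLFit(float(resp.mean()), float(resp.mean()),
                         float("nan"), float("nan"), 0.0, conc.size,
                         status="no_response",
                         message="response is flat across concentrations")

    def residuals(p):
        bottom, top, logec50, hill = p
        pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logec50 - logc)))
        return pred - resp

    p0 = _init_4pl(logc, resp)
    lb = [-np.inf, -np.inf, logc.min() - 6.0, 0.1]
    ub = [np.inf, np.inf, logc.max() + 6.0, 10.0]
    sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        return FourPLFit(*p0[:2], 10.0 ** p0[2], p0[3], float(np.inf),
                         conc.size, status="failed", message=sol.message)
    bottom, top, logec50, hill = sol.x
    return FourPLFit(float(bottom), float(top), float(10.0 ** logec50),
                     float(hill), float(2.0 * sol.cost), int(conc.size))


# ---------------------------------------------------------------------------
# standard-curve calibration
# ---------------------------------------------------------------------------

@dataclass
class InterpolationResult:
    conc_nM: float
    in_range: bool


class StandardCurve:
    """Monotone 4PL calibration of HTRF ratio against known cAMP.

    Fitted as ratio = 4PL(conc) on log10 concentration (the HTRF
    competitive immunoassay gives ratios monotone in cAMP — decreasing
    for the physical assay, but either direction is accepted) and
    inverted analytically for interpolation.
    """

    def __init__(self, conc_nM, ratios):
        conc = np.asarray(conc_nM, dtype=float)
        ratio = np.asarray(ratios, dtype=float)
        if conc.size < 4:
            raise ValueError("standard curve needs at least 4 points")
        order = np.argsort(conc)
        conc, ratio = conc[order], ratio[order]
        d = np.diff(ratio)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("ratios must be strictly monotone in concentration")
        self.conc_nM = conc
        self.ratios = ratio
        self.fit = fit_4pl(conc, ratio)
        if self.fit.status != "ok":
            raise ValueError(f"calibration fit failed: {self.fit.message}")
        self._rmin = float(min(ratio.min(), ratio.max()))
        self._rlo, self._rhi = float(ratio.min()), float(ratio.max())

    def ratio_of(self, conc_nM: float) -> float:
        return float(self.fit.predict(conc_nM))

    def conc_of(self, ratio: float) -> InterpolationResult:
        f = self.fit
        in_range = self._rlo <= ratio <= self._rhi
        # invert r = b + (t-b)/(1+(ec50/c)^h)  =>  c = ec50 / x^(1/h),
        # x = (t-r)/(r-b)
        num = f.top - ratio
        den = ratio - f.bottom
        if num * den <= 0:  # outside the fitted asymptotes: no inverse
            return InterpolationResult(float("nan"), False)
        x = num / den
        conc = f.ec50 / x ** (1.0 / f.hill)
        return InterpolationResult(float(conc), bool(in_range))


def interpolate_camp(curve: StandardCurve, ratio: float) -> InterpolationResult:
    """Invert the fitted calibration; flags out-of-range ratios."""
    return curve.conc_of(ratio)


# ---------------------------------------------------------------------------
# scalar receptor math
# ---------------------------------------------------------------------------

@dataclass
class PotencyShift:
    compound_id: str
    ec50_wt: float
    ec50_mut: float

    @property
    def delta_potency(self) -> float:
        return self.ec50_mut / self.ec50_wt


def percent_efficacy(fit: FourPLFit, positive_control_response: float) -> float:
    """Emax% = 100 * fitted top asymptote / full-agonist control response."""
    if positive_control_response <= 0:
        raise ValueError("positive control response must be positive")
    return 100.0 * fit.top / positive_control_response


def percent_desensitization(treated_camp: float, vehicle_camp: float) -> float:
    """Percent decrease in challenge-evoked cAMP vs vehicle pretreatment.

    Negative values (sensitization) are preserved, not clipped.
    """
    if vehicle_camp <= 0:
        raise ValueError("vehicle cAMP must be positive")
    return 100.0 * (vehicle_camp - treated_camp) / vehicle_camp


def delta_potency(ec50_mut: float, ec50_wt: float,
                  compound_id: str = "") -> PotencyShift:
    """EC50(mutant)/EC50(wild type); > 1 means the mutation impairs potency."""
    if ec50_mut <= 0 or ec50_wt <= 0:
        raise ValueError("EC50 values must be positive")
    return PotencyShift(compound_id, ec50_wt=ec50_wt, ec50_mut=ec50_mut)


def cheng_prusoff_ki(ic50: float, radioligand_conc: float, kd: float) -> float:
    """Ki = IC50 / (1 + L/Kd)."""
    if min(ic50, radioligand_conc, kd) <= 0:
        raise ValueError("all inputs must be positive")
    return ic50 / (1.0 + radioligand_conc / kd)


def apparent_kb(ic50: float, agonist_conc: float, agonist_ec50: float) -> float:
    """Apparent Kb = IC50 / (1 + [A]/EC50_A) for functional antagonism."""
    if min(ic50, agonist_conc, agonist_ec50) <= 0:
        raise ValueError("all inputs must be positive")
    return ic50 / (1.0 + agonist_conc / agonist_ec50)


def receptor_occupancy(c_b_u: float, ki: float) -> float:
    """RO% = 100 * C / (C + Ki) at unbound brain concentration C."""
    if ki <= 0:
        raise ValueError("Ki must be positive")
    c = np.asarray(c_b_u, dtype=float)
    if (c < 0).any():
        raise ValueError("concentration must be nonnegative")
    out = 100.0 * c / (c + ki)
    return float(out) if np.isscalar(c_b_u) or c.ndim == 0 else out


# ---------------------------------------------------------------------------
# occupancy over a PK profile
# ---------------------------------------------------------------------------

@dataclass
class OccupancyPoint:
    time_h: float
    c_b_total: float
    fu_b: float
    ki: float

    @property
    def c_b_u(self) -> float:
        return self.c_b_total * self.fu_b

    @property
    def ro_percent(self) -> float:
        return receptor_occupancy(self.c_b_u, self.ki)


def occupancy_profile(pk: pd.DataFrame, fu_b: float, ki: float,
                      threshold_percent: float | None = None
                      ) -> tuple[pd.DataFrame, float | None]:
    """Per-timepoint occupancy from a (time_h, c_total_brain_nM) table.

    Returns the augmented table and, when ``threshold_percent`` is given,
    the (time-weighted, trapezoid-rule) fraction of the profiled interval
    at or above that occupancy.
    """
    if pk.empty:
        raise ValueError("PK table is empty")
    if not (0 < fu_b <= 1):
        raise ValueError("fu_b must lie in (0, 1]")
    if ki <= 0:
        raise ValueError("Ki must be positive")
    out = pk.copy()
    out["c_b_u_nM"] = out["c_total_brain_nM"] * fu_b
    out["ro_percent"] = 100.0 * out["c_b_u_nM"] / (out["c_b_u_nM"] + ki)
    frac = None
    if threshold_percent is not None:
        t = out["time_h"].to_numpy()
        above = (out["ro_percent"].to_numpy() >= threshold_percent).astype(float)
        if t.size > 1:
            frac = float(np.trapezoid(above, t) / (t[-1] - t[0]))
        else:
            frac = float(above[0])
    return out, frac


def _mean_ro(pk: pd.DataFrame, fu_b: float, ki: float, scale: float) -> float:
    t = pk["time_h"].to_numpy()
    c = pk["c_total_brain_nM"].to_numpy() * fu_b * scale
    ro = 100.0 * c / (c + ki)
    if t.size > 1:
        return float(np.trapezoid(ro, t) / (t[-1] - t[0]))
    return float(ro[0])


def match_occupancy_dose(pk_ref: pd.DataFrame, fu_b_ref: float, ki_ref: float,
                         pk_test: pd.DataFrame, fu_b_test: float,
                         ki_test: float) -> float:
    """Dose scaler for the test compound matching the reference's mean RO.

    Because a one-compartment profile is linear in dose, multiplying the
    test concentrations by the returned scaler equates the two compounds'
    time-averaged occupancy over their profiled intervals — the
    normalization used to compare compounds with different Ki and
    kinetics at equal target engagement.
    """
    target = _mean_ro(pk_ref, fu_b_ref, ki_ref, 1.0)
    if not (0 < target < 100):
        raise ValueError("reference profile gives a degenerate mean occupancy")
    if (pk_test["c_total_brain_nM"] <= 0).all():
        raise ValueError("test profile has no positive concentrations")

    def f(log_s):
        return _mean_ro(pk_test, fu_b_test, ki_test, 10.0 ** log_s) - target

    lo, hi = -8.0, 8.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("no dose scaler in [1e-8, 1e8] matches the target")
    return float(10.0 ** brentq(f, lo, hi, xtol=1e-12))
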