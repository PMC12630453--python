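"""Variable-J estimation of mesophyll conductance and FvCB parameters.

The estimation chain follows the standard combined gas-exchange +
fluorescence workflow:

1. *Calibration* of the fluorescence-to-electron-transport scaling ``s``
   and day respiration ``RL`` from a low-O2, high-CO2 light-response series
   (Yin method): OLS of An on Qin * ((Fm'-F')/Fm') / 4 gives s as the slope
   and -RL as the intercept.
2. The *apparent* photorespiratory compensation point ``ci*`` from low-ca
   An-ci curves at several sub-saturating lights via the slope-intercept
   regression (Laisk / Walker-Ort): fit An = a_k + b_k ci per light, then
   a = alpha + beta b across lights; ci* = -beta, RL = -alpha.
3. Per record, J = Qin s (Fm'-F')/Fm', the Harley variable-J inversion
   cc = G* (J + 8(An+RL)) / (J - 4(An+RL)), and Fick's law
   gm = An / (ci - cc).
4. ``G*`` either fixed (default 42.5 umol mol-1) or iterated to the fixed
   point of G* = ci* + RL / gm with gm aggregated over valid records.
5. Vcmax as the slope of An against (cc-G*)/(cc + Kc(1+O/Ko)).

Kinetic constants (Kc, Ko, O) carry no package defaults; they are part of
the user's configuration, as they depend on temperature and species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticConstants",
    "CalibrationResult",
    "ConductanceEstimate",
    "VcmaxFit",
    "gsc_from_gsw",
    "yin_calibrate",
    "electron_transport",
    "laisk_ci_star",
    "chloroplast_co2",
    "mesophyll_conductance_point",
    "estimate_gm",
    "fit_vcmax",
]


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco Michaelis constants and oxygen mole fraction.

    kc in umol mol-1, ko and o2 in mmol mol-1.
    """

    kc: float
    ko: float
    o2: float

    def __post_init__(self) -> None:
        if min(self.kc, self.ko, self.o2) <= 0:
            raise ValueError("kinetic constants must be positive")

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc (1 + O/Ko), umol mol-1."""
        return self.kc * (1.0 + self.o2 / self.ko)


@dataclass
class CalibrationResult:
    s: float
    rl_yin: float
    ci_star: float | None = None
    rl_laisk: float | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ConductanceEstimate:
    per_record: pd.DataFrame       # columns j, cc, gm, gsc, valid
    gamma_star: float
    gm_mean: float
    iterations: int
    converged: bool
    n_invalid: int


@dataclass
class VcmaxFit:
    vcmax: float
    rl_fit: float
    r_squared: float
    warning: str | None = None


# ---------------------------------------------------------------------------
# elementary operations


def gsc_from_gsw(gsw):
    """Stomatal conductance to CO2: gsw / 1.6 (diffusivity ratio)."""
    gsw = np.asarray(gsw, dtype=float)
    if np.any(gsw < 0):
        raise ValueError("gsw must be non-negative")
    out = gsw / 1.6
    return float(out) if out.ndim == 0 else out


def electron_transport(records: pd.DataFrame, s: float) -> np.ndarray:
    """J = Qin * s * (Fm' - F')/Fm' per record."""
    fm, f = records["fmprime"].to_numpy(float), records["fprime"].to_numpy(float)
    if np.any(fm <= f):
        raise ValueError("Fm' must exceed F'")
    return records["qin"].to_numpy(float) * s * (fm - f) / fm


def yin_calibrate(records: pd.DataFrame) -> tuple[float, float]:
    """Calibrate (s, RL) from a low-O2 light-response series.

    OLS of An on x = Qin ((Fm'-F')/Fm')/4: the slope is the
    fluorescence-to-J scaling s, the intercept is -RL.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 light levels for the s/RL calibration")
    fm, f = records["fmprime"].to_numpy(float), records["fprime"].to_numpy(float)
    x = records["qin"].to_numpy(float) * (fm - f) / fm / 4.0
    y = records["an"].to_numpy(float)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate design: no variation in Qin*PSII yield")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(-intercept)


def laisk_ci_star(records: pd.DataFrame) -> tuple[float, float, dict]:
    """Apparent compensation point via the slope-intercept regression.

    Fits An = a_k + b_k ci for each light level k over the low-ca steps,
    then regresses a on b across lights: a = alpha + beta b. The common
    intersection of the lines sits at ci = -beta with An = alpha, so
    ci* = -beta and RL = -alpha.
    """
    lights = sorted(records["qin"].unique())
    if len(lights) < 3:
        raise ValueError("need >= 3 light levels for the ci* regression")
    slopes, intercepts = [], []
    for q in lights:
        sub = records[records["qin"] == q]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 ca steps at light {q}")
        b, a = np.polyfit(sub["ci"].to_numpy(float), sub["an"].to_numpy(float), 1)
        slopes.append(b)
        intercepts.append(a)
    slopes = np.asarray(slopes)
    intercepts = np.asarray(intercepts)
    if np.ptp(slopes) < 1e-12:
        raise ValueError("An-ci lines are parallel; intersection undefined")
    beta, alpha = np.polyfit(slopes, intercepts, 1)
    diags = {
        "per_light_slopes": slopes.tolist(),
        "per_light_intercepts": intercepts.tolist(),
    }
    return float(-beta), float(-alpha), diags


def chloroplast_co2(an, j, rl: float, gamma_star: float):
    """Harley variable-J inversion: cc = G*(J + 8(An+RL)) / (J - 4(An+RL)).

    Records with J <= 4(An+RL) have no solution; they return NaN and must
    be excluded by the caller.
    """
    an = np.asarray(an, dtype=float)
    j = np.asarray(j, dtype=float)
    denom = j - 4.0 * (an + rl)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = gamma_star * (j + 8.0 * (an + rl)) / denom
    cc = np.where(denom > 0, cc, np.nan)
    return float(cc) if cc.ndim == 0 else cc


def mesophyll_conductance_point(an, ci, cc):
    """Fick's first law: gm = An / (ci - cc)."""
    an = np.asarray(an, dtype=float)
    ci = np.asarray(ci, dtype=float)
    cc = np.asarray(cc, dtype=float)
    gap = ci - cc
    if np.any(np.abs(gap) < 1e-12) and np.any(np.abs(an) > 0):
        raise ValueError("ci equals cc; gm undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        gm = np.where(np.abs(an) > 0, an / gap, 0.0)
    return float(gm) if gm.ndim == 0 else gm


# ---------------------------------------------------------------------------
# estimation driver


def estimate_gm(
    records: pd.DataFrame,
    calib: CalibrationResult,
    gamma_star_mode: str = "fixed",
    gamma_star_fixed: float = 42.5,
    aggregate: str = "mean",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ConductanceEstimate:
    """Per-record J, cc and gm, with fixed or iteratively estimated G*.

    In ``fixed`` mode G* is ``gamma_star_fixed`` (42.5 umol mol-1 lies in
    the 40-45 normal range for C3 leaves). In ``iterative`` mode G* is
    initialised there and driven to the fixed point of
    G* = ci* + RL/gm_agg, where gm_agg aggregates per-record gm over valid
    records (mean by default, median via ``aggregate``). Records whose
    variable-J denominator J - 4(An+RL) is not positive are flagged
    invalid and excluded from the aggregate.
    """
    if gamma_star_mode not in ("fixed", "iterative"):
        raise ValueError("gamma_star_mode must be 'fixed' or 'iterative'")
    if gamma_star_mode == "iterative" and calib.ci_star is None:
        raise ValueError("iterative mode needs a ci* calibration")
    agg_fn = {"mean": np.nanmean, "median": np.nanmedian}[aggregate]

    j = electron_transport(records, calib.s)
    an = records["an"].to_numpy(float)
    ci = records["ci"].to_numpy(float)
    gsc = gsc_from_gsw(records["gsw"].to_numpy(float))
    rl = calib.rl_yin

    def one_pass(gamma_star: float):
        cc = chloroplast_co2(an, j, rl, gamma_star)
        valid = np.isfinite(cc) & (np.abs(ci - cc) > 1e-12)
        gm = np.full_like(cc, np.nan)
        gm[valid] = an[valid] / (ci[valid] - cc[valid])
        valid &= np.nan_to_num(gm, nan=-1.0) > 0
        gm[~valid] = np.nan
        return cc, gm, valid

    gamma_star = gamma_star_fixed
    iterations = 0
    converged = True
    if gamma_star_mode == "iterative":
        converged = False
        for iterations in range(1, max_iter + 1):
            cc, gm, valid = one_pass(gamma_star)
            if not valid.any():
                raise ValueError("all records invalid under current G*")
            new_gamma = calib.ci_star + rl / agg_fn(gm)
            if abs(new_gamma - gamma_star) < tol:
                gamma_star = new_gamma
                converged = True
                break
            gamma_star = new_gamma
        if not converged:
            warnings.warn("G* iteration did not converge; returning last iterate")
    cc, gm, valid = one_pass(gamma_star)
    if not valid.any():
        raise ValueError("all records invalid")

    per_record = pd.DataFrame(
        {"j": j, "cc": cc, "gm": gm, "gsc": gsc, "valid": valid},
        index=records.index,
    )
    return ConductanceEstimate(
        per_record=per_record,
        gamma_star=float(gamma_star),
        gm_mean=float(agg_fn(gm)),
        iterations=iterations,
        converged=converged,
        n_invalid=int((~valid).sum()),
    )


def fit_vcmax(
    records: pd.DataFrame,
    constants: KineticConstants,
    gamma_star: float,
    cc: np.ndarray | None = None,
) -> VcmaxFit:
    """Vcmax as the slope of An on (cc - G*)/(cc + Kc(1+O/Ko)).

    Requires Rubisco-limited records; a concave An-x relation (detected by
    the median second difference) indicates RuBP-regeneration-limited
    points that bias the slope low, and raises a diagnostic warning.
    """
    if cc is None:
        cc = records["cc"].to_numpy(float)
    cc = np.asarray(cc, dtype=float)
    an = records["an"].to_numpy(float)
    keep = np.isfinite(cc) & np.isfinite(an)
    cc, an = cc[keep], an[keep]
    if len(an) < 3:
        raise ValueError("need >= 3 records with finite cc for the Vcmax fit")
    x = (cc - gamma_star) / (cc + constants.km)
    if np.ptp(x) < 1e-12:
        raise ValueError("rank-deficient design: no variation in cc")
    slope, intercept = np.polyfit(x, an, 1)
    resid = an - (slope * x + intercept)
    ss_tot = np.sum((an - an.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    warning = None
    order = np.argsort(x)
    xs, ys = x[order], an[order]
    distinct = np.concatenate([[True], np.diff(xs) > 1e-12])
    xs, ys = xs[distinct], ys[distinct]
    if len(xs) >= 4:
        d2 = np.diff(np.diff(ys) / np.diff(xs))
        if np.median(d2) < -0.05 * abs(slope) * float(np.mean(np.diff(xs))):
            warning = (
                "An-x relation is concave: records likely span the "
                "RuBP-regeneration-limited regime; Vcmax biased low"
            )
            warnings.warn(warning)
    return VcmaxFit(vcmax=float(slope), rl_fit=float(-intercept), r_squared=r2, warning=warning)
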