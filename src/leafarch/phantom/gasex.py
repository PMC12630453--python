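"""Forward simulation of steady-state gas exchange with PAM fluorescence.

The simulator couples the FvCB demand functions to the two diffusive supply
steps (stomatal and mesophyll) and solves for the chloroplastic CO2 mole
fraction cc at each protocol step:

    An = (1 - G*/cc) min(wc, wj) - RL
    wc = Vcmax cc / (cc + Kc (1 + O/Ko))
    wj = Jpot cc / (4 cc + 8 G*)
    An = gsc (ca - ci) = gm (ci - cc),      gsc = gsw / 1.6

The minimum is taken over the carboxylation velocities wc (Rubisco-limited)
and wj (RuBP-regeneration-limited), so light limitation remains operative
below the compensation point, where the net-rate forms would flip sign.

The photorespiratory compensation point scales with the oxygen mole
fraction, G*(O) = G*_ref * O / O_ref, which is what makes low-O2
calibration protocols informative. Fluorescence is emitted from the
*realised* electron transport rate J_act — the rate consistent with the
achieved assimilation, J_act = (An + RL)(4 cc + 8 G*)/(cc - G*) — because
PSII operating efficiency tracks actual linear electron flow regardless of
which limitation is engaged; under RuBP-regeneration limitation
J_act = Jpot(Q) exactly. PSII yield is (Fm' - F')/Fm' = J_act / (s Qin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GasExTruth",
    "ProtocolStep",
    "GasExchangeRecord",
    "simulate_gas_exchange",
    "reference_protocol",
    "records_to_frame",
]


@dataclass
class GasExTruth:
    """Ground-truth leaf parameters for the forward simulator.

    Units: conductances mol m-2 s-1 (gm as umol m-2 s-1 per umol mol-1,
    numerically identical); fluxes umol m-2 s-1; mole fractions umol mol-1
    except O and Ko in mmol mol-1; s dimensionless.
    """

    gm: float = 0.20
    vcmax: float = 60.0
    rl: float = 1.0
    gamma_star: float = 42.5          # at o_ref
    s: float = 0.45
    gsw: float = 0.25
    kc: float = 404.9                 # Michaelis constant for CO2
    ko: float = 278.4                 # Michaelis constant for O2, mmol mol-1
    o_ref: float = 210.0              # reference O2, mmol mol-1 (21 %)
    j_alpha: float = 0.30             # initial slope of Jpot(Q)
    j_sat: float = 210.0              # asymptote of Jpot(Q)
    fm_prime: float = 1.8             # arbitrary fluorescence scale
    noise_sd: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gm", "vcmax", "gamma_star", "s", "gsw", "kc", "ko", "o_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rl < 0:
            raise ValueError("rl must be >= 0")

    # derived quantities -------------------------------------------------
    @property
    def gsc(self) -> float:
        return self.gsw / 1.6

    @property
    def ci_star(self) -> float:
        """Apparent compensation point at o_ref: ci* = G* - RL/gm."""
        return self.gamma_star - self.rl / self.gm

    def gamma_star_at(self, o2: float) -> float:
        return self.gamma_star * o2 / self.o_ref

    def j_pot(self, qin: float) -> float:
        """Rectangular-hyperbola potential electron transport rate."""
        return self.j_alpha * qin * self.j_sat / (self.j_alpha * qin + self.j_sat)


@dataclass(frozen=True)
class ProtocolStep:
    phase: str        # survey | yin | laisk
    ca: float         # umol mol-1
    qin: float        # umol m-2 s-1
    o2: float         # mmol mol-1


@dataclass
class GasExchangeRecord:
    """One steady-state gas-exchange + fluorescence observation."""

    phase: str
    an: float
    ca: float
    ci: float
    gsw: float
    qin: float
    o2: float
    fprime: float
    fmprime: float
    cc_true: float = float("nan")
    j_true: float = float("nan")


def _solve_cc(truth: GasExTruth, step: ProtocolStep) -> float:
    g_star = truth.gamma_star_at(step.o2)
    km = truth.kc * (1.0 + step.o2 / truth.ko)
    j_pot = truth.j_pot(step.qin)
    r_tot = 1.0 / truth.gsc + 1.0 / truth.gm

    def demand(cc: float) -> float:
        wc = truth.vcmax * cc / (cc + km)
        wj = j_pot * cc / (4.0 * cc + 8.0 * g_star) if (cc > 0 or g_star > 0) else j_pot / 4.0
        return (1.0 - g_star / cc) * min(wc, wj) - truth.rl if cc > 0 else -truth.rl

    def g(cc: float) -> float:
        return demand(cc) - (step.ca - cc) / r_tot

    lo, hi = 1e-9, step.ca + 2000.0
    if g(lo) >= 0 or g(hi) <= 0:
        raise ValueError(f"no steady state in cc for step {step}")
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-15)


def simulate_gas_exchange(
    truth: GasExTruth, protocol: list[ProtocolStep]
) -> list[GasExchangeRecord]:
    """Simulate one record per protocol step; noise per ``truth.noise_sd``.

    ``noise_sd`` maps channel names to multiplicative Gaussian standard
    deviations; missing channels are noise-free. Noise enters through the
    *primary* channels — ``an``, ``gsw`` and the PSII yield ``phi``
    (perturbing F' at fixed Fm') — and the reported ci is then re-derived
    from the noisy An and gsw as ci = ca - An/gsc, exactly as a
    gas-exchange instrument computes it; an optional independent ``ci``
    channel adds jitter on top of that for sensitivity studies.
    """
    if not protocol:
        raise ValueError("protocol is empty")
    rng = np.random.default_rng(truth.rng_seed)
    sd = truth.noise_sd
    records = []
    for step in protocol:
        cc = _solve_cc(truth, step)
        g_star = truth.gamma_star_at(step.o2)
        km = truth.kc * (1.0 + step.o2 / truth.ko)
        wc = truth.vcmax * cc / (cc + km)
        wj = truth.j_pot(step.qin) * cc / (4.0 * cc + 8.0 * g_star)
        an = (1.0 - g_star / cc) * min(wc, wj) - truth.rl
        ci = cc + an / truth.gm
        denom = cc - g_star
        if abs(denom) < 1e-9:
            j_act = truth.j_pot(step.qin)
        else:
            j_act = (an + truth.rl) * (4.0 * cc + 8.0 * g_star) / denom
        phi = j_act / (truth.s * step.qin)
        if not 0.0 <= phi < 1.0:
            raise ValueError(f"PSII yield {phi:.3f} outside [0, 1) for step {step}")

        def jitter(x: float, channel: str) -> float:
            s_ = sd.get(channel, 0.0)
            return x * (1.0 + s_ * rng.standard_normal()) if s_ > 0 else x

        phi_obs = jitter(phi, "phi")
        fmprime = truth.fm_prime
        fprime = fmprime * (1.0 - phi_obs)
        an_obs = jitter(an, "an")
        gsw_obs = jitter(truth.gsw, "gsw")
        # the instrument derives ci from the measured fluxes
        ci_obs = jitter(step.ca - an_obs / (gsw_obs / 1.6), "ci")
        records.append(
            GasExchangeRecord(
                phase=step.phase,
                an=an_obs,
                ca=step.ca,
                ci=ci_obs,
                gsw=gsw_obs,
                qin=step.qin,
                o2=step.o2,
                fprime=fprime,
                fmprime=fmprime,
                cc_true=cc,
                j_true=j_act,
            )
        )
    return records


def reference_protocol(
    survey_ca: tuple[float, ...] = (410.0, 360.0, 310.0, 410.0),
    survey_qin: float = 700.0,
    yin_qin: tuple[float, ...] = (140.0, 120.0, 100.0, 80.0, 60.0),
    yin_ca: float = 1200.0,
    yin_o2: float = 20.0,
    laisk_ca: tuple[float, ...] = (25.0, 40.0, 60.0, 80.0),
    laisk_qin: tuple[float, ...] = (110.0, 70.0, 50.0),
    o2: float = 210.0,
) -> list[ProtocolStep]:
    """The measurement protocol the estimators expect.

    Survey steps at ambient O2 and saturating light across four ca set
    points; a low-O2 high-CO2 light-response series for the s/RL
    calibration; and a low-ca grid at three sub-saturating lights for the
    regression-intercept ci* estimate.
    """
    steps = [ProtocolStep("survey", ca, survey_qin, o2) for ca in survey_ca]
    steps += [ProtocolStep("yin", yin_ca, q, yin_o2) for q in yin_qin]
    steps += [
        ProtocolStep("laisk", ca, q, o2) for q in laisk_qin for ca in laisk_ca
    ]
    return steps


def records_to_frame(records: list[GasExchangeRecord]):
    """Records as a tidy DataFrame (one row per steady state)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "phase": [r.phase for r in records],
            "an": [r.an for r in records],
            "ca": [r.ca for r in records],
            "ci": [r.ci for r in records],
            "gsw": [r.gsw for r in records],
            "qin": [r.qin for r in records],
            "o2": [r.o2 for r in records],
            "fprime": [r.fprime for r in records],
            "fmprime": [r.fmprime for r in records],
        }
    )
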