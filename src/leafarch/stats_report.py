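"""Comparison statistics, growth-plateau detection and pipeline assembly.

Group comparisons use Welch's unequal-variance t-test on per-scan summary
values (e.g. KDE modes), the two-sample Kolmogorov-Smirnov test on pooled
distributions, and Pearson correlation for paired group summaries such as
maximum porosity vs maximum tortuosity. Uncertainty on voxel-counting
statistics uses a slice bootstrap with confidence-level trimming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "GrowthSeries",
    "welch_t",
    "ks_two_sample",
    "pearson_r",
    "bootstrap_se",
    "growth_plateau_week",
    "run_pipeline",
]


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("group sample needs at least one value")


@dataclass
class GrowthSeries:
    """Leaf areas (mm^2) per leaf at strictly increasing week numbers."""

    weeks: np.ndarray
    areas: list[np.ndarray]   # one array of per-leaf areas per week

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if len(self.areas) != len(self.weeks):
            raise ValueError("one area array per week required")
        self.areas = [np.asarray(a, dtype=float) for a in self.areas]


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 0.0, float(len(x) + len(y) - 2), 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic on the empirical CDFs, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with the t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bootstrap_se(
    values,
    statistic=np.mean,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
) -> float:
    """SD of a statistic over with-replacement resamples, conf-trimmed.

    The replicate statistics are trimmed symmetrically to the central
    ``conf`` mass before taking the standard deviation, matching the
    slice-bootstrap convention used for the tissue fractions.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n = values.size
    for b in range(n_boot):
        reps[b] = statistic(values[rng.integers(0, n, size=n)])
    reps.sort()
    cut = int(np.floor((1.0 - conf) / 2.0 * n_boot))
    if n_boot - 2 * cut >= 1:
        reps = reps[cut : n_boot - cut]
    return float(np.std(reps))


def growth_plateau_week(series: GrowthSeries, threshold: float = 0.10) -> float:
    """Week at which median leaf-area growth stays below the threshold.

    Median relative growth is computed per consecutive week pair (paired
    per leaf when the arrays align, else on the medians). The plateau is
    the first interval whose growth is below ``threshold`` *and* is
    confirmed by the following interval (two-step detection); the
    returned week linearly interpolates the threshold crossing between
    that interval's left endpoint and the preceding one. ``inf`` when
    growth never plateaus within the series.
    """
    if len(series.weeks) < 3:
        raise ValueError("need >= 3 weeks for plateau detection")
    growths = []
    for a0, a1 in zip(series.areas[:-1], series.areas[1:]):
        if len(a0) == len(a1):
            growths.append(float(np.median((a1 - a0) / a0)))
        else:
            m0, m1 = np.median(a0), np.median(a1)
            growths.append(float((m1 - m0) / m0))
    g = np.asarray(growths)
    w = series.weeks[:-1]  # interval left endpoints
    below = g < threshold
    confirmed = below[:-1] & below[1:]
    # final interval can only confirm, not start, a two-step run
    idx = np.where(confirmed)[0]
    if idx.size == 0:
        return float("inf")
    k = int(idx[0])
    if k == 0 or g[k - 1] <= threshold:
        return float(w[k])
    frac = (g[k - 1] - threshold) / (g[k - 1] - g[k])
    return float(w[k - 1] + frac * (w[k] - w[k - 1]))


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Run profiles, tortuosity, persistence and gas-exchange fitting.

    ``config`` lists inputs under ``volumes`` (labelled TIFF/NRRD paths)
    and ``gas_exchange`` (record CSVs with a ``phase`` column); optional
    keys: ``ph_min_birth`` (voxels), ``kinetics`` {kc, ko, o2},
    ``gamma_star_mode``. Outputs are tidy CSVs plus a manifest with
    versions, the seed, and per-input status; failures are isolated per
    input and reported in the manifest.
    """
    from . import __version__, gas_exchange, persistence, tissue_metrics, tortuosity
    from .volume import crop_spongy_subvolume, read_labelled_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "inputs": {}, "config": config}

    for path in config.get("volumes", []):
        name = Path(path).stem
        entry: dict = {"kind": "volume", "path": str(path)}
        try:
            vol = read_labelled_volume(path)
            prof = tissue_metrics.porosity_profile(vol).to_frame()
            prof["air_surface_ratio"] = tissue_metrics.air_surface_profile(vol).air_surface_ratio
            prof.to_csv(out_dir / f"{name}_profiles.csv", index=False)

            frac = tissue_metrics.volume_fractions(vol, seed=seed)
            pd.DataFrame(
                {
                    "class": list(frac.fractions),
                    "fraction": list(frac.fractions.values()),
                    "se": [frac.se[k] for k in frac.fractions],
                }
            ).to_csv(out_dir / f"{name}_fractions.csv", index=False)

            field = tortuosity.tortuosity_field(vol)
            summary = tortuosity.tortuosity_summary(field)
            pd.DataFrame(
                {
                    "tau": field.tau,
                    "d_air_um": field.d_air_um,
                    "d_direct_um": field.d_direct_um,
                    "reachable": field.reachable,
                }
            ).to_csv(out_dir / f"{name}_tortuosity.csv", index=False)

            crop = crop_spongy_subvolume(vol, pad=2)
            sedt = persistence.signed_edt(crop)
            diag = persistence.cubical_diagram(sedt, dims=(0, 2))
            diag = persistence.filter_low_persistence(diag)
            diag = persistence.quadrant_classify(diag)
            diag.to_frame().to_csv(out_dir / f"{name}_persistence.csv", index=False)
            air, cell = persistence.radius_distributions(diag)

            entry.update(
                status="ok",
                thickness_um=tissue_metrics.leaf_thickness(vol)[0],
                air_to_tissue=frac.air_to_tissue,
                tau_max=summary.tau_max,
                fraction_unreachable=summary.fraction_unreachable,
                air_radius_mode_um=air.mode_um,
                cell_radius_mode_um=cell.mode_um,
            )
        except Exception as exc:  # noqa: BLE001 - failures isolated per input
            entry.update(status="error", error=f"{type(exc).__name__}: {exc}")
        manifest["inputs"][name] = entry

    for path in config.get("gas_exchange", []):
        name = Path(path).stem
        entry = {"kind": "gas_exchange", "path": str(path)}
        try:
            records = pd.read_csv(path)
            calib_s, rl = gas_exchange.yin_calibrate(records[records["phase"] == "yin"])
            ci_star, rl_laisk, _ = gas_exchange.laisk_ci_star(
                records[records["phase"] == "laisk"]
            )
            calib = gas_exchange.CalibrationResult(
                s=calib_s, rl_yin=rl, ci_star=ci_star, rl_laisk=rl_laisk
            )
            survey = records[records["phase"] == "survey"]
            est = gas_exchange.estimate_gm(
                survey, calib, gamma_star_mode=config.get("gamma_star_mode", "iterative")
            )
            est.per_record.to_csv(out_dir / f"{name}_gm.csv", index=False)
            summary = {
                "s": calib.s,
                "rl_yin": calib.rl_yin,
                "ci_star": calib.ci_star,
                "gamma_star": est.gamma_star,
                "gm_mean": est.gm_mean,
                "converged": est.converged,
            }
            kin = config.get("kinetics")
            if kin:
                constants = gas_exchange.KineticConstants(**kin)
                fit = gas_exchange.fit_vcmax(
                    survey.assign(cc=est.per_record["cc"].to_numpy()),
                    constants,
                    est.gamma_star,
                )
                summary.update(vcmax=fit.vcmax, rl_fit=fit.rl_fit, r_squared=fit.r_squared)
            (out_dir / f"{name}_summary.json").write_text(json.dumps(summary, indent=1))
            entry.update(status="ok", **summary)
        except Exception as exc:  # noqa: BLE001
            entry.update(status="error", error=f"{type(exc).__name__}: {exc}")
        manifest["inputs"][name] = entry

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    n_err = sum(1 for e in manifest["inputs"].values() if e["status"] != "ok")
    manifest["n_errors"] = n_err
    return manifest
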