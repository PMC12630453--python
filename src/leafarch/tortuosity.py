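"""Air-path tortuosity of the leaf airspace by fast marching.

Tortuosity compares, for every airspace entry point p on the abaxial side,
the geodesic distance through the connected airspace to the adaxial
boundary exposed to internal air (d_air) with the unconstrained distance
through the whole leaf interior from the same boundary (d_direct):

    tau(p) = d_air(p, S) / d_direct(p, S)

Both distances solve the eikonal equation with unit speed by first-order
fast marching, with the adaxial air-exposed boundary S as the source
front. tau = 1 means air crosses the lamina on a straight path; larger
values mean air must wind around mesophyll cells. Starts that cannot
reach S through air are reported unreachable, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from ._fmm import fmm_distance
from .volume import SemanticVolume, valid_cylinder_mask

__all__ = [
    "TortuosityField",
    "TortuositySummary",
    "front_distance",
    "tortuosity_field",
    "tortuosity_summary",
]


@dataclass
class TortuosityField:
    """Per-start-point tortuosity over the abaxial airspace boundary."""

    start_points: np.ndarray      # (n, 3) voxel indices
    d_air_um: np.ndarray
    d_direct_um: np.ndarray
    tau: np.ndarray               # NaN where unreachable
    reachable: np.ndarray         # boolean
    d_air_grid_um: np.ndarray | None = None
    d_direct_grid_um: np.ndarray | None = None


@dataclass
class TortuositySummary:
    tau_max: float
    fraction_unreachable: float
    density_grid: np.ndarray | None
    density: np.ndarray | None
    n_reachable: int
    #: robust operational maximum: on small volumes the strict max over
    #: start points is an extreme statistic dominated by single pockets
    tau_q99: float = float("nan")


def front_distance(
    domain_mask: np.ndarray,
    sources: np.ndarray,
    pitch_um: float = 1.0,
    exact_init_radius: float = 0.0,
) -> np.ndarray:
    """First-arrival distance from a source set, in micrometres.

    ``sources`` is either a boolean mask or an (n, 3) index array; source
    voxels carry distance 0. With ``exact_init_radius`` > 0 (useful for
    point sources, where the scheme's near-source curvature error is
    largest), voxels within that radius of any source are initialised with
    their exact Euclidean distance.
    """
    domain_mask = np.asarray(domain_mask, dtype=bool)
    if sources.dtype == bool:
        if sources.shape != domain_mask.shape:
            raise ValueError("source mask shape mismatch")
        src_idx = np.argwhere(sources)
    else:
        src_idx = np.atleast_2d(np.asarray(sources, dtype=np.int64))
    if len(src_idx) == 0:
        raise ValueError("empty source set")
    if not domain_mask[tuple(src_idx.T)].all():
        raise ValueError("sources must lie inside the domain")

    seed = np.full(domain_mask.shape, np.inf)
    seed[tuple(src_idx.T)] = 0.0
    if exact_init_radius > 0:
        r = int(np.ceil(exact_init_radius))
        for p in src_idx:
            lo = np.maximum(p - r, 0)
            hi = np.minimum(p + r + 1, domain_mask.shape)
            grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, p)))
            box = seed[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            np.minimum(box, np.where(d <= exact_init_radius, d, np.inf), out=box)
        seed[~domain_mask] = np.inf
    return fmm_distance(domain_mask, seed) * pitch_um


def _adjacent_air(vol: SemanticVolume, pavement: str, cyl: np.ndarray) -> np.ndarray:
    """Air voxels face-adjacent to the named pavement layer."""
    pav = vol.mask(pavement)
    halo = ndimage.binary_dilation(pav, structure=_faces())
    return vol.air_mask & cyl & halo & ~pav


def _faces():
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = s[0, 1, 1] = s[2, 1, 1] = s[1, 0, 1] = s[1, 2, 1] = s[1, 1, 0] = s[1, 1, 2] = True
    return s


def tortuosity_field(vol: SemanticVolume, keep_grids: bool = False) -> TortuosityField:
    """Tortuosity at every abaxial airspace start of a labelled volume.

    Sources are the air voxels face-adjacent to the adaxial pavement (the
    exposed adaxial boundary S); starts are the air voxels face-adjacent
    to the abaxial pavement. d_air marches through the air phase only,
    d_direct through the whole leaf interior, both from the same sources
    and both restricted to the valid cylinder. tau is clamped below at 1,
    since discretisation can make d_air fall short of d_direct by a
    fraction of a voxel.
    """
    cyl, _ = valid_cylinder_mask(vol)
    air = vol.air_mask & cyl
    interior = vol.leaf_mask & cyl
    sources = _adjacent_air(vol, "adaxial_pavement", cyl)
    starts = np.argwhere(_adjacent_air(vol, "abaxial_pavement", cyl))
    if len(starts) == 0:
        raise ValueError("no start points: no air adjacent to the abaxial pavement")
    if not sources.any():
        raise ValueError("no source surface: no air adjacent to the adaxial pavement")

    d_air = front_distance(air, sources, vol.voxel_pitch_um)
    d_dir = front_distance(interior, sources, vol.voxel_pitch_um)

    at = tuple(starts.T)
    da = d_air[at]
    dd = d_dir[at]
    reachable = np.isfinite(da) & np.isfinite(dd) & (dd > 0)
    tau = np.full(len(starts), np.nan)
    tau[reachable] = np.maximum(da[reachable] / dd[reachable], 1.0)
    return TortuosityField(
        start_points=starts,
        d_air_um=da,
        d_direct_um=dd,
        tau=tau,
        reachable=reachable,
        d_air_grid_um=d_air if keep_grids else None,
        d_direct_grid_um=d_dir if keep_grids else None,
    )


def tortuosity_summary(
    field: TortuosityField, bandwidth: float | str | None = None, grid_points: int = 512
) -> TortuositySummary:
    """Density, maximum and unreachable fraction of a tortuosity field."""
    tau = field.tau[field.reachable]
    if len(tau) == 0:
        raise ValueError("all start points unreachable")
    frac_unreachable = 1.0 - len(tau) / len(field.tau)
    tau_max = float(tau.max())
    tau_q99 = float(np.quantile(tau, 0.99))
    if np.ptp(tau) < 1e-12:
        return TortuositySummary(tau_max, frac_unreachable, None, None, len(tau), tau_q99)
    kde = gaussian_kde(tau, bw_method=bandwidth)
    lo, hi = tau.min(), tau.max()
    bw = float(kde.factor * tau.std(ddof=1))
    pad = max(0.05 * (hi - lo), 3.0 * bw)
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    return TortuositySummary(
        tau_max=tau_max,
        fraction_unreachable=frac_unreachable,
        density_grid=grid,
        density=kde(grid),
        n_reachable=len(tau),
        tau_q99=tau_q99,
    )
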