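"""Generators for labelled 3D leaf phantoms with construction-time truth.

Three families of phantoms cover the geometry the anatomy modules measure:

* :func:`make_leaf_phantom` — a layered lamina (pavement slabs, columnar
  palisade cylinders, two layers of lobed spongy spheroids, internal air)
  with tunable spongy lobedness and porosity;
* :func:`make_channel_phantom` — a tissue slab pierced by an air channel of
  known polyline length, the oracle for geodesic tortuosity;
* :func:`make_inclusion_phantom` — spheres of one phase in a uniform
  background, the oracle for persistent-homology radius recovery.

All truths are recorded by construction and are recomputable by exhaustive
voxel counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import DEFAULT_CLASS_MAP, InstanceVolume, SemanticVolume, valid_cylinder_mask

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_leaf_phantom",
    "make_channel_phantom",
    "make_inclusion_phantom",
]

_AIR = 4
_PALISADE = 5
_SPONGY = 6
_ADAX = 1
_ABAX = 2
_OUTSIDE = 0


@dataclass
class PhantomSpec:
    """Geometry of a layered leaf phantom (all lengths in voxels)."""

    dims: tuple[int, int, int] = (80, 96, 96)
    voxel_pitch_um: float = 1.3
    outside_top: int = 6
    adaxial_pavement: int = 5
    palisade_depth: int = 30
    spongy_depth: int = 28
    abaxial_pavement: int = 5
    palisade_radius: float = 6.2
    palisade_spacing: int = 12
    spongy_cell_radius: float = 9.0
    lobedness: float = 0.5
    target_spongy_porosity: float = 0.50
    porosity_tolerance: float = 0.02
    stomatal_channels: tuple[tuple[int, int, float], ...] = ()
    palisade_detached: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        used = (
            self.outside_top
            + self.adaxial_pavement
            + self.palisade_depth
            + self.spongy_depth
            + self.abaxial_pavement
        )
        if used > self.dims[0]:
            raise ValueError("layer thicknesses exceed depth dimension")
        if not 0.0 < self.target_spongy_porosity:
            raise ValueError("target_spongy_porosity must be positive")
        if not 0.0 <= self.lobedness <= 1.0:
            raise ValueError("lobedness must be in [0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth recorded while building a phantom."""

    voxel_pitch_um: float = 1.0
    layer_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_slice_porosity: np.ndarray | None = None
    spongy_porosity: float | None = None
    air_to_tissue: float | None = None
    leaf_thickness_vox: float | None = None
    palisade_feret_vox: dict[int, float] = field(default_factory=dict)
    palisade_touches_adaxial: dict[int, bool] = field(default_factory=dict)
    air_sphere_radii: list[float] = field(default_factory=list)
    air_sphere_centers: list[tuple[int, int, int]] = field(default_factory=list)
    tissue_ball_radii: list[float] = field(default_factory=list)
    tissue_ball_centers: list[tuple[int, int, int]] = field(default_factory=list)
    channel_path_length_vox: float | None = None
    channel_straight_length_vox: float | None = None
    channel_tau: float | None = None
    channel_reachable: bool | None = None


# ---------------------------------------------------------------------------
# geometry helpers


def _paint_ball(mask: np.ndarray, center, radius: float) -> None:
    lo = [max(int(np.floor(c - radius)) - 1, 0) for c in center]
    hi = [min(int(np.ceil(c + radius)) + 2, s) for c, s in zip(center, mask.shape)]
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius**2


def _paint_capsule(mask: np.ndarray, p, q, radius: float) -> None:
    """Mark voxels within ``radius`` of the segment p-q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    lo = [max(int(np.floor(min(a, b) - radius)) - 1, 0) for a, b in zip(p, q)]
    hi = [
        min(int(np.ceil(max(a, b) + radius)) + 2, s)
        for a, b, s in zip(p, q, mask.shape)
    ]
    grids = np.meshgrid(
        *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True
    )
    d = q - p
    len2 = float(d @ d)
    if len2 == 0:
        t = 0.0
    else:
        t = sum((g - a) * b for g, a, b in zip(grids, p, d)) / len2
        t = np.clip(t, 0.0, 1.0)
    d2 = sum((g - (a + t * b)) ** 2 for g, a, b in zip(grids, p, d))
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius**2


def _real_sph_harm_basis(l_values, theta, phi, coeffs):
    """Random low-order real spherical-harmonic field on given directions."""
    try:  # SciPy >= 1.15
        from scipy.special import sph_harm_y

        def _y(l, m):
            return sph_harm_y(l, m, theta, phi)

    except ImportError:  # pragma: no cover - older SciPy
        from scipy.special import sph_harm

        def _y(l, m):
            return sph_harm(m, l, phi, theta)

    out = np.zeros_like(theta, dtype=float)
    k = 0
    for l in l_values:
        for m in range(0, l + 1):
            y = _y(l, m)
            out += coeffs[k] * y.real
            k += 1
            if m > 0:
                out += coeffs[k] * y.imag
                k += 1
    return out


def _paint_lobed_cell(
    mask: np.ndarray, center, radius: float, lobedness: float, rng: np.random.Generator
) -> None:
    """Spheroid whose surface is perturbed by low-order spherical harmonics."""
    amp = 0.35 * lobedness
    rmax = radius * (1.0 + amp) + 1.0
    lo = [max(int(np.floor(c - rmax)) - 1, 0) for c in center]
    hi = [min(int(np.ceil(c + rmax)) + 2, s) for c, s in zip(center, mask.shape)]
    grids = np.meshgrid(
        *[np.arange(a, b, dtype=float) for a, b in zip(lo, hi)], indexing="ij"
    )
    v = [g - c for g, c in zip(grids, center)]
    rho = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    n_coeffs = sum(2 * l + 1 for l in (3, 4))
    coeffs = rng.normal(size=n_coeffs)
    if lobedness > 0:
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(np.where(rho > 0, v[0] / np.maximum(rho, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(v[2], v[1])
        pert = _real_sph_harm_basis((3, 4), theta, phi, coeffs)
        peak = np.max(np.abs(pert))
        if peak > 0:
            pert = pert / peak
        r_dir = radius * (1.0 + amp * pert)
    else:
        r_dir = radius
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= rho <= r_dir


# ---------------------------------------------------------------------------
# leaf phantom


def _precompute_cell_fields(
    shape, centers, base_radius: float, lobedness: float, seed: int, z_lo: int, z_hi: int
):
    """Per-cell (bbox, radial distance, directional radius) fields.

    The angular perturbation of each cell is fixed, so rescaling all cell
    radii during porosity bisection only moves the radial threshold; the
    expensive spherical-harmonic evaluation happens once.
    """
    rng = np.random.default_rng(seed)
    amp = 0.35 * lobedness
    rmax = base_radius * 1.5 * (1.0 + amp) + 1.0
    n_coeffs = sum(2 * l + 1 for l in (3, 4))
    fields = []
    for c in centers:
        coeffs = rng.normal(size=n_coeffs)
        lo = [max(int(np.floor(cc - rmax)) - 1, 0) for cc in c]
        hi = [min(int(np.ceil(cc + rmax)) + 2, s) for cc, s in zip(c, shape)]
        lo[0] = max(lo[0], z_lo)
        hi[0] = min(hi[0], z_hi)
        if lo[0] >= hi[0]:
            continue
        grids = np.meshgrid(
            *[np.arange(a, b, dtype=float) for a, b in zip(lo, hi)], indexing="ij"
        )
        v = [g - cc for g, cc in zip(grids, c)]
        rho = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        if lobedness > 0:
            theta = np.arccos(np.clip(v[0] / np.maximum(rho, 1e-12), -1, 1))
            phi = np.arctan2(v[2], v[1])
            pert = _real_sph_harm_basis((3, 4), theta, phi, coeffs)
            peak = np.max(np.abs(pert))
            if peak > 0:
                pert /= peak
            r_dir = 1.0 + amp * pert
        else:
            r_dir = np.ones_like(rho)
        slc = tuple(slice(a, b) for a, b in zip(lo, hi))
        fields.append((slc, rho.astype(np.float32), r_dir.astype(np.float32)))
    return fields


def _spongy_mask_from_fields(shape, fields, radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for slc, rho, r_dir in fields:
        mask[slc] |= rho <= radius * r_dir
    return mask


def make_leaf_phantom(
    spec: PhantomSpec,
) -> tuple[SemanticVolume, InstanceVolume, PhantomTruth]:
    """Build a layered leaf phantom; see :class:`PhantomSpec` for knobs.

    The spongy-cell radius is rescaled by bisection until the realised
    air-to-tissue ratio of the spongy slab (inside the valid cylinder)
    matches ``target_spongy_porosity`` within ``porosity_tolerance``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    d0, d1, d2 = spec.dims
    labels = np.full(spec.dims, _OUTSIDE, dtype=np.uint8)

    z0 = spec.outside_top
    z1 = z0 + spec.adaxial_pavement
    z2 = z1 + spec.palisade_depth
    z3 = z2 + spec.spongy_depth
    z4 = z3 + spec.abaxial_pavement
    bounds = {
        "adaxial_pavement": (z0, z1),
        "palisade": (z1, z2),
        "spongy": (z2, z3),
        "abaxial_pavement": (z3, z4),
    }

    labels[z0:z1] = _ADAX
    labels[z3:z4] = _ABAX
    labels[z1:z3] = _AIR  # interior default: air

    # --- palisade: jittered square grid of vertical cylinders -------------
    instance_ids = np.zeros(spec.dims, dtype=np.int32)
    half = spec.palisade_spacing // 2
    ys = np.arange(half, d1, spec.palisade_spacing)
    zs = np.arange(half, d2, spec.palisade_spacing)
    next_id = 1
    pal_region = np.zeros(spec.dims, dtype=bool)
    truth = PhantomTruth(voxel_pitch_um=spec.voxel_pitch_um, layer_bounds=bounds)
    n_detached = 0
    for y in ys:
        for z in zs:
            cy = y + rng.uniform(-1, 1)
            cz = z + rng.uniform(-1, 1)
            top = z1
            if n_detached < spec.palisade_detached:
                top = z1 + 3
                n_detached += 1
            # staggered cell bottoms: the palisade/spongy transition is not
            # a plane in a real lamina
            bottom = z2 + int(rng.integers(0, 7))
            cell = np.zeros(spec.dims, dtype=bool)
            _paint_capsule_cylinder(cell, top, bottom, cy, cz, spec.palisade_radius)
            cell &= ~pal_region  # first cell wins contested voxels
            pal_region |= cell
            instance_ids[cell] = next_id
            truth.palisade_feret_vox[next_id] = float(bottom - top)
            truth.palisade_touches_adaxial[next_id] = top == z1
            next_id += 1
    labels[pal_region] = _PALISADE

    # --- spongy: two layers of lobed cells, porosity tuned by bisection ---
    # lateral spacing follows from the porosity target at the nominal cell
    # radius (two layers of spheres in the slab); the bisection on cell
    # radius then only fine-tunes, keeping the slab fully covered in depth
    n_layers = 2
    layer_depths = [z2 + 0.27 * spec.spongy_depth, z3 - 0.18 * spec.spongy_depth]
    tissue_frac = 1.0 / (1.0 + spec.target_spongy_porosity)
    cell_vol = 4.0 / 3.0 * np.pi * spec.spongy_cell_radius**3
    spacing = float(np.sqrt(n_layers * cell_vol / (tissue_frac * spec.spongy_depth)))
    spacing = max(spacing, 1.05 * spec.spongy_cell_radius)
    centers = []
    for i, zd in enumerate(layer_depths):
        off = (i % 2) * spacing / 2.0
        for y in np.arange(spacing / 2.0 + off, d1, spacing):
            for z in np.arange(spacing / 2.0 + off, d2, spacing):
                centers.append(
                    (
                        zd + rng.uniform(-1.5, 1.5),
                        y + rng.uniform(-1.5, 1.5),
                        z + rng.uniform(-1.5, 1.5),
                    )
                )
    cell_seed = int(rng.integers(2**31 - 1))

    cyl_plane, _ = _cylinder_plane(spec.dims, rotation_axis=1)
    slab = np.zeros(spec.dims, dtype=bool)
    slab[z2:z3] = True
    slab &= cyl_plane

    # spongy cells may reach a few voxels up between the palisade columns
    # (no planar air gap at the layer transition, as in a real lamina)
    fields = _precompute_cell_fields(
        spec.dims, centers, spec.spongy_cell_radius, spec.lobedness, cell_seed,
        max(z2 - 4, z1), z3,
    )

    def realised_porosity(scale: float) -> tuple[float, np.ndarray]:
        cells = _spongy_mask_from_fields(spec.dims, fields, spec.spongy_cell_radius * scale)
        cells &= ~pal_region
        tissue = int(((cells | pal_region) & slab).sum())
        airv = int(slab.sum()) - tissue
        if tissue == 0:
            return np.inf, cells
        return airv / tissue, cells

    lo_s, hi_s = 0.75, 1.45
    p_lo, _ = realised_porosity(hi_s)  # large cells -> low porosity
    p_hi, _ = realised_porosity(lo_s)
    if not (p_lo - spec.porosity_tolerance <= spec.target_spongy_porosity <= p_hi + spec.porosity_tolerance):
        raise ValueError(
            f"target spongy porosity {spec.target_spongy_porosity} infeasible "
            f"(attainable range [{p_lo:.3f}, {p_hi:.3f}] at this cell radius)"
        )
    scale = 1.0
    cells = None
    for _ in range(40):
        p, cells = realised_porosity(scale)
        if abs(p - spec.target_spongy_porosity) <= spec.porosity_tolerance * 0.5:
            break
        if p > spec.target_spongy_porosity:
            lo_s = scale  # too porous -> grow cells
        else:
            hi_s = scale
        scale = 0.5 * (lo_s + hi_s)
    if abs(p - spec.target_spongy_porosity) > spec.porosity_tolerance:
        raise ValueError(
            f"could not reach spongy porosity {spec.target_spongy_porosity} "
            f"(best {p:.3f}) at this cell radius"
        )
    labels[cells] = _SPONGY
    truth.spongy_porosity = float(p)

    # --- stomatal channels through the abaxial pavement -------------------
    for y, z, width in spec.stomatal_channels:
        ch = np.zeros(spec.dims, dtype=bool)
        _paint_capsule(ch, (z3 - 1, y, z), (min(z4 + 1, d0 - 1), y, z), width / 2.0)
        ch[: z3 - 2] = False
        labels[ch] = _AIR

    # --- truth by exhaustive counting inside the valid cylinder -----------
    vol = SemanticVolume(
        labels=labels,
        voxel_pitch_um=spec.voxel_pitch_um,
        depth_axis=0,
        rotation_axis=1,
        class_map=dict(DEFAULT_CLASS_MAP),
        meta={"phantom": "leaf", "rng_seed": spec.rng_seed},
    )
    cyl, _ = valid_cylinder_mask(vol)
    leaf = vol.leaf_mask & cyl
    air = (labels == _AIR) & cyl
    tissue = leaf & ~air
    truth.air_to_tissue = float(air.sum() / tissue.sum())
    truth.leaf_thickness_vox = float(z4 - z0)
    prof = np.zeros(d0)
    for i in range(d0):
        t = int(tissue[i].sum())
        prof[i] = air[i].sum() / t if t > 0 else 0.0
    truth.per_slice_porosity = prof

    instances = InstanceVolume(instance_ids=instance_ids, parent_class="palisade")
    return vol, instances, truth


def _paint_capsule_cylinder(mask, top, bottom, cy, cz, radius) -> None:
    d1, d2 = mask.shape[1], mask.shape[2]
    y = np.arange(d1, dtype=float)[:, None]
    z = np.arange(d2, dtype=float)[None, :]
    disk = (y - cy) ** 2 + (z - cz) ** 2 <= radius**2
    mask[top:bottom] |= disk[None, :, :]


def _cylinder_plane(dims, rotation_axis):
    labels = np.zeros(dims, dtype=np.uint8)
    vol = SemanticVolume(labels=labels, voxel_pitch_um=1.0, rotation_axis=rotation_axis)
    return valid_cylinder_mask(vol)


# ---------------------------------------------------------------------------
# channel phantom


def make_channel_phantom(
    kind: str = "straight",
    dims: tuple[int, int, int] = (112, 160, 112),
    channel_width: float = 3.5,
    waypoints: list[tuple[float, float, float]] | None = None,
    voxel_pitch_um: float = 1.3,
    serpentine_tau: float = 3.0,
) -> tuple[SemanticVolume, PhantomTruth]:
    """Tissue slab pierced by an air channel of known polyline length.

    ``kind='straight'`` gives true tortuosity 1; ``'serpentine'`` follows an
    axis-aligned switchback whose polyline length is ``serpentine_tau``
    times the slab thickness; ``'blocked'`` leaves two dead-end stubs so no
    abaxial start can reach the adaxial surface. Explicit ``waypoints``
    (depth-first coordinates from the adaxial to the abaxial inner face)
    override the built-in shapes.
    """
    if channel_width < 3:
        raise ValueError("channel width < 3 voxels is below the eikonal accuracy floor")
    d0, d1, d2 = dims
    pav = 4
    out = 2
    z_top = out + pav          # first interior slice
    z_bot = d0 - out - pav - 1  # last interior slice
    thickness = float(z_bot - z_top)
    # the channel's width coordinate stays at the in-plane centre so the
    # valid cylinder (depth x width disc, free along the rotation axis)
    # covers the full depth extent; lateral excursions run along axis 1
    y0, z0 = d1 // 3, (d2 - 1) / 2.0
    if min(d0, d2) < d0:
        raise ValueError("width (axis 2) must be >= depth so the valid cylinder spans the slab")

    labels = np.full(dims, _SPONGY, dtype=np.uint8)
    labels[:out] = _OUTSIDE
    labels[-out:] = _OUTSIDE
    labels[out : out + pav] = _ADAX
    labels[d0 - out - pav : d0 - out] = _ABAX

    truth = PhantomTruth(voxel_pitch_um=voxel_pitch_um)
    air = np.zeros(dims, dtype=bool)
    reachable = True
    if waypoints is None:
        if kind == "straight":
            waypoints = [(z_top - 1, y0, z0), (z_bot + 1, y0, z0)]
        elif kind == "serpentine":
            lateral = (serpentine_tau - 1.0) * thickness / 2.0
            if y0 + lateral > d1 - 6:
                raise ValueError("dims too small for requested serpentine_tau")
            a = z_top + thickness * 0.25
            b = z_top + thickness * 0.75
            waypoints = [
                (z_top - 1, y0, z0),
                (a, y0, z0),
                (a, y0 + lateral, z0),
                (b, y0 + lateral, z0),
                (b, y0, z0),
                (z_bot + 1, y0, z0),
            ]
        elif kind == "blocked":
            mid = (z_top + z_bot) // 2
            for seg in (
                [(z_top - 1, y0, z0), (mid - 4, y0, z0)],
                [(mid + 4, y0 + 20, z0), (z_bot + 1, y0 + 20, z0)],
            ):
                _paint_capsule(air, seg[0], seg[1], channel_width / 2.0)
            reachable = False
            waypoints = []
        else:
            raise ValueError(f"unknown channel kind {kind!r}")

    if waypoints:
        for p, q in zip(waypoints[:-1], waypoints[1:]):
            _paint_capsule(air, p, q, channel_width / 2.0)
        pts = np.asarray(waypoints, dtype=float)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        # clip the overshoot into the pavements: the measured path runs
        # between the interior faces
        overshoot = (z_top - pts[0, 0]) + (pts[-1, 0] - z_bot)
        truth.channel_path_length_vox = float(seg_len - overshoot)
        truth.channel_straight_length_vox = thickness
        truth.channel_tau = truth.channel_path_length_vox / thickness

    air[: z_top] = False
    air[z_bot + 1 :] = False
    # re-open the channel mouths through to the pavement faces
    if waypoints:
        mouth = np.zeros(dims, dtype=bool)
        # narrow mouths keep the start/source voxels near the centreline so
        # measured distances match the polyline endpoints
        r_mouth = min(channel_width / 2.0, 1.25)
        _paint_capsule(mouth, waypoints[0], (z_top, waypoints[0][1], waypoints[0][2]), r_mouth)
        _paint_capsule(mouth, waypoints[-1], (z_bot, waypoints[-1][1], waypoints[-1][2]), r_mouth)
        mouth[: z_top] = False
        mouth[z_bot + 1 :] = False
        air |= mouth
    labels[air] = _AIR
    truth.channel_reachable = reachable

    vol = SemanticVolume(
        labels=labels,
        voxel_pitch_um=voxel_pitch_um,
        depth_axis=0,
        rotation_axis=1,
        class_map=dict(DEFAULT_CLASS_MAP),
        meta={"phantom": f"channel:{kind}"},
    )
    return vol, truth


# ---------------------------------------------------------------------------
# inclusion phantom


def make_inclusion_phantom(
    inclusions: list[tuple[tuple[int, int, int], float]],
    phase: str = "air",
    dims: tuple[int, int, int] = (64, 64, 64),
    connect: bool = True,
    voxel_pitch_um: float = 1.0,
) -> tuple[SemanticVolume, PhantomTruth]:
    """Spheres of one phase in the opposite-phase background.

    ``phase='air'`` places air spheres in tissue; ``phase='tissue'`` places
    tissue balls in air. With ``connect=True`` (the default, mimicking the
    single connected airspace / contiguous cell packing of a real leaf)
    every sphere is joined by a thin bridge to a large anchor slab of its
    own phase at the bottom face, so air bodies merge within the air phase
    and cells separate from their neighbours within the tissue phase.
    """
    if phase not in ("air", "tissue"):
        raise ValueError("phase must be 'air' or 'tissue'")
    for (c1, r1) in inclusions:
        for a, s in zip(c1, dims):
            if a - r1 < 2 or a + r1 > s - 3:
                raise ValueError(f"inclusion at {c1} closer than 2 voxels to the boundary")
    for i, (c1, r1) in enumerate(inclusions):
        for c2, r2 in inclusions[i + 1 :]:
            gap = np.linalg.norm(np.subtract(c1, c2)) - (r1 + r2)
            if gap <= 1:
                raise ValueError("inclusions overlap or touch")

    sphere = np.zeros(dims, dtype=bool)
    for c, r in inclusions:
        _paint_ball(sphere, c, r)

    anchor = np.zeros(dims, dtype=bool)
    if connect:
        rmax = max(r for _, r in inclusions)
        slab_h = int(np.ceil(2 * rmax + 6))
        if slab_h >= dims[0] - 4:
            raise ValueError("phantom too shallow for the anchor slab")
        anchor[dims[0] - slab_h :] = True
        for c, r in inclusions:
            _paint_capsule(anchor, c, (dims[0] - slab_h + 1, c[1], c[2]), 1.5)

    fg = sphere | anchor
    if phase == "air":
        labels = np.where(fg, _AIR, _SPONGY).astype(np.uint8)
    else:
        labels = np.where(fg, _SPONGY, _AIR).astype(np.uint8)

    truth = PhantomTruth(voxel_pitch_um=voxel_pitch_um)
    if phase == "air":
        truth.air_sphere_radii = [float(r) for _, r in inclusions]
        truth.air_sphere_centers = [tuple(c) for c, _ in inclusions]
    else:
        truth.tissue_ball_radii = [float(r) for _, r in inclusions]
        truth.tissue_ball_centers = [tuple(c) for c, _ in inclusions]

    vol = SemanticVolume(
        labels=labels,
        voxel_pitch_um=voxel_pitch_um,
        depth_axis=0,
        rotation_axis=1,
        class_map=dict(DEFAULT_CLASS_MAP),
        meta={"phantom": f"inclusion:{phase}", "two_phase": True},
    )
    return vol, truth
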