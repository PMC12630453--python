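"""Per-volume and per-depth tissue descriptors of a labelled leaf volume.

Covers the bulk composition measures (class volume fractions with
slice-bootstrap standard errors, air-to-tissue ratio, leaf thickness via
per-slice distance transforms) and the depth-resolved profiles (2D
porosity and air-to-cell-surface ratio), plus palisade cell lengths as
inertia-aligned bounding-box (Feret) diameters.

All voxel-counting measures are restricted to the valid reconstruction
cylinder; slices with no tissue content report zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import InstanceVolume, SemanticVolume, valid_cylinder_mask

__all__ = [
    "VolumeFractions",
    "TissueProfile",
    "CellMeasurement",
    "volume_fractions",
    "leaf_thickness",
    "porosity_profile",
    "air_surface_profile",
    "palisade_feret",
]


@dataclass
class VolumeFractions:
    """Class voxel fractions normalised to the leaf volume."""

    fractions: dict[str, float]
    se: dict[str, float]
    air_to_tissue: float
    n_boot: int
    conf: float


@dataclass
class TissueProfile:
    """Depth-resolved per-slice ratios along the adaxial->abaxial axis."""

    depth_index: np.ndarray
    depth_um: np.ndarray
    porosity: np.ndarray | None = None
    air_surface_ratio: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"depth_index": self.depth_index, "depth_um": self.depth_um}
        if self.porosity is not None:
            data["porosity"] = self.porosity
        if self.air_surface_ratio is not None:
            data["air_surface_ratio"] = self.air_surface_ratio
        return pd.DataFrame(data)


@dataclass
class CellMeasurement:
    instance_id: int
    feret_um: float
    touches_adaxial: bool = True
    fully_in_valid_cylinder: bool = True


# ---------------------------------------------------------------------------


def _leaf_class_names(vol: SemanticVolume) -> list[str]:
    return [n for n in vol.class_map.values() if n != "outside"]


def volume_fractions(
    vol: SemanticVolume,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
    ratio_denominator: str = "tissue",
) -> VolumeFractions:
    """Per-class voxel fractions of the leaf volume with bootstrap SEs.

    Fractions are voxels(class)/voxels(leaf) inside the valid cylinder.
    The SE of each fraction is the SD of the statistic over ``n_boot``
    with-replacement resamples of depth-axis slices, after symmetric
    trimming to the ``conf`` central mass. The air-to-tissue ratio reads
    "air to tissue" literally — air voxels over non-air leaf voxels; set
    ``ratio_denominator='leaf'`` for the air fraction of the whole leaf
    instead.
    """
    if ratio_denominator not in ("tissue", "leaf"):
        raise ValueError("ratio_denominator must be 'tissue' or 'leaf'")
    cyl, _ = valid_cylinder_mask(vol)
    leaf = vol.leaf_mask & cyl
    if not leaf.any():
        raise ValueError("empty leaf mask inside the valid cylinder")
    names = _leaf_class_names(vol)
    depth = vol.depth_axis
    other = tuple(a for a in range(3) if a != depth)

    # per-depth-slice voxel counts per class: the bootstrap resampling unit
    counts = {
        n: ((vol.labels == vol.code(n)) & cyl).sum(axis=other).astype(float) for n in names
    }
    leaf_counts = leaf.sum(axis=other).astype(float)
    total_leaf = leaf_counts.sum()
    fractions = {n: float(counts[n].sum() / total_leaf) for n in names}
    air = counts["air"].sum() if "air" in counts else 0.0
    if ratio_denominator == "tissue":
        air_to_tissue = float(air / (total_leaf - air))
    else:
        air_to_tissue = float(air / total_leaf)

    rng = np.random.default_rng(seed)
    n_slices = leaf_counts.size
    se = {}
    boot = np.empty((n_boot, len(names)))
    stacked = np.stack([counts[n] for n in names])  # (class, depth)
    for b in range(n_boot):
        idx = rng.integers(0, n_slices, size=n_slices)
        tot = leaf_counts[idx].sum()
        boot[b] = stacked[:, idx].sum(axis=1) / tot if tot > 0 else 0.0
    lo = (1.0 - conf) / 2.0
    for i, n in enumerate(names):
        vals = np.sort(boot[:, i])
        cut = int(np.floor(lo * n_boot))
        trimmed = vals[cut : n_boot - cut] if n_boot - 2 * cut >= 1 else vals
        se[n] = float(np.std(trimmed)) if n_boot > 1 else 0.0
    return VolumeFractions(
        fractions=fractions, se=se, air_to_tissue=air_to_tissue, n_boot=n_boot, conf=conf
    )


def leaf_thickness(vol: SemanticVolume, slice_axis: int | None = None) -> tuple[float, np.ndarray]:
    """Leaf thickness from per-slice distance transforms.

    For each 2D slice along ``slice_axis`` (default: the rotation axis),
    the Euclidean distance transform of the leaf mask is computed and its
    maximum taken; that maximum marks the mid-plane, so the thickness is
    twice the mean of the per-slice maxima, scaled to micrometres. The
    volume must contain ``outside`` voxels on both faces of the lamina.
    """
    axis = vol.rotation_axis if slice_axis is None else slice_axis
    leaf = vol.leaf_mask
    if not leaf.any():
        raise ValueError("empty leaf mask")
    maxima = []
    for i in range(vol.labels.shape[axis]):
        sl = np.take(leaf, i, axis=axis)
        if not sl.any():
            continue
        maxima.append(float(ndimage.distance_transform_edt(sl).max()))
    if not maxima:
        raise ValueError("no slices with leaf content")
    per_slice = 2.0 * np.asarray(maxima) * vol.voxel_pitch_um
    return float(per_slice.mean()), per_slice


def _depth_iter_masks(vol: SemanticVolume):
    cyl, _ = valid_cylinder_mask(vol)
    air = vol.air_mask & cyl
    tissue = vol.leaf_mask & cyl & ~air
    return air, tissue


def porosity_profile(vol: SemanticVolume) -> TissueProfile:
    """Per-depth-slice air-to-tissue ratio inside the valid cylinder."""
    air, tissue = _depth_iter_masks(vol)
    other = tuple(a for a in range(3) if a != vol.depth_axis)
    a = air.sum(axis=other).astype(float)
    t = tissue.sum(axis=other).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        porosity = np.where(t > 0, a / np.maximum(t, 1), 0.0)
    idx = np.arange(vol.labels.shape[vol.depth_axis])
    return TissueProfile(
        depth_index=idx, depth_um=idx * vol.voxel_pitch_um, porosity=porosity
    )


def air_surface_profile(vol: SemanticVolume) -> TissueProfile:
    """Per-depth-slice free-cell-surface to tissue-area ratio.

    The free cell surface of a slice is the zero level of the air mask's
    signed distance transform — in discrete terms, the air pixels
    4-adjacent (in-plane) to a tissue pixel, i.e. the inner boundary of
    the airspace where it touches cell walls. The ratio divides their
    count by the slice's tissue pixel count.
    """
    air, tissue = _depth_iter_masks(vol)
    depth = vol.depth_axis
    in_plane = [a for a in range(3) if a != depth]
    interface = np.zeros_like(air)
    for axis in in_plane:
        for shift in (1, -1):
            interface |= air & np.roll(tissue, shift, axis=axis) & _roll_valid(
                air.shape, shift, axis
            )
    other = tuple(in_plane)
    n_int = interface.sum(axis=other).astype(float)
    n_tis = tissue.sum(axis=other).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_tis > 0, n_int / np.maximum(n_tis, 1), 0.0)
    idx = np.arange(vol.labels.shape[depth])
    return TissueProfile(
        depth_index=idx, depth_um=idx * vol.voxel_pitch_um, air_surface_ratio=ratio
    )


def _roll_valid(shape, shift, axis):
    """Mask excluding positions where np.roll wrapped around."""
    valid = np.ones(shape, dtype=bool)
    sl = [slice(None)] * len(shape)
    sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
    valid[tuple(sl)] = False
    return valid


# ---------------------------------------------------------------------------
# palisade morphometrics


def palisade_feret(
    instances: InstanceVolume,
    vol: SemanticVolume,
    include_excluded: bool = False,
) -> list[CellMeasurement]:
    """Feret diameter per palisade cell via inertia-tensor alignment.

    Each cell's voxel coordinates are rotated into the eigenbasis of
    their second-moment (inertia) tensor; the Feret diameter is the
    largest side of the axis-aligned bounding box there (+1 voxel for the
    voxel extent), in micrometres. Cells that do not touch the adaxial
    pavement or are not fully inside the valid cylinder are excluded
    (they are incomplete cells), unless ``include_excluded`` is set.
    """
    ids_arr = instances.instance_ids
    if ids_arr.shape != vol.labels.shape:
        raise ValueError("instance volume not co-registered with semantic volume")
    cyl, _ = valid_cylinder_mask(vol)
    adax = vol.mask("adaxial_pavement")
    adax_halo = ndimage.binary_dilation(adax, structure=_face_structure())

    out = []
    objects = ndimage.find_objects(ids_arr)
    for idx, slc in enumerate(objects):
        if slc is None:
            continue
        cell_id = idx + 1
        local = ids_arr[slc] == cell_id
        n = int(local.sum())
        if n == 0:
            continue
        if n < 4:
            raise ValueError(f"instance {cell_id} has fewer than 4 voxels; inertia tensor degenerate")
        touches = bool((local & adax_halo[slc]).any())
        inside = bool((local <= cyl[slc]).all())
        if not include_excluded and not (touches and inside):
            continue
        coords = np.argwhere(local).astype(float)
        coords += [s.start for s in slc]
        centered = coords - coords.mean(axis=0)
        cov = centered.T @ centered / n
        _, vecs = np.linalg.eigh(cov)
        proj = centered @ vecs
        extent = proj.max(axis=0) - proj.min(axis=0) + 1.0
        out.append(
            CellMeasurement(
                instance_id=cell_id,
                feret_um=float(extent.max() * vol.voxel_pitch_um),
                touches_adaxial=touches,
                fully_in_valid_cylinder=inside,
            )
        )
    return out


def _face_structure():
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = s[0, 1, 1] = s[2, 1, 1] = s[1, 0, 1] = s[1, 2, 1] = s[1, 1, 0] = s[1, 1, 2] = True
    return s
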