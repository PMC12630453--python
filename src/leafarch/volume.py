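"""Labelled 3D leaf volumes: containers, I/O, downsampling and masking.

A leaf tomogram is stored as a :class:`SemanticVolume` — a 3D grid of small
integer class codes (pavement layers, palisade and spongy mesophyll, veins,
internal air, and the space outside the leaf) together with the physical
voxel pitch and two axis conventions: the *depth axis* runs through the
thickness of the lamina, oriented adaxial → abaxial, and the *rotation axis*
is the tomographic rotation axis used to define the valid reconstruction
cylinder. Orientation is explicit metadata rather than inferred from the
array, because slice naming in tomography stacks is not standardised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._nrrd import read_nrrd, write_nrrd

__all__ = [
    "DEFAULT_CLASS_MAP",
    "SemanticVolume",
    "InstanceVolume",
    "ValidCylinder",
    "read_labelled_volume",
    "write_labelled_volume",
    "downsample_labels",
    "valid_cylinder_mask",
    "crop_spongy_subvolume",
]

#: Default label taxonomy. "mesophyll" is the union {palisade, spongy};
#: "leaf" is everything except ``outside``.
DEFAULT_CLASS_MAP: dict[int, str] = {
    0: "outside",
    1: "adaxial_pavement",
    2: "abaxial_pavement",
    3: "vein",
    4: "air",
    5: "palisade",
    6: "spongy",
}

#: Tie-break priority for majority-pooled downsampling (first wins).
_POOL_PRIORITY = (
    "air",
    "palisade",
    "spongy",
    "vein",
    "adaxial_pavement",
    "abaxial_pavement",
    "outside",
)


@dataclass
class SemanticVolume:
    """3D integer class-label grid with physical and axis metadata."""

    labels: np.ndarray
    voxel_pitch_um: float
    depth_axis: int = 0
    rotation_axis: int = 1
    class_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.voxel_pitch_um <= 0:
            raise ValueError("voxel_pitch_um must be positive")
        if self.depth_axis == self.rotation_axis:
            raise ValueError("depth_axis and rotation_axis must differ")
        present = np.unique(self.labels)
        unknown = sorted(int(c) for c in present if int(c) not in self.class_map)
        if unknown:
            raise ValueError(f"label codes not in class_map: {unknown}")

    # -- label lookups ---------------------------------------------------
    def code(self, name: str) -> int:
        for c, n in self.class_map.items():
            if n == name:
                return c
        raise KeyError(f"class {name!r} not in class_map")

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named classes."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for name in names:
            out |= self.labels == self.code(name)
        return out

    @property
    def leaf_mask(self) -> np.ndarray:
        """Everything except ``outside`` — the five tissue-or-air classes."""
        return self.labels != self.code("outside")

    @property
    def air_mask(self) -> np.ndarray:
        return self.mask("air")

    @property
    def mesophyll_mask(self) -> np.ndarray:
        return self.mask("palisade", "spongy")


@dataclass
class InstanceVolume:
    """Per-cell instance ids (0 = background) over one semantic class."""

    instance_ids: np.ndarray
    parent_class: str = "palisade"

    def __post_init__(self) -> None:
        self.instance_ids = np.asarray(self.instance_ids)
        if self.instance_ids.ndim != 3:
            raise ValueError("instance_ids must be a 3D array")

    def ids(self) -> np.ndarray:
        u = np.unique(self.instance_ids)
        return u[u > 0]


@dataclass(frozen=True)
class ValidCylinder:
    """Maximal cylinder inscribed in the in-plane bounding rectangle."""

    axis: int
    center: tuple[float, float]
    radius: float


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_labelled_volume(vol: SemanticVolume, path: str | Path) -> Path:
    """Write labels (TIFF or NRRD by suffix) plus a JSON metadata sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(vol.labels))
    elif suffix == ".nrrd":
        write_nrrd(path, vol.labels)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    sidecar = {
        "class_map": {str(k): v for k, v in vol.class_map.items()},
        "voxel_pitch_um": vol.voxel_pitch_um,
        "depth_axis": vol.depth_axis,
        "rotation_axis": vol.rotation_axis,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_labelled_volume(
    path: str | Path,
    class_map: dict[int, str] | None = None,
    *,
    voxel_pitch_um: float | None = None,
    depth_axis: int | None = None,
    rotation_axis: int | None = None,
) -> SemanticVolume:
    """Read a labelled volume; metadata from the sidecar unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        labels = np.asarray(tifffile.imread(path))
    elif suffix == ".nrrd":
        labels = read_nrrd(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{path} does not contain integer label data")

    side = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
    if class_map is None:
        if "class_map" not in side:
            raise ValueError(f"no class_map given and no sidecar at {sidecar}")
        class_map = {int(k): v for k, v in side["class_map"].items()}
    pitch = voxel_pitch_um if voxel_pitch_um is not None else side.get("voxel_pitch_um", 1.0)
    return SemanticVolume(
        labels=labels,
        voxel_pitch_um=float(pitch),
        depth_axis=int(depth_axis if depth_axis is not None else side.get("depth_axis", 0)),
        rotation_axis=int(
            rotation_axis if rotation_axis is not None else side.get("rotation_axis", 1)
        ),
        class_map=class_map,
    )


# ---------------------------------------------------------------------------
# Downsampling


def downsample_labels(vol: SemanticVolume, factor: int) -> SemanticVolume:
    """Majority-pool each ``factor**3`` block to one voxel.

    Ties are broken by a fixed class-priority order (air first, outside
    last) so the result does not depend on code numbering. Dimensions not
    divisible by ``factor`` are padded by edge replication, recorded in
    ``meta['downsample_padding']``.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return replace(vol, labels=vol.labels.copy(), meta=dict(vol.meta))

    labels = vol.labels
    pad = [(-s) % factor for s in labels.shape]
    if any(pad):
        labels = np.pad(labels, [(0, p) for p in pad], mode="edge")
    shape = labels.shape
    blocks = (shape[0] // factor, shape[1] // factor, shape[2] // factor)

    codes = sorted(vol.class_map)
    priority = {name: i for i, name in enumerate(_POOL_PRIORITY)}
    order = sorted(codes, key=lambda c: priority.get(vol.class_map[c], len(_POOL_PRIORITY)))

    counts = np.empty((len(order),) + blocks, dtype=np.int64)
    for i, c in enumerate(order):
        counts[i] = (
            (labels == c)
            .reshape(blocks[0], factor, blocks[1], factor, blocks[2], factor)
            .sum(axis=(1, 3, 5))
        )
    # argmax returns the first maximum, i.e. the highest-priority class on ties
    winner = np.argmax(counts, axis=0)
    new_labels = np.asarray(order, dtype=vol.labels.dtype)[winner]

    meta = dict(vol.meta)
    meta["downsample_factor"] = meta.get("downsample_factor", 1) * factor
    if any(pad):
        meta["downsample_padding"] = tuple(pad)
    return SemanticVolume(
        labels=new_labels,
        voxel_pitch_um=vol.voxel_pitch_um * factor,
        depth_axis=vol.depth_axis,
        rotation_axis=vol.rotation_axis,
        class_map=dict(vol.class_map),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Valid cylinder


def valid_cylinder_mask(vol: SemanticVolume) -> tuple[np.ndarray, ValidCylinder]:
    """Mask of the maximal cylinder inscribed about the rotation axis.

    Voxel coordinates are voxel-centred, so a plane of n voxels spans
    physical extent n and the inscribed radius is ``min(extents) / 2``.
    """
    axis = vol.rotation_axis
    plane_axes = [a for a in range(3) if a != axis]
    n1, n2 = (vol.labels.shape[a] for a in plane_axes)
    c1, c2 = (n1 - 1) / 2.0, (n2 - 1) / 2.0
    radius = min(n1, n2) / 2.0
    i1 = np.arange(n1)[:, None]
    i2 = np.arange(n2)[None, :]
    plane = (i1 - c1) ** 2 + (i2 - c2) ** 2 <= radius**2
    mask = np.expand_dims(plane, axis=axis)
    mask = np.broadcast_to(mask, _axes_shape(vol.labels.shape, axis, plane.shape)).copy()
    return mask, ValidCylinder(axis=axis, center=(c1, c2), radius=radius)


def _axes_shape(shape: tuple[int, ...], axis: int, plane_shape: tuple[int, int]):
    out = list(plane_shape)
    out.insert(axis, shape[axis])
    return tuple(out)


# ---------------------------------------------------------------------------
# Spongy crop


def crop_spongy_subvolume(vol: SemanticVolume, pad: int = 0) -> SemanticVolume:
    """Crop the spongy-mesophyll bounding box and binarise to air / tissue.

    The crop is the axis-aligned bounding box of spongy voxels inside the
    valid cylinder, extended by ``pad`` voxels along the depth axis. Inside
    the crop every voxel is reduced to two phases for downstream topology:
    ``air`` and not-air (written with the spongy code). Voxels outside the
    valid cylinder are treated as tissue, as are the crop faces.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    cyl_mask, _ = valid_cylinder_mask(vol)
    spongy = vol.mask("spongy") & cyl_mask
    if not spongy.any():
        raise ValueError("volume contains no spongy voxels inside the valid cylinder")

    slices = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        occupied = np.where(spongy.any(axis=other))[0]
        lo, hi = int(occupied[0]), int(occupied[-1]) + 1
        if axis == vol.depth_axis:
            lo = max(lo - pad, 0)
            hi = min(hi + pad, vol.labels.shape[axis])
        slices.append(slice(lo, hi))
    slices = tuple(slices)

    air_code = vol.code("air")
    spongy_code = vol.code("spongy")
    air = (vol.labels[slices] == air_code) & cyl_mask[slices]
    labels = np.where(air, air_code, spongy_code).astype(vol.labels.dtype)
    meta = dict(vol.meta)
    meta.update(
        two_phase=True,
        crop_bounds=tuple((s.start, s.stop) for s in slices),
        crop_pad=pad,
        boundary_phase="tissue",
    )
    return SemanticVolume(
        labels=labels,
        voxel_pitch_um=vol.voxel_pitch_um,
        depth_axis=vol.depth_axis,
        rotation_axis=vol.rotation_axis,
        class_map=dict(vol.class_map),
        meta=meta,
    )
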