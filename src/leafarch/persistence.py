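"""Cubical persistent homology of signed-distance-transformed volumes.

The spongy-mesophyll subvolume is treated as a two-phase system (air vs
tissue) and converted to a signed Euclidean distance transform (SEDT):
negative inside air, positive inside tissue, magnitude = distance to the
phase boundary. Sublevel-set filtration of the SEDT then sweeps from the
deepest air to the deepest tissue, and the resulting persistence pairs
carry geometric meaning:

* dim-0 classes (connected components) are born at air-pocket centres;
  |birth| is the maximal inscribed air-space radius. Negative-death pairs
  (quadrant Q3) merge within air — connected air bodies; positive-death
  pairs (Q2) only merge through tissue — disconnected air bodies.
* dim-2 classes (enclosed voids) die at tissue-cell centres; the death
  value is the inscribed cell radius (quadrant Q1 for cells that separate
  from their neighbours within tissue).
* dim-1 classes (loops) are computed and exported but not analysed
  further.

The complex is the full cubical complex with voxels as top cells and
face values induced as the minimum over incident voxels, so sublevel
components connect by 26-adjacency and their complement by 6-adjacency.
Dims 0 and 2 are computed by union-find over the primal and dual merge
trees (numba-accelerated); dim 1 uses boundary-matrix reduction with
clearing. Zero-persistence pairs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.stats import gaussian_kde

from .volume import SemanticVolume

__all__ = [
    "SEDTField",
    "PersistenceDiagram",
    "RadiusDistribution",
    "signed_edt",
    "cubical_diagram",
    "filter_low_persistence",
    "quadrant_classify",
    "radius_distributions",
]


@dataclass
class SEDTField:
    """Signed EDT in voxel units: negative in air, positive in tissue."""

    values: np.ndarray
    voxel_pitch_um: float = 1.0


@dataclass
class PersistenceDiagram:
    """Persistence pairs (dim, birth, death) with quadrant annotations.

    ``death`` is +inf for essential classes; ``quadrant`` is an empty
    string until :func:`quadrant_classify` runs (essential classes keep
    it empty). Values are in voxel units unless stated in ``meta``.
    """

    dim: np.ndarray
    birth: np.ndarray
    death: np.ndarray
    quadrant: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.lexsort((self.death, self.birth, self.dim))
        self.dim = np.asarray(self.dim)[order]
        self.birth = np.asarray(self.birth)[order]
        self.death = np.asarray(self.death)[order]
        if self.quadrant is not None:
            self.quadrant = np.asarray(self.quadrant)[order]

    def __len__(self) -> int:
        return len(self.dim)

    @property
    def essential(self) -> np.ndarray:
        return np.isinf(self.death)

    def select(self, dim: int, quadrant: str | None = None) -> "PersistenceDiagram":
        keep = self.dim == dim
        if quadrant is not None:
            if self.quadrant is None:
                raise ValueError("diagram has no quadrant annotations yet")
            keep &= self.quadrant == quadrant
        return PersistenceDiagram(
            dim=self.dim[keep],
            birth=self.birth[keep],
            death=self.death[keep],
            quadrant=None if self.quadrant is None else self.quadrant[keep],
            meta=dict(self.meta),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dim": self.dim,
                "birth": self.birth,
                "death": self.death,
                "quadrant": self.quadrant if self.quadrant is not None else "",
            }
        )


@dataclass
class RadiusDistribution:
    """Radii (um) of air bodies or cells with a Gaussian-KDE mode."""

    kind: str                     # air_body | cell
    radii_um: np.ndarray
    mode_um: float
    bandwidth: float | None = None


# ---------------------------------------------------------------------------
# SEDT


def signed_edt(volume: SemanticVolume | np.ndarray) -> SEDTField:
    """Signed EDT of a two-phase volume: -dist in air, +dist in tissue."""
    if isinstance(volume, SemanticVolume):
        air = volume.air_mask
        pitch = volume.voxel_pitch_um
    else:
        air = np.asarray(volume, dtype=bool)
        pitch = 1.0
    if not air.any() or air.all():
        raise ValueError("signed EDT needs both phases present")
    inside_air = ndimage.distance_transform_edt(air)
    inside_tissue = ndimage.distance_transform_edt(~air)
    return SEDTField(values=inside_tissue - inside_air, voxel_pitch_um=pitch)


# ---------------------------------------------------------------------------
# union-find merge trees (numba kernels)


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        parent[i], i = root, parent[i]
    return root


@njit(cache=True)
def _merge_tree_sublevel(vals, n0, n1, n2, order):
    """Dim-0 pairs of the sublevel filtration, 26-connectivity."""
    n = n0 * n1 * n2
    parent = np.full(n, -1, dtype=np.int64)
    birth_val = np.empty(n)
    birth_pos = np.empty(n, dtype=np.int64)
    births = np.empty(n)
    deaths = np.empty(n)
    cnt = 0
    for p in range(n):
        i = order[p]
        parent[i] = i
        birth_val[i] = vals[i]
        birth_pos[i] = p
        z = i // (n1 * n2)
        y = (i // n2) % n1
        x = i % n2
        for dz in range(-1, 2):
            nz = z + dz
            if nz < 0 or nz >= n0:
                continue
            for dy in range(-1, 2):
                ny = y + dy
                if ny < 0 or ny >= n1:
                    continue
                for dx in range(-1, 2):
                    if dz == 0 and dy == 0 and dx == 0:
                        continue
                    nx = x + dx
                    if nx < 0 or nx >= n2:
                        continue
                    j = (nz * n1 + ny) * n2 + nx
                    if parent[j] == -1:
                        continue
                    ri = _find(parent, i)
                    rj = _find(parent, j)
                    if ri == rj:
                        continue
                    if birth_val[ri] < birth_val[rj] or (
                        birth_val[ri] == birth_val[rj] and birth_pos[ri] < birth_pos[rj]
                    ):
                        elder, young = ri, rj
                    else:
                        elder, young = rj, ri
                    if vals[i] > birth_val[young]:
                        births[cnt] = birth_val[young]
                        deaths[cnt] = vals[i]
                        cnt += 1
                    parent[young] = elder
    # essential classes: surviving roots
    ess = np.empty(n)
    ecnt = 0
    for i in range(n):
        if _find(parent, i) == i:
            ess[ecnt] = birth_val[i]
            ecnt += 1
    return births[:cnt], deaths[:cnt], ess[:ecnt]


@njit(cache=True)
def _merge_tree_superlevel(vals, n0, n1, n2, order):
    """Dim-2 pairs via the dual: superlevel components, 6-connectivity.

    A virtual outside node (value +inf) adjoins every boundary voxel, so
    components that reach the volume boundary are never enclosed voids.
    Returned pairs are (birth = merge level, death = component maximum).
    """
    n = n0 * n1 * n2
    parent = np.full(n + 1, -1, dtype=np.int64)
    birth_val = np.empty(n + 1)
    birth_pos = np.empty(n + 1, dtype=np.int64)
    parent[n] = n
    birth_val[n] = np.inf
    birth_pos[n] = -1
    births = np.empty(n)
    deaths = np.empty(n)
    cnt = 0
    for p in range(n):
        i = order[p]
        parent[i] = i
        birth_val[i] = vals[i]
        birth_pos[i] = p
        z = i // (n1 * n2)
        y = (i // n2) % n1
        x = i % n2
        on_boundary = z == 0 or z == n0 - 1 or y == 0 or y == n1 - 1 or x == 0 or x == n2 - 1
        for k in range(7):
            if k == 0:
                j = i - n1 * n2 if z > 0 else -1
            elif k == 1:
                j = i + n1 * n2 if z < n0 - 1 else -1
            elif k == 2:
                j = i - n2 if y > 0 else -1
            elif k == 3:
                j = i + n2 if y < n1 - 1 else -1
            elif k == 4:
                j = i - 1 if x > 0 else -1
            elif k == 5:
                j = i + 1 if x < n2 - 1 else -1
            else:
                j = n if on_boundary else -1
            if j < 0 or parent[j] == -1:
                continue
            ri = _find(parent, i)
            rj = _find(parent, j)
            if ri == rj:
                continue
            # elder component: larger maximum (earlier in decreasing order)
            if birth_val[ri] > birth_val[rj] or (
                birth_val[ri] == birth_val[rj] and birth_pos[ri] < birth_pos[rj]
            ):
                elder, young = ri, rj
            else:
                elder, young = rj, ri
            if birth_val[young] > vals[i]:
                births[cnt] = vals[i]
                deaths[cnt] = birth_val[young]
                cnt += 1
            parent[young] = elder
    return births[:cnt], deaths[:cnt]


# ---------------------------------------------------------------------------
# full-complex reduction (dim 1)


def _cell_values(voxels: np.ndarray) -> np.ndarray:
    """Values on the full cubical complex: min over incident voxels.

    The cell grid has shape (2n+1, ...) with voxels at odd coordinates;
    a cell's filtration value is the minimum over the voxels it bounds.
    """
    out = voxels.astype(float)
    for axis in range(out.ndim):
        n = out.shape[axis]
        shape = list(out.shape)
        shape[axis] = 2 * n + 1
        expanded = np.full(shape, np.inf)
        sl_odd = [slice(None)] * out.ndim
        sl_odd[axis] = slice(1, 2 * n + 1, 2)
        expanded[tuple(sl_odd)] = out
        sl_even = [slice(None)] * out.ndim
        sl_even[axis] = slice(2, 2 * n, 2)
        lo = [slice(None)] * out.ndim
        lo[axis] = slice(0, n - 1)
        hi = [slice(None)] * out.ndim
        hi[axis] = slice(1, n)
        expanded[tuple(sl_even)] = np.minimum(out[tuple(lo)], out[tuple(hi)])
        first = [slice(None)] * out.ndim
        first[axis] = slice(0, 1)
        last = [slice(None)] * out.ndim
        last[axis] = slice(2 * n, 2 * n + 1)
        edge_lo = [slice(None)] * out.ndim
        edge_lo[axis] = slice(0, 1)
        edge_hi = [slice(None)] * out.ndim
        edge_hi[axis] = slice(n - 1, n)
        expanded[tuple(first)] = out[tuple(edge_lo)]
        expanded[tuple(last)] = out[tuple(edge_hi)]
        out = expanded
    return out


def _reduction_dim1(voxels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dim-1 pairs by twist-reduced boundary-matrix reduction.

    Cube columns are reduced first; their pivots (squares paired with
    cubes) are cleared before the square columns are reduced, whose
    pivots are the edges that create loops.
    """
    cell_vals = _cell_values(voxels)
    shape = cell_vals.shape
    flat_vals = cell_vals.ravel()
    coords = np.indices(shape).reshape(3, -1)
    parity = (coords % 2).sum(axis=0).astype(np.int8)
    order = np.lexsort((np.arange(flat_vals.size), parity, flat_vals))
    pos = np.empty(flat_vals.size, dtype=np.int64)
    pos[order] = np.arange(flat_vals.size)
    strides = (shape[1] * shape[2], shape[2], 1)

    def faces(idx: int) -> list[int]:
        out = []
        c = (idx // strides[0], (idx % strides[0]) // strides[1], idx % strides[1])
        for axis in range(3):
            if c[axis] % 2 == 1:
                out.append(idx - strides[axis])
                out.append(idx + strides[axis])
        return out

    def reduce_columns(cell_dim: int, cleared: set[int]):
        pivots: dict[int, list[int]] = {}
        pairs_b, pairs_d = [], []
        new_cleared: set[int] = set()
        cols = order[parity[order] == cell_dim]
        for idx in cols:
            if pos[idx] in cleared:
                continue  # already paired as a pivot one dimension up
            col = sorted(pos[f] for f in faces(idx))
            col = _reduce(col, pivots)
            if col:
                low = col[-1]
                pivots[low] = col
                new_cleared.add(low)
                b = flat_vals[order[low]]
                d = flat_vals[idx]
                if d > b:
                    pairs_b.append(b)
                    pairs_d.append(d)
        return np.asarray(pairs_b), np.asarray(pairs_d), new_cleared

    def _reduce(col: list[int], pivots: dict[int, list[int]]) -> list[int]:
        while col:
            low = col[-1]
            other = pivots.get(low)
            if other is None:
                return col
            col = _sym_diff(col, other)
        return col

    _, _, cleared_squares = reduce_columns(3, set())
    b1, d1, _ = reduce_columns(2, cleared_squares)
    return b1, d1


def _sym_diff(a: list[int], b: list[int]) -> list[int]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i] == b[j]:
            i += 1
            j += 1
        elif a[i] < b[j]:
            out.append(a[i])
            i += 1
        else:
            out.append(b[j])
            j += 1
    out.extend(a[i:])
    out.extend(b[j:])
    return out


# ---------------------------------------------------------------------------
# public diagram API


def cubical_diagram(
    sedt: SEDTField | np.ndarray, dims: tuple[int, ...] = (0, 1, 2)
) -> PersistenceDiagram:
    """Sublevel-set cubical persistence of a (signed-EDT) scalar field.

    Returns finite positive-persistence pairs in the requested dimensions
    plus the essential dim-0 classes (death = +inf). Voxel units.
    """
    vals = sedt.values if isinstance(sedt, SEDTField) else np.asarray(sedt, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("field must be finite")
    flat = vals.ravel().astype(np.float64)
    n0, n1, n2 = vals.shape
    all_dim, all_birth, all_death = [], [], []
    if 0 in dims:
        order = np.argsort(flat, kind="stable")
        b, d, ess = _merge_tree_sublevel(flat, n0, n1, n2, order)
        all_dim += [np.zeros(len(b) + len(ess), dtype=np.int64)]
        all_birth += [np.concatenate([b, ess])]
        all_death += [np.concatenate([d, np.full(len(ess), np.inf)])]
    if 1 in dims:
        b, d = _reduction_dim1(vals)
        all_dim += [np.ones(len(b), dtype=np.int64)]
        all_birth += [b]
        all_death += [d]
    if 2 in dims:
        order = np.argsort(-flat, kind="stable")
        b, d = _merge_tree_superlevel(flat, n0, n1, n2, order)
        all_dim += [np.full(len(b), 2, dtype=np.int64)]
        all_birth += [b]
        all_death += [d]
    pitch = sedt.voxel_pitch_um if isinstance(sedt, SEDTField) else 1.0
    return PersistenceDiagram(
        dim=np.concatenate(all_dim) if all_dim else np.empty(0, dtype=np.int64),
        birth=np.concatenate(all_birth) if all_birth else np.empty(0),
        death=np.concatenate(all_death) if all_death else np.empty(0),
        meta={"units": "voxel", "voxel_pitch_um": pitch, "dims": tuple(dims)},
    )


def filter_low_persistence(
    diag: PersistenceDiagram, min_birth_voxels: float = 1.0
) -> PersistenceDiagram:
    """Drop noise features with |birth| below one voxel (default).

    Sub-voxel births sit on the phase boundary and reflect voxelisation
    noise rather than anatomy; the threshold applies symmetrically to the
    negative births of air components and the positive births of voids.
    """
    keep = np.abs(diag.birth) >= min_birth_voxels
    meta = dict(diag.meta)
    meta["min_birth_voxels"] = min_birth_voxels
    return PersistenceDiagram(
        dim=diag.dim[keep],
        birth=diag.birth[keep],
        death=diag.death[keep],
        quadrant=None if diag.quadrant is None else diag.quadrant[keep],
        meta=meta,
    )


def quadrant_classify(diag: PersistenceDiagram) -> PersistenceDiagram:
    """Annotate each finite pair with its sign quadrant.

    Q1 (+,+): features living in tissue (cell radii for dim 2);
    Q2 (-,+): born in air, dying in tissue (disconnected air bodies);
    Q3 (-,-): born and dying in air (connected air bodies);
    Q4 (+,-): empty, as death >= birth. Essential classes get no quadrant.
    """
    quad = np.empty(len(diag), dtype=object)
    finite = np.isfinite(diag.death)
    for i in range(len(diag)):
        if not finite[i]:
            quad[i] = ""
        elif diag.birth[i] < 0:
            quad[i] = "Q3" if diag.death[i] < 0 else "Q2"
        else:
            quad[i] = "Q1" if diag.death[i] >= 0 else "Q4"
    return PersistenceDiagram(
        dim=diag.dim.copy(),
        birth=diag.birth.copy(),
        death=diag.death.copy(),
        quadrant=quad.astype(str),
        meta=dict(diag.meta),
    )


def _kde_mode(values: np.ndarray, bandwidth=None, grid_points: int = 512) -> float:
    if len(values) == 1 or np.ptp(values) < 1e-12:
        return float(values[0])
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def radius_distributions(
    diag: PersistenceDiagram,
    pitch_um: float | None = None,
    bandwidth=None,
    include_q2_air: bool = False,
) -> tuple[RadiusDistribution, RadiusDistribution]:
    """Air-body and cell radius distributions from a classified diagram.

    Air radii are |birth| of dim-0 Q3 pairs (optionally also Q2); cell
    radii are the deaths of dim-2 Q1 pairs. Radii are scaled to um and
    summarised by the mode of a Gaussian KDE (Scott's rule by default)
    evaluated on a 512-point grid.
    """
    if diag.quadrant is None:
        raise ValueError("diagram must be quadrant-classified first")
    if pitch_um is None:
        pitch_um = float(diag.meta.get("voxel_pitch_um", 1.0))
    air_sel = (diag.dim == 0) & (diag.quadrant == "Q3")
    if include_q2_air:
        air_sel |= (diag.dim == 0) & (diag.quadrant == "Q2")
    cell_sel = (diag.dim == 2) & (diag.quadrant == "Q1")
    air_r = np.abs(diag.birth[air_sel]) * pitch_um
    cell_r = diag.death[cell_sel] * pitch_um
    if len(air_r) == 0:
        raise ValueError("no connected air bodies (dim-0 Q3 pairs) in diagram")
    if len(cell_r) == 0:
        raise ValueError("no cell features (dim-2 Q1 pairs) in diagram")
    air = RadiusDistribution("air_body", air_r, _kde_mode(air_r, bandwidth), bandwidth)
    cell = RadiusDistribution("cell", cell_r, _kde_mode(cell_r, bandwidth), bandwidth)
    return air, cell
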