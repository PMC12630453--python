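"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and written independently of the
package internals: full cubical-complex boundary-matrix reduction for
persistence, graph-search geodesics for fast marching, and exhaustive
per-voxel predicates for masks and distances.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# persistence: naive full reduction of the cubical complex


def cubical_pairs_bruteforce(vox: np.ndarray):
    """All positive-persistence pairs + essential classes, by plain
    column-by-column reduction over the full cubical complex (voxels as
    top cells, face values = min over incident voxels)."""
    vox = np.asarray(vox, dtype=float)
    n0, n1, n2 = vox.shape
    cells: dict[tuple[int, int, int], float] = {}
    for a in range(2 * n0 + 1):
        zs = [a // 2] if a % 2 == 1 else [z for z in ((a // 2) - 1, a // 2) if 0 <= z < n0]
        for b in range(2 * n1 + 1):
            ys = [b // 2] if b % 2 == 1 else [y for y in ((b // 2) - 1, b // 2) if 0 <= y < n1]
            for c in range(2 * n2 + 1):
                xs = [c // 2] if c % 2 == 1 else [x for x in ((c // 2) - 1, c // 2) if 0 <= x < n2]
                cells[(a, b, c)] = min(vox[z, y, x] for z in zs for y in ys for x in xs)

    def dim(cell):
        return sum(k % 2 for k in cell)

    order = sorted(cells, key=lambda cc: (cells[cc], dim(cc), cc))
    pos = {cc: i for i, cc in enumerate(order)}

    def faces(cc):
        out = []
        for ax in range(3):
            if cc[ax] % 2 == 1:
                for d in (-1, 1):
                    f = list(cc)
                    f[ax] += d
                    out.append(pos[tuple(f)])
        return sorted(out)

    pivots: dict[int, list[int]] = {}
    pairs = []
    creators_zero = set()
    for i, cc in enumerate(order):
        col = faces(cc)
        while col:
            low = col[-1]
            if low not in pivots:
                break
            col = sorted(set(col) ^ set(pivots[low]))
        if col:
            low = col[-1]
            pivots[low] = col
            b, d = cells[order[low]], cells[cc]
            if d > b:
                pairs.append((dim(order[low]), b, d))
        else:
            creators_zero.add(i)
    essential = [
        (dim(order[i]), cells[order[i]], np.inf)
        for i in sorted(creators_zero - set(pivots.keys()))
    ]
    return pairs, essential


def diagram_multiset(dims, births, deaths, ndigits: int = 9):
    """Canonical multiset of (dim, birth, death) for exact comparison."""
    from collections import Counter

    return Counter(
        (int(d), round(float(b), ndigits), round(float(x), ndigits))
        for d, b, x in zip(dims, births, deaths)
    )


# ---------------------------------------------------------------------------
# geodesic distance: Dijkstra on the 26-connected voxel graph


def dijkstra_geodesic(mask: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Shortest 26-neighbour path length from a source mask, via MCP."""
    from skimage.graph import MCP_Geometric

    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    dist, _ = mcp.find_costs(np.argwhere(sources))
    return dist


# ---------------------------------------------------------------------------
# morphometrics: exhaustive rotation search for the Feret diameter


def feret_rotation_search(coords: np.ndarray, n_dirs: int = 2000, seed: int = 0) -> float:
    """Maximal extent of a voxel point cloud over many random directions."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    proj = coords @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).max() + 1.0)


def feret_eigendirection_extent(coords: np.ndarray) -> float:
    """Max pairwise-projection extent over the inertia eigen-directions.

    Independent route: SVD of the centred coordinates for the axes, then
    an exhaustive pairwise projection-difference search per axis.
    """
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    best = 0.0
    for axis in vt:
        proj = centered @ axis
        ext = max(abs(a - b) for a in proj for b in proj)
        best = max(best, ext)
    return best + 1.0
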