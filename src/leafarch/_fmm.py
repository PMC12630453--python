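"""First-order fast-marching solver for the eikonal equation |grad T| = 1.

Upwind first-order discretisation on a regular grid with 6-neighbour
causality, a binary min-heap with lazy deletion, and frozen-only upwind
stencils. Compiled with numba; distances are in voxel units (the caller
scales by the physical pitch).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fmm_distance"]


@njit(cache=True)
def _heap_push(keys, idxs, size, key, idx):
    keys[size] = key
    idxs[size] = idx
    i = size
    while i > 0:
        p = (i - 1) // 2
        if keys[p] > keys[i]:
            keys[p], keys[i] = keys[i], keys[p]
            idxs[p], idxs[i] = idxs[i], idxs[p]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(keys, idxs, size):
    key = keys[0]
    idx = idxs[0]
    size -= 1
    keys[0] = keys[size]
    idxs[0] = idxs[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and keys[l] < keys[m]:
            m = l
        if r < size and keys[r] < keys[m]:
            m = r
        if m == i:
            break
        keys[m], keys[i] = keys[i], keys[m]
        idxs[m], idxs[i] = idxs[i], idxs[m]
        i = m
    return key, idx, size


@njit(cache=True)
def _update(dist, state, mask, j, s0, s1, n0, n1, n2):
    """Solve the upwind quadratic at flat index j from frozen neighbours."""
    z = j // s0
    rem = j % s0
    y = rem // s1
    x = rem % s1
    a0 = np.inf
    if z > 0 and state[j - s0] == 2:
        a0 = dist[j - s0]
    if z < n0 - 1 and state[j + s0] == 2 and dist[j + s0] < a0:
        a0 = dist[j + s0]
    a1 = np.inf
    if y > 0 and state[j - s1] == 2:
        a1 = dist[j - s1]
    if y < n1 - 1 and state[j + s1] == 2 and dist[j + s1] < a1:
        a1 = dist[j + s1]
    a2 = np.inf
    if x > 0 and state[j - 1] == 2:
        a2 = dist[j - 1]
    if x < n2 - 1 and state[j + 1] == 2 and dist[j + 1] < a2:
        a2 = dist[j + 1]
    # sort ascending
    if a0 > a1:
        a0, a1 = a1, a0
    if a1 > a2:
        a1, a2 = a2, a1
    if a0 > a1:
        a0, a1 = a1, a0
    if a0 == np.inf:
        return np.inf
    t = a0 + 1.0
    if a1 < np.inf and t > a1:
        s = a0 + a1
        disc = 2.0 - (a0 - a1) ** 2
        if disc > 0:
            t = 0.5 * (s + np.sqrt(disc))
        if a2 < np.inf and t > a2:
            s = a0 + a1 + a2
            q = s * s - 3.0 * (a0 * a0 + a1 * a1 + a2 * a2 - 1.0)
            if q > 0:
                t = (s + np.sqrt(q)) / 3.0
    return t


@njit(cache=True)
def _fmm(mask, seed):
    n0, n1, n2 = mask.shape
    s0 = n1 * n2
    s1 = n2
    n = n0 * s0
    maskf = mask.reshape(n)
    seedf = seed.reshape(n)
    dist = np.full(n, np.inf)
    state = np.zeros(n, dtype=np.uint8)  # 0 far, 1 trial, 2 frozen
    cap = 8 * n + 16
    keys = np.empty(cap)
    idxs = np.empty(cap, dtype=np.int64)
    size = 0
    for i in range(n):
        if maskf[i] and seedf[i] < np.inf:
            dist[i] = seedf[i]
            state[i] = 1
            size = _heap_push(keys, idxs, size, seedf[i], i)
    while size > 0:
        key, i, size = _heap_pop(keys, idxs, size)
        if state[i] == 2:
            continue
        state[i] = 2
        z = i // s0
        rem = i % s0
        y = rem // s1
        x = rem % s1
        for d in range(6):
            if d == 0:
                if z == 0:
                    continue
                j = i - s0
            elif d == 1:
                if z == n0 - 1:
                    continue
                j = i + s0
            elif d == 2:
                if y == 0:
                    continue
                j = i - s1
            elif d == 3:
                if y == n1 - 1:
                    continue
                j = i + s1
            elif d == 4:
                if x == 0:
                    continue
                j = i - 1
            else:
                if x == n2 - 1:
                    continue
                j = i + 1
            if not maskf[j] or state[j] == 2:
                continue
            t = _update(dist, state, maskf, j, s0, s1, n0, n1, n2)
            if t < dist[j]:
                dist[j] = t
                state[j] = 1
                size = _heap_push(keys, idxs, size, t, j)
    return dist.reshape((n0, n1, n2))


def fmm_distance(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """First-arrival distance inside ``mask`` from finite entries of ``seed``.

    ``seed`` holds initial distances (0 at sources, +inf elsewhere);
    returns +inf outside the mask and in unreached pockets. Voxel units.
    """
    mask = np.ascontiguousarray(mask.astype(np.uint8))
    seed = np.ascontiguousarray(seed.astype(np.float64))
    if mask.shape != seed.shape:
        raise ValueError("mask and seed shapes differ")
    return _fmm(mask, seed)
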