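"""Brute-force reference implementations used as independent oracles.

Everything here is written for clarity, not speed: per-pixel Python loops,
explicit neighbourhood gathers, and plain data structures.  The documented
operator semantics are re-derived from scratch so the package implementation
and these oracles share no code path beyond numpy indexing.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage as ndi

FOUR = ((-1, 0), (1, 0), (0, -1), (0, 1))


def line_offsets(length: int, theta_deg: float) -> list[tuple[int, int]]:
    """Digital line offsets: Bresenham between rounded ±(L-1)/2 endpoints."""
    t = np.deg2rad(theta_deg)
    half = (length - 1) / 2.0
    r1 = int(round(half * np.sin(t)))
    c1 = int(round(half * np.cos(t)))
    n = max(abs(r1), abs(c1)) * 2 + 1
    rr = np.round(np.linspace(-r1, r1, n)).astype(int)
    cc = np.round(np.linspace(-c1, c1, n)).astype(int)
    return sorted(set(zip(rr.tolist(), cc.tolist())))


def _gather(img: np.ndarray, r: int, c: int, offs) -> list[float]:
    """Values under the footprint with edge replication."""
    h, w = img.shape
    out = []
    for dr, dc in offs:
        rr = min(max(r + dr, 0), h - 1)
        cc = min(max(c + dc, 0), w - 1)
        out.append(img[rr, cc])
    return out


def directional_filter(
    img: np.ndarray, operation: str, combine: str, length: int, n_directions: int
) -> np.ndarray:
    """Per-pixel re-derivation of the oriented line filter.

    Medians over an even number of samples take the upper median (rank n//2,
    0-based), per the package's documented convention.
    """
    img = np.asarray(img, float)
    h, w = img.shape
    acc = None
    for k in range(n_directions):
        offs = line_offsets(length, k * 180.0 / n_directions)
        res = np.empty_like(img)
        for r in range(h):
            for c in range(w):
                vals = _gather(img, r, c, offs)
                if operation == "median":
                    res[r, c] = sorted(vals)[len(vals) // 2]
                else:  # closing: dilation then erosion, symmetric footprint
                    pass
        if operation == "closing":
            # exact closing on the edge-replicated domain: work on a padded
            # canvas large enough that no stage ever clamps an index
            rad = max(max(abs(dr) for dr, _ in offs),
                      max(abs(dc) for _, dc in offs))
            pad = 2 * rad
            P = np.pad(img, pad, mode="edge")
            dil = np.empty_like(P)
            ph, pw = P.shape
            for r in range(ph):
                for c in range(pw):
                    dil[r, c] = max(_gather(P, r, c, offs))
            for r in range(h):
                for c in range(w):
                    res[r, c] = min(
                        dil[r + pad + dr, c + pad + dc] for dr, dc in offs
                    )
        if acc is None:
            acc = res
        elif combine == "min":
            acc = np.minimum(acc, res)
        else:
            acc = np.maximum(acc, res)
    return acc


def reconstruct_by_erosion(seed: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Iterate J <- max(mask, 4-neighbour erosion of J) to the fixpoint."""
    J = np.asarray(seed, float).copy()
    mask = np.asarray(mask, float)
    h, w = J.shape
    while True:
        changed = False
        new = J.copy()
        for r in range(h):
            for c in range(w):
                m = J[r, c]
                for dr, dc in FOUR:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and J[rr, cc] < m:
                        m = J[rr, cc]
                v = max(mask[r, c], m)
                if v != new[r, c]:
                    new[r, c] = v
                    changed = True
        J = new
        if not changed:
            return J


def regional_minima(img: np.ndarray) -> np.ndarray:
    """4-connected plateau components with no lower neighbour."""
    img = np.asarray(img, float)
    h, w = img.shape
    out = np.zeros(img.shape, bool)
    seen = np.zeros(img.shape, bool)
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0]:
                continue
            v = img[r0, c0]
            comp, stack = [], [(r0, c0)]
            seen[r0, c0] = True
            is_min = True
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr, dc in FOUR:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        if img[rr, cc] == v and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                        elif img[rr, cc] < v:
                            is_min = False
            if is_min:
                for r, c in comp:
                    out[r, c] = True
    return out


def extended_minima(img: np.ndarray, h_tol: float) -> np.ndarray:
    """Regional minima of the h-minima transform."""
    img = np.asarray(img, float)
    if img.max() == img.min():
        return np.ones(img.shape, bool)
    hmin = reconstruct_by_erosion(img + h_tol, img)
    return regional_minima(hmin)


def impose_minima(img: np.ndarray, markers: np.ndarray) -> np.ndarray:
    img = np.asarray(img, float)
    markers = np.asarray(markers, bool)
    fm = np.where(markers, img.min() - 1.0, img.max() + 1.0)
    return reconstruct_by_erosion(fm, np.minimum(img + 1.0, fm))


def label_markers(markers: np.ndarray) -> np.ndarray:
    """4-connected components numbered in row-major first-pixel order."""
    markers = np.asarray(markers, bool)
    h, w = markers.shape
    out = np.zeros(markers.shape, np.int32)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if markers[r0, c0] and out[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                out[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr, dc in FOUR:
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h and 0 <= cc < w
                            and markers[rr, cc] and out[rr, cc] == 0
                        ):
                            out[rr, cc] = nxt
                            stack.append((rr, cc))
    return out


def marker_watershed(img: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Meyer flooding re-derived with per-level FIFO buckets (no heap).

    The relief is the minima imposition of the image at the markers; pixels
    flood 4-connectedly in order of (flooding level, entry age), where the
    flooding level of a pixel is the running maximum of relief values along
    its flood path and age is first-in-first-out.  A pixel belongs to the
    basin that reaches it first.
    """
    markers = np.asarray(markers)
    if markers.dtype == bool:
        lab = label_markers(markers)
    else:
        lab = markers.astype(np.int32)
    relief = impose_minima(img, lab > 0)
    h, w = relief.shape
    out = lab.copy()
    # neighbour order matters for FIFO ties: raster order of offsets
    neigh = ((-1, 0), (0, -1), (0, 1), (1, 0))
    buckets: dict[float, deque] = {}
    for r in range(h):
        for c in range(w):
            if out[r, c]:
                buckets.setdefault(relief[r, c], deque()).append((relief[r, c], r, c))
    while buckets:
        level = min(buckets)
        q = buckets[level]
        flood_level, r, c = q.popleft()
        if not q:
            del buckets[level]
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and out[rr, cc] == 0:
                out[rr, cc] = out[r, c]
                lvl = max(relief[rr, cc], flood_level)
                buckets.setdefault(lvl, deque()).append((lvl, rr, cc))
    return out


CHAMFER = (
    [(dr, dc, 5) for dr, dc in FOUR]
    + [(dr, dc, 7) for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
    + [
        (dr, dc, 11)
        for dr, dc in (
            (-2, -1), (-2, 1), (-1, -2), (-1, 2),
            (1, -2), (1, 2), (2, -1), (2, 1),
        )
    ]
)


def chamfer_geodesic(mask: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Single-source chamfer (5,7,11) geodesic distances by plain Dijkstra."""
    import heapq

    h, w = mask.shape
    INF = float("inf")
    dist = {start: 0}
    heap = [(0, start)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist.get((r, c), INF):
            continue
        for dr, dc, wgt in CHAMFER:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                nd = d + wgt
                if nd < dist.get((rr, cc), INF):
                    dist[(rr, cc)] = nd
                    heapq.heappush(heap, (nd, (rr, cc)))
    out = np.full(mask.shape, -5.0)
    for (r, c), d in dist.items():
        out[r, c] = d
    return out / 5.0


def geodesic_elongation(mask: np.ndarray) -> float:
    """Two-sweep geodesic diameter over inscribed-disk diameter."""
    mask = np.asarray(mask, bool)
    if mask.sum() == 1:
        return 1.0
    edt = ndi.distance_transform_edt(mask)
    start = np.unravel_index(int(np.argmax(edt)), mask.shape)
    d1 = chamfer_geodesic(mask, start)
    p1 = np.unravel_index(int(np.argmax(d1)), mask.shape)
    d2 = chamfer_geodesic(mask, p1)
    gd = float(d2.max())
    inscribed = 2.0 * float(edt.max())
    return gd / inscribed if inscribed > 0 else 1.0


def white_top_hat(img: np.ndarray, radius: int) -> np.ndarray:
    """img − opening with an exact disk, per-pixel gathers, edge replication."""
    img = np.asarray(img, float)
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    h, w = img.shape
    ero = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            ero[r, c] = min(_gather(img, r, c, offs))
    opened = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            opened[r, c] = max(_gather(ero, r, c, offs))
    return np.maximum(img - opened, 0.0)
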