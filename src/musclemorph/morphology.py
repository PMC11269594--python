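"""Morphological operator suite shared by the cells and histo pipelines.

All operators are pure: they never modify their inputs.  Greyscale work is
done in float64.  Connectivity conventions follow the MorphoLibJ-style
platform both pipelines emulate: minima and markers are 4-connected, label
regions are treated as 8-connected.

The marker-controlled watershed is implemented here rather than delegated,
because its tie-breaking must be fully specified for reproducibility:
Meyer flooding with priority equal to the flooding level (the running
maximum of image values along the flood path), FIFO age as the tie-break,
markers seeded in raster order, and each pixel labelled by the basin that
reaches it first.  Ridge pixels therefore belong to the first-reached basin.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as _disk
from skimage.morphology import local_minima, reconstruction

__all__ = [
    "line_footprint",
    "directional_filter",
    "white_top_hat",
    "find_edges",
    "clahe",
    "extended_minima",
    "impose_minima",
    "marker_watershed",
    "kill_border",
    "filter_labels_by_area",
    "geodesic_elongation",
    "erode_labels",
    "fill_holes",
    "morph_closing",
    "add_gaussian_noise",
]

CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: chamfer weights for geodesic distances: orthogonal, diagonal, knight moves
#: (the (5, 7, 11)/5 convention), kept as integers scaled by 5 for exactness.
_CHAMFER_MOVES = (
    [(dr, dc, 5) for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))]
    + [(dr, dc, 7) for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1))]
    + [
        (dr, dc, 11)
        for dr, dc in (
            (-2, -1), (-2, 1), (-1, -2), (-1, 2),
            (1, -2), (1, 2), (2, -1), (2, 1),
        )
    ]
)


# ---------------------------------------------------------------------------
# directional filtering
# ---------------------------------------------------------------------------


def line_footprint(length: int, theta_deg: float) -> np.ndarray:
    """Digital line structuring element of ~``length`` px at ``theta_deg``.

    A Bresenham line through the center between the rounded endpoints at
    ±(length-1)/2 along the direction; diagonal lines thus hold slightly
    fewer pixels than ``length``, the usual digital-line behaviour.
    """
    if length < 1:
        raise ValueError("line length must be >= 1")
    t = np.deg2rad(theta_deg)
    half = (length - 1) / 2.0
    r1 = int(round(half * np.sin(t)))
    c1 = int(round(half * np.cos(t)))
    n = max(abs(r1), abs(c1)) * 2 + 1
    rr = np.round(np.linspace(-r1, r1, n)).astype(int)
    cc = np.round(np.linspace(-c1, c1, n)).astype(int)
    rad = max(abs(r1), abs(c1))
    fp = np.zeros((2 * rad + 1, 2 * rad + 1), bool)
    fp[rr + rad, cc + rad] = True
    return fp


def directional_filter(
    img: np.ndarray,
    operation: str,
    combine: str,
    line_length: int,
    n_directions: int,
) -> np.ndarray:
    """Oriented line filtering combined across ``n_directions`` orientations.

    For each orientation θ_k = k·180°/n_directions the image is filtered with
    a digital line of ``line_length`` px (``operation`` = ``'median'`` or
    ``'closing'``; borders replicate the edge value), and the results are
    combined per pixel with ``combine`` = ``'min'`` or ``'max'``.

    ``min`` over directional medians suppresses structures that are not
    line-like in *every* orientation (speckle removal); ``max`` keeps
    structures that are line-like in *some* orientation, which enhances and
    bridges curvilinear networks such as fiber outlines.

    Note: medians over an even number of footprint pixels take the upper
    median (rank ``n//2``, 0-based), matching :func:`scipy.ndimage.median_filter`.
    """
    if operation not in ("median", "closing"):
        raise ValueError(f"unknown operation {operation!r}")
    if combine not in ("min", "max"):
        raise ValueError(f"unknown combine {combine!r}")
    if line_length < 1 or n_directions < 1:
        raise ValueError("line_length and n_directions must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    acc = None
    for k in range(n_directions):
        fp = line_footprint(line_length, k * 180.0 / n_directions)
        if operation == "median":
            res = ndi.median_filter(img, footprint=fp, mode="nearest")
        else:
            # pad so the two-stage closing is exact on the replicated domain
            # (single-stage border clamping would break extensivity)
            rad = fp.shape[0] // 2
            padded = np.pad(img, 2 * rad, mode="edge")
            res = ndi.grey_closing(padded, footprint=fp, mode="nearest")
            res = res[2 * rad : -2 * rad, 2 * rad : -2 * rad]
        if acc is None:
            acc = res
        elif combine == "min":
            np.minimum(acc, res, out=acc)
        else:
            np.maximum(acc, res, out=acc)
    return acc


# ---------------------------------------------------------------------------
# pointwise / local enhancement
# ---------------------------------------------------------------------------


def white_top_hat(img: np.ndarray, radius: int) -> np.ndarray:
    """Image minus its greyscale opening with a disk of ``radius`` px.

    Enhances bright structures thinner than the disk; non-negative
    everywhere.  Large radii use a decomposed (sequence) disk for speed.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    padded = np.pad(img, 2 * radius, mode="edge")
    if radius <= 8:
        fp = _disk(radius)
        opened = ndi.grey_opening(padded, footprint=fp, mode="nearest")
    else:
        from skimage.morphology import opening as _sk_opening

        fp = _disk(radius, decomposition="sequence")
        opened = _sk_opening(padded, fp)
    opened = opened[2 * radius : -2 * radius, 2 * radius : -2 * radius]
    return np.maximum(img - opened, 0.0)


def find_edges(img: np.ndarray) -> np.ndarray:
    """3x3 Sobel gradient magnitude, the ImageJ "Find Edges" convention."""
    img = np.asarray(img, dtype=np.float64)
    gx = ndi.sobel(img, axis=1, mode="nearest")
    gy = ndi.sobel(img, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def clahe(
    img: np.ndarray,
    block_size: int,
    histogram_bins: int = 256,
    max_slope: float = 3.0,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tiles of side ``block_size`` are equalized with the clip limit derived
    from ``max_slope`` (clip ≈ max_slope · tile_pixels / bins, the ImageJ
    CLAHE parameterization) and blended bilinearly.  The output spans the
    input range; ``max_slope = 1`` is an identity mapping to within one grey
    level and a constant image is returned unchanged.
    """
    if block_size < 8:
        raise ValueError("block_size must be >= 8")
    if histogram_bins < 2:
        raise ValueError("histogram_bins must be >= 2")
    if max_slope < 1:
        raise ValueError("max_slope must be >= 1")
    from skimage.exposure import equalize_adapthist

    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return img.copy()
    norm = (img - lo) / (hi - lo)
    out = equalize_adapthist(
        norm,
        kernel_size=int(block_size),
        clip_limit=min(1.0, max_slope / histogram_bins),
        nbins=int(histogram_bins),
    )
    return out * (hi - lo) + lo


# ---------------------------------------------------------------------------
# extrema, imposition, watershed
# ---------------------------------------------------------------------------


def extended_minima(img: np.ndarray, tolerance_h: float) -> np.ndarray:
    """Extended minima: regional minima of the h-minima transform.

    Returns the 4-connected binary marker mask of basins whose dynamic
    (depth below their lowest escape ridge) is at least ``tolerance_h``.
    A constant image is a single basin covering the whole raster.
    """
    if tolerance_h <= 0:
        raise ValueError("tolerance_h must be > 0")
    img = np.asarray(img, dtype=np.float64)
    if img.max() == img.min():
        return np.ones(img.shape, bool)
    hmin = reconstruction(img + tolerance_h, img, method="erosion", footprint=CROSS)
    return local_minima(hmin, connectivity=1, allow_borders=True)


def impose_minima(img: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Force the regional minima of ``img`` to be exactly ``markers``.

    Morphological reconstruction by erosion of ``min(img + 1, fm)`` above the
    marker function ``fm`` (−∞ on markers, +∞ elsewhere, bounded to the image
    range).  The unit shift assumes grey-level-scaled data, as in the integer
    implementation of the morphology suite this mirrors.
    """
    markers = np.asarray(markers, dtype=bool)
    img = np.asarray(img, dtype=np.float64)
    if markers.shape != img.shape:
        raise ValueError("markers must have the same shape as the image")
    if not markers.any():
        raise ValueError("cannot impose an empty marker set")
    lo = img.min() - 1.0
    hi = img.max() + 1.0
    fm = np.where(markers, lo, hi)
    return reconstruction(
        fm, np.minimum(img + 1.0, fm), method="erosion", footprint=CROSS
    )


def marker_watershed(img: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Marker-controlled watershed partition of the raster.

    ``markers`` may be a boolean mask (components labelled 4-connected in
    row-major first-pixel order) or an integer label image.  The minima of
    ``img`` are first imposed at the markers, then basins are flooded
    4-connectedly with a priority queue keyed on (flooding level, entry age):
    the flooding level of a pixel is the maximum image value along its flood
    path, and ties are broken first-in-first-out, so ridge pixels join the
    basin that reaches them first.  Every pixel receives exactly one label.
    """
    img = np.asarray(img, dtype=np.float64)
    markers = np.asarray(markers)
    if markers.shape != img.shape:
        raise ValueError("markers must have the same shape as the image")
    if markers.dtype == bool:
        lab, n = ndi.label(markers, structure=CROSS)
    else:
        lab = markers.astype(np.int64)
        n = lab.max()
    if n < 1:
        raise ValueError("watershed needs at least one marker component")

    relief = impose_minima(img, lab > 0)
    h, w = relief.shape
    flat = relief.ravel()
    out = lab.ravel().astype(np.int32).copy()

    heap: list[tuple[float, int, int]] = []
    age = 0
    for idx in np.flatnonzero(out):
        heap.append((flat[idx], age, int(idx)))
        age += 1
    heapq.heapify(heap)
    push, pop = heapq.heappush, heapq.heappop
    total = h * w
    while heap:
        level, _, idx = pop(heap)
        label = out[idx]
        c = idx % w
        for off in (-w, -1, 1, w):
            if (off == -1 and c == 0) or (off == 1 and c == w - 1):
                continue
            j = idx + off
            if 0 <= j < total and out[j] == 0:
                out[j] = label
                v = flat[j]
                if v < level:
                    v = level
                age += 1
                push(heap, (v, age, j))
    return out.reshape(h, w).astype(np.int32)


# ---------------------------------------------------------------------------
# label filtering and editing
# ---------------------------------------------------------------------------


def kill_border(labels: np.ndarray) -> np.ndarray:
    """Remove every label that touches the raster border."""
    labels = np.asarray(labels)
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = border[border > 0]
    out = labels.copy()
    if border.size:
        out[np.isin(out, border)] = 0
    return out


def filter_labels_by_area(
    labels: np.ndarray,
    min_area: float,
    max_area: float,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Keep labels whose area (µm²) lies in [min_area, max_area] (inclusive)."""
    if not 0 <= min_area < max_area:
        raise ValueError("need 0 <= min_area < max_area")
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    areas = counts * pixel_size * pixel_size
    bad = ids[(areas < min_area) | (areas > max_area)]
    out = labels.copy()
    if bad.size:
        out[np.isin(out, bad)] = 0
    return out


def _geodesic_distance(mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Chamfer (5,7,11)/5 geodesic distance inside ``mask`` from ``seeds``.

    Vectorized Bellman–Ford relaxation over the 16-move chamfer
    neighbourhood; distances are kept as integers scaled by 5, so the result
    (divided by 5 on return) is exact and independent of relaxation order.
    Unreachable mask pixels get -1.
    """
    INF = np.iinfo(np.int64).max // 4
    d = np.full(mask.shape, INF, dtype=np.int64)
    d[seeds] = 0
    d[~mask] = -INF  # sentinel; never relaxed
    h, w = mask.shape
    changed = True
    while changed:
        changed = False
        for dr, dc, wgt in _CHAMFER_MOVES:
            src = d[
                max(0, -dr) : h - max(0, dr),
                max(0, -dc) : w - max(0, dc),
            ]
            dst = d[
                max(0, dr) : h - max(0, -dr),
                max(0, dc) : w - max(0, -dc),
            ]
            cand = src + wgt
            valid = (src >= 0) & (dst >= 0) & (cand < dst)
            if valid.any():
                dst[valid] = cand[valid]
                changed = True
    out = np.where(mask, d, -5)
    out[mask & (d >= INF)] = -5
    return out / 5.0


def _geodesic_diameter_px(mask: np.ndarray) -> float:
    """Two-sweep chamfer geodesic diameter of a connected 8-region, in px.

    Sweep 1 starts at the innermost pixel (max Euclidean distance transform,
    row-major first on ties) and finds the geodesically furthest pixel;
    sweep 2 measures the maximum distance from there.
    """
    if mask.sum() == 1:
        return 0.0
    edt = ndi.distance_transform_edt(mask)
    start = np.unravel_index(int(np.argmax(edt)), mask.shape)
    seeds = np.zeros(mask.shape, bool)
    seeds[start] = True
    d1 = _geodesic_distance(mask, seeds)
    p1 = np.unravel_index(int(np.argmax(d1)), mask.shape)
    seeds[:] = False
    seeds[p1] = True
    d2 = _geodesic_distance(mask, seeds)
    return float(d2.max())


def geodesic_elongation(labels: np.ndarray) -> dict[int, float]:
    """Geodesic diameter over inscribed-disk diameter, per label.

    The geodesic diameter uses chamfer (5,7,11)/5 weights (two-sweep from the
    innermost point); the inscribed disk diameter is twice the maximum of the
    Euclidean distance transform.  Near 1 for disks, ≈ length/width for bars
    and bent tubes; a single-pixel label is defined as 1.
    """
    labels = np.asarray(labels)
    out: dict[int, float] = {}
    for sl, lab_id in _iter_label_slices(labels):
        mask = labels[sl] == lab_id
        if mask.sum() == 1:
            out[lab_id] = 1.0
            continue
        gd = _geodesic_diameter_px(mask)
        inscribed = 2.0 * float(ndi.distance_transform_edt(mask).max())
        out[lab_id] = gd / inscribed if inscribed > 0 else 1.0
    return out


def _iter_label_slices(labels: np.ndarray):
    """(padded bounding-box slice, label id) pairs for every label."""
    objects = ndi.find_objects(labels)
    for i, sl in enumerate(objects):
        if sl is None:
            continue
        lab_id = i + 1
        r, c = sl
        # pad one pixel (clamped) so masks never touch the sub-raster border
        r = slice(max(0, r.start - 2), min(labels.shape[0], r.stop + 2))
        c = slice(max(0, c.start - 2), min(labels.shape[1], c.stop + 2))
        yield (r, c), lab_id


def erode_labels(labels: np.ndarray, radius: int) -> np.ndarray:
    """Erode each label independently by a disk; vanished labels are dropped."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = np.asarray(labels)
    if radius == 0:
        return labels.copy()
    fp = _disk(radius)
    out = np.zeros_like(labels)
    for sl, lab_id in _iter_label_slices(labels):
        mask = labels[sl] == lab_id
        eroded = ndi.binary_erosion(mask, structure=fp, border_value=0)
        out[sl][eroded] = lab_id
    return out


# ---------------------------------------------------------------------------
# binary helpers and noise
# ---------------------------------------------------------------------------


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Background components not connected to the border become foreground."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def morph_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disk of ``radius`` px.

    The raster is padded with background by ``radius`` so closing near the
    border behaves as in an unbounded plane.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    fp = _disk(radius)
    padded = np.pad(mask, radius)
    closed = ndi.binary_erosion(
        ndi.binary_dilation(padded, structure=fp), structure=fp, border_value=1
    )
    return closed[radius:-radius, radius:-radius]


def add_gaussian_noise(
    img: np.ndarray,
    sd: float,
    seed: int,
    region: np.ndarray | None = None,
    clip_range: tuple[float, float] | None = (0.0, 255.0),
) -> np.ndarray:
    """Add seeded Gaussian noise, optionally only inside ``region``.

    The result is clipped to ``clip_range`` (8-bit grey by default); the same
    seed always produces the same raster.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    rng = np.random.default_rng(seed)
    out = img.copy()
    if region is None:
        out += rng.normal(0.0, sd, img.shape) if sd > 0 else 0.0
    elif sd > 0:
        region = np.asarray(region, dtype=bool)
        n = int(region.sum())
        out[region] += rng.normal(0.0, sd, n)
    if clip_range is not None:
        np.clip(out, clip_range[0], clip_range[1], out=out)
    return out
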