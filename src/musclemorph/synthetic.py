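"""Seeded synthetic microscopy scenes with exact ground truth.

Two generators stand in for microscope acquisitions in every test:

* :func:`gen_myotube_field` — elongated constant-width tubes on a textured
  background, in the style of a phase-contrast field of differentiated
  myotubes, together with an ideal centerline probability map;
* :func:`gen_fiber_mosaic` — a Lloyd-relaxed Voronoi mosaic of polygonal
  muscle fibers whose boundary band forms the outline-stain (laminin)
  channel and whose per-fiber type drives the myosin channel intensities.

Both are deterministic under their seed.  The default calibration is
0.548 µm/px.  The scenes emulate geometry and intensity statistics only: no
point-spread function, no shading, no real phase-contrast optics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .raster import DEFAULT_PIXEL_SIZE, CalibratedImage, LabelMap

__all__ = ["GroundTruth", "gen_myotube_field", "gen_fiber_mosaic",
           "DEFAULT_INTENSITY_MODEL", "write_scene"]


@dataclass
class GroundTruth:
    """Exact truth for one synthetic scene."""

    label_raster: LabelMap
    per_object: pd.DataFrame  # id, class, true_width_um, true_csa_um2
    centerlines: dict  # tube id -> (n, 2) float array of (x, y) px


# ---------------------------------------------------------------------------
# myotube fields
# ---------------------------------------------------------------------------


def _random_centerline(
    rng: np.random.Generator,
    shape: tuple[int, int],
    length_px: float,
    margin: float,
    curvature: float,
) -> np.ndarray | None:
    """Smooth random walk of the requested arc length, or None if it exits."""
    h, w = shape
    start = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
    )
    heading = rng.uniform(0, 2 * np.pi)
    step = 2.0
    pts = [start.copy()]
    pos = start.copy()
    n_steps = int(length_px / step)
    for _ in range(n_steps):
        heading += rng.normal(0.0, curvature)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (margin <= pos[0] < h - margin and margin <= pos[1] < w - margin):
            return None
        pts.append(pos.copy())
    return np.array(pts)


def gen_myotube_field(
    n_tubes: int = 4,
    width_range: tuple[float, float] = (10.0, 30.0),  # µm
    length_range: tuple[float, float] = (100.0, 250.0),  # µm
    curvature: float = 0.02,  # rad per 2-px step
    noise_sd: float = 3.0,  # grey levels, fine texture
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (640, 640),
    seed: int = 0,
    rim_width: int = 2,  # px, dark phase-halo rim
    background_grey: float = 100.0,
    tube_grey: float = 160.0,
    rim_grey: float = 55.0,
) -> tuple[CalibratedImage, CalibratedImage, GroundTruth]:
    """Synthetic myotube field, ideal probability map, and ground truth.

    Tubes are constant-width sweeps along smooth random centerlines: interior
    grey above the textured background, with a darker ``rim_width``-px rim
    standing in for the phase halo.  Tube length is drawn from
    ``length_range`` restricted to 7–28× the width so the true elongation
    stays inside the usual trimming window.  The probability map is the
    rasterized centerline blurred with a σ = 2 px Gaussian and scaled to
    [0, 1].  Truth records the exact width, label raster and centerline of
    every tube.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    labels = np.zeros(shape, np.int32)
    occupied = np.zeros(shape, bool)
    centerline_raster = np.zeros(shape, bool)
    rows = []
    centerlines: dict[int, np.ndarray] = {}

    for tube_id in range(1, n_tubes + 1):
        placed = False
        for _ in range(100):
            width_um = rng.uniform(*width_range)
            lo = max(length_range[0], 7.0 * width_um)
            hi = min(length_range[1], 28.0 * width_um)
            if lo >= hi:
                lo, hi = 7.0 * width_um, 7.5 * width_um
            length_um = rng.uniform(lo, hi)
            width_px = width_um / pixel_size
            margin = width_px / 2 + 12
            path = _random_centerline(
                rng, shape, length_um / pixel_size, margin, curvature
            )
            if path is None:
                continue
            cl = np.zeros(shape, bool)
            # dense rasterization of the polyline
            for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
                n = max(2, int(np.hypot(r1 - r0, c1 - c0) * 2))
                rr = np.round(np.linspace(r0, r1, n)).astype(int)
                cc = np.round(np.linspace(c0, c1, n)).astype(int)
                cl[rr, cc] = True
            dist = ndi.distance_transform_edt(~cl)
            mask = dist <= (width_px - 1.0) / 2.0
            # keep tubes separated by at least 8 px
            if (ndi.binary_dilation(mask, iterations=8) & occupied).any():
                continue
            labels[mask] = tube_id
            occupied |= mask
            centerline_raster |= cl
            centerlines[tube_id] = path[:, ::-1].copy()  # (x, y)
            rows.append(
                {
                    "id": tube_id,
                    "class": "myotube",
                    "true_width_um": width_um,
                    "true_csa_um2": float(mask.sum()) * pixel_size**2,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tube {tube_id} after 100 attempts; "
                "reduce n_tubes or widths"
            )

    # textured background + tubes with a halo rim centered on the boundary:
    # like a real phase halo, the rim straddles the true edge (half inside,
    # half outside), so a mid-rim segmentation boundary is the true boundary
    smooth = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), 25.0)
    smooth *= 6.0 / max(smooth.std(), 1e-9)
    img = np.full(shape, background_grey) + smooth
    tube_mask = labels > 0
    half_in = max(1, rim_width // 2)
    half_out = max(1, rim_width - half_in)
    interior = ndi.binary_erosion(tube_mask, iterations=half_in, border_value=0)
    rim = ndi.binary_dilation(tube_mask, iterations=half_out) & ~interior
    img[interior] = tube_grey
    img += rng.normal(0.0, noise_sd, shape)
    # the rim is rendered noise-free: it is the watershed barrier the
    # segmentation must find, and a constant rim keeps the scene's ground
    # truth unambiguous (noise realism lives in interior and background)
    img[rim] = rim_grey
    img = np.clip(np.round(img), 0, 255)

    prob = ndi.gaussian_filter(centerline_raster.astype(float), 2.0)
    pmax = prob.max()
    if pmax > 0:
        prob /= pmax

    field = CalibratedImage(img, pixel_size=pixel_size, bit_depth_hint=8,
                            channel_role="phase_contrast")
    prob_img = CalibratedImage(prob, pixel_size=pixel_size, bit_depth_hint=32,
                               channel_role="probability")
    truth = GroundTruth(
        label_raster=LabelMap(labels, pixel_size),
        per_object=pd.DataFrame(
            rows, columns=["id", "class", "true_width_um", "true_csa_um2"]
        ),
        centerlines=centerlines,
    )
    return field, prob_img, truth


# ---------------------------------------------------------------------------
# fiber mosaics
# ---------------------------------------------------------------------------

#: per-class mean grey in (channel I, channel IIA, channel IIX) plus noise sd.
#: Chosen so both the raw ±40 and the normalized ±0.2 threshold systems
#: classify the noise-free model correctly, with class separation ≥ 5 sd.
DEFAULT_INTENSITY_MODEL = {
    "fiber_I": (180.0, 30.0, 30.0),
    "fiber_IIA": (30.0, 180.0, 30.0),
    "fiber_IIX": (30.0, 30.0, 180.0),
    "noise_sd": 10.0,
    "boundary_grey": 220.0,
    "background_grey": 20.0,
}

_CLASSES = ("fiber_I", "fiber_IIA", "fiber_IIX")


def gen_fiber_mosaic(
    n_fibers: int = 120,
    type_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    intensity_model: dict | None = None,
    boundary_width: int = 4,  # px
    gap_fraction: float = 0.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
    n_channels: int = 3,
    lloyd_iterations: int = 4,
) -> tuple[list[CalibratedImage], GroundTruth]:
    """Synthetic fiber mosaic: outline-stain + myosin channels with truth.

    Fibers are Lloyd-relaxed Voronoi cells of random seed points.  The
    outline channel holds a bright band of ``boundary_width`` px along cell
    boundaries (optionally with ``gap_fraction`` of its pixels knocked out in
    random arcs) over a dark background; each myosin channel holds the
    per-class mean grey plus Gaussian noise.  Truth stores the class and the
    exact CSA (band excluded) of every fiber.

    Returns ``(channels, truth)`` with channels ordered outline, type I,
    type IIA (and type IIX when ``n_channels`` = 4).
    """
    if abs(sum(type_fractions) - 1.0) > 1e-9:
        raise ValueError("type_fractions must sum to 1")
    if n_channels not in (3, 4):
        raise ValueError("n_channels must be 3 or 4")
    model = dict(DEFAULT_INTENSITY_MODEL)
    if intensity_model:
        model.update(intensity_model)
    rng = np.random.default_rng(seed)
    h, w = shape
    if n_fibers < 1 or n_fibers > h * w // 100:
        raise ValueError(f"{n_fibers} fibers is infeasible on a {h}x{w} raster")

    seeds = rng.uniform([0, 0], [h, w], size=(n_fibers, 2))
    ys, xs = np.mgrid[0:h, 0:w]
    grid = np.column_stack([ys.ravel(), xs.ravel()])
    for _ in range(lloyd_iterations + 1):
        _, assign = cKDTree(seeds).query(grid)
        voronoi = assign.reshape(h, w).astype(np.int32) + 1
        # recentre each seed on its cell centroid (Lloyd relaxation)
        idx = np.arange(1, n_fibers + 1)
        cy = ndi.mean(ys, labels=voronoi, index=idx)
        cx = ndi.mean(xs, labels=voronoi, index=idx)
        seeds = np.column_stack([cy, cx])

    # boundary band: pixels within boundary_width/2 of a label transition
    edge = np.zeros(shape, bool)
    edge[:-1, :] |= voronoi[:-1, :] != voronoi[1:, :]
    edge[:, :-1] |= voronoi[:, :-1] != voronoi[:, 1:]
    band = ndi.distance_transform_edt(~edge) <= boundary_width / 2.0

    if gap_fraction > 0:
        target = gap_fraction * band.sum()
        removed = np.zeros(shape, bool)
        bys, bxs = np.nonzero(band)
        order = rng.permutation(len(bys))
        gap_r = 5
        k = 0
        while removed[band].sum() < target and k < len(order):
            r, c = bys[order[k]], bxs[order[k]]
            rr = slice(max(0, r - gap_r), min(h, r + gap_r + 1))
            cc = slice(max(0, c - gap_r), min(w, c + gap_r + 1))
            removed[rr, cc] = True
            k += 1
        band &= ~removed

    fiber_labels = np.where(band, 0, voronoi).astype(np.int32)

    classes = rng.choice(len(_CLASSES), size=n_fibers, p=type_fractions)
    rows = []
    counts = np.bincount(fiber_labels.ravel(), minlength=n_fibers + 1)
    for i in range(n_fibers):
        rows.append(
            {
                "id": i + 1,
                "class": _CLASSES[classes[i]],
                "true_width_um": np.nan,
                "true_csa_um2": float(counts[i + 1]) * pixel_size**2,
            }
        )

    sd = float(model["noise_sd"])
    lam = np.full(shape, float(model["background_grey"]))
    lam[band] = float(model["boundary_grey"])
    lam += rng.normal(0.0, sd, shape)
    channels = [
        CalibratedImage(np.clip(np.round(lam), 0, 255), pixel_size=pixel_size,
                        bit_depth_hint=8, channel_role="outline_stain")
    ]
    roles = ["mhc_I", "mhc_IIA", "mhc_IIX"][: n_channels - 1]
    for ch in range(n_channels - 1):
        means = np.array([model[c][ch] for c in _CLASSES])
        px = means[classes][voronoi - 1]  # per-fiber class mean, band included
        px = px + rng.normal(0.0, sd, shape)
        channels.append(
            CalibratedImage(np.clip(np.round(px), 0, 255), pixel_size=pixel_size,
                            bit_depth_hint=8, channel_role=roles[ch])
        )

    truth = GroundTruth(
        label_raster=LabelMap(fiber_labels, pixel_size),
        per_object=pd.DataFrame(
            rows, columns=["id", "class", "true_width_um", "true_csa_um2"]
        ),
        centerlines={},
    )
    return channels, truth


# ---------------------------------------------------------------------------
# scene export (used by the synth CLI subcommand)
# ---------------------------------------------------------------------------


def write_scene(out_dir, images: dict, truth: GroundTruth) -> None:
    """Write scene channels as TIFF plus the truth table and label raster."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, img in images.items():
        res = 1.0 / img.pixel_size
        dtype = {8: np.uint8, 16: np.uint16, 32: np.float32}[img.bit_depth_hint]
        tifffile.imwrite(out_dir / f"{name}.tif",
                         img.pixels.astype(dtype), resolution=(res, res),
                         resolutionunit="NONE")
    tifffile.imwrite(
        out_dir / "truth_labels.tif",
        truth.label_raster.labels.astype(np.uint16),
        resolution=(1.0 / truth.label_raster.pixel_size,) * 2,
        resolutionunit="NONE",
    )
    truth.per_object.to_csv(out_dir / "truth_objects.csv", index=False)
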