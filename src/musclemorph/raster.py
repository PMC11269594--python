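"""Calibrated raster data model, image I/O, and generic label-map morphometry.

Conventions used throughout the package:

* coordinates are 0-based, ``x`` increases to the right (columns), ``y``
  increases downward (rows); pixel centers sit at integer coordinates;
* all physical quantities are micrometres (µm) or µm²;
* grey values are kept in floating point internally; the 8-bit hint only
  constrains input validation and noise clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import ConvexHull
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.segmentation import find_boundaries

__all__ = [
    "CalibratedImage",
    "LabelMap",
    "RoiPolygon",
    "RegionMorphometry",
    "FormatError",
    "read_image",
    "crop_to_square",
    "resize",
    "labels_to_rois",
    "rasterize_roi",
    "region_morphometry",
    "write_outputs",
]

#: the acquisition calibration assumed when a file carries no resolution tag
DEFAULT_PIXEL_SIZE = 0.548  # µm / px

CHANNEL_ROLES = {
    "phase_contrast",
    "probability",
    "outline_stain",
    "mhc_I",
    "mhc_IIA",
    "mhc_IIX",
    "generic",
}


class FormatError(ValueError):
    """Raised for rasters the pipelines cannot consume (e.g. RGB files)."""


@dataclass
class CalibratedImage:
    """A 2-D greyscale raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of grey values; stored as float64.
    pixel_size : float
        Side of one pixel in µm.
    bit_depth_hint : {8, 16, 32}
        Bit depth of the source file; 8-bit-hinted images must stay in
        [0, 255].
    channel_role : str
        What the channel depicts (``phase_contrast``, ``probability``,
        ``outline_stain``, ``mhc_I``, ``mhc_IIA``, ``mhc_IIX`` or
        ``generic``).
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    bit_depth_hint: int = 8
    channel_role: str = "generic"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite pixel values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.bit_depth_hint not in (8, 16, 32):
            raise ValueError("bit_depth_hint must be 8, 16 or 32")
        if self.bit_depth_hint == 8 and (
            self.pixels.min() < 0 or self.pixels.max() > 255
        ):
            raise ValueError("8-bit-hinted image has values outside [0, 255]")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel_role {self.channel_role!r}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def copy_with(self, pixels: np.ndarray, **kwargs) -> "CalibratedImage":
        params = dict(
            pixel_size=self.pixel_size,
            bit_depth_hint=self.bit_depth_hint,
            channel_role=self.channel_role,
        )
        params.update(kwargs)
        return CalibratedImage(pixels, **params)


@dataclass
class LabelMap:
    """Integer raster, 0 = background, positive integers = object labels."""

    labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def ids(self) -> np.ndarray:
        """Label ids present, ascending, excluding background."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class RoiPolygon:
    """Outer contour of one label, as ordered (x, y) pixel coordinates."""

    label_id: int
    vertices: np.ndarray  # (n, 2) float, columns x, y

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.label_id <= 0:
            raise ValueError("label_id must be positive")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


@dataclass
class RegionMorphometry:
    """Per-label shape measurements in physical units."""

    label_id: int
    area: float  # µm²
    perimeter: float  # µm, Crofton 4-direction estimate
    orientation: float  # degrees in [0, 180), from +x axis, y down
    min_feret: float  # µm
    centroid: tuple  # (x, y) px


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from TIFF resolution tags, or None when absent."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0 or den == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 1
    unit = int(unit)
    if px_per_unit == 1 and unit in (0, 1):
        return None  # the writer's placeholder (1, 1) tag, not a calibration
    if unit == 2:  # pixels per inch
        um_per_unit = 25400.0
    elif unit == 3:  # pixels per centimetre
        um_per_unit = 10000.0
    else:  # RESUNIT.NONE — interpreted as pixels per µm
        um_per_unit = 1.0
    return um_per_unit / px_per_unit


def read_image(
    path,
    default_pixel_size: float = DEFAULT_PIXEL_SIZE,
    channel_role: str = "generic",
) -> CalibratedImage:
    """Read a greyscale TIFF or PNG into a :class:`CalibratedImage`.

    The pixel size is taken from the TIFF resolution tags when present
    (interpreted as pixels/µm for unit-less tags), otherwise
    ``default_pixel_size`` is used.  Multi-channel files are rejected:
    channels are supplied as separate files, one folder per stain.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    suffix = path.suffix.lower()
    pixel_size = None
    if suffix in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tif:
                arr = tif.asarray()
                pixel_size = _pixel_size_from_tiff(tif)
        except (tifffile.TiffFileError, ValueError) as exc:
            raise IOError(f"unreadable TIFF {path}: {exc}") from exc
    else:
        try:
            arr = iio.imread(path)
        except Exception as exc:  # imageio raises many flavours
            raise IOError(f"unreadable image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4) and np.array_equal(
        arr[..., 0], arr[..., 1]
    ) and np.array_equal(arr[..., 0], arr[..., 2] if arr.shape[2] > 2 else arr[..., 0]):
        # grey image saved with replicated channels: accept the first plane
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(
            f"{path} is multi-channel (shape {arr.shape}); supply one greyscale "
            "file per channel"
        )
    if arr.dtype == np.uint8:
        hint = 8
    elif arr.dtype == np.uint16:
        hint = 16
    else:
        hint = 32
    return CalibratedImage(
        arr.astype(np.float64),
        pixel_size=pixel_size if pixel_size is not None else default_pixel_size,
        bit_depth_hint=hint,
        channel_role=channel_role,
    )


def crop_to_square(img: CalibratedImage, anchor: str = "topleft") -> CalibratedImage:
    """Crop to a square of side ``min(width, height)``.

    ``anchor='topleft'`` (default) keeps the top-left corner;
    ``anchor='center'`` keeps the central square.
    """
    side = min(img.width, img.height)
    if anchor == "topleft":
        r0 = c0 = 0
    elif anchor == "center":
        r0 = (img.height - side) // 2
        c0 = (img.width - side) // 2
    else:
        raise ValueError("anchor must be 'topleft' or 'center'")
    return img.copy_with(img.pixels[r0 : r0 + side, c0 : c0 + side].copy())


def resize(img: CalibratedImage, new_w: int, new_h: int) -> CalibratedImage:
    """Bilinear resample to ``new_w`` x ``new_h`` pixels.

    The pixel size is rescaled by the width ratio; for the square rasters
    both pipelines use, the two axis ratios coincide.
    """
    from skimage.transform import resize as sk_resize

    if new_w < 1 or new_h < 1:
        raise ValueError("target size must be at least 1x1")
    if (new_h, new_w) == img.pixels.shape:
        return img.copy_with(img.pixels.copy())
    out = sk_resize(
        img.pixels,
        (new_h, new_w),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    new_ps = img.pixel_size * (img.width / new_w)
    # bilinear interpolation can overshoot floating-point-wise; clamp 8-bit range
    if img.bit_depth_hint == 8:
        out = np.clip(out, 0.0, 255.0)
    return img.copy_with(out, pixel_size=new_ps)


# ---------------------------------------------------------------------------
# Labels <-> ROIs
# ---------------------------------------------------------------------------


def labels_to_rois(lm: LabelMap) -> list[RoiPolygon]:
    """Outer contour polygon of each label's pixel set.

    The contour is traced at the 0.5 iso-level of the padded binary mask, so
    rasterizing the polygon back (pixel centers inside) recovers the label's
    pixels exactly on hole-free labels.
    """
    rois: list[RoiPolygon] = []
    for props in skmeasure.regionprops(lm.labels):
        r0, c0, r1, c1 = props.bbox
        mask = np.pad(props.image, 1).astype(float)
        contours = skmeasure.find_contours(mask, 0.5)
        if not contours:  # pragma: no cover - regionprops guarantees pixels
            continue
        contour = max(contours, key=len)  # outer contour is the longest
        # contour columns are (row, col) in the padded bbox frame
        y = contour[:, 0] - 1 + r0
        x = contour[:, 1] - 1 + c0
        rois.append(RoiPolygon(props.label, np.column_stack([x, y])))
    return rois


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    rr, cc = skdraw.polygon(roi.vertices[:, 1], roi.vertices[:, 0], shape)
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------


def _orientation_deg(mask: np.ndarray) -> float:
    """Ellipse-fit major-axis angle from +x, degrees in [0, 180), ties -> 0."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = (x * x).sum()
    mu02 = (y * y).sum()
    mu11 = (x * y).sum()
    if mu11 == 0 and mu20 == mu02:
        return 0.0
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    deg = np.degrees(theta) % 180.0
    return float(deg)


def _min_feret_px(mask: np.ndarray) -> float:
    """Minimum caliper width over the convex hull of pixel corners.

    Pixels are treated as unit squares (corners at centers ± 0.5), the
    rotating-calipers convention that makes an n-pixel-wide bar measure n.
    """
    ys, xs = np.nonzero(mask)
    if len(xs) == 1:
        return 1.0
    pts = np.empty((4 * len(xs), 2), float)
    for i, (dx, dy) in enumerate(((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))):
        pts[i::4, 0] = xs + dx
        pts[i::4, 1] = ys + dy
    try:
        hull = ConvexHull(pts)
    except Exception:  # pragma: no cover - corners are never collinear
        return 1.0
    hp = pts[hull.vertices]
    n = len(hp)
    best = np.inf
    for i in range(n):
        p, q = hp[i], hp[(i + 1) % n]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        # width of the hull measured perpendicular to this edge
        ux, uy = edge / norm
        d = np.abs(ux * (hp[:, 1] - p[1]) - uy * (hp[:, 0] - p[0]))
        best = min(best, d.max())
    return float(best)


def region_morphometry(lm: LabelMap) -> list[RegionMorphometry]:
    """Area, Crofton perimeter, orientation, minimum Feret diameter per label.

    Area is the exact pixel count times ``pixel_size**2``; the perimeter is
    the 4-direction Crofton estimate (the convention of the MorphoLibJ-style
    morphology suite); ``min_feret`` comes from rotating calipers over the
    convex hull of the pixel squares.
    """
    ps = lm.pixel_size
    out: list[RegionMorphometry] = []
    for props in skmeasure.regionprops(lm.labels):
        mask = props.image
        cy, cx = props.centroid
        out.append(
            RegionMorphometry(
                label_id=int(props.label),
                area=float(props.num_pixels) * ps * ps,
                perimeter=float(props.perimeter_crofton) * ps,
                orientation=_orientation_deg(mask),
                min_feret=_min_feret_px(mask) * ps,
                centroid=(float(cx), float(cy)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def _overlay_rgb(image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """8-bit RGB: the source image with label boundaries burnt in red."""
    lo, hi = float(image.min()), float(image.max())
    scale = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    grey = (scale * 255).astype(np.uint8)
    rgb = np.stack([grey, grey, grey], axis=-1)
    edges = find_boundaries(labels, mode="outer")
    rgb[edges] = (255, 40, 40)
    return rgb


def write_outputs(
    lm: LabelMap,
    records: pd.DataFrame,
    out_dir,
    stem: str,
    original: CalibratedImage | None = None,
    write_xlsx: bool = False,
) -> dict[str, Path]:
    """Write the standard artifact set for one processed image.

    Produces ``<stem>_labels.tif`` (16-bit label raster with resolution
    tags), ``<stem>_rois.csv`` (polygon vertices), ``<stem>_records.csv``
    (one row per object; header-only when empty), optionally
    ``<stem>_records.xlsx``, and ``<stem>_overlay.png`` when the source
    image is provided.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / f".{stem}.probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths: dict[str, Path] = {}
    if lm.labels.max() > np.iinfo(np.uint16).max:
        warnings.warn("label ids exceed 16-bit range; clipping for TIFF export")
    res = 1.0 / lm.pixel_size  # px per µm, stored with RESUNIT.NONE
    paths["labels"] = out_dir / f"{stem}_labels.tif"
    tifffile.imwrite(
        paths["labels"],
        np.clip(lm.labels, 0, np.iinfo(np.uint16).max).astype(np.uint16),
        resolution=(res, res),
        resolutionunit="NONE",
    )

    rois = labels_to_rois(lm)
    roi_rows = [
        {"label_id": roi.label_id, "vertex": i, "x": vx, "y": vy}
        for roi in rois
        for i, (vx, vy) in enumerate(roi.vertices)
    ]
    paths["rois"] = out_dir / f"{stem}_rois.csv"
    pd.DataFrame(roi_rows, columns=["label_id", "vertex", "x", "y"]).to_csv(
        paths["rois"], index=False, float_format="%.3f"
    )

    paths["records"] = out_dir / f"{stem}_records.csv"
    records.to_csv(paths["records"], index=False, float_format="%.6g")
    if write_xlsx:
        paths["xlsx"] = out_dir / f"{stem}_records.xlsx"
        records.to_excel(paths["xlsx"], index=False)

    if original is not None:
        paths["overlay"] = out_dir / f"{stem}_overlay.png"
        iio.imwrite(paths["overlay"], _overlay_rgb(original.pixels, lm.labels))
    return paths
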