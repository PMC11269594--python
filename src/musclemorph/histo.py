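"""Muscle-fiber segmentation, CSA morphometry, and fiber-type attribution.

From a fluorescent outline stain (laminin or dystrophin) plus co-registered
myosin channels, the pipeline segments individual fibers, measures their
cross-sectional area and shape, quantifies per-fiber channel intensities and
attributes the metabolic fiber type:

1. preprocess the outline channel: optional edge filter, directional median
   (max-combined, so curvilinear boundaries are enhanced and small gaps
   bridged) and an auto-parameterized CLAHE;
2. marker-controlled watershed seeded at extended minima (fiber interiors
   are the dark basins between bright boundary ridges);
3. trim labels by area, border contact and geodesic elongation, then erode
   each fiber so the boundary band never bleeds into intensity measures;
4. measure mean grey per fiber on each (CLAHE-adjusted) myosin channel;
5. score Δ = I − IIA (raw grey levels) or its symmetric contrast
   (I − IIA)/(I + IIA) and attribute type I / IIA / IIB+IIX, flagging
   putative I/IIA hybrids for manual confirmation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import morphology as mo
from .raster import (
    CalibratedImage,
    LabelMap,
    read_image,
    region_morphometry,
    write_outputs,
)

log = logging.getLogger(__name__)

__all__ = [
    "HistoConfig",
    "FiberRecord",
    "auto_clahe_params",
    "preprocess_laminin",
    "segment_fibers",
    "measure_intensities",
    "delta_score",
    "attribute_type",
    "flag_hybrid",
    "run_histo",
    "remove_labels",
    "find_label",
    "relabel_sequential",
]

_EPS = 1e-6


@dataclass
class HistoConfig:
    """Tunable parameters of the fiber pipeline."""

    use_find_edges: bool = False
    median_line: int = 20  # px
    n_directions: int = 15
    clahe_bins: int = 256  # fixed by the CLAHE parameterization
    emin_tolerance: float = 20.0  # grey levels
    min_area: float = 2000.0  # µm²
    max_area: float = 200_000.0  # µm²
    max_elongation: float = 4.0
    erosion_radius: int = 3  # px
    score_mode: str = "normalized"  # or "raw"
    lo_threshold: float | None = None  # defaults to -0.2 / -40 per mode
    hi_threshold: float | None = None  # defaults to +0.2 / +40 per mode
    hybrid_gI_min: float = 100.0  # grey, hybrid flag channel-I floor
    hybrid_gIIA_min: float = 100.0  # grey, hybrid flag channel-IIA floor
    raw_intensities: bool = True  # measure myosin channels without CLAHE
    report_eroded_area: bool = False  # spreadsheet CSA from eroded labels
    manual_checkpoint: bool = False
    eval_pre_erosion: bool = True

    def __post_init__(self) -> None:
        if self.score_mode not in ("normalized", "raw"):
            raise ValueError("score_mode must be 'normalized' or 'raw'")
        if self.lo_threshold is None:
            self.lo_threshold = -0.2 if self.score_mode == "normalized" else -40.0
        if self.hi_threshold is None:
            self.hi_threshold = 0.2 if self.score_mode == "normalized" else 40.0
        if not self.lo_threshold < self.hi_threshold:
            raise ValueError("lo_threshold must be < hi_threshold")
        if self.erosion_radius < 0:
            raise ValueError("erosion_radius must be >= 0")
        if not 0 <= self.min_area < self.max_area:
            raise ValueError("need 0 <= min_area < max_area")
        if self.median_line < 1 or self.n_directions < 1:
            raise ValueError("median_line and n_directions must be >= 1")


@dataclass
class FiberRecord:
    """Morphometry, channel intensities and attributed type of one fiber."""

    image_id: str
    fiber_id: int
    area: float  # µm²
    perimeter: float  # µm
    min_feret: float  # µm
    g_I: float
    g_IIA: float
    g_IIX: float | None = None
    delta_score: float | None = None
    fiber_type: str | None = None  # I, IIA or IIB_IIX
    hybrid_flag: bool = False

    def as_row(self, with_type: bool = True) -> dict:
        row = {
            "image_id": self.image_id,
            "fiber_id": self.fiber_id,
            "area": self.area,
            "perimeter": self.perimeter,
            "min_feret": self.min_feret,
            "g_I": self.g_I,
            "g_IIA": self.g_IIA,
        }
        if self.g_IIX is not None:
            row["g_IIX"] = self.g_IIX
        if with_type:
            row["delta_score"] = self.delta_score
            row["fiber_type"] = self.fiber_type
            row["hybrid"] = "Hybrid?" if self.hybrid_flag else ""
        return row


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def auto_clahe_params(img: np.ndarray) -> tuple[int, int, float]:
    """Adaptive CLAHE arguments from image width and mean grey.

    block_size = round(width / 5); 256 histogram bins;
    max_slope = (mean grey / 60) / 0.05, floored at 1 so a black image
    degenerates to a no-op rather than an error.
    """
    img = np.asarray(img)
    block = max(8, round(img.shape[1] / 5))
    slope = max(1.0, (float(img.mean()) / 60.0) / 0.05)
    return block, 256, slope


def preprocess_laminin(
    img: CalibratedImage, cfg: HistoConfig, return_stages: bool = False
):
    """Boundary-enhancing preprocessing of the outline-stain channel.

    Optional Sobel edge filter (for weak or heterogeneous stains), then a
    max-combined directional median that keeps and bridges curvilinear
    boundary segments while wiping speckle, then auto-parameterized CLAHE.
    Deterministic.

    With ``return_stages`` the pre-CLAHE (median) stage is returned alongside
    the CLAHE relief: the extended-minima tolerance is calibrated in original
    grey levels, so markers are detected on the median stage while the
    watershed floods the contrast-normalized relief.
    """
    px = img.pixels
    if cfg.use_find_edges:
        px = mo.find_edges(px)
    median_stage = mo.directional_filter(
        px, "median", "max", cfg.median_line, cfg.n_directions
    )
    block, bins, slope = auto_clahe_params(median_stage)
    relief = mo.clahe(median_stage, block, bins, slope)
    if return_stages:
        return median_stage, relief
    return relief


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_fibers(
    preprocessed: np.ndarray,
    cfg: HistoConfig,
    pixel_size: float,
    marker_image: np.ndarray | None = None,
) -> LabelMap:
    """Fiber labels from the preprocessed outline image (pre-erosion).

    Extended minima (dynamic ≥ ``emin_tolerance``) seed a marker-controlled
    watershed: fiber interiors are dark basins between boundary ridges.
    The minima are detected on ``marker_image`` when given (normally the
    pre-CLAHE median stage, whose grey levels match the tolerance's units;
    CLAHE can amplify flat-interior noise past any fixed tolerance), and the
    flood runs on ``preprocessed``.  Basins are trimmed by area, border
    contact and geodesic elongation (> ``max_elongation`` dropped).  Erosion
    is applied separately (see :func:`erode_for_measurement`) so the
    cross-sectional area can be reported from the un-eroded labels.
    """
    preprocessed = np.asarray(preprocessed, dtype=np.float64)
    basis = preprocessed if marker_image is None else np.asarray(
        marker_image, dtype=np.float64
    )
    markers = mo.extended_minima(basis, cfg.emin_tolerance)
    if not markers.any():
        return LabelMap(np.zeros(preprocessed.shape, np.int32), pixel_size)
    labels = mo.marker_watershed(preprocessed, markers)
    return trim_fibers(LabelMap(labels, pixel_size), cfg)


def trim_fibers(lm: LabelMap, cfg: HistoConfig) -> LabelMap:
    """Area, border and geodesic-elongation trimming of putative fibers."""
    labels = mo.filter_labels_by_area(
        lm.labels, cfg.min_area, cfg.max_area, lm.pixel_size
    )
    labels = mo.kill_border(labels)
    elong = mo.geodesic_elongation(labels)
    bad = [i for i, e in elong.items() if e > cfg.max_elongation]
    if bad:
        labels[np.isin(labels, bad)] = 0
    return LabelMap(labels, lm.pixel_size)


def erode_for_measurement(lm: LabelMap, cfg: HistoConfig) -> LabelMap:
    """Per-label disk erosion that keeps intensity measures off the boundary."""
    return LabelMap(mo.erode_labels(lm.labels, cfg.erosion_radius), lm.pixel_size)


# ---------------------------------------------------------------------------
# intensities and typing
# ---------------------------------------------------------------------------


def measure_intensities(
    lm: LabelMap,
    channels: dict[str, CalibratedImage],
    apply_clahe: bool = True,
) -> pd.DataFrame:
    """Mean grey per (eroded) label on each myosin channel.

    Each channel first receives its own auto-parameterized CLAHE (matching
    the contrast adjustment the typing thresholds were designed against)
    unless ``apply_clahe`` is false.
    """
    ids = lm.ids
    out = pd.DataFrame({"fiber_id": ids})
    for name, ch in channels.items():
        if ch.pixels.shape != lm.labels.shape:
            raise ValueError(f"channel {name} shape {ch.pixels.shape} does not "
                             f"match labels {lm.labels.shape}")
        px = ch.pixels
        if apply_clahe:
            block, bins, slope = auto_clahe_params(px)
            px = mo.clahe(px, block, bins, slope)
        means = ndi.mean(px, labels=lm.labels, index=ids) if len(ids) else []
        out[f"g_{name}"] = list(means)
    return out


def delta_score(g_I: float, g_IIA: float, mode: str = "normalized") -> float:
    """Type-attribution score from the two myosin intensities.

    ``raw``: g_I − g_IIA in grey levels (the ±40 rule operates on this);
    ``normalized``: the symmetric contrast (g_I − g_IIA)/(g_I + g_IIA + ε),
    guaranteed inside (−1, 1) (the ±0.2 rule operates on this).
    """
    if g_I < 0 or g_IIA < 0:
        raise ValueError("mean grey values must be >= 0")
    if mode == "raw":
        return float(g_I - g_IIA)
    if mode == "normalized":
        return float((g_I - g_IIA) / (g_I + g_IIA + _EPS))
    raise ValueError("mode must be 'normalized' or 'raw'")


def attribute_type(score: float, cfg: HistoConfig) -> str:
    """score < lo → IIA; score > hi → I; otherwise (ties included) IIB_IIX."""
    if score < cfg.lo_threshold:
        return "IIA"
    if score > cfg.hi_threshold:
        return "I"
    return "IIB_IIX"


def flag_hybrid(record: FiberRecord, cfg: HistoConfig) -> bool:
    """Putative I/IIA hybrid: an IIB/IIX call with both channels bright.

    Hybrids express both myosins, so both mean greys sit above their floors
    while the difference score stays inside the IIB/IIX window.
    """
    return (
        record.fiber_type == "IIB_IIX"
        and record.g_I >= cfg.hybrid_gI_min
        and record.g_IIA >= cfg.hybrid_gIIA_min
    )


# ---------------------------------------------------------------------------
# label utilities (label-image editing pipeline)
# ---------------------------------------------------------------------------


def remove_labels(lm: LabelMap, ids: Sequence[int]) -> LabelMap:
    """Zero out the listed label ids."""
    labels = lm.labels.copy()
    ids = np.asarray(list(ids))
    if ids.size:
        labels[np.isin(labels, ids)] = 0
    return LabelMap(labels, lm.pixel_size)


def find_label(lm: LabelMap, label_id: int) -> tuple[float, float] | None:
    """Centroid (x, y) of a label, or None when absent."""
    mask = lm.labels == label_id
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    return float(xs.mean()), float(ys.mean())


def relabel_sequential(lm: LabelMap) -> LabelMap:
    """Renumber labels 1..n in raster order of each label's first pixel."""
    flat = lm.labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    keep = ids > 0
    order = np.argsort(first[keep])
    mapping = np.zeros(int(lm.labels.max()) + 1, dtype=lm.labels.dtype)
    for new, old in enumerate(ids[keep][order], start=1):
        mapping[old] = new
    return LabelMap(mapping[lm.labels], lm.pixel_size)


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------


def _matched_files(*dirs) -> list[tuple[Path, ...]]:
    lists = []
    for d in dirs:
        files = sorted(
            p for p in Path(d).iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        lists.append(files)
    counts = {len(l) for l in lists}
    if len(counts) != 1:
        raise ValueError(
            "channel folders hold different file counts: "
            + ", ".join(f"{d}: {len(l)}" for d, l in zip(dirs, lists))
        )
    return list(zip(*lists))


def process_section(
    laminin: CalibratedImage,
    ch_I: CalibratedImage,
    ch_IIA: CalibratedImage,
    ch_IIX: CalibratedImage | None,
    cfg: HistoConfig,
    image_id: str = "section",
    edited_labels: LabelMap | None = None,
) -> tuple[LabelMap, LabelMap, list[FiberRecord]]:
    """Segment + measure one section; returns (labels, eroded labels, records).

    ``edited_labels`` replaces the automatic segmentation (the file-based
    manual-checkpoint round trip).  With a type-IIX channel present the
    pipeline runs in measurement-only mode: three intensities per fiber and
    no type attribution.
    """
    if edited_labels is not None:
        lm = edited_labels
    else:
        median_stage, relief = preprocess_laminin(laminin, cfg, return_stages=True)
        lm = segment_fibers(relief, cfg, laminin.pixel_size,
                            marker_image=median_stage)
    eroded = erode_for_measurement(lm, cfg)

    channels = {"I": ch_I, "IIA": ch_IIA}
    if ch_IIX is not None:
        channels["IIX"] = ch_IIX
    gtab = measure_intensities(eroded, channels, apply_clahe=not cfg.raw_intensities)
    gtab = gtab.set_index("fiber_id")

    area_map = eroded if cfg.report_eroded_area else lm
    morpho = {m.label_id: m for m in region_morphometry(area_map)}

    records: list[FiberRecord] = []
    for fid in eroded.ids:
        if fid not in morpho:  # label vanished under erosion settings
            continue
        m = morpho[fid]
        rec = FiberRecord(
            image_id=image_id,
            fiber_id=int(fid),
            area=m.area,
            perimeter=m.perimeter,
            min_feret=m.min_feret,
            g_I=float(gtab.loc[fid, "g_I"]),
            g_IIA=float(gtab.loc[fid, "g_IIA"]),
            g_IIX=float(gtab.loc[fid, "g_IIX"]) if ch_IIX is not None else None,
        )
        if ch_IIX is None:
            rec.delta_score = delta_score(rec.g_I, rec.g_IIA, cfg.score_mode)
            rec.fiber_type = attribute_type(rec.delta_score, cfg)
            rec.hybrid_flag = flag_hybrid(rec, cfg)
        records.append(rec)
    return lm, eroded, records


def records_to_frame(records: Sequence[FiberRecord], with_type: bool) -> pd.DataFrame:
    cols = ["image_id", "fiber_id", "area", "perimeter", "min_feret", "g_I", "g_IIA"]
    if not with_type:
        cols = cols + ["g_IIX"]
    else:
        cols = cols + ["delta_score", "fiber_type", "hybrid"]
    return pd.DataFrame([r.as_row(with_type=with_type) for r in records], columns=cols)


def run_histo(
    laminin_dir,
    typeI_dir,
    typeIIA_dir,
    out_dir,
    typeIIX_dir=None,
    cfg: HistoConfig | None = None,
    default_pixel_size: float | None = None,
    write_xlsx: bool = False,
    checkpoint_hook=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Batch driver over matched channel folders (sorted-name pairing).

    With ``manual_checkpoint`` enabled the segmentation label raster is
    written to disk and, when ``checkpoint_hook`` (called with the label
    TIFF path) returns, re-imported before measurement — the file-based
    label-editing round trip.  Per-image failures are logged and returned;
    the batch continues.
    """
    cfg = cfg or HistoConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dirs = [laminin_dir, typeI_dir, typeIIA_dir]
    if typeIIX_dir is not None:
        dirs.append(typeIIX_dir)
    groups = _matched_files(*dirs)
    with_type = typeIIX_dir is None
    all_records: list[FiberRecord] = []
    failures: list[dict] = []
    kwargs = {}
    if default_pixel_size is not None:
        kwargs["default_pixel_size"] = default_pixel_size
    for group in groups:
        stem = group[0].stem
        try:
            lam = read_image(group[0], channel_role="outline_stain", **kwargs)
            chI = read_image(group[1], channel_role="mhc_I", **kwargs)
            chIIA = read_image(group[2], channel_role="mhc_IIA", **kwargs)
            chIIX = (
                read_image(group[3], channel_role="mhc_IIX", **kwargs)
                if typeIIX_dir is not None
                else None
            )
            edited = None
            if cfg.manual_checkpoint:
                med0, rel0 = preprocess_laminin(lam, cfg, return_stages=True)
                lm0 = segment_fibers(rel0, cfg, lam.pixel_size,
                                     marker_image=med0)
                import tifffile

                ck = out_dir / f"{stem}_labels_checkpoint.tif"
                tifffile.imwrite(ck, lm0.labels.astype(np.uint16))
                if checkpoint_hook is not None:
                    checkpoint_hook(ck)
                edited = LabelMap(
                    tifffile.imread(ck).astype(np.int32), lam.pixel_size
                )
            lm, eroded, records = process_section(
                lam, chI, chIIA, chIIX, cfg, image_id=stem, edited_labels=edited
            )
            df = records_to_frame(records, with_type)
            write_outputs(lm, df, out_dir, stem, original=lam, write_xlsx=write_xlsx)
            all_records.extend(records)
            log.info("%s: %d fibers", stem, len(records))
        except Exception as exc:
            failures.append({"image": str(group[0]), "error": str(exc)})
            log.error("failed on %s: %s", group[0], exc)
    combined = records_to_frame(all_records, with_type)
    combined.to_csv(out_dir / "fibers_combined.csv", index=False, float_format="%.6g")
    return combined, failures
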