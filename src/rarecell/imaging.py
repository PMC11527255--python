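"""Multi-channel immunofluorescence slide segmentation and feature extraction.

Slides carry one grayscale plane per stain: DAPI (nuclei), EPI
(pan-cytokeratin epithelial cocktail), CD45 (leukocyte exclusion marker)
and VAR (a variable fourth channel for candidate markers).  Each channel
is segmented independently by adaptive (local-mean) thresholding; the
per-channel masks are merged by union into a single cell mask, and the
DAPI mask defines nuclei.  Per-object morphometric features and raw
intensity statistics are extracted for downstream phenotype gating.
Nuclear size is summarized as the equivalent diameter — the diameter of
the circle whose area equals the measured nucleus area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_local
from skimage.measure import label as cc_label

__all__ = [
    "SlideImage",
    "SegmentationConfig",
    "CellRecord",
    "segment_channel",
    "build_cell_mask",
    "extract_cells",
    "estimate_background",
    "equivalent_diameter",
    "count_fish_spots",
    "records_to_frame",
    "read_slide_tiff",
    "write_slide_tiff",
]

DEFAULT_CHANNELS = ("DAPI", "EPI", "CD45", "VAR")


@dataclass
class SlideImage:
    """Aligned multi-channel slide: named 2-D intensity planes + pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, ch: str) -> np.ndarray:
        if ch not in self.channels:
            raise KeyError(f"channel {ch!r} not in slide (has {list(self.channels)})")
        return self.channels[ch]


@dataclass
class SegmentationConfig:
    """Adaptive-threshold segmentation parameters.

    A pixel is foreground when its intensity exceeds the local arithmetic
    mean over a ``block_size_px`` neighborhood by more than ``offset``
    intensity units.  ``offset`` should sit a few noise standard
    deviations above zero; objects below ``min_object_area_px`` are
    discarded as debris.
    """

    block_size_px: int = 51
    offset: float = 40.0
    min_object_area_px: int = 20
    channels_for_cell_mask: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.block_size_px < 3 or self.block_size_px % 2 == 0:
            raise ValueError("block_size_px must be an odd integer >= 3")
        if self.min_object_area_px < 1:
            raise ValueError("min_object_area_px must be >= 1")


@dataclass
class CellRecord:
    """One segmented object with morphometry and per-channel intensities.

    ``channel_stats`` maps ``"<channel>_<region>_<stat>"`` (region in
    {cell, nucleus}; stat in {mean, median, max, total}) to a float.
    Nucleus features are NaN when the cell contains no DAPI component
    (``n_nuclei == 0``); such cells are reported, not dropped.
    """

    cell_id: int
    centroid: tuple[float, float]  # (row, col) in pixels
    cell_area_px: int
    cell_area_um2: float
    nucleus_area_px: int
    nucleus_area_um2: float
    nucleus_equivalent_diameter_um: float
    n_nuclei: int
    channel_stats: dict[str, float] = field(default_factory=dict)


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: d = 2 sqrt(A / pi)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area_um2 / np.pi)


def segment_channel(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Adaptive-threshold one channel into a binary foreground mask.

    Foreground iff intensity > local mean over ``block_size_px`` minus
    ``offset`` is exceeded, i.e. ``image > local_mean + offset`` after
    sign bookkeeping; small objects are removed.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if cfg.block_size_px > min(image.shape):
        raise ValueError(
            f"block_size_px {cfg.block_size_px} exceeds image extent {image.shape}"
        )
    local_mean = threshold_local(
        image, block_size=cfg.block_size_px, method="mean", offset=0.0
    )
    mask = image > (local_mean + cfg.offset)
    labels = cc_label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < cfg.min_object_area_px)
    return mask & ~np.isin(labels, small[small > 0])


def build_cell_mask(slide: SlideImage, cfg: SegmentationConfig) -> np.ndarray:
    """Merge per-channel masks into one labeled cell mask.

    Pixelwise union (logical OR) of the adaptive masks of the configured
    channels, then 8-connected component labeling.  Union is commutative
    and idempotent, so channel order never matters.
    """
    if not cfg.channels_for_cell_mask:
        raise ValueError("channels_for_cell_mask is empty")
    missing = [ch for ch in cfg.channels_for_cell_mask if ch not in slide.channels]
    if missing:
        raise ValueError(f"slide lacks channels {missing}")
    union = np.zeros(slide.shape, dtype=bool)
    for ch in cfg.channels_for_cell_mask:
        union |= segment_channel(slide[ch], cfg)
    return cc_label(union, connectivity=2)


def estimate_background(slide: SlideImage, cell_mask: np.ndarray) -> dict[str, tuple[float, float]]:
    """Per-channel background (median, sd) over non-cell pixels.

    Used by gating to set positivity thresholds; the median is robust to
    the few bright foreground pixels that escape the mask.
    """
    bg = cell_mask == 0
    out = {}
    for ch, img in slide.channels.items():
        vals = np.asarray(img, dtype=float)[bg]
        out[ch] = (float(np.median(vals)), float(vals.std()))
    return out


def extract_cells(
    slide: SlideImage,
    cell_mask: np.ndarray,
    dapi_mask: np.ndarray,
    cfg: SegmentationConfig,
) -> list[CellRecord]:
    """One CellRecord per labeled cell; nucleus = DAPI components inside it.

    Intensity statistics are computed over the original, unthresholded
    intensities on both the cell mask and the nucleus mask.  A cell
    without any DAPI component keeps ``n_nuclei = 0`` and NaN nucleus
    features rather than being dropped.
    """
    if cell_mask.shape != slide.shape or dapi_mask.shape != slide.shape:
        raise ValueError("masks must match the slide shape")
    px_area = slide.pixel_size_um**2
    dapi_labels = cc_label(np.asarray(dapi_mask, dtype=bool), connectivity=2)

    records: list[CellRecord] = []
    objects = ndimage.find_objects(cell_mask)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        local = cell_mask[sl] == lab
        rr, cc = np.nonzero(local)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        cell_area_px = int(local.sum())
        centroid = (float(rows.mean()), float(cols.mean()))

        nuc_ids = np.unique(dapi_labels[sl][local])
        nuc_ids = nuc_ids[nuc_ids > 0]
        # full extent of each intersecting DAPI component, not just the overlap
        if nuc_ids.size:
            nuc_mask_local = np.isin(dapi_labels[sl], nuc_ids) & local
            nucleus_area_px = int(nuc_mask_local.sum())
        else:
            nuc_mask_local = np.zeros_like(local)
            nucleus_area_px = 0

        stats: dict[str, float] = {}
        for ch, img in slide.channels.items():
            plane = np.asarray(img, dtype=float)[sl]
            cell_vals = plane[local]
            stats[f"{ch}_cell_mean"] = float(cell_vals.mean())
            stats[f"{ch}_cell_median"] = float(np.median(cell_vals))
            stats[f"{ch}_cell_max"] = float(cell_vals.max())
            stats[f"{ch}_cell_total"] = float(cell_vals.sum())
            if nucleus_area_px:
                nuc_vals = plane[nuc_mask_local]
                stats[f"{ch}_nucleus_mean"] = float(nuc_vals.mean())
                stats[f"{ch}_nucleus_median"] = float(np.median(nuc_vals))
                stats[f"{ch}_nucleus_max"] = float(nuc_vals.max())
                stats[f"{ch}_nucleus_total"] = float(nuc_vals.sum())
            else:
                for s in ("mean", "median", "max", "total"):
                    stats[f"{ch}_nucleus_{s}"] = float("nan")

        nucleus_area_um2 = nucleus_area_px * px_area
        records.append(
            CellRecord(
                cell_id=lab,
                centroid=centroid,
                cell_area_px=cell_area_px,
                cell_area_um2=cell_area_px * px_area,
                nucleus_area_px=nucleus_area_px,
                nucleus_area_um2=nucleus_area_um2,
                nucleus_equivalent_diameter_um=(
                    equivalent_diameter(nucleus_area_um2) if nucleus_area_px else float("nan")
                ),
                n_nuclei=int(nuc_ids.size),
                channel_stats=stats,
            )
        )
    return records


def count_fish_spots(
    dapi_nucleus_mask: np.ndarray,
    spot_channel: np.ndarray,
    min_distance: int = 3,
    k_sigma: float = 5.0,
) -> dict[int, int]:
    """Count FISH puncta (e.g. centromere probes) per nucleus.

    Local maxima in the spot channel are detected above the background
    median plus ``k_sigma`` background standard deviations, restricted to
    nucleus interiors; puncta closer than ``min_distance`` pixels merge.
    Returns {nucleus label: spot count}; puncta outside every nucleus are
    ignored.
    """
    spot_channel = np.asarray(spot_channel, dtype=float)
    mask = np.asarray(dapi_nucleus_mask)
    if mask.shape != spot_channel.shape:
        raise ValueError("spot channel must be aligned with the nucleus mask")
    labels = mask if mask.dtype != bool else cc_label(mask, connectivity=2)
    bg_vals = spot_channel[labels == 0]
    thr = float(np.median(bg_vals) + k_sigma * bg_vals.std()) if bg_vals.size else 0.0
    counts = {int(lab): 0 for lab in np.unique(labels) if lab > 0}
    peaks = peak_local_max(
        spot_channel, min_distance=min_distance, threshold_abs=thr, labels=labels
    )
    for r, c in peaks:
        counts[int(labels[r, c])] += 1
    return counts


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten CellRecords into a feature table (one row per cell)."""
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "cell_area_px": r.cell_area_px,
            "cell_area_um2": r.cell_area_um2,
            "nucleus_area_px": r.nucleus_area_px,
            "nucleus_area_um2": r.nucleus_area_um2,
            "nucleus_equivalent_diameter_um": r.nucleus_equivalent_diameter_um,
            "n_nuclei": r.n_nuclei,
        }
        row.update(r.channel_stats)
        rows.append(row)
    return pd.DataFrame(rows)


def write_slide_tiff(slide: SlideImage, path) -> None:
    """Write a slide as multi-page 16-bit TIFF (one page per channel)."""
    meta = {"channels": list(slide.channels), "pixel_size_um": slide.pixel_size_um}
    pages = np.stack(
        [np.clip(slide.channels[ch], 0, 65535).astype(np.uint16) for ch in slide.channels]
    )
    tifffile.imwrite(
        path, pages, photometric="minisblack", planarconfig="separate",
        description=json.dumps(meta),
    )


def read_slide_tiff(path) -> SlideImage:
    """Read a multi-page TIFF written by :func:`write_slide_tiff`."""
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    channels = {ch: pages[i].astype(float) for i, ch in enumerate(meta["channels"])}
    return SlideImage(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))
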