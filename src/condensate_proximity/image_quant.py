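"""Droplet (puncta) detection and image-level condensate statistics.

Given one or more fluorescence channels of a cell, this module computes the
three quantities used throughout condensate image analysis:

* the **condensate-formation ratio** — the fraction of a cell's total channel
  intensity residing in detected puncta above an area cutoff,
* the **partition coefficient (PC)** — mean per-pixel intensity inside puncta
  divided by mean per-pixel intensity outside (within the cell), a proxy for
  concentration enrichment of the tagged protein in the dense phase,
* **channel signal ratios** (e.g. GFP/mCh or Dronpa/mCh) over a whole cell or
  over individual droplets, reporting interaction-probe turn-on per scaffold.

Puncta are 8-connected components above an intensity threshold; components
are retained only if their physical area is *strictly greater* than the
configured minimum (default 0.01 um^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "ChannelImage",
    "PunctaSet",
    "PartitionResult",
    "estimate_cell_mask",
    "segment_puncta",
    "condensate_fraction",
    "partition_coefficient",
    "signal_ratio",
]


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel: a 2D intensity field with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of nonnegative intensities (arbitrary units).
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if np.any(px < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass(frozen=True)
class PunctaSet:
    """Labelled droplet regions with per-region area and intensity records.

    ``labels`` is a 2D integer field (0 = background) whose positive values
    are contiguous region ids 1..n matching the rows of ``regions``
    (columns: label, area_um2, total_intensity, mean_intensity).
    """

    labels: np.ndarray
    regions: pd.DataFrame
    min_area_um2: float
    threshold: float | None = None

    @property
    def n_puncta(self) -> int:
        return len(self.regions)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of all puncta pixels."""
        return self.labels > 0


@dataclass(frozen=True)
class PartitionResult:
    """Partition coefficient: mean intensity inside puncta over mean outside."""

    pc: float
    mean_inside: float
    mean_outside: float


def estimate_cell_mask(img: ChannelImage, quantile: float = 0.05) -> np.ndarray:
    """Crude cell outline: pixels above a low fixed quantile of the channel.

    Intended for synthetic frames where the cell fills the field; real cell
    outlines are normally supplied explicitly.
    """
    cutoff = np.quantile(img.pixels, quantile)
    return img.pixels >= cutoff


def _resolve_threshold(
    values: np.ndarray, threshold_mode: str | float
) -> float | None:
    if isinstance(threshold_mode, str):
        if threshold_mode != "otsu":
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        if np.ptp(values) == 0:
            warnings.warn(
                "image is constant within the cell mask; automatic threshold "
                "is undefined, returning zero puncta",
                stacklevel=3,
            )
            return None
        return float(threshold_otsu(values))
    return float(threshold_mode)


def segment_puncta(
    img: ChannelImage,
    cell_mask: np.ndarray | None = None,
    threshold_mode: str | float = "otsu",
    min_area_um2: float = 0.01,
) -> PunctaSet:
    """Detect condensate puncta in one channel.

    Pixels within ``cell_mask`` whose intensity is strictly above the
    threshold are grouped into 8-connected components; components whose area
    is <= ``min_area_um2`` are discarded (strictly greater-than retained).

    Parameters
    ----------
    img
        Channel to segment.
    cell_mask
        Boolean mask restricting the analysis to one cell. ``None`` means the
        whole frame.
    threshold_mode
        ``"otsu"`` for Otsu's threshold computed within the cell mask, or a
        fixed intensity value.
    min_area_um2
        Area cutoff in um^2; regions must exceed it strictly.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    if cell_mask is None:
        cell_mask = np.ones(img.pixels.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != img.pixels.shape:
        raise ValueError("cell_mask shape must match image shape")
    if not cell_mask.any():
        raise ValueError("cell_mask is empty")

    thr = _resolve_threshold(img.pixels[cell_mask], threshold_mode)
    empty = PunctaSet(
        labels=np.zeros(img.pixels.shape, dtype=np.int32),
        regions=pd.DataFrame(
            columns=["label", "area_um2", "total_intensity", "mean_intensity"]
        ),
        min_area_um2=min_area_um2,
        threshold=thr,
    )
    if thr is None:
        return empty

    binary = (img.pixels > thr) & cell_mask
    raw = _cc_label(binary, connectivity=2)
    if raw.max() == 0:
        return empty

    pixel_area = img.pixel_area_um2
    labels = np.zeros_like(raw, dtype=np.int32)
    records = []
    next_id = 1
    for lab in range(1, raw.max() + 1):
        region = raw == lab
        area = int(region.sum()) * pixel_area
        # strict >: regions whose area equals the cutoff (to fp tolerance) drop
        if area <= min_area_um2 * (1.0 + 1e-9):
            continue
        vals = img.pixels[region]
        labels[region] = next_id
        records.append(
            {
                "label": next_id,
                "area_um2": area,
                "total_intensity": float(vals.sum()),
                "mean_intensity": float(vals.mean()),
            }
        )
        next_id += 1
    regions = pd.DataFrame.from_records(
        records, columns=["label", "area_um2", "total_intensity", "mean_intensity"]
    )
    return PunctaSet(labels=labels, regions=regions, min_area_um2=min_area_um2, threshold=thr)


def condensate_fraction(
    img: ChannelImage, puncta: PunctaSet, cell_mask: np.ndarray | None = None
) -> float:
    """Condensate-formation ratio: summed puncta intensity over whole-cell intensity.

    Returns Σ(intensity over puncta pixels) / Σ(intensity over cell_mask),
    a value in [0, 1]. Invariant under multiplication of the image by a
    positive constant.
    """
    if cell_mask is None:
        cell_mask = np.ones(img.pixels.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    total = float(img.pixels[cell_mask].sum())
    if total <= 0:
        raise ValueError("total cell intensity is zero")
    inside = float(img.pixels[puncta.mask & cell_mask].sum())
    return inside / total


def partition_coefficient(
    img: ChannelImage, puncta: PunctaSet, cell_mask: np.ndarray | None = None
) -> PartitionResult:
    """Partition coefficient: mean per-pixel intensity inside puncta / outside.

    'Outside' is the cell mask minus puncta pixels. Mean (not summed)
    intensities are used so that regions of unequal area compare scale-free.
    """
    if cell_mask is None:
        cell_mask = np.ones(img.pixels.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    inside_mask = puncta.mask & cell_mask
    outside_mask = cell_mask & ~puncta.mask
    if not inside_mask.any():
        raise ValueError("no puncta pixels inside the cell mask")
    if not outside_mask.any():
        raise ValueError("outside region is empty")
    mean_in = float(img.pixels[inside_mask].mean())
    mean_out = float(img.pixels[outside_mask].mean())
    if mean_out <= 0:
        raise ValueError("mean outside intensity is zero")
    return PartitionResult(pc=mean_in / mean_out, mean_inside=mean_in, mean_outside=mean_out)


def signal_ratio(
    num: ChannelImage, den: ChannelImage, region_mask: np.ndarray
) -> float:
    """Total-intensity ratio of two channels over a region (cell or droplet).

    Returns Σ num / Σ den over ``region_mask``; used for GFP/mCh- or
    Dronpa/mCh-style probe turn-on ratios.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region_mask is empty")
    if num.pixels.shape != den.pixels.shape:
        raise ValueError("channel shapes differ")
    den_sum = float(den.pixels[region_mask].sum())
    if den_sum <= 0:
        raise ValueError("denominator channel sums to zero over the region")
    return float(num.pixels[region_mask].sum()) / den_sum
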