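"""Semi-automated cortical ER morphology quantification.

Cortical (tangential) sections show the peripheral ER as a network of
tubules plus sheet patches.  Each marker channel is segmented in two passes
with ring-kernel contrast tests — one tuned for small features (tubules),
one for large features (sheets) — gated by an Otsu-derived background level.
Sheets are then separated from tubules by a morphological opening whose
degree is set by the "trimming factor":

* features of the general-marker (Sec63) mask that survive the opening are
  provisional sheets, the rest are tubules;
* sheet-like regions of the curvature-marker (Rtn1) mask that overlap the
  Sec63 mask are "tubular clusters" — dense tubule tangles that masquerade
  as sheets in the general marker; they are moved from sheets to tubules.

Final tubule and sheet masks exactly partition the Sec63 total-ER mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, restoration, segmentation, transform

__all__ = [
    "ClassifierParams",
    "ChannelMasks",
    "CorticalClassification",
    "rolling_ball_background",
    "preprocess_brightfield",
    "ring_kernel",
    "feature_segment",
    "segment_channel",
    "classify",
    "assign_to_cells",
    "summarize_population",
    "segment_cells_from_brightfield",
    "classify_cortical_field",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Segmentation and classification parameters.

    Radii are ring-kernel radii in pixels; strengths are contrast thresholds
    on the [0, 1]-normalized image (a pixel must exceed the mean of its
    surrounding ring by more than the strength).  ``tubule_bg`` and
    ``total_er_bg`` multiply the Otsu background level of the curvature and
    general channel, respectively.  ``trimming_factor`` is the opening radius
    separating sheet-like from tubule-like features.
    """

    tubule_radius: float = 2.0
    sheet_radius: float = 10.0
    tubule_strength: float = 0.02
    sheet_strength: float = 0.01
    tubule_bg: float = 1.0
    total_er_bg: float = 1.0
    trimming_factor: float = 3.0
    rolling_ball_radius: float = 50.0

    def __post_init__(self) -> None:
        if self.tubule_radius < 1 or self.sheet_radius < 1:
            raise ValueError("ring radii must be >= 1")
        if self.sheet_radius <= self.tubule_radius:
            raise ValueError("sheet_radius must exceed tubule_radius")
        if self.tubule_bg <= 0 or self.total_er_bg <= 0:
            raise ValueError("background multipliers must be > 0")
        if self.trimming_factor < 0:
            raise ValueError("trimming_factor must be >= 0")


@dataclass
class ChannelMasks:
    """Small- and large-feature segmentation masks of one channel."""

    small_feature_mask: np.ndarray
    large_feature_mask: np.ndarray

    @property
    def total_mask(self) -> np.ndarray:
        return self.small_feature_mask | self.large_feature_mask


@dataclass
class CorticalClassification:
    tubule_mask: np.ndarray
    sheet_mask: np.ndarray
    cluster_mask: np.ndarray


def rolling_ball_background(image: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction; the result is >= 0 everywhere.

    The ball's intensity semi-axis scales with the image's intensity range so
    the operation commutes with global intensity scaling (as Fiji's rolling
    ball effectively does via image-type scaling).
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    ptp = np.ptp(image)
    if ptp == 0:
        return np.zeros_like(image)
    kernel = restoration.ellipsoid_kernel(
        (radius * 2, radius * 2), 0.2 * ptp
    )
    background = restoration.rolling_ball(image, kernel=kernel)
    return np.clip(image - background, 0.0, None)


def preprocess_brightfield(bf: np.ndarray) -> np.ndarray:
    """Enhance cell outlines in a bright-field image.

    Gaussian blur (sigma 2) to suppress noise, 0.5x downscale to suppress
    small detail, tubeness (sigma 1) to highlight the cell border, and
    upscale back to the original resolution.
    """
    bf = np.asarray(bf, dtype=float)
    blurred = ndi.gaussian_filter(bf, 2.0)
    small = transform.rescale(blurred, 0.5, anti_aliasing=True)
    if np.ptp(small) == 0:
        return np.zeros_like(bf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tube = filters.sato(small, sigmas=(1.0,), black_ridges=True)
    out = transform.resize(tube, bf.shape, anti_aliasing=True)
    return out


def ring_kernel(radius: float) -> np.ndarray:
    """Normalized ring (annulus) convolution kernel of inner radius ``radius``.

    The annulus spans Euclidean distances in [radius, radius + 1] from the
    center (center weight 0) and is widened by 0.5 px if it would contain
    fewer than 8 pixels; weights are uniform and sum to 1.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    outer = radius + 1.0
    size = int(np.ceil(outer)) * 2 + 1
    c = size // 2
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.hypot(rr - c, cc - c)
    ring = (dist >= radius) & (dist <= outer)
    ring[c, c] = False
    if ring.sum() < 8:
        ring = (dist >= radius - 0.5) & (dist <= outer + 0.5)
        ring[c, c] = False
    kernel = ring.astype(float)
    return kernel / kernel.sum()


def feature_segment(
    channel: np.ndarray, radius: float, strength: float, bg_multiplier: float
) -> np.ndarray:
    """One ring-kernel segmentation pass on a [0, 1]-normalized channel.

    A pixel is segmented when its 3x3-median-filtered intensity exceeds the
    mean of the surrounding ring by more than ``strength`` AND exceeds the
    Otsu threshold of the image times ``bg_multiplier``.
    """
    channel = np.asarray(channel, dtype=float)
    if np.ptp(channel) == 0:
        warnings.warn("constant image: background level undefined, empty mask")
        return np.zeros(channel.shape, dtype=bool)
    med = ndi.median_filter(channel, size=3)
    ring_mean = ndi.convolve(med, ring_kernel(radius), mode="reflect")
    bg_level = filters.threshold_otsu(channel) * bg_multiplier
    return (med - ring_mean > strength) & (med > bg_level)


def segment_channel(
    channel: np.ndarray, params: ClassifierParams, channel_role: str
) -> ChannelMasks:
    """Two-pass (small/large feature) segmentation of one marker channel.

    ``channel_role`` selects the background multiplier: ``"general"`` uses
    ``total_er_bg`` (Sec63-like), ``"curvature"`` uses ``tubule_bg``
    (Rtn1-like).
    """
    if channel_role not in ("general", "curvature"):
        raise ValueError("channel_role must be 'general' or 'curvature'")
    bg = params.total_er_bg if channel_role == "general" else params.tubule_bg
    small = feature_segment(channel, params.tubule_radius, params.tubule_strength, bg)
    large = feature_segment(channel, params.sheet_radius, params.sheet_strength, bg)
    return ChannelMasks(small_feature_mask=small, large_feature_mask=large)


def _sheetlike(mask: np.ndarray, radius: int) -> np.ndarray:
    """Regions of a binary mask that survive an opening with a disk of the
    given radius: wide (sheet-like) features at close to their full extent,
    with structures narrower than the disk removed.

    A reconstruction back to the full connected component is deliberately
    not applied: the cortical ER is usually one connected network, so
    reconstruction would designate the entire network sheet-like as soon as
    any patch survived the opening.
    """
    if radius <= 0:
        return mask.copy()
    return morphology.opening(mask, morphology.disk(radius))


def classify(
    sec63_masks: ChannelMasks,
    rtn1_masks: ChannelMasks,
    trimming_factor: float,
) -> CorticalClassification:
    """Tubule / sheet / tubular-cluster classification from the channel masks.

    Sheet-like = survives an opening with a disk of radius ``trimming_factor``.
    Tubular clusters are
    sheet-like Rtn1 regions overlapping the Sec63 mask; they are subtracted
    from sheets and added to tubules.
    """
    sec_total = sec63_masks.total_mask
    rtn_total = rtn1_masks.total_mask
    if sec_total.shape != rtn_total.shape:
        raise ValueError("channel masks differ in shape")
    r = int(round(trimming_factor))
    provisional_sheets = _sheetlike(sec_total, r)
    tubules = sec_total & ~provisional_sheets
    rtn_sheetlike = _sheetlike(rtn_total, r)
    clusters = rtn_sheetlike & sec_total
    sheets = provisional_sheets & ~clusters
    tubules = tubules | clusters
    return CorticalClassification(
        tubule_mask=tubules, sheet_mask=sheets, cluster_mask=clusters
    )


def assign_to_cells(
    classification: CorticalClassification, cell_labels: np.ndarray
) -> pd.DataFrame:
    """Per-cell class areas and cortex-coverage fractions.

    ER pixels outside any labeled cell are ignored; the cortex area of a cell
    is its label area in the cortical section.
    """
    labels = np.asarray(cell_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for i in ids:
        cell = labels == i
        cortex = int(cell.sum())
        t = int((classification.tubule_mask & cell).sum())
        s = int((classification.sheet_mask & cell).sum())
        c = int((classification.cluster_mask & cell).sum())
        rows.append(
            {
                "cell": int(i),
                "tubule_area_px": t,
                "sheet_area_px": s,
                "cluster_area_px": c,
                "cortex_area_px": cortex,
                "tubule_fraction": t / cortex if cortex else 0.0,
                "sheet_fraction": s / cortex if cortex else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell",
            "tubule_area_px",
            "sheet_area_px",
            "cluster_area_px",
            "cortex_area_px",
            "tubule_fraction",
            "sheet_fraction",
        ],
    )


def summarize_population(per_cell: pd.DataFrame) -> dict[str, float]:
    """Median class measurements across the whole cell population."""
    if len(per_cell) == 0:
        raise ValueError("empty cell population")
    return {
        "median_tubule_fraction": float(per_cell["tubule_fraction"].median()),
        "median_sheet_fraction": float(per_cell["sheet_fraction"].median()),
        "median_cluster_area_px": float(per_cell["cluster_area_px"].median()),
        "n_cells": int(len(per_cell)),
    }


def segment_cells_from_brightfield(
    bf: np.ndarray, min_area: int = 200
) -> np.ndarray:
    """Fallback cortical cell segmenter (bright-field outline + watershed).

    Used when no external label mask is supplied.
    """
    outline = preprocess_brightfield(bf)
    if np.ptp(outline) == 0:
        return np.zeros(bf.shape, dtype=np.int32)
    border = outline > filters.threshold_otsu(outline)
    interior = ~morphology.dilation(border, morphology.disk(1))
    lab = measure.label(interior, connectivity=1)
    h, w = bf.shape
    keep = np.zeros(lab.max() + 1, dtype=bool)
    for o in measure.regionprops(lab):
        rmin, cmin, rmax, cmax = o.bbox
        if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
            continue
        if o.area < min_area:
            continue
        keep[o.label] = True
    mask = keep[lab]
    dist = ndi.distance_transform_edt(mask)
    markers, _ = ndi.label(dist > 0.5 * max(dist.max(), 1e-9))
    if markers.max() == 0:
        return np.zeros(bf.shape, dtype=np.int32)
    return segmentation.watershed(-dist, markers, mask=mask).astype(np.int32)


def _normalize(image: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(image, [0.1, 99.9])
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def classify_cortical_field(
    sec63: np.ndarray,
    rtn1: np.ndarray,
    cell_labels: np.ndarray | None = None,
    bf: np.ndarray | None = None,
    params: ClassifierParams | None = None,
    background_subtract: bool = True,
) -> tuple[CorticalClassification, pd.DataFrame, dict[str, float]]:
    """End-to-end cortical quantification of one field.

    Channels are rolling-ball background subtracted, percentile-normalized to
    [0, 1], segmented, classified, and assigned to cells.  ``cell_labels``
    (e.g. from an external segmenter or ground truth) takes precedence over
    the bright-field fallback segmenter.
    """
    params = params or ClassifierParams()
    sec63 = np.asarray(sec63, dtype=float)
    rtn1 = np.asarray(rtn1, dtype=float)
    if background_subtract:
        sec63 = rolling_ball_background(sec63, params.rolling_ball_radius)
        rtn1 = rolling_ball_background(rtn1, params.rolling_ball_radius)
    sec_n = _normalize(sec63)
    rtn_n = _normalize(rtn1)
    sec_masks = segment_channel(sec_n, params, "general")
    rtn_masks = segment_channel(rtn_n, params, "curvature")
    cls = classify(sec_masks, rtn_masks, params.trimming_factor)
    if cell_labels is None:
        if bf is None:
            raise ValueError("need cell_labels or a bright-field image")
        cell_labels = segment_cells_from_brightfield(bf)
    per_cell = assign_to_cells(cls, cell_labels)
    summary = summarize_population(per_cell) if len(per_cell) else {
        "median_tubule_fraction": float("nan"),
        "median_sheet_fraction": float("nan"),
        "median_cluster_area_px": float("nan"),
        "n_cells": 0,
    }
    return cls, per_cell, summary
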