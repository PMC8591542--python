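"""Automated mid-section cell segmentation and ER size measurement.

The pipeline mirrors a high-content screen's per-field analysis of yeast
optical mid sections:

1. pick the best-focused slice from the BFP z-stack (maximal intensity SD);
2. enhance cell borders in the BFP image (Fourier bandpass, then Frangi
   vesselness, Otsu binarization, morphological opening and a size filter to
   suppress vacuole-induced false borders);
3. segment cell interiors from the enclosed space, discard dim objects
   (mean BFP below median - k*MAD) and split touching cells by watershed;
4. refine each cell: re-pick its focal slice from the curvature-marker crop,
   segment the ER in both marker channels (tubeness + Otsu), and fit the
   minimum-volume enclosing ellipse to the combined ER mask to define the
   cell border; the cell periphery is the 5-px band inside that ellipse;
5. compute three ER-size metrics per cell and drop population outliers
   (any measurement beyond 2.5 SD of the population mean).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

from .ellipse import Ellipse, min_volume_ellipse

logger = logging.getLogger(__name__)

__all__ = [
    "MidcellParams",
    "CellRecord",
    "ERSizeMetrics",
    "select_best_slice",
    "enhance_cell_borders",
    "segment_cells",
    "refine_cells",
    "compute_er_metrics",
    "filter_population",
    "analyze_mid_field",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("peripheral_er_size", "er_profile_size", "er_gaps_per_um")
FILTER_COLUMNS = (
    "cell_area",
    "mean_sec63",
    "mean_rtn1",
    "roundness",
    *METRIC_COLUMNS,
)


@dataclass(frozen=True)
class MidcellParams:
    """Tunable parameters of the mid-section pipeline.

    ``bandpass_low``/``bandpass_high`` are the retained wavelengths in pixels
    (features between 2 and 40 px survive by default).  ``mad_k`` is the
    robust brightness cut (objects dimmer than median - mad_k*MAD are
    discarded); ``population_sd_limit`` is the final outlier cut.
    """

    bandpass_low: float = 2.0  # shortest retained wavelength, px
    bandpass_high: float = 40.0  # longest retained wavelength, px
    frangi_scales_border: tuple[float, ...] = (1.0, 1.5, 2.0)
    frangi_scales_er: tuple[float, ...] = (1.0,)
    min_cell_area: float = 450.0  # px; ~pi * r_min^2 for r_min ~ 12 px
    mad_k: float = 2.0
    periphery_width: float = 5.0
    population_sd_limit: float = 2.5
    mve_tolerance: float = 1e-3
    pixel_size: float = 0.108  # um / px
    opening_radius: int = 1
    border_expand: int = 3
    min_cells_watershed_distance: int = 8
    min_gap_area: int = 5  # px; a genuine gap spans the periphery band radially

    def __post_init__(self) -> None:
        if self.periphery_width < 1:
            raise ValueError("periphery_width must be >= 1")
        if self.mad_k <= 0 or self.population_sd_limit <= 0:
            raise ValueError("mad_k and population_sd_limit must be > 0")


@dataclass
class ERSizeMetrics:
    """The three mid-section ER size metrics of one cell."""

    peripheral_er_size: float  # peripheral ER area / periphery band area
    er_profile_size: float  # mean ER profile area / periphery band area
    er_gaps_per_um: float  # gaps in the peripheral ER mask per um periphery
    n_gaps: int
    periphery_um: float


@dataclass
class CellRecord:
    """One refined cell: border ellipse, periphery band, and measurements."""

    label: int
    mask: np.ndarray  # boolean, full-frame
    border_ellipse: Ellipse
    periphery_band: np.ndarray  # boolean, full-frame
    cell_area: float
    roundness: float
    mean_sec63: float
    mean_rtn1: float
    best_slice: int


def select_best_slice(stack: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Index of the in-focus slice: maximal per-slice intensity SD.

    Focused wide-field images have the highest contrast, hence the highest
    SD.  Ties resolve to the lowest index.  ``mask`` restricts the SD to a
    region (used for the per-cell refocusing on the curvature-marker crop).
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty stack")
    if mask is not None:
        sds = np.array([s[mask].std() if mask.any() else 0.0 for s in stack])
    else:
        sds = stack.std(axis=(1, 2))
    return int(np.argmax(sds))


def _normalize(image: np.ndarray, plo: float = 0.1, phi: float = 99.9) -> np.ndarray:
    lo, hi = np.percentile(image, [plo, phi])
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def _fourier_bandpass(image: np.ndarray, low_px: float, high_px: float) -> np.ndarray:
    """Annular Fourier-magnitude bandpass retaining wavelengths in [low, high] px.

    Soft (Gaussian-tapered) edges limit ringing.
    """
    h, w = image.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    freq = np.hypot(fy, fx)
    f_lo = 1.0 / high_px  # low cutoff in cycles/px
    f_hi = 1.0 / low_px
    taper = 0.2
    gain = np.ones_like(freq)
    gain *= 1.0 - np.exp(-0.5 * (freq / (f_lo * (1 + taper))) ** 4)
    gain *= np.exp(-0.5 * (freq / f_hi) ** 4)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * gain))


def enhance_cell_borders(bfp: np.ndarray, params: MidcellParams) -> np.ndarray:
    """Binary mask of apparent cell borders from a single BFP mid section."""
    bfp = np.asarray(bfp, dtype=float)
    if np.ptp(bfp) == 0:
        return np.zeros(bfp.shape, dtype=bool)
    img = _normalize(bfp)
    band = _fourier_bandpass(img, params.bandpass_low, params.bandpass_high)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vessel = filters.frangi(
            band, sigmas=params.frangi_scales_border, black_ridges=False
        )
    if np.ptp(vessel) == 0:
        return np.zeros(bfp.shape, dtype=bool)
    mask = vessel > filters.threshold_otsu(vessel)
    # the vesselness ridge is 1-2 px wide; thicken it so the opening removes
    # speckle without erasing the border itself, and so borders seal interiors
    mask = morphology.dilation(mask, morphology.disk(1))
    mask = morphology.opening(mask, morphology.disk(params.opening_radius))
    mask = morphology.remove_small_objects(mask, max_size=int(0.25 * params.min_cell_area) - 1)
    return mask


def segment_cells(
    border_mask: np.ndarray, bfp: np.ndarray, params: MidcellParams
) -> np.ndarray:
    """Label cell interiors enclosed by the border mask.

    Dim objects (mean BFP below median - mad_k*MAD over objects) are removed;
    touching cells, including mother/bud pairs, are split by watershed seeded
    from interior distance-transform maxima.
    """
    if border_mask.shape != np.asarray(bfp).shape:
        raise ValueError("border mask and intensity image must share a shape")
    interior = ~border_mask
    lab = measure.label(interior, connectivity=1)
    objs = measure.regionprops(lab, intensity_image=bfp)
    h, w = border_mask.shape
    keep = np.zeros(lab.max() + 1, dtype=bool)
    means = {}
    for o in objs:
        rmin, cmin, rmax, cmax = o.bbox
        touches_edge = rmin == 0 or cmin == 0 or rmax == h or cmax == w
        too_small = o.area < 0.25 * params.min_cell_area
        too_big = o.area > 6.0 * params.min_cell_area * 4  # generous upper bound
        if touches_edge or too_small or too_big:
            continue
        keep[o.label] = True
        means[o.label] = o.intensity_mean
    if means:
        vals = np.array(list(means.values()))
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        cut = med - params.mad_k * mad
        for l, m in means.items():
            if m < cut:
                keep[l] = False
    mask = keep[lab]
    if not mask.any():
        warnings.warn("no cell interiors found")
        return np.zeros_like(lab)
    # watershed split of touching interiors
    dist = ndi.distance_transform_edt(mask)
    peaks = feature.peak_local_max(
        dist,
        min_distance=params.min_cells_watershed_distance,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros_like(lab)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(mask)
    split = segmentation.watershed(-dist, markers, mask=mask)
    return measure.label(split > 0) if split.max() == 0 else split


def _segment_er(crop: np.ndarray, params: MidcellParams) -> np.ndarray:
    """Tubeness (Sato) + Otsu segmentation of the ER in one channel crop."""
    if np.ptp(crop) == 0:
        return np.zeros(crop.shape, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tube = filters.sato(
            _normalize(crop), sigmas=params.frangi_scales_er, black_ridges=False
        )
    if np.ptp(tube) == 0:
        return np.zeros(crop.shape, dtype=bool)
    norm = _normalize(crop)
    thr = filters.threshold_otsu(norm)
    # tubeness ridges continue across short interruptions of a profile; gate
    # them by minimal intensity support so real gaps stay open
    mask = (tube > filters.threshold_otsu(tube)) & (norm > 0.5 * thr)
    # tubeness peaks at the profile centerline and clips the profile's radial
    # extent; recover full width with a direct intensity threshold
    mask |= norm > thr
    return morphology.remove_small_objects(mask, max_size=7)


def refine_cells(
    cells: np.ndarray,
    sec63: np.ndarray,
    rtn1: np.ndarray,
    params: MidcellParams,
) -> tuple[list[CellRecord], dict[int, np.ndarray]]:
    """Refine segmented cells and define ellipse borders from the ER masks.

    ``sec63`` and ``rtn1`` are stacks (n_slices, H, W) or single 2D images.
    Returns the refined records plus the per-cell combined ER mask (full
    frame), which feeds the metric computation.  Cells with an empty ER mask
    are dropped with a logged reason.
    """
    sec63 = _as_stack(sec63)
    rtn1 = _as_stack(rtn1)
    shape = cells.shape
    territories = segmentation.expand_labels(cells, distance=params.border_expand + 3)
    # cell objects expanded to the apparent border but contained within the
    # watershed territories; they anchor the ellipse fit where the ER is sparse
    expanded = segmentation.expand_labels(cells, distance=params.border_expand)
    records: list[CellRecord] = []
    er_masks: dict[int, np.ndarray] = {}
    for obj in measure.regionprops(cells):
        label = obj.label
        rmin, cmin, rmax, cmax = obj.bbox
        pad = int(params.periphery_width + params.border_expand + 6)
        rlo, rhi = max(rmin - pad, 0), min(rmax + pad, shape[0])
        clo, chi = max(cmin - pad, 0), min(cmax + pad, shape[1])
        terr_crop = territories[rlo:rhi, clo:chi] == label
        rtn_crop_stack = rtn1[:, rlo:rhi, clo:chi]
        best = select_best_slice(rtn_crop_stack, mask=terr_crop)
        sec_crop = sec63[best, rlo:rhi, clo:chi]
        rtn_crop = rtn1[best, rlo:rhi, clo:chi]
        er = (_segment_er(sec_crop, params) | _segment_er(rtn_crop, params)) & terr_crop
        if not er.any():
            logger.info("cell %d dropped: empty ER mask", label)
            continue
        # combined ER mask plus the expanded cell object (shrunk 1 px so the
        # detected ER sets the outer contour where present): with sparse
        # peripheral ER alone the minimal ellipse would collapse across gaps
        obj_fit = morphology.erosion(
            expanded[rlo:rhi, clo:chi] == label, morphology.disk(1)
        )
        pts = np.argwhere(er | obj_fit).astype(float)
        try:
            hull_pts = _hull_points(pts)
            ell = min_volume_ellipse(hull_pts, tolerance=params.mve_tolerance)
        except ValueError as exc:
            logger.info("cell %d dropped: ellipse fit failed (%s)", label, exc)
            continue
        ell = Ellipse(
            (ell.center[0] + rlo, ell.center[1] + clo), ell.axes, ell.orientation
        )
        cell_mask = ell.mask(shape)
        band = cell_mask & ~ell.shrunk(params.periphery_width).mask(shape)
        if not band.any():
            logger.info("cell %d dropped: degenerate periphery band", label)
            continue
        er_full = np.zeros(shape, dtype=bool)
        er_full[rlo:rhi, clo:chi] = er
        sec_best = sec63[best]
        rtn_best = rtn1[best]
        records.append(
            CellRecord(
                label=label,
                mask=cell_mask,
                border_ellipse=ell,
                periphery_band=band,
                cell_area=float(cell_mask.sum()),
                roundness=ell.roundness,
                mean_sec63=float(sec_best[cell_mask].mean()),
                mean_rtn1=float(rtn_best[cell_mask].mean()),
                best_slice=best,
            )
        )
        er_masks[label] = er_full
    return records, er_masks


def _as_stack(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    return image[None] if image.ndim == 2 else image


def _hull_points(pts: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a pixel point set (keeps the ellipse fit cheap)."""
    from scipy.spatial import ConvexHull, QhullError

    if len(pts) <= 12:
        return pts
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:
        return pts


def compute_er_metrics(
    cell: CellRecord, er_mask: np.ndarray, params: MidcellParams
) -> ERSizeMetrics:
    """The three ER-size metrics of one cell.

    * peripheral ER size  = |ER ∩ band| / |band|
    * ER profile size     = mean connected-component area of ER ∩ band / |band|
    * ER gaps per um      = connected components of band \\ ER (of at least
      ``min_gap_area`` px, suppressing 1-px discretization slivers) per um of
      periphery (Crofton perimeter of the band's mid ellipse, times pixel size)
    """
    band = cell.periphery_band
    band_area = int(band.sum())
    if band_area == 0:
        raise ValueError("cell has an empty periphery band")
    er_in_band = er_mask & band
    peripheral = er_in_band.sum() / band_area
    n_profiles = measure.label(er_in_band, connectivity=2).max()
    profile_size = (
        (er_in_band.sum() / n_profiles) / band_area if n_profiles else 0.0
    )
    gaps = band & ~er_mask
    gap_labels = measure.label(gaps, connectivity=2)
    if gap_labels.max():
        sizes = np.bincount(gap_labels.ravel())[1:]
        # a genuine gap interrupts the band through its depth; components that
        # only graze the outer rim (ellipse-fit discretization slivers) or are
        # smaller than min_gap_area are not counted
        inner_half = band & cell.border_ellipse.shrunk(
            0.4 * params.periphery_width
        ).mask(band.shape)
        deep = np.zeros(gap_labels.max() + 1, dtype=bool)
        deep[np.unique(gap_labels[inner_half & gaps])] = True
        deep[0] = False
        counted = deep[1:] & (sizes >= params.min_gap_area)
        n_gaps = int(counted.sum())
    else:
        n_gaps = 0
    mid_ellipse = cell.border_ellipse.shrunk(params.periphery_width / 2.0)
    perimeter_px = measure.perimeter_crofton(
        mid_ellipse.mask(band.shape), directions=4
    )
    periphery_um = float(perimeter_px) * params.pixel_size
    if periphery_um <= 0:
        raise ValueError("zero-length periphery")
    return ERSizeMetrics(
        peripheral_er_size=float(peripheral),
        er_profile_size=float(profile_size),
        er_gaps_per_um=n_gaps / periphery_um,
        n_gaps=n_gaps,
        periphery_um=periphery_um,
    )


def filter_population(
    df: pd.DataFrame,
    sd_limit: float = 2.5,
    columns: tuple[str, ...] = FILTER_COLUMNS,
) -> pd.DataFrame:
    """Keep cells whose every measurement lies within ``sd_limit`` SDs of the
    population mean (single pass).  Columns with zero SD never exclude."""
    if len(df) < 2:
        return df.copy()
    keep = np.ones(len(df), dtype=bool)
    for col in columns:
        if col not in df.columns:
            continue
        vals = df[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        keep &= np.abs(vals - vals.mean()) <= sd_limit * sd
    return df.loc[keep].copy()


def analyze_mid_field(
    channels: dict[str, np.ndarray],
    params: MidcellParams | None = None,
    apply_population_filter: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, list[CellRecord]]:
    """Run the full mid-section pipeline on one field.

    ``channels`` maps ``bfp``/``sec63``/``rtn1`` to stacks (n_slices, H, W).
    Returns (cell label mask, per-cell table, refined records).
    """
    params = params or MidcellParams()
    bfp_stack = _as_stack(channels["bfp"])
    best = select_best_slice(bfp_stack)
    bfp = bfp_stack[best]
    border = enhance_cell_borders(bfp, params)
    cells = segment_cells(border, bfp, params)
    records, er_masks = refine_cells(
        cells, channels["sec63"], channels["rtn1"], params
    )
    rows = []
    for rec in records:
        metrics = compute_er_metrics(rec, er_masks[rec.label], params)
        rows.append(
            {
                "label": rec.label,
                "cell_area": rec.cell_area,
                "roundness": rec.roundness,
                "mean_sec63": rec.mean_sec63,
                "mean_rtn1": rec.mean_rtn1,
                "best_slice": rec.best_slice,
                "peripheral_er_size": metrics.peripheral_er_size,
                "er_profile_size": metrics.er_profile_size,
                "er_gaps_per_um": metrics.er_gaps_per_um,
                "n_gaps": metrics.n_gaps,
                "periphery_um": metrics.periphery_um,
            }
        )
    table = pd.DataFrame(rows)
    if apply_population_filter and len(table) >= 2:
        table = filter_population(table, params.population_sd_limit)
    return cells, table, records
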