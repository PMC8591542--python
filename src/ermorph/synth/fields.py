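"""Seeded synthetic yeast microscopy fields with ground truth.

Renders multi-channel fields that emulate the imaging geometry of a
budding-yeast ER morphology experiment:

* **mid sections** — the cytosolic BFP fills cell interiors and the ER
  channels form a band of profiles along the cell border, interrupted by a
  controlled number of gaps;
* **cortical sections** — the general ER marker (Sec63-like) labels tubule
  networks plus sheet patches, while the curvature marker (Rtn1-like) labels
  tubules and a 1-2 px sheet rim but not sheet interiors, and fills dense
  "tubular cluster" patches.

Fields are stacks of ``n_slices`` optical slices (default five, spaced 1 um)
with focus-dependent blur; ground-truth masks are recorded before blur and
noise.  All randomness derives from one seed per field, with per-cell
sub-streams spawned deterministically, so identical specs reproduce identical
pixel values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..ellipse import Ellipse

__all__ = [
    "NoiseModel",
    "FieldSpec",
    "SyntheticField",
    "generate_cell_geometry",
    "render_mid_field",
    "render_cortical_field",
]


@dataclass(frozen=True)
class NoiseModel:
    """Read noise (Gaussian, as fraction of signal amplitude) and optional shot noise."""

    gaussian_sd: float = 0.05
    poisson_scale: float = 0.0


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field.

    Geometry is in pixels at ``pixel_size`` um/px (default 0.108, a 60x
    objective on an sCMOS-class camera).  Cells are ellipses with axis ratio
    <= 1.5 and radii drawn from ``cell_radius_range``; defaults correspond to
    diploid yeast (~3.5-5 um diameter).
    """

    image_size: tuple[int, int] = (360, 360)
    n_cells: int = 8
    cell_radius_range: tuple[float, float] = (16.0, 24.0)
    pixel_size: float = 0.108
    section: str = "mid"
    n_slices: int = 5
    slice_spacing: float = 1.0
    target_tubule_fraction: float = 0.15
    target_sheet_fraction: float = 0.10
    target_cluster_fraction: float = 0.0
    er_band_coverage: float = 0.9
    n_gaps_per_cell: int = 2
    er_band_width: float = 6.0
    tubule_width: float = 2.0
    psf_sigma: float = 1.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        if self.section not in ("mid", "cortical"):
            raise ValueError(f"unknown section {self.section!r}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        rmin, rmax = self.cell_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("invalid cell_radius_range")
        for name in (
            "target_tubule_fraction",
            "target_sheet_fraction",
            "target_cluster_fraction",
            "er_band_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = (
            self.target_tubule_fraction
            + self.target_sheet_fraction
            + self.target_cluster_fraction
        )
        if total > 1.0:
            raise ValueError("tubule + sheet (+ cluster) fractions exceed 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.section == "mid":
            self._validate_band()

    def _validate_band(self) -> None:
        c, g = self.er_band_coverage, self.n_gaps_per_cell
        if g < 0:
            raise ValueError("n_gaps_per_cell must be >= 0")
        if g == 0 and c < 1.0:
            raise ValueError(
                "er_band_coverage < 1 with n_gaps_per_cell = 0 is infeasible: "
                "a partially covered band has at least one gap"
            )
        if g > 0 and c >= 1.0:
            raise ValueError("er_band_coverage = 1 leaves no room for gaps")
        if g > 0:
            rmin = self.cell_radius_range[0]
            min_arc = 2.0  # pixels
            if (1.0 - c) * 2 * np.pi * rmin / g < min_arc:
                raise ValueError("gaps too narrow to rasterize at this coverage")
            if c * 2 * np.pi * rmin / g < min_arc:
                raise ValueError("covered arcs too narrow at this gap count")


@dataclass
class SyntheticField:
    """Rendered channels plus ground truth.

    ``channels`` maps channel name (``bf``, ``bfp``, ``sec63``, ``rtn1``) to a
    float stack of shape (n_slices, H, W) normalized to [0, 1].  Truth masks
    are recorded before blur and noise.  ``per_cell_truth`` has one row per
    cell: for cortical fields the realized tubule/sheet/cluster area fractions
    of the cell cortex; for mid fields the realized band coverage and gap
    count.
    """

    channels: dict[str, np.ndarray]
    truth_cells: np.ndarray
    truth_tubules: np.ndarray
    truth_sheets: np.ndarray
    truth_clusters: np.ndarray
    per_cell_truth: pd.DataFrame
    focus_slice: int
    cell_ellipses: list[Ellipse]
    spec: FieldSpec


# ---------------------------------------------------------------------------
# cell placement


def _place_cells(spec: FieldSpec, rng: np.random.Generator) -> list[Ellipse]:
    h, w = spec.image_size
    rmin, rmax = spec.cell_radius_range
    margin = 2.0
    cells: list[Ellipse] = []
    attempts = 0
    max_attempts = 300 * max(spec.n_cells, 1)
    while len(cells) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.image_size} after {max_attempts} attempts"
            )
        attempts += 1
        a = rng.uniform(rmin, rmax)
        ratio = rng.uniform(1.0, 1.5)
        b = a / ratio
        if 2 * a + margin > min(h, w):
            continue
        r0 = rng.uniform(a + margin, h - a - margin)
        c0 = rng.uniform(a + margin, w - a - margin)
        ok = True
        for other in cells:
            dist = np.hypot(r0 - other.center[0], c0 - other.center[1])
            if dist < a + other.axes[0] + margin:
                ok = False
                break
        if ok:
            cells.append(Ellipse((r0, c0), (a, b), rng.uniform(0, np.pi)))
    return cells


def generate_cell_geometry(
    spec: FieldSpec, return_ellipses: bool = False
) -> np.ndarray | tuple[np.ndarray, list[Ellipse]]:
    """Place non-overlapping elliptical cells; label mask with labels 1..n.

    Deterministic given ``spec.seed``.  Raises ``RuntimeError`` after a
    bounded number of rejection-sampling attempts if the cells do not fit.
    """
    spec.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    cells = _place_cells(spec, rng)
    labels = np.zeros(spec.image_size, dtype=np.int32)
    for i, cell in enumerate(cells, start=1):
        labels[cell.mask(spec.image_size)] = i
    if return_ellipses:
        return labels, cells
    return labels


# ---------------------------------------------------------------------------
# rendering helpers


def _cell_streams(spec: FieldSpec, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(spec.seed).spawn(n)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def _coords(shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.stack([rr, cc], axis=-1).astype(float)


def _focus_stack(
    clean: np.ndarray, spec: FieldSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Blur one clean 2D image into an n_slices stack with a designated focus.

    Defocus grows linearly with distance from the focal plane (1.2 px of extra
    Gaussian blur per um), so per-slice intensity SD is strictly maximal at
    the focus slice.  Noise is added per slice, then the stack is clipped to
    non-negative values and rescaled to [0, 1].
    """
    focus = spec.n_slices // 2
    slices = []
    for i in range(spec.n_slices):
        sigma = spec.psf_sigma + 1.2 * abs(i - focus) * spec.slice_spacing
        img = ndi.gaussian_filter(clean, sigma) if sigma > 0 else clean.copy()
        if spec.noise_model.poisson_scale > 0:
            scale = spec.noise_model.poisson_scale
            img = rng.poisson(np.clip(img, 0, None) * scale).astype(float) / scale
        if spec.noise_model.gaussian_sd > 0:
            img = img + rng.normal(0.0, spec.noise_model.gaussian_sd, img.shape)
        slices.append(img)
    stack = np.clip(np.stack(slices), 0.0, None)
    peak = stack.max()
    if peak > 0:
        stack /= peak
    return stack, focus


def _band_masks(
    cell: Ellipse, shape: tuple[int, int], width: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior, band, and in-ellipse-frame angle maps for one cell (cropped)."""
    interior = cell.mask(shape)
    inner = cell.shrunk(width).mask(shape)
    band = interior & ~inner
    coords = _coords(shape)
    d = coords - np.asarray(cell.center)
    co, si = np.cos(cell.orientation), np.sin(cell.orientation)
    u = d[..., 0] * co + d[..., 1] * si
    v = -d[..., 0] * si + d[..., 1] * co
    angle = np.arctan2(v / cell.axes[1], u / cell.axes[0]) % (2 * np.pi)
    return interior, band, angle


# ---------------------------------------------------------------------------
# mid sections


def render_mid_field(spec: FieldSpec) -> SyntheticField:
    """Render a mid-section field: BFP-filled cells with a gapped ER border band."""
    if spec.section != "mid":
        raise ValueError("spec.section must be 'mid'")
    spec.validate()
    labels, cells = generate_cell_geometry(spec, return_ellipses=True)
    shape = spec.image_size
    er_truth = np.zeros(shape, dtype=bool)
    interior_all = labels > 0
    rows = []
    streams = _cell_streams(spec, spec.n_cells + 1)
    noise_rng = streams[-1]
    for i, cell in enumerate(cells, start=1):
        rng = streams[i - 1]
        _, band, angle = _band_masks(cell, shape, spec.er_band_width)
        c, g = spec.er_band_coverage, spec.n_gaps_per_cell
        covered = band.copy()
        if g > 0:
            theta0 = rng.uniform(0, 2 * np.pi)
            half = (1.0 - c) * np.pi / g
            for k in range(g):
                center = (theta0 + 2 * np.pi * k / g) % (2 * np.pi)
                diff = np.abs((angle - center + np.pi) % (2 * np.pi) - np.pi)
                covered &= ~(diff < half)
        er_truth |= covered
        n_gap_real = _count_angular_components(band & ~covered)
        rows.append(
            {
                "cell": i,
                "er_coverage": covered.sum() / max(band.sum(), 1),
                "n_gaps": n_gap_real,
                "tubule_fraction": np.nan,
                "sheet_fraction": np.nan,
            }
        )
    bfp = np.where(interior_all, 0.7, 0.0)
    sec63 = np.where(er_truth, 0.9, 0.0)
    rtn1 = np.where(er_truth, 0.85, 0.0)
    edge = _cell_edge_mask(cells, shape)
    bf = 0.5 - 0.35 * edge.astype(float)

    channels = {}
    focus = spec.n_slices // 2
    for name, clean in (("bf", bf), ("bfp", bfp), ("sec63", sec63), ("rtn1", rtn1)):
        channels[name], focus = _focus_stack(clean, spec, noise_rng)
    return SyntheticField(
        channels=channels,
        truth_cells=labels,
        truth_tubules=er_truth,
        truth_sheets=np.zeros(shape, dtype=bool),
        truth_clusters=np.zeros(shape, dtype=bool),
        per_cell_truth=pd.DataFrame(rows),
        focus_slice=focus,
        cell_ellipses=cells,
        spec=spec,
    )


def _count_angular_components(mask: np.ndarray) -> int:
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    return int(n)


def _cell_edge_mask(cells: list[Ellipse], shape: tuple[int, int]) -> np.ndarray:
    edge = np.zeros(shape, dtype=bool)
    for cell in cells:
        outer = Ellipse(
            cell.center, (cell.axes[0] + 1.0, cell.axes[1] + 1.0), cell.orientation
        ).mask(shape)
        inner = cell.shrunk(1.0).mask(shape)
        edge |= outer & ~inner
    return edge


# ---------------------------------------------------------------------------
# cortical sections


def _add_blobs(
    target_area: float,
    allowed: np.ndarray,
    existing: np.ndarray,
    cell: Ellipse,
    shape: tuple[int, int],
    rng: np.random.Generator,
    radius_range: tuple[float, float] = (4.0, 8.0),
    tol_frac: float = 0.03,
    max_blobs: int = 200,
) -> np.ndarray:
    """Accumulate elliptical patches inside ``allowed`` until their area
    reaches ``target_area`` within ``tol_frac`` of the cell area."""
    blobs = np.zeros(shape, dtype=bool)
    cell_area = allowed.sum()
    tol = tol_frac * cell_area
    for _ in range(max_blobs):
        have = (blobs & allowed & ~existing).sum()
        remaining = target_area - have
        if remaining <= tol:
            break
        r_fit = float(np.sqrt(max(remaining, 4.0) / np.pi))
        r_b = min(max(r_fit, radius_range[0] * 0.5), radius_range[1])
        r_b = min(r_b, rng.uniform(0.8, 1.0) * r_b + 0.5)
        rho = rng.uniform(0, 0.75)
        phi = rng.uniform(0, 2 * np.pi)
        a, b = cell.axes
        co, si = np.cos(cell.orientation), np.sin(cell.orientation)
        u, v = rho * a * np.cos(phi), rho * b * np.sin(phi)
        r0 = cell.center[0] + u * co - v * si
        c0 = cell.center[1] + u * si + v * co
        ratio = rng.uniform(1.0, 1.4)
        blob = Ellipse(
            (r0, c0), (r_b * np.sqrt(ratio), r_b / np.sqrt(ratio)), rng.uniform(0, np.pi)
        ).mask(shape)
        blobs |= blob & allowed
    return blobs & allowed & ~existing


def _random_walk_tubules(
    target_area: float,
    allowed: np.ndarray,
    blocked: np.ndarray,
    cell: Ellipse,
    shape: tuple[int, int],
    rng: np.random.Generator,
    width: float,
    max_strands: int = 300,
) -> np.ndarray:
    """Dilated random-walk skeletons until tubule area (outside ``blocked``)
    reaches ``target_area``."""
    skel = np.zeros(shape, dtype=bool)
    dil_r = max(int(round((width - 1) / 2)), 0)
    struct = _disk(dil_r) if dil_r > 0 else None

    def current_area() -> int:
        tub = ndi.binary_dilation(skel, structure=struct) if struct is not None else skel
        return int((tub & allowed & ~blocked).sum())

    n_strands = 0
    while current_area() < target_area and n_strands < max_strands:
        n_strands += 1
        # start inside the cell, away from the boundary
        rho = np.sqrt(rng.uniform(0.0, 0.85**2))
        phi = rng.uniform(0, 2 * np.pi)
        a, b = cell.axes
        co, si = np.cos(cell.orientation), np.sin(cell.orientation)
        u, v = rho * a * np.cos(phi), rho * b * np.sin(phi)
        r = cell.center[0] + u * co - v * si
        c = cell.center[1] + u * si + v * co
        direction = rng.uniform(0, 2 * np.pi)
        steps = int(rng.integers(20, 70))
        pos = np.array([r, c], dtype=float)
        for _ in range(steps):
            direction += rng.normal(0.0, 0.35)
            pos = pos + np.array([np.cos(direction), np.sin(direction)])
            if cell.normalized_radius(pos) > 0.92:
                direction += np.pi / 2  # turn along the cortex rim
                pos = pos - np.array([np.cos(direction - np.pi / 2), 0.0])
                if cell.normalized_radius(pos) > 0.95:
                    break
            ri, ci = int(round(pos[0])), int(round(pos[1]))
            if 0 <= ri < shape[0] and 0 <= ci < shape[1] and not blocked[ri, ci]:
                skel[ri, ci] = True
    tub = ndi.binary_dilation(skel, structure=struct) if struct is not None else skel
    return tub & allowed


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


def render_cortical_field(spec: FieldSpec) -> SyntheticField:
    """Render a cortical-section field with tubule networks, sheets, clusters.

    Per cell, sheet patches are placed first, then a tubule network is grown
    until the realized (non-sheet) tubule area matches the target fraction;
    optional cluster patches are sheet-sized but belong to the tubule class.
    Targets are met within a placement tolerance of ~0.05; infeasible targets
    raise ``RuntimeError``.
    """
    if spec.section != "cortical":
        raise ValueError("spec.section must be 'cortical'")
    spec.validate()
    labels, cells = generate_cell_geometry(spec, return_ellipses=True)
    shape = spec.image_size
    sheets_all = np.zeros(shape, dtype=bool)
    tubules_all = np.zeros(shape, dtype=bool)
    clusters_all = np.zeros(shape, dtype=bool)
    rims_all = np.zeros(shape, dtype=bool)
    rows = []
    streams = _cell_streams(spec, spec.n_cells + 1)
    noise_rng = streams[-1]
    erode2 = _disk(2)
    for i, cell in enumerate(cells, start=1):
        rng = streams[i - 1]
        allowed = cell.shrunk(1.5).mask(shape)
        cell_area = int((labels == i).sum())
        sheets = _add_blobs(
            spec.target_sheet_fraction * cell_area, allowed, np.zeros(shape, bool),
            cell, shape, rng,
        )
        clusters = _add_blobs(
            spec.target_cluster_fraction * cell_area, allowed, sheets, cell, shape, rng
        )
        tub_target = spec.target_tubule_fraction * cell_area
        blocked = sheets | clusters
        tubules = _random_walk_tubules(
            tub_target, allowed, blocked, cell, shape, rng, spec.tubule_width
        )
        tubules &= ~blocked
        realized_t = (tubules.sum() + clusters.sum()) / max(cell_area, 1)
        realized_s = sheets.sum() / max(cell_area, 1)
        if spec.target_tubule_fraction > 0 and realized_t < spec.target_tubule_fraction - 0.07:
            raise RuntimeError(
                f"cell {i}: tubule fraction target {spec.target_tubule_fraction:.2f} "
                f"unreachable (got {realized_t:.2f}); targets may be jointly infeasible"
            )
        sheets_all |= sheets
        tubules_all |= tubules | clusters
        clusters_all |= clusters
        rims_all |= sheets & ~ndi.binary_erosion(sheets, structure=erode2)
        rows.append(
            {
                "cell": i,
                "tubule_fraction": realized_t,
                "sheet_fraction": realized_s,
                "cluster_fraction": clusters.sum() / max(cell_area, 1),
                "er_coverage": np.nan,
                "n_gaps": np.nan,
            }
        )

    sec63 = np.where(tubules_all | sheets_all, 0.9, 0.0)
    rtn1 = np.where((tubules_all & ~rims_all) | clusters_all, 0.85, 0.0)
    rtn1 = np.maximum(rtn1, np.where(rims_all, 0.8, 0.0))
    bfp = np.where(labels > 0, 0.7, 0.0)
    bf = 0.5 - 0.35 * _cell_edge_mask(cells, shape).astype(float)

    channels = {}
    focus = spec.n_slices // 2
    for name, clean in (("bf", bf), ("bfp", bfp), ("sec63", sec63), ("rtn1", rtn1)):
        channels[name], focus = _focus_stack(clean, spec, noise_rng)
    if (tubules_all & sheets_all).any():
        warnings.warn("tubule/sheet truth overlap detected; carving tubules")
        tubules_all &= ~sheets_all
    return SyntheticField(
        channels=channels,
        truth_cells=labels,
        truth_tubules=tubules_all,
        truth_sheets=sheets_all,
        truth_clusters=clusters_all,
        per_cell_truth=pd.DataFrame(rows),
        focus_slice=focus,
        cell_ellipses=cells,
        spec=spec,
    )


def mid_spec(**kwargs) -> FieldSpec:
    """Convenience constructor for a mid-section FieldSpec."""
    return replace(FieldSpec(section="mid"), **kwargs)


def cortical_spec(**kwargs) -> FieldSpec:
    """Convenience constructor for a cortical-section FieldSpec."""
    return replace(FieldSpec(section="cortical"), **kwargs)
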