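"""QC overlay images for segmentation and classification results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import segmentation


def save_mid_overlay(
    bfp: np.ndarray, cells: np.ndarray, path: str | Path
) -> None:
    """BFP slice with cell-label boundaries marked."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(segmentation.mark_boundaries(_to_rgb(bfp), cells, color=(1, 0, 0)))
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_class_overlay(
    sec63: np.ndarray,
    tubule_mask: np.ndarray,
    sheet_mask: np.ndarray,
    cluster_mask: np.ndarray,
    path: str | Path,
) -> None:
    """General-ER channel with tubules (magenta), sheets (green) and
    tubular clusters (yellow) tinted on top."""
    rgb = _to_rgb(sec63) * 0.6
    rgb[tubule_mask] = 0.55 * rgb[tubule_mask] + 0.45 * np.array([1.0, 0.2, 1.0])
    rgb[sheet_mask] = 0.55 * rgb[sheet_mask] + 0.45 * np.array([0.2, 1.0, 0.2])
    rgb[cluster_mask] = 0.55 * rgb[cluster_mask] + 0.45 * np.array([1.0, 1.0, 0.2])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.clip(rgb, 0, 1))
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _to_rgb(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1, 99.5])
    g = np.clip((img - lo) / max(hi - lo, 1e-12), 0, 1)
    return np.repeat(g[..., None], 3, axis=-1)
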