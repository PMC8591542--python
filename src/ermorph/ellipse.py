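"""Minimum-volume enclosing ellipse and shared ellipse geometry.

The cell border in the mid-section pipeline is defined by the smallest-area
ellipse enclosing the segmented ER mask.  The solver is the classic Khachiyan
barycentric-coordinate ascent for the minimum-volume enclosing ellipsoid,
specialised to 2D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Ellipse:
    """An ellipse given by center, semi-axes (major >= minor) and orientation.

    ``orientation`` is the angle in radians of the major axis, measured from
    the first (row) coordinate axis.  Coordinates are (row, col) throughout.
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float

    def __post_init__(self) -> None:
        if self.axes[0] < self.axes[1]:
            raise ValueError("major semi-axis must be listed first")

    def normalized_radius(self, coords: np.ndarray) -> np.ndarray:
        """Elliptic radius of points: 1 on the boundary, < 1 inside.

        ``coords`` is (N, 2) or a pair of broadcastable row/col arrays stacked
        on the last axis.
        """
        coords = np.asarray(coords, dtype=float)
        d = coords - np.asarray(self.center)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = d[..., 0] * c + d[..., 1] * s
        v = -d[..., 0] * s + d[..., 1] * c
        a, b = self.axes
        return np.sqrt((u / a) ** 2 + (v / b) ** 2)

    def contains(self, coords: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.normalized_radius(coords) <= 1.0 + tol

    def shrunk(self, margin: float) -> "Ellipse":
        """Ellipse with both semi-axes reduced by ``margin`` pixels (floored)."""
        a = max(self.axes[0] - margin, 1e-3)
        b = max(self.axes[1] - margin, 1e-3)
        return Ellipse(self.center, (a, b), self.orientation)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the filled ellipse on an image of ``shape``."""
        r0, c0 = self.center
        a = self.axes[0]
        rlo = max(int(np.floor(r0 - a)) - 1, 0)
        rhi = min(int(np.ceil(r0 + a)) + 2, shape[0])
        clo = max(int(np.floor(c0 - a)) - 1, 0)
        chi = min(int(np.ceil(c0 + a)) + 2, shape[1])
        out = np.zeros(shape, dtype=bool)
        if rlo >= rhi or clo >= chi:
            return out
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        pts = np.stack([rr, cc], axis=-1).astype(float)
        out[rlo:rhi, clo:chi] = self.normalized_radius(pts) <= 1.0
        return out

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])

    @property
    def perimeter(self) -> float:
        """Ramanujan's second approximation to the ellipse perimeter."""
        a, b = self.axes
        h = ((a - b) / (a + b)) ** 2
        return float(np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h))))

    @property
    def roundness(self) -> float:
        """Minor/major axis ratio, 1 for a circle."""
        return float(self.axes[1] / self.axes[0])


def min_volume_ellipse(
    points: np.ndarray, tolerance: float = 1e-4, max_iter: int = 5000
) -> Ellipse:
    """Smallest-area ellipse enclosing a 2D point set (Khachiyan iteration).

    Parameters
    ----------
    points : (N, 2) array
        At least three non-collinear points.
    tolerance : float
        Convergence tolerance of the barycentric ascent; all points lie inside
        the returned ellipse up to this relative tolerance.

    Returns
    -------
    Ellipse
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to define an enclosing ellipse")
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(P).max())) < 2:
        raise ValueError("points are collinear or coincident")

    d = 2
    Q = np.column_stack([P, np.ones(n)]).T  # (3, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        err = np.linalg.norm((1.0 - step) * u + step * (np.arange(n) == j) - u)
        u = (1.0 - step) * u
        u[j] += step
        if err < tolerance:
            break

    c = u @ P
    A = np.linalg.inv(P.T @ np.diag(u) @ P - np.outer(c, c)) / d
    eigvals, eigvecs = np.linalg.eigh(A)
    # eigvals ascending -> axes descending
    axes = 1.0 / np.sqrt(eigvals)
    major_vec = eigvecs[:, 0]
    orientation = float(np.arctan2(major_vec[1], major_vec[0]))
    # canonical orientation in [0, pi)
    orientation = orientation % np.pi
    return Ellipse(
        center=(float(c[0]), float(c[1])),
        axes=(float(axes[0]), float(axes[1])),
        orientation=orientation,
    )
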