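"""PC ordination of aligned shapes, density landscapes, and focal regions.

The morphospace is a covariance-matrix PCA of the flattened Procrustes
coordinates: each taxon becomes a point whose leading two scores (PC1, PC2)
carry most of the shape variation. Occupancy structure of that plane is
summarized by a Gaussian kernel density landscape, and regions of interest
(occupancy peaks, off-peak areas) are expressed as ellipses or explicit
taxon sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .shapes import AlignedShapes

__all__ = [
    "Morphospace",
    "DensityLandscape",
    "FocalRegion",
    "pca",
    "pca_matrix",
    "variance_explained",
    "kde_landscape",
    "region_members",
    "shape_at",
]


@dataclass
class Morphospace:
    """Principal-component ordination of shape variables.

    ``scores`` is ``(n, m)`` (taxa by components, column-centered);
    ``eigenvectors`` is ``(m, d)`` with one loading row per component over
    the ``d`` flattened coordinates; ``consensus`` is the mean shape
    (reshaped ``(d/2, 2)``) added back for reconstruction.
    """

    scores: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    consensus: np.ndarray
    taxon_order: list[str]

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def scores_for(self, taxa: Sequence[str], n_components: int = 2) -> np.ndarray:
        index = {t: i for i, t in enumerate(self.taxon_order)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in morphospace: {missing}")
        return self.scores[[index[t] for t in taxa], :n_components]

    def scores_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.taxon_order, name="taxon"),
            columns=[f"PC{i + 1}" for i in range(self.m)],
        )

    def to_csv(self, path: str | Path) -> None:
        self.scores_frame().to_csv(path)


@dataclass
class DensityLandscape:
    """Gaussian-KDE density over a regular (PC1, PC2) grid."""

    x: np.ndarray  # grid_resolution x-coordinates
    y: np.ndarray  # grid_resolution y-coordinates
    density: np.ndarray  # (len(y), len(x)), rows indexed by y
    bandwidth: tuple[float, float]
    contour_levels: np.ndarray

    def integral(self) -> float:
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.density.sum() * dx * dy)

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"pc1": xx.ravel(), "pc2": yy.ravel(), "density": self.density.ravel()}
        )


@dataclass
class FocalRegion:
    """Ellipse in the (PC1, PC2) plane, or an explicit taxon set.

    The ellipse is the user-facing analogue of a hand-drawn occupancy-peak
    outline; ``angle`` rotates the semi-axes counter-clockwise (radians).
    """

    label: str = "region"
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    angle: float = 0.0
    taxa: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.taxa = frozenset(self.taxa)
        if self.center is None and not self.taxa:
            raise ValueError(f"region {self.label!r}: need an ellipse or a taxon set")
        if self.center is not None:
            if self.semi_axes is None:
                raise ValueError(f"region {self.label!r}: ellipse needs semi_axes")
            if min(self.semi_axes) <= 0:
                raise ValueError(f"region {self.label!r}: semi-axes must be positive")

    @property
    def is_ellipse(self) -> bool:
        return self.center is not None

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (boundary inclusive)."""
        if not self.is_ellipse:
            raise ValueError("explicit-set region has no spatial extent")
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        # rotate into the ellipse frame
        u = pts[:, 0] * c + pts[:, 1] * s
        v = -pts[:, 0] * s + pts[:, 1] * c
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12


def pca_matrix(data: np.ndarray, taxa: Sequence[str],
               consensus: np.ndarray | None = None) -> Morphospace:
    """Covariance PCA of an ``(n, d)`` data matrix.

    The sign of each eigenvector is fixed so its largest-magnitude loading
    is positive (axis polarity is otherwise arbitrary).
    """
    data = np.asarray(data, dtype=float)
    n, d = data.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]  # columns are components
    m = min(n - 1, d)
    eigval = eigval[:m]
    eigvec = eigvec[:, :m]
    # deterministic sign: largest-|loading| positive
    for j in range(m):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    scores = centered @ eigvec
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.zeros_like(eigval)
    if consensus is None:
        consensus = mean.reshape(-1, 2) if d % 2 == 0 else mean.reshape(-1, 1)
    return Morphospace(
        scores=scores,
        eigenvectors=eigvec.T,
        eigenvalues=eigval,
        variance_fraction=frac,
        consensus=consensus,
        taxon_order=list(taxa),
    )


def pca(aligned: AlignedShapes) -> Morphospace:
    """PCA over flattened Procrustes-aligned coordinates.

    The stored consensus is the coordinate-wise mean of the aligned
    shapes, so score-times-loading reconstruction is exact at full rank.
    """
    return pca_matrix(aligned.flat(), aligned.taxa)


def variance_explained(ms: Morphospace, n_components: int) -> float:
    """Cumulative variance fraction of the leading components."""
    if n_components > ms.m:
        raise ValueError(f"asked for {n_components} of {ms.m} components")
    return float(ms.variance_fraction[:n_components].sum())


def shape_at(ms: Morphospace, component: int, score: float) -> np.ndarray:
    """Model shape at a position along one PC axis: consensus + score x loading."""
    if component >= ms.m:
        raise ValueError(f"component {component} out of range (m={ms.m})")
    disp = score * ms.eigenvectors[component]
    return ms.consensus + disp.reshape(ms.consensus.shape)


def _silverman_bandwidth(values: np.ndarray) -> float:
    # per-axis Silverman factor for a 2-D Gaussian product kernel
    n = len(values)
    sd = values.std(ddof=1)
    return float(sd * n ** (-1.0 / 6.0))


def kde_landscape(scores: np.ndarray,
                  bandwidth: tuple[float, float] | None = None,
                  grid_resolution: int = 200,
                  span_bandwidths: float = 3.0,
                  n_levels: int = 10) -> DensityLandscape:
    """Gaussian-kernel density landscape over the (PC1, PC2) plane.

    Bandwidths default to Silverman's rule applied per axis. The grid spans
    the data range padded by ``span_bandwidths`` bandwidths; contour levels
    are placed at equal quantiles of the positive density values.
    """
    pts = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    n = pts.shape[0]
    if bandwidth is None:
        if n < 2:
            raise ValueError("automatic bandwidth needs at least 2 points")
        bandwidth = (_silverman_bandwidth(pts[:, 0]), _silverman_bandwidth(pts[:, 1]))
        if min(bandwidth) <= 0:
            raise ValueError(
                "zero variance along an axis; pass an explicit bandwidth"
            )
    hx, hy = bandwidth
    x = np.linspace(pts[:, 0].min() - span_bandwidths * hx,
                    pts[:, 0].max() + span_bandwidths * hx, grid_resolution)
    y = np.linspace(pts[:, 1].min() - span_bandwidths * hy,
                    pts[:, 1].max() + span_bandwidths * hy, grid_resolution)
    # (ny, nx) evaluation by separable Gaussian kernels
    dx = (x[None, :] - pts[:, 0][:, None]) / hx  # (n, nx)
    dy = (y[None, :] - pts[:, 1][:, None]) / hy  # (n, ny)
    gx = np.exp(-0.5 * dx**2)
    gy = np.exp(-0.5 * dy**2)
    density = (gy.T @ gx) / (n * 2.0 * np.pi * hx * hy)
    positive = density[density > 0]
    levels = np.quantile(positive, np.linspace(0, 1, n_levels + 2)[1:-1])
    return DensityLandscape(x=x, y=y, density=density,
                            bandwidth=(float(hx), float(hy)),
                            contour_levels=levels)


def region_members(scores: np.ndarray, taxa: Sequence[str],
                   region: FocalRegion) -> set[str]:
    """Taxa whose (PC1, PC2) point lies inside the region."""
    if not region.is_ellipse:
        return set(region.taxa) & set(taxa)
    pts = np.atleast_2d(np.asarray(scores, dtype=float))[:, :2]
    mask = region.contains(pts)
    return {t for t, inside in zip(taxa, mask) if inside}
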