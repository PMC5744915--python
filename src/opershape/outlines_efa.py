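"""Elliptical Fourier analysis (EFA) of closed bone outlines.

The outline morphospace is an independent cross-check of the landmark
morphospace: each closed outline (about 400 digitized xy points) is
decomposed into harmonic ellipses; the normalized coefficients (size,
orientation, and starting-point phase removed by the standard
first-harmonic convention) are ordinated by PCA just like Procrustes
coordinates.

Outlines are expected to be equally spaced along the curve (use
:func:`resample_outline` first); the default parametrization then assigns
each segment an equal parameter increment, under which a uniformly sampled
ellipse is represented exactly by its first harmonic. Chord-length
parametrization is available for unevenly spaced input.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .morphospace import Morphospace, pca_matrix

__all__ = [
    "Outline",
    "EFACoefficients",
    "resample_outline",
    "efa",
    "efa_reconstruct",
    "efa_morphospace",
]


@dataclass
class Outline:
    """Closed ordered point sequence; the first point is not repeated."""

    points: np.ndarray  # (q, 2)
    taxon: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("outline points must be (q, 2)")
        if self.points.shape[0] < 3:
            raise ValueError("outline needs at least 3 points")

    @property
    def q(self) -> int:
        return self.points.shape[0]

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    def is_simple(self) -> bool:
        """Brute-force check that no two non-adjacent segments cross."""
        closed = np.vstack([self.points, self.points[:1]])
        segs = [(closed[i], closed[i + 1]) for i in range(self.q)]

        def cross2(u, v) -> float:
            return u[0] * v[1] - u[1] * v[0]

        def crosses(p1, p2, p3, p4) -> bool:
            d1 = cross2(p2 - p1, p3 - p1)
            d2 = cross2(p2 - p1, p4 - p1)
            d3 = cross2(p4 - p3, p1 - p3)
            d4 = cross2(p4 - p3, p2 - p3)
            return bool((d1 * d2 < 0) and (d3 * d4 < 0))

        q = self.q
        for i, j in combinations(range(q), 2):
            if abs(i - j) <= 1 or {i, j} == {0, q - 1}:
                continue
            if crosses(*segs[i], *segs[j]):
                return False
        return True


@dataclass
class EFACoefficients:
    """Harmonic coefficients, rows ``(a_n, b_n, c_n, d_n)``, plus DC term."""

    coeffs: np.ndarray  # (H, 4)
    a0: float = 0.0
    c0: float = 0.0
    normalized: bool = False
    taxon: str = ""

    @property
    def harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flat(self) -> np.ndarray:
        return self.coeffs.ravel()


def resample_outline(points: np.ndarray | Outline, q: int = 400,
                     taxon: str | None = None) -> Outline:
    """Resample a closed polyline to q points equally spaced by arc length."""
    if isinstance(points, Outline):
        if taxon is None:
            taxon = points.taxon
        points = points.points
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate outline (zero perimeter)")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(q) * total / q
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return Outline(points=np.column_stack([x, y]), taxon=taxon or "")


def _raw_efa(points: np.ndarray, H: int,
             parametrization: str) -> tuple[np.ndarray, float, float]:
    """Piecewise-linear Kuhl-Giardina coefficients of a closed polygon."""
    closed = np.vstack([points, points[:1]])
    dxy = np.diff(closed, axis=0)
    if parametrization == "chord":
        dt = np.linalg.norm(dxy, axis=1)
        keep = dt > 0
        dxy, dt = dxy[keep], dt[keep]
        starts = closed[:-1][keep]
    elif parametrization == "uniform":
        dt = np.full(len(dxy), 1.0)
        starts = closed[:-1]
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, H + 1)[:, None]  # (H, 1)
    cos_diff = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_diff = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = const * (cos_diff @ vx)
    b = const * (sin_diff @ vx)
    c = const * (cos_diff @ vy)
    d = const * (sin_diff @ vy)
    ends = starts + dxy
    mean = (0.5 * (starts + ends) * dt[:, None]).sum(axis=0) / T
    return np.column_stack([a, b, c, d]), float(mean[0]), float(mean[1])


def _rot(x: float) -> np.ndarray:
    return np.array([[np.cos(x), -np.sin(x)], [np.sin(x), np.cos(x)]])


def _normalize(coeffs: np.ndarray) -> np.ndarray:
    """First-harmonic normalization: phase, orientation, and size removed.

    Afterwards the first harmonic is canonical: ``a1 > 0``, ``b1 = c1 = 0``
    and ``d1 >= 0`` (the last fixes traversal direction, so digitization
    direction is irrelevant).
    """
    a1, b1, c1, d1 = coeffs[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1**2 + c1**2 - b1**2 - d1**2)
    out = np.empty_like(coeffs)
    H = coeffs.shape[0]
    for i in range(H):
        out[i] = (coeffs[i].reshape(2, 2) @ _rot((i + 1) * theta)).ravel()
    a1p, _, c1p, _ = out[0]
    psi = np.arctan2(c1p, a1p)
    orient = _rot(-psi)
    for i in range(H):
        out[i] = (orient @ out[i].reshape(2, 2)).ravel()
    scale = out[0, 0]  # = hypot(a1p, c1p) > 0 by construction
    out /= scale
    if out[0, 3] < 0:
        out[:, 1] *= -1
        out[:, 3] *= -1
    return out


def efa(outline: Outline | np.ndarray, H: int = 30, normalize: bool = True,
        parametrization: str = "uniform") -> EFACoefficients:
    """Elliptical Fourier coefficients of a closed outline.

    ``H`` harmonics (default 30, counting the first); with ``normalize``
    the first-harmonic convention removes size, orientation, and
    starting-point phase. Raises if ``H`` exceeds q/2 (aliasing).
    """
    if isinstance(outline, Outline):
        pts = outline.points
        taxon = outline.taxon
    else:
        pts = np.asarray(outline, dtype=float)
        taxon = ""
    if H > pts.shape[0] / 2:
        raise ValueError(f"H = {H} exceeds q/2 = {pts.shape[0] / 2:g} (aliasing)")
    coeffs, a0, c0 = _raw_efa(pts, H, parametrization)
    if normalize:
        coeffs = _normalize(coeffs)
        a0 = c0 = 0.0
    return EFACoefficients(coeffs=coeffs, a0=a0, c0=c0,
                           normalized=normalize, taxon=taxon)


def efa_reconstruct(coeffs: EFACoefficients, q: int = 400,
                    H: int | None = None) -> np.ndarray:
    """Reconstruct a q-point outline from the leading H harmonics."""
    C = coeffs.coeffs if H is None else coeffs.coeffs[:H]
    Hn = C.shape[0]
    t = np.linspace(0.0, 2.0 * np.pi, q, endpoint=False)
    n = np.arange(1, Hn + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    x = coeffs.a0 + C[:, 0] @ cos_nt + C[:, 1] @ sin_nt
    y = coeffs.c0 + C[:, 2] @ cos_nt + C[:, 3] @ sin_nt
    return np.column_stack([x, y])


def efa_morphospace(coefficient_sets: Sequence[EFACoefficients]) -> Morphospace:
    """PCA over flattened normalized EFA coefficients."""
    sets = list(coefficient_sets)
    if len(sets) < 2:
        raise ValueError("need at least 2 coefficient sets")
    H = sets[0].harmonics
    if any(s.harmonics != H for s in sets):
        raise ValueError("coefficient sets differ in harmonic count")
    data = np.vstack([s.flat() for s in sets])
    taxa = [s.taxon or f"outline_{i}" for i, s in enumerate(sets)]
    return pca_matrix(data, taxa)
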