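"""Landmark configurations, TPS/CSV input and output, and generalized
Procrustes analysis (GPA).

The opercle scheme digitizes 18 points per bone: 4 fixed landmarks at
homologous positions (joint socket, ventral and posterior apices) and 14
semilandmarks placed at regular intervals along the bone edge.
Semilandmarks are treated as fixed points here (no sliding step).

GPA removes translation, scale, and rotation: every configuration is
centered, scaled to unit centroid size, and rotated onto an iteratively
re-estimated consensus. The residual coordinates ("Procrustes shape
variables") are the input to all downstream ordination and comparative
statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

FIXED = "fixed"
SEMILANDMARK = "semilandmark"

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "AlignedShapes",
    "MalformedRecordError",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
    "centroid_size",
    "average_specimens",
    "gpa",
    "procrustes_distance",
    "optimal_rotation",
]


class MalformedRecordError(ValueError):
    """A TPS record is internally inconsistent (e.g. LM= count mismatch)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2-D landmark configuration.

    Parameters
    ----------
    specimen_id
        Unique specimen identifier (e.g. image name).
    taxon
        Taxon (species or family) the specimen represents.
    coords
        ``(k, 2)`` array of landmark coordinates, in digitization order.
    roles
        Length-``k`` sequence of ``"fixed"`` or ``"semilandmark"`` labels.
        Defaults to all fixed.
    side
        ``"left"``, ``"right"`` or ``"unknown"``. Left-side configurations
        are mirrored onto the right before superimposition.
    """

    specimen_id: str
    taxon: str
    coords: np.ndarray
    roles: tuple[str, ...] = ()
    side: str = "unknown"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: coords must be (k, 2), got {self.coords.shape}"
            )
        k = self.coords.shape[0]
        if k < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if not self.roles:
            self.roles = (FIXED,) * k
        self.roles = tuple(self.roles)
        if len(self.roles) != k:
            raise ValueError(
                f"{self.specimen_id}: {len(self.roles)} roles for {k} landmarks"
            )
        bad = set(self.roles) - {FIXED, SEMILANDMARK}
        if bad:
            raise ValueError(f"{self.specimen_id}: unknown roles {sorted(bad)}")
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"{self.specimen_id}: invalid side {self.side!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def mirrored(self) -> "LandmarkConfiguration":
        """Reflect about the y-axis (flips left to right)."""
        out = self.coords.copy()
        out[:, 0] = -out[:, 0]
        new_side = {"left": "right", "right": "left"}.get(self.side, "unknown")
        return replace(self, coords=out, side=new_side)


@dataclass
class LandmarkDataset:
    """A homogeneous collection of landmark configurations."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.configurations:
            k = self.configurations[0].k
            roles = self.configurations[0].roles
            for c in self.configurations:
                if c.k != k:
                    raise ValueError(
                        f"inconsistent landmark counts: {c.specimen_id} has {c.k}, "
                        f"expected {k}"
                    )
                if c.roles != roles:
                    raise ValueError(
                        f"inconsistent landmark roles in {c.specimen_id}"
                    )

    @property
    def landmark_count(self) -> int:
        if not self.configurations:
            raise ValueError("empty dataset")
        return self.configurations[0].k

    @property
    def taxa(self) -> list[str]:
        return [c.taxon for c in self.configurations]

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an ``(n, k, 2)`` array."""
        return np.stack([c.coords for c in self.configurations])


@dataclass
class AlignedShapes:
    """Procrustes-superimposed shapes.

    ``coords`` has shape ``(n, k, 2)``; every configuration is centered at
    the origin with unit centroid size. ``consensus`` is the coordinate-wise
    mean shape and ``centroid_sizes`` the original sizes removed by scaling.
    """

    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    taxa: list[str]
    iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def flat(self) -> np.ndarray:
        """Flattened ``(n, 2k)`` coordinate matrix (x1, y1, x2, y2, ...)."""
        return self.coords.reshape(self.n, -1)

    def subset(self, taxa: Sequence[str]) -> "AlignedShapes":
        """Restrict to the given taxa, preserving their order."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in aligned set: {missing}")
        idx = [index[t] for t in taxa]
        sub = self.coords[idx]
        return AlignedShapes(
            coords=sub,
            consensus=sub.mean(axis=0),
            centroid_sizes=self.centroid_sizes[idx],
            taxa=list(taxa),
            iterations=self.iterations,
            converged=self.converged,
        )


# ---------------------------------------------------------------------------
# TPS / CSV I/O


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS file (tpsDig convention) into a :class:`LandmarkDataset`.

    Each record starts with ``LM=<k>``, followed by ``k`` whitespace-separated
    coordinate lines, then optional ``ID=``, ``IMAGE=`` and ``SCALE=`` lines.
    SCALE factors, when present, multiply the record's coordinates.
    """
    path = Path(path)
    text = path.read_text()
    configs: list[LandmarkConfiguration] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        m = re.match(r"LM\s*=\s*(\d+)", line, re.IGNORECASE)
        if not m:
            raise MalformedRecordError(
                f"{path.name}: expected LM= at line {i + 1}, got {line!r}"
            )
        record_no += 1
        k = int(m.group(1))
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            ln = lines[i]
            if not ln or "=" in ln:
                break
            parts = ln.split()
            if len(parts) != 2:
                break
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise MalformedRecordError(
                f"{path.name}: record {record_no} declares LM={k} but has "
                f"{len(coords)} coordinate lines"
            )
        specimen_id = f"record_{record_no}"
        image = None
        scale = None
        while i < len(lines):
            ln = lines[i]
            if not ln:
                i += 1
                continue
            if re.match(r"LM\s*=", ln, re.IGNORECASE):
                break
            key, _, value = ln.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "ID":
                specimen_id = value
            elif key == "IMAGE":
                image = value
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if specimen_id.startswith("record_") and image:
            specimen_id = image
        arr = np.array(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        configs.append(
            LandmarkConfiguration(specimen_id=specimen_id, taxon=specimen_id, coords=arr)
        )
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset | Iterable[LandmarkConfiguration],
              path: str | Path) -> None:
    """Write configurations to TPS (LM=, coordinates, ID=)."""
    configs = list(dataset)
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_landmark_csv(path: str | Path) -> LandmarkDataset:
    """Read a wide CSV: specimen_id, taxon, side, x1, y1, ..., xk, yk."""
    import pandas as pd

    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if re.fullmatch(r"[xy]\d+", c)]
    k = len(coord_cols) // 2
    configs = []
    for _, row in df.iterrows():
        xy = np.array(
            [[row[f"x{j}"], row[f"y{j}"]] for j in range(1, k + 1)], dtype=float
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                taxon=str(row["taxon"]),
                coords=xy,
                side=str(row.get("side", "unknown")),
            )
        )
    return LandmarkDataset(configs)


def write_landmark_csv(dataset: LandmarkDataset | Iterable[LandmarkConfiguration],
                       path: str | Path) -> None:
    import pandas as pd

    configs = list(dataset)
    rows = []
    for c in configs:
        row: dict = {"specimen_id": c.specimen_id, "taxon": c.taxon, "side": c.side}
        for j, (x, y) in enumerate(c.coords, start=1):
            row[f"x{j}"] = x
            row[f"y{j}"] = y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geometry


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    xy = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    centered = xy - xy.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_and_scale(xy: np.ndarray, specimen_id: str = "?") -> tuple[np.ndarray, float]:
    centered = xy - xy.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size <= 0:
        raise ValueError(f"degenerate configuration (zero centroid size): {specimen_id}")
    return centered / size, float(size)


def optimal_rotation(a: np.ndarray, b: np.ndarray,
                     allow_reflection: bool = False) -> np.ndarray:
    """Rotation matrix R minimizing ||a - b @ R|| for centered shapes.

    Solved by SVD of the cross-covariance ``b.T @ a``; when reflection is
    disallowed the smallest singular vector pair is sign-flipped to force
    ``det(R) = +1``.
    """
    u, _, vt = np.linalg.svd(b.T @ a)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray,
                        allow_reflection: bool = False,
                        rescale: bool = True) -> float:
    """Root summed squared difference after optimally rotating b onto a.

    Inputs are centered and unit-scaled first when ``rescale`` (so the
    distance is a pure shape distance); symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    if rescale:
        a, _ = _center_and_scale(a, "a")
        b, _ = _center_and_scale(b, "b")
    r = optimal_rotation(a, b, allow_reflection=allow_reflection)
    return float(np.sqrt(np.sum((a - b @ r) ** 2)))


def gpa(dataset: LandmarkDataset | Sequence[LandmarkConfiguration],
        allow_reflection: bool = False,
        tol: float = 1e-10,
        max_iter: int = 100,
        reflect_left: bool = True) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running consensus (mean shape, itself
    re-centered and unit-scaled each round) until the consensus
    root-mean-square displacement drops below ``tol``.

    Parameters
    ----------
    allow_reflection
        Permit improper rotations during fitting. Off by default; side
        mirroring is handled explicitly via ``reflect_left``.
    reflect_left
        Reflect configurations labeled ``side == "left"`` onto the right
        side before superimposition.
    """
    configs = list(dataset)
    if not configs:
        raise ValueError("empty dataset")
    if reflect_left:
        configs = [c.mirrored() if c.side == "left" else c for c in configs]
    taxa = [c.taxon for c in configs]
    scaled = []
    sizes = []
    for c in configs:
        s, size = _center_and_scale(c.coords, c.specimen_id)
        scaled.append(s)
        sizes.append(size)
    coords = np.stack(scaled)
    n, k, _ = coords.shape
    if n == 1:
        return AlignedShapes(coords=coords, consensus=coords[0].copy(),
                             centroid_sizes=np.array(sizes), taxa=taxa,
                             iterations=0, converged=True)

    # initial consensus: everything rotated to the first shape
    consensus = coords[0]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = optimal_rotation(consensus, coords[i], allow_reflection)
            coords[i] = coords[i] @ r
        new_consensus = coords.mean(axis=0)
        new_consensus, _ = _center_and_scale(new_consensus, "consensus")
        shift = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    # report the plain coordinate-wise mean, so residuals sum to zero exactly
    consensus = coords.mean(axis=0)
    return AlignedShapes(coords=coords, consensus=consensus,
                         centroid_sizes=np.array(sizes), taxa=taxa,
                         iterations=iterations, converged=converged)


def average_specimens(configs: Sequence[LandmarkConfiguration],
                      superimpose: bool = True) -> LandmarkConfiguration:
    """Average replicate configurations of a single taxon.

    Replicates are GPA-superimposed together first (unless ``superimpose``
    is False, in which case they are assumed pre-aligned), then averaged
    coordinate-wise.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations to average")
    taxa = {c.taxon for c in configs}
    if len(taxa) != 1:
        raise ValueError(f"mixed taxa in average_specimens: {sorted(taxa)}")
    if len(configs) == 1:
        return configs[0]
    if superimpose:
        aligned = gpa(configs)
        mean = aligned.coords.mean(axis=0)
    else:
        mean = np.stack([c.coords for c in configs]).mean(axis=0)
    c0 = configs[0]
    return LandmarkConfiguration(
        specimen_id=f"{c0.taxon}_mean",
        taxon=c0.taxon,
        coords=mean,
        roles=c0.roles,
        side="right" if any(c.side != "unknown" for c in configs) else "unknown",
    )


def average_by_taxon(dataset: LandmarkDataset) -> LandmarkDataset:
    """Collapse replicate specimens to one averaged configuration per taxon."""
    by_taxon: dict[str, list[LandmarkConfiguration]] = {}
    order: list[str] = []
    for c in dataset:
        if c.taxon not in by_taxon:
            by_taxon[c.taxon] = []
            order.append(c.taxon)
        by_taxon[c.taxon].append(c)
    return LandmarkDataset([average_specimens(by_taxon[t]) for t in order])
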