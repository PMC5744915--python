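"""Synthetic opercle-like datasets with known ground truth.

The generator emulates the study design this package analyzes: a clade of
~100 families on an ultrametric time tree (crown depth on the order of
250 My), each family's 18-point opercle shape produced by latent traits
evolving under Brownian motion or an Ornstein-Uhlenbeck process (optionally
with shared optima for designated "convergent" tip sets), mapped through a
fixed orthonormal deformation basis applied to a template bone outline,
plus within-species replicate landmark noise.

Because the deformation basis is orthonormal in flattened coordinate
space, latent traits map near-linearly to Procrustes/PC space, so
parameter-recovery and convergence-power tests have analyzable ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .shapes import (FIXED, SEMILANDMARK, LandmarkConfiguration,
                     LandmarkDataset, centroid_size)
from .phylo import TimeTree, bm_simulate
from .outlines_efa import Outline, resample_outline

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "simulate_tree",
    "template_opercle",
    "deformation_basis",
    "simulate_shape_dataset",
    "simulate_outlines",
    "pick_distant_clades",
    "write_dataset",
]


@dataclass
class SimulationScenario:
    """Study-scale defaults: ~100 tips, ~250 My crown depth, 2 shape axes.

    ``rate`` is the per-trait Brownian variance per My; the default gives
    tip-shape standard deviations of ~0.08 Procrustes units at the default
    depth. ``regimes`` maps a regime label to ``{"taxa": [...],
    "optimum": [...]}`` and is only meaningful with
    ``shape_model="OU_convergent"``.
    """

    n_taxa: int = 100
    tree_model: str = "pure_birth"
    birth_rate: float = 0.0167  # per My; Yule crown depth ~250 My at n=100
    shape_model: str = "BM"  # BM | OU_single | OU_convergent
    rate: float = 2.5e-5
    ou_alpha: float = 0.008  # per My; alpha * depth ~ 2 at defaults
    regimes: dict | None = None
    deformation_dims: int = 2
    noise_sd: float = 0.005
    replicates_per_species: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if min(self.rate, self.birth_rate, self.noise_sd) < 0:
            raise ValueError("rates and noise_sd must be non-negative")
        if self.shape_model not in ("BM", "OU_single", "OU_convergent"):
            raise ValueError(f"unknown shape model {self.shape_model!r}")
        if self.regimes and self.shape_model != "OU_convergent":
            raise ValueError("regimes require shape_model='OU_convergent'")


@dataclass
class GroundTruth:
    """Full provenance of one simulated dataset."""

    scenario: SimulationScenario
    newick: str
    tip_traits: dict[str, list[float]]
    node_traits: dict[str, list[float]]
    basis: np.ndarray  # (D, 2k)
    template: np.ndarray  # (k, 2)
    regimes: dict | None = None

    def to_json(self) -> str:
        payload = {
            "scenario": asdict(self.scenario),
            "newick": self.newick,
            "tip_traits": self.tip_traits,
            "node_traits": self.node_traits,
            "basis": self.basis.tolist(),
            "template": self.template.tolist(),
            "regimes": self.regimes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def simulate_tree(n_taxa: int, birth_rate: float, seed: int | None = None) -> TimeTree:
    """Pure-birth (Yule) tree conditioned on the number of tips.

    Simulation stops when the n-th lineage appears; the present is placed
    one additional exponential waiting time later (truncated just before
    the next speciation), so terminal branches have positive length and
    the tree is exactly ultrametric.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # node records: (parent_record_index, start_time); root has parent -1
    parents = [-1]
    starts = [0.0]
    children: list[list[int]] = [[]]
    active: list[int] = []
    for _ in range(2):
        parents.append(0)
        starts.append(0.0)
        children.append([])
        children[0].append(len(parents) - 1)
        active.append(len(parents) - 1)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = active.pop(int(rng.integers(len(active))))
        ends_at = t
        for _ in range(2):
            parents.append(idx)
            starts.append(ends_at)
            children.append([])
            children[idx].append(len(parents) - 1)
            active.append(len(parents) - 1)
    present = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    ends = [0.0] * len(parents)
    for rec in range(1, len(parents)):
        ends[rec] = starts[children[rec][0]] if children[rec] else present
    # preorder flatten
    order: list[int] = []
    stack = [0]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    pos = {rec: j for j, rec in enumerate(order)}
    n_nodes = len(order)
    parent_arr = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    is_tip = np.zeros(n_nodes, dtype=bool)
    labels = [""] * n_nodes
    tip_no = 0
    for rec in order:
        j = pos[rec]
        if parents[rec] >= 0:
            parent_arr[j] = pos[parents[rec]]
            blen[j] = ends[rec] - starts[rec]
        if not children[rec]:
            is_tip[j] = True
            tip_no += 1
            labels[j] = f"t{tip_no}"
        else:
            labels[j] = f"nd{j}"
    return TimeTree(parent_arr, blen, labels, is_tip)


def template_opercle() -> LandmarkConfiguration:
    """Fixed 18-point fan-shaped template: 4 landmarks + 14 semilandmarks.

    Points lie on a star-convex (hence simple) closed curve; fixed
    landmarks sit at the joint, socket, ventral apex, and posterior apex
    positions. Centered at the origin with unit centroid size.
    """
    k = 18
    theta = 2.0 * np.pi * np.arange(k) / k
    r = 1.0 + 0.35 * np.sin(theta) - 0.2 * np.cos(2.0 * theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts -= pts.mean(axis=0)
    pts /= centroid_size(pts)
    roles = [SEMILANDMARK] * k
    for i in (0, 5, 9, 14):
        roles[i] = FIXED
    return LandmarkConfiguration(specimen_id="template", taxon="template",
                                 coords=pts, roles=tuple(roles))


def deformation_basis(dims: int, k: int = 18) -> np.ndarray:
    """Orthonormal smooth edge-displacement fields, shape (dims, 2k).

    Low-order trigonometric displacement patterns around the outline,
    projected off uniform translations and orthonormalized, so each latent
    trait unit moves the flattened coordinates by a unit-norm vector.
    """
    if dims > 2 * k - 4:
        raise ValueError(f"at most {2 * k - 4} deformation dims for k = {k}")
    j = np.arange(k)
    fields = []
    order = 2
    phase = 0.0
    while len(fields) < dims:
        u = np.cos(2.0 * np.pi * order * j / k + phase)
        v = np.sin(2.0 * np.pi * order * j / k + 0.5 * phase + 0.9)
        fields.append(np.column_stack([u, v]).ravel())
        phase += 1.1
        order += 1
    B = np.array(fields, dtype=float)
    # project off rigid translations (uniform x and y shifts)
    for tvec in (np.tile([1.0, 0.0], k), np.tile([0.0, 1.0], k)):
        tvec = tvec / np.linalg.norm(tvec)
        B -= np.outer(B @ tvec, tvec)
    # Gram-Schmidt
    Q = np.linalg.qr(B.T)[0].T[:dims]
    # deterministic sign
    for row in Q:
        i = np.argmax(np.abs(row))
        if row[i] < 0:
            row *= -1
    return Q


def _ou_simulate_nodes(tree: TimeTree, rate: float, alpha: float,
                       optima_per_edge: np.ndarray, root_state: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """OU trait values at every node; optima_per_edge is (n_nodes, p)."""
    p = root_state.shape[0]
    states = np.zeros((tree.n_nodes, p))
    states[0] = root_state
    for i in range(1, tree.n_nodes):
        b = tree.blen[i]
        theta = optima_per_edge[i]
        if alpha * b < 1e-12:
            mean = states[tree.parent[i]]
            var = rate * b
        else:
            e = np.exp(-alpha * b)
            mean = theta + (states[tree.parent[i]] - theta) * e
            var = rate * (1.0 - e * e) / (2.0 * alpha)
        states[i] = mean + np.sqrt(var) * rng.standard_normal(p)
    return states


def _edge_optima(tree: TimeTree, regimes: Mapping | None, p: int) -> np.ndarray:
    """Per-edge OU optimum: a regime's optimum on edges whose descendant
    tips all belong to that regime's taxon set; baseline 0 elsewhere."""
    optima = np.zeros((tree.n_nodes, p))
    if not regimes:
        return optima
    tip_sets: dict[int, set[str]] = {}
    # descendant tip labels per node (postorder accumulation)
    for i in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip[i]:
            tip_sets[i] = {tree.labels[i]}
        else:
            tip_sets[i] = set().union(*(tip_sets[c] for c in tree.children[i]))
    for spec in regimes.values():
        taxa = set(spec["taxa"])
        opt = np.asarray(spec["optimum"], dtype=float)
        if opt.shape != (p,):
            raise ValueError(f"optimum must have {p} dims")
        for i in range(1, tree.n_nodes):
            if tip_sets[i] <= taxa:
                optima[i] = opt
    return optima


def simulate_latent_traits(tree: TimeTree, scenario: SimulationScenario,
                           rng: np.random.Generator) -> np.ndarray:
    """Latent trait values at all nodes, (n_nodes, deformation_dims)."""
    p = scenario.deformation_dims
    root = np.zeros(p)
    if scenario.shape_model == "BM":
        seed = int(rng.integers(2**31))
        _, nodes = bm_simulate(tree, scenario.rate, root, n_sims=1,
                               seed=seed, return_nodes=True)
        return nodes[0]
    optima = _edge_optima(
        tree,
        scenario.regimes if scenario.shape_model == "OU_convergent" else None,
        p,
    )
    return _ou_simulate_nodes(tree, scenario.rate, scenario.ou_alpha,
                              optima, root, rng)


def simulate_shape_dataset(scenario: SimulationScenario
                           ) -> tuple[LandmarkDataset, TimeTree, GroundTruth]:
    """Generate a landmark dataset, its tree, and a full ground-truth record.

    Each tip's configuration is the template plus the latent traits mapped
    through the orthonormal deformation basis, with independent Gaussian
    landmark noise per replicate specimen.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = simulate_tree(scenario.n_taxa, scenario.birth_rate,
                         seed=int(rng.integers(2**31)))
    template = template_opercle()
    k = template.k
    B = deformation_basis(scenario.deformation_dims, k)
    node_traits = simulate_latent_traits(tree, scenario, rng)
    configs = []
    tip_traits: dict[str, list[float]] = {}
    for idx, label in zip(tree.tip_indices, tree.tip_labels):
        z = node_traits[idx]
        tip_traits[label] = z.tolist()
        shape = template.coords + (z @ B).reshape(k, 2)
        for rep in range(scenario.replicates_per_species):
            noisy = shape + scenario.noise_sd * rng.standard_normal((k, 2))
            # single-replicate datasets keep the taxon as specimen id so
            # TPS round-trips (ID= is the only identity TPS carries)
            sid = label if scenario.replicates_per_species == 1 \
                else f"{label}_rep{rep + 1}"
            configs.append(LandmarkConfiguration(
                specimen_id=sid,
                taxon=label, coords=noisy, roles=template.roles, side="right",
            ))
    truth = GroundTruth(
        scenario=scenario,
        newick=tree.to_newick(),
        tip_traits=tip_traits,
        node_traits={tree.labels[i]: node_traits[i].tolist()
                     for i in range(tree.n_nodes) if not tree.is_tip[i]},
        basis=B,
        template=template.coords,
        regimes=scenario.regimes,
    )
    return LandmarkDataset(configs), tree, truth


def _smooth_closed_curve(points: np.ndarray, q: int) -> np.ndarray:
    """Periodic cubic spline through the points, sampled at q positions."""
    from scipy.interpolate import CubicSpline

    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    cs = CubicSpline(t, closed, bc_type="periodic")
    return cs(np.linspace(0.0, t[-1], 4 * q, endpoint=False))


def simulate_outlines(scenario: SimulationScenario, q: int = 400
                      ) -> tuple[list[Outline], TimeTree, GroundTruth]:
    """Closed q-point outlines from smoothly interpolated deformed templates.

    Each taxon's noise-free deformed 18-point edge polygon is checked for
    self-intersection and rejected (raising) if it crosses itself; the
    smooth periodic interpolant through the accepted polygon is resampled
    to q points equally spaced by arc length.
    """
    dataset, tree, truth = simulate_shape_dataset(scenario)
    outlines = []
    seen = set()
    for cfg in dataset:
        if cfg.taxon in seen:  # one outline per taxon
            continue
        seen.add(cfg.taxon)
        z = np.asarray(truth.tip_traits[cfg.taxon])
        shape = truth.template + (z @ truth.basis).reshape(-1, 2)
        control = Outline(points=shape, taxon=cfg.taxon)
        if not control.is_simple():
            raise ValueError(
                f"deformation produced a self-intersecting outline for {cfg.taxon}"
            )
        dense = _smooth_closed_curve(shape, q)
        outlines.append(resample_outline(dense, q=q, taxon=cfg.taxon))
    return outlines, tree, truth


def pick_distant_clades(tree: TimeTree, clade_size: int,
                        n_clades: int = 2) -> list[list[str]]:
    """Designate convergent tip sets: disjoint clades of ~clade_size tips
    whose stem nodes are phylogenetically distant (greedy farthest pick)."""
    depths = tree.depths()
    candidates = []
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            continue
        tips = [j for j in tree.subtree_nodes(i) if tree.is_tip[j]]
        if len(tips) == clade_size:
            candidates.append((i, [tree.labels[j] for j in tips]))
    if len(candidates) < n_clades:
        raise ValueError(
            f"tree has only {len(candidates)} clades of size {clade_size}"
        )

    def node_dist(a: int, b: int) -> float:
        m = tree.mrca(a, b)
        return depths[a] + depths[b] - 2.0 * depths[m]

    chosen = [candidates[0]]
    rest = candidates[1:]
    while len(chosen) < n_clades and rest:
        rest = [c for c in rest
                if not set(c[1]) & set().union(*(set(x[1]) for x in chosen))]
        if not rest:
            break
        best = max(rest, key=lambda c: min(node_dist(c[0], x[0]) for x in chosen))
        chosen.append(best)
        rest.remove(best)
    if len(chosen) < n_clades:
        raise ValueError("could not find enough disjoint clades")
    return [c[1] for c in chosen]


def write_dataset(out_dir: str | Path, dataset: LandmarkDataset,
                  tree: TimeTree, truth: GroundTruth,
                  outlines: Sequence[Outline] | None = None) -> None:
    """Write TPS, Newick, optional outline CSV, and the ground-truth JSON."""
    from .shapes import write_tps

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tps(dataset, out / "landmarks.tps")
    tree.write(out / "tree.nwk")
    (out / "ground_truth.json").write_text(truth.to_json())
    if outlines is not None:
        import pandas as pd

        rows = []
        for o in outlines:
            for x, y in o.points:
                rows.append({"taxon": o.taxon, "x": x, "y": y})
        pd.DataFrame(rows).to_csv(out / "outlines.csv", index=False)
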