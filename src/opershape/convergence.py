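"""Phenotypic convergence measures on the PC1-PC2 phylomorphospace.

Similarity-based measures for a pair of lineages ending at focal tips
(aggregated over all focal pairs by the mean):

* ``Dtip`` — distance between the two tips; ``Dmax`` — the maximum
  distance between any two states, one drawn from each lineage (tip or
  reconstructed ancestor back to the common ancestor).
* ``C1 = 1 - Dtip/Dmax`` in [0, 1]: 1 when tips coincide after having been
  maximally dissimilar, 0 under pure divergence.
* ``C2 = Dmax - Dtip`` (morphospace distance units).
* ``C3 = C2 / total evolution along the two lineages`` (summed
  state-change magnitudes per edge).
* ``C4 = C2 / total evolution in the whole clade`` descending from the
  common ancestor.

The frequency-based measure ``C5`` counts independent entries into a
user-specified morphospace region: edges whose parent (ancestral) point
lies outside and whose child point lies inside. Significance of all
metrics comes from Brownian-motion simulations on the tree, with the
per-axis BM rate estimated from the observed scores; p-values use the
bare count/n_sims convention, so a p of 0 means no simulation reached the
empirical value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .morphospace import FocalRegion, region_members
from .phylo import (PhylomorphospaceLayout, ScpSolver, TimeTree,
                    phylomorphospace)

__all__ = [
    "ConvergenceResult",
    "c_similarity",
    "c5_count",
    "c5_tip_entries",
    "convergence_test",
]


@dataclass
class ConvergenceResult:
    focal_taxa: list[str]
    region_label: str | None
    C1: float
    C2: float
    C3: float
    C4: float
    C5: int | None
    p_C1: float
    p_C2: float
    p_C3: float
    p_C4: float
    p_C5: float | None
    n_sims: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "focal_taxa": self.focal_taxa, "region": self.region_label,
            "N": len(self.focal_taxa),
            "C1": self.C1, "C2": self.C2, "C3": self.C3, "C4": self.C4,
            "C5": self.C5,
            "p_C1": self.p_C1, "p_C2": self.p_C2, "p_C3": self.p_C3,
            "p_C4": self.p_C4, "p_C5": self.p_C5,
            "n_sims": self.n_sims, "seed": self.seed,
        }


class _PairGeometry:
    """Precomputed tree indices for one focal pair (lineages and clade)."""

    __slots__ = ("lineage1", "lineage2", "edges_lineages", "edges_clade",
                 "tip1", "tip2")

    def __init__(self, tree: TimeTree, tip1: int, tip2: int):
        m = tree.mrca(tip1, tip2)
        self.tip1, self.tip2 = tip1, tip2

        def lineage(tip: int) -> list[int]:
            path = [tip]
            while path[-1] != m:
                path.append(tree.parent[path[-1]])
            return path

        self.lineage1 = np.array(lineage(tip1))
        self.lineage2 = np.array(lineage(tip2))
        # edges (child nodes) along both lineages, excluding the MRCA itself
        self.edges_lineages = np.concatenate(
            [self.lineage1[:-1], self.lineage2[:-1]]
        )
        clade = tree.subtree_nodes(m)
        self.edges_clade = np.array([i for i in clade if i != m])


def _pair_metrics(states: np.ndarray, geom: _PairGeometry) -> tuple[float, float, float, float]:
    s1 = states[geom.lineage1]  # (L1, 2)
    s2 = states[geom.lineage2]
    dtip = float(np.linalg.norm(states[geom.tip1] - states[geom.tip2]))
    diff = s1[:, None, :] - s2[None, :, :]
    dmax = float(np.sqrt(np.max(np.sum(diff * diff, axis=-1))))
    if dmax <= 0:
        return 0.0, 0.0, 0.0, 0.0
    c1 = 1.0 - dtip / dmax
    c2 = dmax - dtip
    return c1, c2, dmax, dtip


def _total_changes(states: np.ndarray, children: np.ndarray,
                   parent: np.ndarray) -> float:
    d = states[children] - states[parent[children]]
    return float(np.sum(np.sqrt(np.sum(d * d, axis=-1))))


def _c_metrics(tree: TimeTree, states: np.ndarray,
               geoms: list[_PairGeometry], aggregate: str = "mean") -> np.ndarray:
    vals = np.zeros((len(geoms), 4))
    for i, g in enumerate(geoms):
        c1, c2, _, _ = _pair_metrics(states, g)
        lin_total = _total_changes(states, g.edges_lineages, tree.parent)
        clade_total = _total_changes(states, g.edges_clade, tree.parent)
        c3 = c2 / lin_total if lin_total > 0 else 0.0
        c4 = c2 / clade_total if clade_total > 0 else 0.0
        vals[i] = (c1, c2, c3, c4)
    agg = {"mean": np.mean, "min": np.min, "max": np.max}[aggregate]
    return agg(vals, axis=0)


def c_similarity(tree: TimeTree, scores, focal_taxa: Sequence[str],
                 taxa: Sequence[str] | None = None,
                 aggregate: str = "mean") -> tuple[float, float, float, float]:
    """C1-C4 for a focal taxon set, ancestors by squared-change parsimony.

    ``scores`` is a taxon -> (PC1, PC2) mapping or an array with ``taxa``
    giving row order (default: tree tip order). Pairwise values over all
    focal pairs are aggregated by ``aggregate`` (mean by default).
    """
    states, tip_idx = _states_matrix(tree, scores, taxa)
    focal = list(focal_taxa)
    if len(focal) < 2:
        raise ValueError("need at least 2 focal taxa")
    missing = [t for t in focal if t not in tip_idx]
    if missing:
        raise KeyError(f"focal taxa not in tree/scores: {missing}")
    geoms = [_PairGeometry(tree, tip_idx[a], tip_idx[b])
             for a, b in combinations(focal, 2)]
    c1, c2, c3, c4 = _c_metrics(tree, states, geoms, aggregate)
    return float(c1), float(c2), float(c3), float(c4)


def _states_matrix(tree: TimeTree, scores, taxa=None,
                   solver: ScpSolver | None = None):
    """All-node (n_nodes, 2) state matrix: empirical tips + SCP ancestors."""
    from .phylo import _tip_matrix

    if isinstance(scores, Mapping):
        tips = _tip_matrix(tree, scores)[:, :2]
    else:
        tips = np.asarray(scores, dtype=float)[:, :2]
        if taxa is not None:
            order = {t: i for i, t in enumerate(taxa)}
            tips = tips[[order[t] for t in tree.tip_labels]]
    if solver is None:
        solver = ScpSolver(tree)
    anc = solver.solve(tips)
    states = np.zeros((tree.n_nodes, 2))
    states[tree.tip_indices] = tips
    states[solver.internal] = anc
    tip_idx = {t: int(i) for t, i in zip(tree.tip_labels, tree.tip_indices)}
    return states, tip_idx


def c5_count(layout: PhylomorphospaceLayout, region: FocalRegion) -> int:
    """Independent entries into the region: edges crossing outside -> inside."""
    inside = region.contains(layout.points)
    parents = layout.edges[:, 0]
    children = layout.edges[:, 1]
    return int(np.sum(~inside[parents] & inside[children]))


def c5_tip_entries(layout: PhylomorphospaceLayout, region: FocalRegion) -> int:
    """Alternative count: entry edges actually reached from inside *tips*.

    Inside tips are traced rootward while they stay inside; the number of
    distinct boundary-crossing edges reached is returned. Equals
    :func:`c5_count` unless an entering edge leads only to internal nodes
    whose descendant tips have all left the region again.
    """
    inside = region.contains(layout.points)
    tree = layout.tree
    entry_edges: set[int] = set()
    for tip in tree.tip_indices:
        if not inside[tip]:
            continue
        node = int(tip)
        while tree.parent[node] >= 0 and inside[tree.parent[node]]:
            node = int(tree.parent[node])
        entry_edges.add(node)  # child node of the crossing (or root-inside) edge
    # tips whose whole path is inside up to the root count as one "entry" each
    return len(entry_edges)


def _ml_bm_rates(tree: TimeTree, tips: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis ML Brownian sigma^2 and GLS root state for (n_tips, 2) scores."""
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    ones = np.ones(tips.shape[0])
    w = Cinv @ ones
    root = (w @ tips) / w.sum()
    R = tips - root
    sig = np.array([R[:, j] @ (Cinv @ R[:, j]) / tips.shape[0] for j in range(tips.shape[1])])
    return sig, root


def convergence_test(tree: TimeTree, scores, focal=None,
                     region: FocalRegion | None = None,
                     n_sims: int = 1000, seed: int | None = None,
                     taxa: Sequence[str] | None = None,
                     aggregate: str = "mean") -> ConvergenceResult:
    """Test C1-C5 against Brownian-motion null simulations on the tree.

    ``focal`` is an explicit taxon set; alternatively (or additionally) a
    spatial ``region`` defines both the focal set (its observed members)
    and the target for the C5 entry count. The per-axis BM rate of the
    nulls is the ML estimate from the observed scores (no trait
    correlation). p-values are bare counts of simulations with metric >=
    observed, divided by n_sims, reproducing the convention under which a
    reported 0 means "never reached in simulation".
    """
    if n_sims < 100:
        warnings.warn(f"n_sims = {n_sims} gives coarse p-value resolution",
                      stacklevel=2)
    states, tip_idx = _states_matrix(tree, scores, taxa)
    tips_obs = states[tree.tip_indices]
    if region is not None and focal is None:
        members = region_members(tips_obs, tree.tip_labels, region)
        if not members:
            raise ValueError(f"region {region.label!r} contains no taxa")
        focal = sorted(members)
    if focal is None:
        raise ValueError("need focal taxa or a region")
    focal = list(focal)
    missing = [t for t in focal if t not in tip_idx]
    if missing:
        raise KeyError(f"focal taxa not in tree/scores: {missing}")
    geoms = [_PairGeometry(tree, tip_idx[a], tip_idx[b])
             for a, b in combinations(focal, 2)]
    obs_c = _c_metrics(tree, states, geoms, aggregate)

    solver = ScpSolver(tree)
    layout_obs = _layout_from_states(tree, states)
    obs_c5 = c5_count(layout_obs, region) if region is not None else None

    sig, root = _ml_bm_rates(tree, tips_obs)
    C = tree.vcv()
    chol = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    counts = np.zeros(4, dtype=int)
    count_c5 = 0
    for _ in range(n_sims):
        z = rng.standard_normal((n, 2))
        sim_tips = root + (chol @ z) * np.sqrt(sig)
        sim_states = np.zeros((tree.n_nodes, 2))
        sim_states[tree.tip_indices] = sim_tips
        sim_states[solver.internal] = solver.solve(sim_tips)
        sim_c = _c_metrics(tree, sim_states, geoms, aggregate)
        counts += sim_c >= obs_c
        if region is not None:
            sim_layout = _layout_from_states(tree, sim_states)
            if c5_count(sim_layout, region) >= obs_c5:
                count_c5 += 1
    p = counts / n_sims
    return ConvergenceResult(
        focal_taxa=focal,
        region_label=region.label if region is not None else None,
        C1=float(obs_c[0]), C2=float(obs_c[1]), C3=float(obs_c[2]),
        C4=float(obs_c[3]),
        C5=obs_c5,
        p_C1=float(p[0]), p_C2=float(p[1]), p_C3=float(p[2]), p_C4=float(p[3]),
        p_C5=(count_c5 / n_sims) if region is not None else None,
        n_sims=n_sims, seed=seed,
    )


def _layout_from_states(tree: TimeTree, states: np.ndarray) -> PhylomorphospaceLayout:
    edges = np.array([[tree.parent[i], i] for i in range(1, tree.n_nodes)])
    return PhylomorphospaceLayout(
        tree=tree, points=states, edges=edges,
        node_ids=list(tree.labels),
        node_types=["tip" if t else "node" for t in tree.is_tip],
    )
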