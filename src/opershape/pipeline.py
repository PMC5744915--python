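"""End-to-end orchestration of the full shape-evolution analysis.

Stages, in order: replicate averaging -> GPA -> PCA -> density landscape ->
phylomorphospace -> phylogenetic signal -> disparity -> evolutionary rates
-> model selection on PC1 and PC2 -> convergence tests per focal region.
Taxa missing from the tree are dropped with a logged list (the study's own
tree covered 103 of 110 families); everything is deterministic given the
seed, and every stage's output is written to the run directory so any
downstream stage can be recomputed from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import comparative_stats as cs
from . import convergence as conv
from .morphospace import FocalRegion, kde_landscape, pca, variance_explained
from .phylo import TimeTree, phylomorphospace, prune_to, read_newick
from .shapes import (AlignedShapes, LandmarkDataset, average_by_taxon, gpa,
                     read_landmark_csv, read_tps)

logger = logging.getLogger("opershape")

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis", "load_regions"]


@dataclass
class RunConfig:
    """Inputs and switches for one full analysis run.

    ``landmarks``/``tree`` may be file paths or in-memory objects
    (:class:`LandmarkDataset` / :class:`TimeTree`). ``groups`` maps taxon
    to group label (e.g. acanthomorph vs nonacanthomorph); ``regions``
    lists :class:`FocalRegion` definitions for the convergence tests.
    """

    landmarks: object
    tree: object
    groups: Mapping[str, str] | None = None
    regions: Sequence[FocalRegion] = ()
    out_dir: str | Path | None = None
    seed: int = 0
    n_perm_signal: int = 999
    n_perm_disparity: int = 1000
    n_sims_rates: int = 1000
    n_sims_convergence: int = 1000
    allow_reflection: bool = False
    do_landscape: bool = True
    do_signal: bool = True
    do_disparity: bool = True
    do_rates: bool = True
    do_models: bool = True
    do_convergence: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        regions = [
            FocalRegion(
                label=r.get("label", f"region_{i + 1}"),
                center=tuple(r["center"]) if "center" in r else None,
                semi_axes=tuple(r["semi_axes"]) if "semi_axes" in r else None,
                angle=float(r.get("angle", 0.0)),
                taxa=frozenset(r.get("taxa", ())),
            )
            for i, r in enumerate(raw.pop("regions", []))
        ]
        groups = raw.pop("groups", None)
        return cls(regions=regions, groups=groups, **raw)

    def config_hash(self) -> str:
        payload = {
            "landmarks": str(self.landmarks), "tree": str(self.tree),
            "groups": dict(self.groups) if self.groups else None,
            "regions": [r.label for r in self.regions],
            "seed": self.seed,
            "n": [self.n_perm_signal, self.n_perm_disparity,
                  self.n_sims_rates, self.n_sims_convergence],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Consolidated results; ``payload`` is the JSON-stable dict."""

    payload: dict = field(default_factory=dict)
    aligned: AlignedShapes | None = None
    morphospace: object = None
    layout: object = None
    model_tables: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=1, sort_keys=True,
                          default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_landmarks(src) -> LandmarkDataset:
    if isinstance(src, LandmarkDataset):
        return src
    path = Path(src)
    if path.suffix.lower() == ".tps":
        return read_tps(path)
    return read_landmark_csv(path)


def _load_tree(src) -> TimeTree:
    if isinstance(src, TimeTree):
        return src
    return read_newick(src)


def load_regions(path: str | Path) -> list[FocalRegion]:
    """Read focal-region definitions from a TOML config block."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    return [
        FocalRegion(
            label=r.get("label", f"region_{i + 1}"),
            center=tuple(r["center"]) if "center" in r else None,
            semi_axes=tuple(r["semi_axes"]) if "semi_axes" in r else None,
            angle=float(r.get("angle", 0.0)),
            taxa=frozenset(r.get("taxa", ())),
        )
        for i, r in enumerate(raw.get("regions", []))
    ]


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis chain for one (landmarks, tree) pair."""
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31))

    dataset = _load_landmarks(config.landmarks)
    tree = _load_tree(config.tree)
    dataset = average_by_taxon(dataset)
    data_taxa = set(t for t in (c.taxon for c in dataset))
    tree_taxa = set(tree.tip_labels)
    dropped = sorted(data_taxa - tree_taxa)
    common = [c.taxon for c in dataset if c.taxon in tree_taxa]
    if dropped:
        logger.info("dropping %d taxa absent from the tree: %s",
                    len(dropped), dropped)
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} taxa shared between landmarks and tree; "
            f"dropped {dropped}"
        )
    dataset = LandmarkDataset([c for c in dataset if c.taxon in tree_taxa])
    if set(tree.tip_labels) - set(common):
        tree = prune_to(tree, common)

    report = AnalysisReport()
    payload = report.payload
    payload["seed"] = config.seed
    payload["config_hash"] = config.config_hash()
    payload["n_taxa"] = len(common)
    payload["dropped_taxa"] = dropped

    aligned = gpa(dataset, allow_reflection=config.allow_reflection)
    report.aligned = aligned
    payload["gpa"] = {
        "n": aligned.n, "k": aligned.k, "iterations": aligned.iterations,
        "converged": aligned.converged,
    }

    ms = pca(aligned)
    report.morphospace = ms
    payload["pca"] = {
        "variance_fraction": ms.variance_fraction.tolist(),
        "pc1_pc2_explained": variance_explained(ms, min(2, ms.m)),
    }

    if config.do_landscape:
        land = kde_landscape(ms.scores[:, :2])
        payload["landscape"] = {
            "bandwidth": list(land.bandwidth),
            "integral": land.integral(),
            "contour_levels": land.contour_levels.tolist(),
        }

    layout = phylomorphospace(tree, ms)
    report.layout = layout
    payload["phylomorphospace"] = {
        "n_points": int(layout.points.shape[0]),
        "n_edges": int(layout.edges.shape[0]),
    }

    if config.do_signal:
        k_res = cs.kmult(aligned, tree, n_perm=config.n_perm_signal,
                         seed=stage_seed())
        payload["phylogenetic_signal"] = k_res.to_dict()

    if config.groups is not None and config.do_disparity:
        disp = cs.disparity_test(aligned, config.groups,
                                 n_perm=config.n_perm_disparity,
                                 seed=stage_seed())
        payload["disparity"] = disp.to_dict()

    if config.groups is not None and config.do_rates:
        rates = cs.compare_evolutionary_rates(
            tree, aligned, config.groups, n_sims=config.n_sims_rates,
            seed=stage_seed())
        payload["rates"] = rates.to_dict()

    if config.do_models:
        payload["models"] = {}
        for pc in range(min(2, ms.m)):
            trait = dict(zip(ms.taxon_order, ms.scores[:, pc]))
            table = cs.fit_evolutionary_models(tree, trait)
            report.model_tables[f"PC{pc + 1}"] = table
            payload["models"][f"PC{pc + 1}"] = {
                m: {"lnL": f.log_likelihood, "k": f.k_params,
                    "AICc": f.aicc, "dAICc": f.daicc, **f.params}
                for m, f in table.fits.items()
            }

    if config.do_convergence and config.regions:
        payload["convergence"] = {}
        scores = {t: ms.scores_for([t])[0] for t in ms.taxon_order}
        for region in config.regions:
            res = conv.convergence_test(
                tree, scores,
                region=region if region.is_ellipse else None,
                focal=sorted(region.taxa) if not region.is_ellipse else None,
                n_sims=config.n_sims_convergence, seed=stage_seed())
            payload["convergence"][region.label] = res.to_dict()

    if config.out_dir is not None:
        _write_outputs(config, report, ms, aligned, layout)
    return report


def _write_outputs(config: RunConfig, report: AnalysisReport, ms, aligned,
                   layout) -> None:
    import pandas as pd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    ms.to_csv(out / "scores.csv")
    flat = aligned.flat()
    cols = [f"{ax}{i + 1}" for i in range(aligned.k) for ax in ("x", "y")]
    pd.DataFrame(flat, index=pd.Index(aligned.taxa, name="taxon"),
                 columns=cols).to_csv(out / "aligned.csv")
    pts, edges = layout.to_frames()
    pts.to_csv(out / "layout_points.csv", index=False)
    edges.to_csv(out / "layout_edges.csv", index=False)
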