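"""End-to-end orchestration: simulation (or user data) -> preprocessing ->
per-(method, task, seed) discovery -> relationship table, with provenance.

The study design analyses each thalamic seed against the basal-ganglia
partners separately (one 9-node discovery per seed), for each of the three
CI methods and both tasks; with three seeds that is 18 discovery runs.  The
orchestrator subsets the panel to {seed} + partners per run.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import build_relationship_table, nature_counts, records_to_frame
from .graphs import default_study_graphs
from .pcmci import DiscoveryConfig, discover
from .preprocess import preprocess
from .simulate import RoiPanel, ConfoundSeries, SubjectSpec, read_panel, simulate_panel

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "panel", "out_dir", "conditions", "methods", "seeds", "partners", "n_subjects",
    "blocks_per_condition", "block_length", "tr", "cutoff_hz", "smooth_halfwidth",
    "zscore", "mask_boundaries", "tau_max", "alpha", "n_permutations", "max_samples",
    "knn", "gp_optimize", "gp_restarts", "master_seed", "normalization", "log_level",
    "max_conds", "pc_alpha",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    ``panel`` may name a panel.json written by the simulate stage; when empty
    a study-shaped simulation (``n_subjects`` x ``blocks_per_condition``
    blocks per condition of ``block_length`` volumes) is generated from the
    default study graphs with the master seed.
    """

    out_dir: str = "run"
    panel: str | None = None
    conditions: list[str] = field(default_factory=lambda: ["resting", "motor"])
    methods: list[str] = field(default_factory=lambda: ["parcorr", "gpdc", "cmiknn"])
    seeds: list[str] = field(default_factory=lambda: ["Tal"])
    partners: list[str] | None = None  # None -> all other ROIs
    n_subjects: int = 20
    blocks_per_condition: int = 2
    block_length: int = 100
    tr: float = 1.6
    cutoff_hz: float = 0.009
    smooth_halfwidth: int = 5
    zscore: bool = False
    mask_boundaries: bool = False
    tau_max: int = 2
    alpha: float = 0.01
    pc_alpha: float | None = None
    max_conds: int | None = None
    n_permutations: int = 500
    max_samples: int | None = 1000
    knn: int | None = None
    gp_optimize: bool = True
    gp_restarts: int = 2
    master_seed: int = 0
    normalization: str = "max_abs"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


_METHOD_LABEL = {"parcorr": "PC", "gpdc": "GPDC", "cmiknn": "CMIknn"}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes per-run graph.json files, table.csv, summary.json and
    provenance.json (config echo, seeds, version, wall-clock).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if cfg.panel:
            panel, confounds = read_panel(cfg.panel)
        else:
            graphs = default_study_graphs(cfg.master_seed)
            subjects = [
                SubjectSpec(
                    f"sub-{i + 1:02d}", cfg.blocks_per_condition, cfg.block_length,
                    cfg.tr, tuple(cfg.conditions),
                    condition_graph_overrides=graphs,
                )
                for i in range(cfg.n_subjects)
            ]
            panel, confounds = simulate_panel(
                graphs[cfg.conditions[0]], subjects, seed=cfg.master_seed
            )
        stage = "preprocess"
        prepped = {
            cond: preprocess(
                panel, confounds, cond, cutoff_hz=cfg.cutoff_hz,
                smooth_halfwidth=cfg.smooth_halfwidth, zscore=cfg.zscore,
            )
            for cond in cfg.conditions
        }
        for cond, cp in prepped.items():
            logger.info("preprocess: condition=%s concatenated length=%d", cond, cp.n_total)

        stage = "discover"
        all_records = []
        graph_index = []
        for seed_roi in cfg.seeds:
            partners = cfg.partners or [r for r in panel.roi_labels if r != seed_roi]
            rois = [seed_roi] + [p for p in partners if p != seed_roi]
            graphs_by_key = {}
            for method in cfg.methods:
                for cond in cfg.conditions:
                    sub = prepped[cond]
                    idx = [sub.roi_labels.index(r) for r in rois]
                    view = copy.copy(sub)
                    view.matrix = sub.matrix[:, idx]
                    view.roi_labels = rois
                    dcfg = DiscoveryConfig(
                        tau_max=cfg.tau_max, alpha=cfg.alpha, ci_method=method,
                        pc_alpha=cfg.pc_alpha, max_conds=cfg.max_conds,
                        seed=cfg.master_seed, n_permutations=cfg.n_permutations,
                        max_samples=cfg.max_samples, knn=cfg.knn,
                        gp_optimize=cfg.gp_optimize, gp_restarts=cfg.gp_restarts,
                        mask_boundaries=cfg.mask_boundaries,
                    )
                    g = discover(view, dcfg)
                    fname = f"graph_{seed_roi}_{method}_{cond}.json"
                    g.save(out / fname)
                    graph_index.append(fname)
                    graphs_by_key[(_METHOD_LABEL[method], cond)] = g
                    logger.info(
                        "discover: seed=%s method=%s task=%s significant lagged=%d contemp=%d",
                        seed_roi, method, cond,
                        len(g.significant_lagged()), len(g.significant_contemp()),
                    )
            stage = "classify"
            all_records.extend(
                build_relationship_table(graphs_by_key, seed_roi, normalization=cfg.normalization)
            )

        table = records_to_frame(all_records)
        table.to_csv(out / "table.csv", index=False)
        summary = nature_counts(all_records)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "config": asdict(cfg),
                    "version": __version__,
                    "graphs": graph_index,
                    "wall_clock_s": round(time.time() - t0, 2),
                },
                indent=2,
                sort_keys=True,
            )
        )
        return out
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise


def classify_stored_graphs(run_dir: str | Path, normalization: str = "max_abs") -> pd.DataFrame:
    """Re-run classification on the graph.json files of a run directory;
    reproduces table.csv exactly (the run directory is self-describing)."""
    run = Path(run_dir)
    from .pcmci import TimeSeriesGraph

    by_seed: dict[str, dict] = {}
    for f in sorted(run.glob("graph_*.json")):
        _, seed_roi, method, cond = f.stem.split("_")
        by_seed.setdefault(seed_roi, {})[(_METHOD_LABEL[method], cond)] = TimeSeriesGraph.load(f)
    records = []
    for seed_roi, graphs in sorted(by_seed.items()):
        records.extend(build_relationship_table(graphs, seed_roi, normalization=normalization))
    return records_to_frame(records)
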