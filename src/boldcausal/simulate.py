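"""Seeded multi-subject ROI panel generator.

Emulates the structure of a block-design BOLD study: each subject contributes
``blocks_per_condition`` blocks of ``block_length`` volumes per condition at a
fixed repetition time, each block an independent realization of the process
defined by a :class:`~boldcausal.graphs.GroundTruthGraph` (with burn-in), plus
a shared low-frequency nuisance component (sinusoids below the high-pass
cutoff and a linear drift) standing in for respiration/cardiac/scanner
confounds.  The nuisance series is returned separately so the preprocessing
stage has a regressor, exactly as the study regressed white-matter/ventricle
signals.

Seeding is counter-based: one master seed is expanded per
(subject index, condition index, block index), so adding subjects to a study
never perturbs the data of earlier subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import GroundTruthGraph

BURN_IN = 50  # discarded start-up steps per block


@dataclass
class SubjectSpec:
    subject_id: str
    blocks_per_condition: int = 2
    block_length: int = 100
    tr: float = 1.6
    conditions: tuple[str, ...] = ("resting", "motor")
    condition_graph_overrides: dict[str, GroundTruthGraph] | None = None

    def __post_init__(self) -> None:
        if self.block_length < 20:
            raise ValueError("block_length must be >= 20")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")


@dataclass
class Block:
    subject_id: str
    condition: str
    block_index: int
    data: np.ndarray  # (block_length, N)


@dataclass
class RoiPanel:
    blocks: list[Block]
    roi_labels: list[str]
    tr: float

    def __post_init__(self) -> None:
        N = len(self.roi_labels)
        lengths = {b.data.shape[0] for b in self.blocks}
        if len(lengths) > 1:
            raise ValueError("block_length must be constant within a panel")
        for b in self.blocks:
            if b.data.shape[1] != N:
                raise ValueError("all blocks must share the ROI count")
            if not np.all(np.isfinite(b.data)):
                raise ValueError(f"non-finite values in block {b.subject_id}/{b.condition}/{b.block_index}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def block_length(self) -> int:
        return self.blocks[0].data.shape[0] if self.blocks else 0

    def keys(self) -> list[tuple[str, str, int]]:
        return [(b.subject_id, b.condition, b.block_index) for b in self.blocks]

    def subset(self, rois: list[str]) -> "RoiPanel":
        idx = [self.roi_labels.index(r) for r in rois]
        return RoiPanel(
            blocks=[Block(b.subject_id, b.condition, b.block_index, b.data[:, idx].copy()) for b in self.blocks],
            roi_labels=list(rois),
            tr=self.tr,
        )


@dataclass
class ConfoundSeries:
    """One nuisance vector per panel block, aligned one-to-one."""

    series: dict[tuple[str, str, int], np.ndarray] = field(default_factory=dict)

    def get(self, key: tuple[str, str, int]) -> np.ndarray:
        return self.series[key]


def _simulate_block(
    graph: GroundTruthGraph, length: int, rng: np.random.Generator
) -> np.ndarray:
    """One independent block realization (burn-in included then discarded)."""
    N = graph.n_nodes
    idx = {n: i for i, n in enumerate(graph.nodes)}
    order = [idx[n] for n in graph.contemporaneous_order()]
    sd = np.array([graph.noise_sd[n] for n in graph.nodes])
    phi = np.array([graph.autocorr[n] for n in graph.nodes])
    w_sd = sd * np.sqrt(1.0 - phi**2)

    by_target: list[list[tuple[int, int, str, float]]] = [[] for _ in range(N)]
    for ln in graph.links:
        by_target[idx[ln.target]].append((idx[ln.source], ln.lag, ln.form, ln.coefficient))

    T = BURN_IN + length
    X = np.zeros((T, N))
    e = np.zeros(N)
    z = rng.standard_normal((T, N))
    for t in range(T):
        e_new = np.empty(N)
        for jn in order:
            mu = 0.0
            scale = 1.0
            for (src, lag, form, c) in by_target[jn]:
                if lag > t:
                    continue
                v = X[t - lag, src]
                if form == "linear":
                    mu += c * v
                elif form == "quadratic":
                    mu += c * v * v
                else:  # multiplicative_noise
                    scale *= 1.0 + abs(c * v)
            w = w_sd[jn] * scale * z[t, jn]
            e_new[jn] = phi[jn] * e[jn] + w
            X[t, jn] = mu + e_new[jn]
        e = e_new
    return X[BURN_IN:]


def _confound(length: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Shared low-frequency nuisance: 3 sinusoids below 0.009 Hz + slow drift."""
    t = np.arange(length) * tr
    c = np.zeros(length)
    for _ in range(3):
        f = rng.uniform(0.002, 0.009)
        ph = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.7, 1.3)
        c += amp * np.sin(2 * np.pi * f * t + ph)
    slope = rng.uniform(-1.0, 1.0)
    c += slope * (t - t.mean()) / max(t[-1] - t[0], tr)
    return c


def simulate_panel(
    graph: GroundTruthGraph,
    subjects: list[SubjectSpec],
    seed: int,
    confound_strength: float = 1.0,
) -> tuple[RoiPanel, ConfoundSeries]:
    """Generate a multi-subject, multi-block ROI panel from a causal graph.

    Each block is generated independently per (subject, condition, block) with
    its own counter-derived RNG stream; a shared low-frequency confound is
    added to every ROI with random per-ROI loadings drawn from U(0.5, 1.5) and
    returned in a :class:`ConfoundSeries`.  Identical inputs give bit-identical
    output.
    """
    if seed is None:
        raise ValueError("an explicit seed is required (no implicit entropy)")
    if not subjects:
        raise ValueError("at least one SubjectSpec is required")
    tr = subjects[0].tr
    blocks: list[Block] = []
    confounds = ConfoundSeries()
    for si, sub in enumerate(subjects):
        if sub.tr != tr:
            raise ValueError("all subjects must share the repetition time")
        for ci, cond in enumerate(sub.conditions):
            g = graph
            if sub.condition_graph_overrides and cond in sub.condition_graph_overrides:
                g = sub.condition_graph_overrides[cond]
            if list(g.nodes) != list(graph.nodes):
                raise ValueError("condition override graphs must share node labels")
            for bi in range(sub.blocks_per_condition):
                rng = np.random.default_rng([int(seed), si, ci, bi])
                data = _simulate_block(g, sub.block_length, rng)
                c = _confound(sub.block_length, tr, rng)
                loadings = rng.uniform(0.5, 1.5, size=g.n_nodes)
                data = data + confound_strength * np.outer(c, loadings)
                blocks.append(Block(sub.subject_id, cond, bi, data))
                confounds.series[(sub.subject_id, cond, bi)] = c
    return RoiPanel(blocks=blocks, roi_labels=list(graph.nodes), tr=tr), confounds


def study_subjects(
    n_subjects: int = 20,
    blocks_per_condition: int = 2,
    block_length: int = 100,
    tr: float = 1.6,
    conditions: tuple[str, ...] = ("resting", "motor"),
) -> list[SubjectSpec]:
    """The study-shaped cohort: 20 subjects, 2 blocks/condition, 100 volumes at 1.6 s."""
    return [
        SubjectSpec(f"sub-{i + 1:02d}", blocks_per_condition, block_length, tr, conditions)
        for i in range(n_subjects)
    ]


# -- plain-text panel I/O --------------------------------------------------

def write_panel(panel: RoiPanel, confounds: ConfoundSeries | None, out_dir: str | Path) -> Path:
    """One TSV per block (header = ROI labels) plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"tr": panel.tr, "roi_labels": panel.roi_labels, "blocks": []}
    for b in panel.blocks:
        fname = f"{b.subject_id}_{b.condition}_block{b.block_index}.tsv"
        pd.DataFrame(b.data, columns=panel.roi_labels).to_csv(out / fname, sep="\t", index=False)
        entry = {
            "subject_id": b.subject_id,
            "condition": b.condition,
            "block_index": b.block_index,
            "file": fname,
        }
        if confounds is not None:
            cname = f"{b.subject_id}_{b.condition}_block{b.block_index}_confound.tsv"
            pd.DataFrame(
                {"confound": confounds.get((b.subject_id, b.condition, b.block_index))}
            ).to_csv(out / cname, sep="\t", index=False)
            entry["confound_file"] = cname
        sidecar["blocks"].append(entry)
    (out / "panel.json").write_text(json.dumps(sidecar, indent=2))
    return out / "panel.json"


def read_panel(panel_json: str | Path) -> tuple[RoiPanel, ConfoundSeries | None]:
    path = Path(panel_json)
    meta = json.loads(path.read_text())
    root = path.parent
    blocks, conf = [], ConfoundSeries()
    have_conf = False
    for entry in meta["blocks"]:
        df = pd.read_csv(root / entry["file"], sep="\t")
        blocks.append(
            Block(entry["subject_id"], entry["condition"], entry["block_index"], df.to_numpy(float))
        )
        if "confound_file" in entry:
            have_conf = True
            cdf = pd.read_csv(root / entry["confound_file"], sep="\t")
            conf.series[(entry["subject_id"], entry["condition"], entry["block_index"])] = (
                cdf["confound"].to_numpy(float)
            )
    panel = RoiPanel(blocks=blocks, roi_labels=list(meta["roi_labels"]), tr=float(meta["tr"]))
    return panel, (conf if have_conf else None)
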