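"""Collapse per-method discovery graphs into relationship records.

The reporting unit is the relationship between a thalamic seed ROI and a
partner ROI in one task, at one lag class, with one causal role:

* lag class — contemporaneous (lag 0), single-delayed (1 step, 1.6 s) or
  double-delayed (2 steps, 3.2 s);
* role — ``undefined`` (significant but undirected), ``causative`` (seed ->
  partner), ``response`` (partner -> seed), or ``interactive`` (a delayed
  dependence running in both directions);
* nature, by triangulation across the three detection methods: ``linear``
  if the partial-correlation method (PC) detected it, else ``non_linear`` if
  the GP/distance-correlation method (GPDC) did, else ``complex`` (only the
  kNN mutual-information method, CMIknn).

Accounting rules (fixed jointly with the packaged link transcription):
an ``interactive`` record requires a single method to evidence both
directions — opposite directions coming only from different methods stay
separate causative/response records; and an undirected relationship detected
by all three methods in both tasks is a task-invariant "permanent"
relationship, counted once with ``task='both'``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .pcmci import TimeSeriesGraph, UNDIRECTED, CONFLICT, DIRECTED_FWD, DIRECTED_BWD

METHOD_NAMES = ("PC", "GPDC", "CMIknn")
LAG_CLASSES = ("contemporaneous", "single_delayed", "double_delayed")
ROLES = ("undefined", "causative", "response", "interactive")
NATURES = ("linear", "non_linear", "complex")
LINK_KINDS = ("undirected", "causative", "response")


@dataclass(frozen=True)
class MethodLink:
    """One significant link as reported by one method: the unit of the
    printed per-method link lists."""

    seed: str
    partner: str
    task: str
    lag: int
    link: str  # undirected | causative (seed->partner) | response (partner->seed)
    method: str
    statistic: float | None = None
    statistic_normalized: float | None = None

    def __post_init__(self) -> None:
        if self.link not in LINK_KINDS:
            raise ValueError(f"unknown link kind {self.link!r}")
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class RelationshipRecord:
    seed: str
    partner: str
    task: str  # resting | motor | both (task-invariant permanent relationship)
    lag_class: str
    role: str
    nature: str
    methods_detecting: frozenset
    statistic_normalized: float | None = None


def lag_class(lag: int) -> str:
    """0 -> contemporaneous, 1 -> single_delayed (1.6 s), 2 -> double_delayed (3.2 s)."""
    if not 0 <= lag <= 2:
        raise ValueError(f"lag {lag} outside the 0..2 range of the analysis")
    return LAG_CLASSES[lag]


def assign_role(links: list[MethodLink]) -> str:
    """Role of a group of links sharing (seed, partner, task, lag class):
    undirected -> undefined; seed->partner -> causative; partner->seed ->
    response; delayed links in both directions -> interactive."""
    if not links:
        raise ValueError("empty link group")
    kinds = {ln.link for ln in links}
    if kinds == {"undirected"}:
        return "undefined"
    if "undirected" in kinds:
        raise ValueError("mixed undirected/directed group; split before assigning a role")
    if kinds == {"causative"}:
        return "causative"
    if kinds == {"response"}:
        return "response"
    return "interactive"


def assign_nature(methods_detecting) -> str:
    """Triangulation rule: PC -> linear; else GPDC -> non_linear; else complex."""
    methods = set(methods_detecting)
    if not methods:
        raise ValueError("empty method set")
    if not methods <= set(METHOD_NAMES):
        raise ValueError(f"unknown methods {methods - set(METHOD_NAMES)}")
    if "PC" in methods:
        return "linear"
    if "GPDC" in methods:
        return "non_linear"
    return "complex"


def normalize_statistics(links: list[MethodLink], scheme: str = "max_abs") -> list[MethodLink]:
    """Per-method statistic normalization into [0, 1].

    ``max_abs`` (default): |stat| / max |stat| over that method's significant
    links; ``minmax``: (|stat| - min) / (max - min); ``rank``: fractional rank
    of |stat|.  The sign is removed before scaling (partial correlations may
    be negative); links without a statistic pass through unchanged.
    """
    if scheme not in ("max_abs", "minmax", "rank"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    out = list(links)
    for method in METHOD_NAMES:
        idx = [k for k, ln in enumerate(out) if ln.method == method and ln.statistic is not None]
        if not idx:
            continue
        vals = [abs(out[k].statistic) for k in idx]
        top, bot = max(vals), min(vals)
        for k, v in zip(idx, vals):
            if scheme == "max_abs":
                z = v / top if top > 0 else 0.0
            elif scheme == "minmax":
                z = (v - bot) / (top - bot) if top > bot else 1.0
            else:
                z = (sorted(vals).index(v) + 1) / len(vals)
            out[k] = replace(out[k], statistic_normalized=z)
    return out


# -- collapse --------------------------------------------------------------

def _record(seed, partner, task, lc, role, links) -> RelationshipRecord:
    methods = frozenset(ln.method for ln in links)
    stats = [ln.statistic_normalized for ln in links if ln.statistic_normalized is not None]
    return RelationshipRecord(
        seed=seed, partner=partner, task=task, lag_class=lc, role=role,
        nature=assign_nature(methods), methods_detecting=methods,
        statistic_normalized=max(stats) if stats else None,
    )


def collapse_links(links: list[MethodLink]) -> list[RelationshipRecord]:
    """Collapse per-method links into relationship records.

    Grouping is per (seed, partner, task, lag class).  Undirected marks form
    an ``undefined`` record; directed marks form a single ``interactive``
    record when one method reports both directions (absorbing all directed
    contributors), otherwise one record per direction.  Undefined records
    found by all three methods in both tasks merge into one ``task='both'``
    permanent record.
    """
    groups: dict[tuple[str, str, str, str], list[MethodLink]] = {}
    for ln in links:
        key = (ln.seed, ln.partner, ln.task, lag_class(ln.lag))
        groups.setdefault(key, []).append(ln)

    records: list[RelationshipRecord] = []
    for (seed, partner, task, lc), grp in sorted(groups.items()):
        undirected = [ln for ln in grp if ln.link == "undirected"]
        directed = [ln for ln in grp if ln.link != "undirected"]
        if undirected:
            records.append(_record(seed, partner, task, lc, "undefined", undirected))
        if directed:
            per_method_kinds: dict[str, set] = {}
            for ln in directed:
                per_method_kinds.setdefault(ln.method, set()).add(ln.link)
            if any(kinds == {"causative", "response"} for kinds in per_method_kinds.values()):
                records.append(_record(seed, partner, task, lc, "interactive", directed))
            else:
                for kind in ("causative", "response"):
                    sub = [ln for ln in directed if ln.link == kind]
                    if sub:
                        records.append(_record(seed, partner, task, lc, assign_role(sub), sub))

    # permanent merge: undefined, all three methods, both tasks
    tasks = sorted({r.task for r in records})
    merged: list[RelationshipRecord] = []
    if len(tasks) == 2:
        by_key: dict[tuple[str, str, str], dict[str, RelationshipRecord]] = {}
        for r in records:
            if r.role == "undefined":
                by_key.setdefault((r.seed, r.partner, r.lag_class), {})[r.task] = r
        drop = set()
        for key, per_task in by_key.items():
            if len(per_task) == 2 and all(
                r.methods_detecting == frozenset(METHOD_NAMES) for r in per_task.values()
            ):
                a, b = (per_task[t] for t in tasks)
                stats = [s for s in (a.statistic_normalized, b.statistic_normalized) if s is not None]
                merged.append(replace(a, task="both", statistic_normalized=max(stats) if stats else None))
                drop.add((key, tasks[0]))
                drop.add((key, tasks[1]))
        records = [
            r for r in records
            if not (r.role == "undefined" and ((r.seed, r.partner, r.lag_class), r.task) in drop)
        ]
    return sorted(records + merged, key=lambda r: (r.seed, r.partner, r.task, r.lag_class, r.role))


def nature_counts(records: list[RelationshipRecord]) -> dict:
    counts = {n: sum(1 for r in records if r.nature == n) for n in NATURES}
    total = len(records)
    nl = counts["non_linear"] + counts["complex"]
    return {
        "total": total,
        **counts,
        "non_linear_or_complex": nl,
        "non_linear_fraction": nl / total if total else 0.0,
    }


# -- extraction from discovery graphs --------------------------------------

def links_from_graph(
    graph: TimeSeriesGraph, seed: str, task: str, method: str
) -> list[MethodLink]:
    """Significant links incident to the seed node, as MethodLink rows."""
    if seed not in graph.nodes:
        raise ValueError(f"seed {seed!r} not among graph nodes")
    s = graph.nodes.index(seed)
    out: list[MethodLink] = []
    for (i, j, lag), v in sorted(graph.lagged.items()):
        if not v.significant or s not in (i, j) or i == j:
            continue
        kind = "causative" if i == s else "response"
        partner = graph.nodes[j if i == s else i]
        out.append(MethodLink(seed, partner, task, lag, kind, method, v.statistic))
    for (i, j), v in sorted(graph.contemp.items()):
        if not v.significant or s not in (i, j):
            continue
        partner = graph.nodes[j if i == s else i]
        if v.mark in (UNDIRECTED, CONFLICT):
            kind = "undirected"
        elif (v.mark == DIRECTED_FWD and i == s) or (v.mark == DIRECTED_BWD and j == s):
            kind = "causative"
        else:
            kind = "response"
        out.append(MethodLink(seed, partner, task, 0, kind, method, v.statistic))
    return out


def build_relationship_table(
    graphs: dict[tuple[str, str], TimeSeriesGraph],
    seed: str,
    normalization: str = "max_abs",
) -> list[RelationshipRecord]:
    """Records for one seed ROI from a (method, task) -> graph map."""
    labels = None
    links: list[MethodLink] = []
    for (method, task), g in sorted(graphs.items()):
        if labels is None:
            labels = list(g.nodes)
        elif list(g.nodes) != labels:
            raise ValueError("node labels differ across method graphs")
        links.extend(links_from_graph(g, seed, task, method))
    return collapse_links(normalize_statistics(links, scheme=normalization))


# -- packaged transcription of the printed link lists ----------------------

def load_link_table(path: str | Path | None = None) -> list[MethodLink]:
    """The packaged machine-readable transcription of the per-method
    significant-link lists printed in the study (three thalamic seeds x two
    tasks x three methods), or any CSV in the same layout."""
    if path is None:
        src = resources.files("boldcausal").joinpath("data/table2_links.csv")
        df = pd.read_csv(src)  # type: ignore[arg-type]
    else:
        df = pd.read_csv(path)
    needed = {"seed", "partner", "task", "lag", "link", "method"}
    if not needed <= set(df.columns):
        raise ValueError(f"link table missing columns {needed - set(df.columns)}")
    out = []
    for row in df.itertuples(index=False):
        stat = getattr(row, "statistic", None)
        out.append(
            MethodLink(
                seed=row.seed, partner=row.partner, task=row.task, lag=int(row.lag),
                link=row.link, method=row.method,
                statistic=None if stat is None or pd.isna(stat) else float(stat),
            )
        )
    return out


def records_to_frame(records: list[RelationshipRecord]) -> pd.DataFrame:
    """Tabular view: role marks follow the printed convention — ``*`` when the
    seed is the causative center, ``<`` when it is the response, ``*<`` for
    interactive, blank for undefined."""
    mark = {"undefined": "", "causative": "*", "response": "<", "interactive": "*<"}
    return pd.DataFrame(
        [
            dict(
                seed=r.seed, partner=r.partner, task=r.task, lag_class=r.lag_class,
                role=r.role, role_mark=mark[r.role], nature=r.nature,
                methods="+".join(m for m in METHOD_NAMES if m in r.methods_detecting),
                statistic_normalized=r.statistic_normalized,
            )
            for r in records
        ]
    )
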