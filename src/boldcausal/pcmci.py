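"""PCMCI+-style causal discovery for multivariate ROI series.

Two-step structure: a PC-style condition-selection phase run separately for
lagged and contemporaneous candidate pools (iterative conditional-independence
tests against the strongest surviving candidates), followed by momentary
conditional independence (MCI) tests that condition each ordered pair on the
selected parents of both variables.  Lagged links are oriented by time order
(causes precede effects); contemporaneous links are oriented by a collider
phase on unshielded triples and a Meek-style rule phase, with contradictory
demands preserved as conflict marks rather than resolved silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .citests import CITestSpec, CITestResult, ci_test
from .preprocess import ConcatenatedPanel

# contemporaneous edge marks (stored once per unordered pair, i < j)
UNDIRECTED = "o-o"
DIRECTED_FWD = "-->"  # i --> j
DIRECTED_BWD = "<--"  # i <-- j
CONFLICT = "x-x"


@dataclass
class DiscoveryConfig:
    tau_max: int = 2
    alpha: float = 0.01
    ci_method: str = "parcorr"
    pc_alpha: float | None = None  # selection-phase level; defaults to alpha
    max_conds: int | None = None
    seed: int = 0
    n_permutations: int = 500
    block_length: int | None = None
    max_samples: int | None = 1000
    knn: int | None = None
    gp_optimize: bool = True
    gp_restarts: int = 2
    mask_boundaries: bool = False
    early_stop: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")

    @property
    def selection_alpha(self) -> float:
        return self.alpha if self.pc_alpha is None else self.pc_alpha


@dataclass
class LinkResult:
    statistic: float
    p_value: float
    conds: tuple[tuple[int, int], ...]
    significant: bool
    mark: str = ""  # contemporaneous links only


@dataclass
class ParentSets:
    """Selected candidate parents per target plus the separating sets recorded
    when candidates were removed (used by the collider phase)."""

    lagged: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    contemp: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    sepsets: dict[tuple[tuple[int, int], int], tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )

    def all_parents(self, j: int) -> list[tuple[int, int]]:
        return list(self.lagged.get(j, [])) + list(self.contemp.get(j, []))


@dataclass
class TimeSeriesGraph:
    """Discovery output: per (ordered pair, lag) statistic, p-value, mark.

    Lagged entries are keyed ``(i, j, lag)`` meaning ``i`` at ``t - lag``
    tested against ``j`` at ``t`` (significant entries are directed
    past -> present).  Contemporaneous entries are keyed ``(i, j)`` with
    ``i < j`` and carry a mark in {o-o, -->, <--, x-x}.
    """

    nodes: list[str]
    tau_max: int
    lagged: dict[tuple[int, int, int], LinkResult] = field(default_factory=dict)
    contemp: dict[tuple[int, int], LinkResult] = field(default_factory=dict)
    config: dict | None = None

    # -- queries -----------------------------------------------------------

    def significant_lagged(self) -> list[tuple[int, int, int]]:
        return [k for k, v in self.lagged.items() if v.significant]

    def significant_contemp(self) -> list[tuple[int, int]]:
        return [k for k, v in self.contemp.items() if v.significant]

    def contemp_mark(self, i: int, j: int) -> str:
        a, b = min(i, j), max(i, j)
        v = self.contemp.get((a, b))
        if v is None or not v.significant:
            return "absent"
        return v.mark

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "tau_max": self.tau_max,
            "lagged": [
                {"i": i, "j": j, "lag": lag, **asdict(v)}
                for (i, j, lag), v in sorted(self.lagged.items())
            ],
            "contemp": [
                {"i": i, "j": j, **asdict(v)} for (i, j), v in sorted(self.contemp.items())
            ],
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TimeSeriesGraph":
        g = cls(nodes=list(d["nodes"]), tau_max=int(d["tau_max"]), config=d.get("config"))
        for e in d["lagged"]:
            g.lagged[(e["i"], e["j"], e["lag"])] = LinkResult(
                e["statistic"], e["p_value"], tuple(map(tuple, e["conds"])), e["significant"], e["mark"]
            )
        for e in d["contemp"]:
            g.contemp[(e["i"], e["j"])] = LinkResult(
                e["statistic"], e["p_value"], tuple(map(tuple, e["conds"])), e["significant"], e["mark"]
            )
        return g

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TimeSeriesGraph":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def edge_list(self) -> pd.DataFrame:
        """One row per non-absent link."""
        rows = []
        for (i, j, lag), v in sorted(self.lagged.items()):
            if v.significant:
                rows.append(
                    dict(source=self.nodes[i], target=self.nodes[j], lag=lag,
                         mark="-->", statistic=v.statistic, p_value=v.p_value)
                )
        for (i, j), v in sorted(self.contemp.items()):
            if v.significant:
                rows.append(
                    dict(source=self.nodes[i], target=self.nodes[j], lag=0,
                         mark=v.mark, statistic=v.statistic, p_value=v.p_value)
                )
        return pd.DataFrame(rows, columns=["source", "target", "lag", "mark", "statistic", "p_value"])


# -- CI-test runner --------------------------------------------------------

def _conds_key(conds) -> int:
    h = 0
    for (k, l) in sorted(conds):
        h = (h * 1000003 + k * 131 + l) % (2**31 - 1)
    return h


class _Runner:
    """Binds data + config; derives a stable per-test seed so reruns (and
    reorderings of the test schedule) are bit-reproducible."""

    def __init__(self, data: ConcatenatedPanel | np.ndarray, cfg: DiscoveryConfig):
        self.data = data
        self.cfg = cfg
        self.n_tests = 0
        self._memo: dict = {}

    def test(self, i: int, lag: int, j: int, conds) -> CITestResult:
        cfg = self.cfg
        key = (i, lag, j, tuple(sorted(conds)))
        if key in self._memo:
            return self._memo[key]
        seed = int(
            np.random.SeedSequence(
                [cfg.seed, i, lag, j, _conds_key(conds)]
            ).generate_state(1)[0] % (2**31 - 1)
        )
        spec = CITestSpec(
            i=i, j=j, lag=lag, Z=list(conds), method=cfg.ci_method, alpha=cfg.alpha,
            n_permutations=cfg.n_permutations, block_length=cfg.block_length, seed=seed,
            tau_max=None, max_samples=cfg.max_samples, knn=cfg.knn,
            gp_optimize=cfg.gp_optimize, gp_restarts=cfg.gp_restarts,
            mask_boundaries=cfg.mask_boundaries, early_stop=cfg.early_stop,
        )
        self.n_tests += 1
        res = ci_test(self.data, spec)
        self._memo[key] = res
        return res


def _n_nodes(data: ConcatenatedPanel | np.ndarray) -> int:
    return data.matrix.shape[1] if isinstance(data, ConcatenatedPanel) else np.asarray(data).shape[1]


def _node_labels(data: ConcatenatedPanel | np.ndarray) -> list[str]:
    if isinstance(data, ConcatenatedPanel):
        return list(data.roi_labels)
    return [f"X{i}" for i in range(_n_nodes(data))]


# -- step 1: condition selection ------------------------------------------

def select_conditions(
    data: ConcatenatedPanel | np.ndarray, cfg: DiscoveryConfig,
    runner: _Runner | None = None,
) -> ParentSets:
    """PC-style iterative removal, run separately on the lagged and the
    contemporaneous candidate pool of every target.

    At iteration q each surviving candidate is tested conditioned on the q
    strongest other surviving candidates (by |statistic| of the latest test,
    ties broken by (node index, lag)); candidates with p > pc_alpha are
    removed and their conditioning set recorded as the separating set.
    """
    N = _n_nodes(data)
    runner = runner or _Runner(data, cfg)
    out = ParentSets()
    for j in range(N):
        pools = {
            "lagged": [(i, lag) for lag in range(1, cfg.tau_max + 1) for i in range(N)],
            "contemp": [(i, 0) for i in range(N) if i != j],
        }
        for name, pool in pools.items():
            surviving = list(pool)
            stats: dict[tuple[int, int], float] = {}
            q = 0
            while surviving:
                if q > 0 and q > len(surviving) - 1:
                    break
                removed = []
                new_stats: dict[tuple[int, int], float] = {}
                for cand in list(surviving):
                    others = [c for c in surviving if c != cand]
                    others.sort(key=lambda c: (-abs(stats.get(c, 0.0)), c[0], c[1]))
                    conds = others[:q]
                    if cfg.max_conds is not None:
                        conds = conds[: cfg.max_conds]
                    res = runner.test(cand[0], cand[1], j, conds)
                    new_stats[cand] = res.statistic
                    if res.p_value > cfg.selection_alpha:
                        removed.append(cand)
                        out.sepsets[(cand, j)] = tuple(conds)
                stats.update(new_stats)
                surviving = [c for c in surviving if c not in removed]
                q += 1
                if cfg.max_conds is not None and q > cfg.max_conds:
                    break
            surviving.sort(key=lambda c: (-abs(stats.get(c, 0.0)), c[0], c[1]))
            getattr(out, name)[j] = surviving
    return out


# -- step 2: MCI tests -----------------------------------------------------

def _shifted_parents(parents: list[tuple[int, int]], shift: int) -> list[tuple[int, int]]:
    return [(k, l + shift) for (k, l) in parents]


def mci_tests(
    data: ConcatenatedPanel | np.ndarray, parents: ParentSets, cfg: DiscoveryConfig,
    runner: _Runner | None = None,
) -> TimeSeriesGraph:
    """Momentary conditional independence: each ordered pair (i at t - lag,
    j at t) is tested given parents(j) \\ {(i, lag)} plus the lag-shifted
    parents of i.  Lagged links with p <= alpha are directed past -> present;
    contemporaneous links enter as undirected pending orientation."""
    N = _n_nodes(data)
    runner = runner or _Runner(data, cfg)
    graph = TimeSeriesGraph(nodes=_node_labels(data), tau_max=cfg.tau_max,
                            config=asdict(cfg))
    cap = cfg.max_conds
    for j in range(N):
        pj = parents.all_parents(j)
        for lag in range(1, cfg.tau_max + 1):
            for i in range(N):
                # Lagged links are tested twice: conditioning on lagged
                # parents only, and additionally on contemporaneous parents.
                # Present-time conditions can open collider paths (they may
                # be children of the effect) while omitting them leaves
                # contemporaneous chains unblocked; a genuine link must stay
                # dependent either way, so the larger p-value is kept.
                lagged_j = [c for c in parents.lagged.get(j, []) if c != (i, lag)]
                shifted = [c for c in _shifted_parents(parents.lagged.get(i, []), lag)
                           if c != (j, 0) and c not in lagged_j and c != (i, lag)]
                contemp_j = [c for c in parents.contemp.get(j, [])
                             if c != (i, lag) and c not in lagged_j + shifted]
                if cap is not None:
                    lagged_j, shifted = lagged_j[:cap], shifted[:cap]
                    contemp_j = contemp_j[:cap]
                res_a = runner.test(i, lag, j, lagged_j + shifted)
                res_b = runner.test(i, lag, j, lagged_j + shifted + contemp_j)
                res, used = (
                    (res_a, lagged_j + shifted)
                    if res_a.p_value >= res_b.p_value
                    else (res_b, lagged_j + shifted + contemp_j)
                )
                graph.lagged[(i, j, lag)] = LinkResult(
                    res.statistic, res.p_value, tuple(used),
                    res.p_value <= cfg.alpha, mark="-->",
                )
    for i in range(N):
        for j in range(i + 1, N):
            conds = [c for c in parents.all_parents(j) if c != (i, 0)]
            conds += [c for c in parents.all_parents(i) if c != (j, 0) and c not in conds]
            if cap is not None:
                conds = conds[: 2 * cap]
            res = runner.test(i, 0, j, conds)
            graph.contemp[(i, j)] = LinkResult(
                res.statistic, res.p_value, tuple(conds),
                res.p_value <= cfg.alpha, mark=UNDIRECTED,
            )
    return graph


# -- step 3: contemporaneous orientation ----------------------------------

def _demand(marks: dict, a: int, b: int, head: int, conflicts: set) -> None:
    """Request an arrowhead at ``head`` on the contemporaneous edge {a, b}."""
    i, j = min(a, b), max(a, b)
    want = DIRECTED_FWD if head == j else DIRECTED_BWD
    cur = marks.get((i, j))
    if cur is None or cur == UNDIRECTED:
        marks[(i, j)] = want
    elif cur != want:
        marks[(i, j)] = CONFLICT
        conflicts.add((i, j))


def orient_contemporaneous(
    graph: TimeSeriesGraph,
    data: ConcatenatedPanel | np.ndarray,
    parents: ParentSets,
    cfg: DiscoveryConfig,
    runner: _Runner | None = None,
) -> TimeSeriesGraph:
    """Collider phase on unshielded triples, then Meek-style propagation.

    Unshielded triples are (i, t - tau) -> k o-o j (tau > 0) and
    i o-o k o-o j (tau = 0) with the outer pair non-adjacent; the middle edge
    is oriented into k when k is absent from the separating set of the outer
    pair.  Unresolved marks stay undirected; contradictions become conflicts.
    """
    adj0 = {n: set() for n in range(len(graph.nodes))}
    for (i, j) in graph.significant_contemp():
        adj0[i].add(j)
        adj0[j].add(i)
    marks: dict[tuple[int, int], str] = {
        k: v.mark for k, v in graph.contemp.items() if v.significant
    }
    conflicts: set[tuple[int, int]] = set()

    sig_lagged = set(graph.significant_lagged())
    runner = runner or _Runner(data, cfg)
    # collider phase, lagged triples: (i, tau) -> k o-o j, (i, tau) -/-> j.
    # The lagged selection pool cannot contain lag-0 conditions, so k's
    # membership in the recorded separating set is uninformative; instead the
    # outer pair is re-tested with (k, 0) added — dependence appearing under
    # that extra condition identifies k as a collider.
    for (i, k, tau) in sorted(sig_lagged):
        for j in sorted(adj0[k]):
            if j == i or (i, j, tau) in sig_lagged:
                continue
            base = parents.sepsets.get(((i, tau), j))
            if base is None:
                base = tuple(c for c in graph.lagged[(i, j, tau)].conds if c != (k, 0))
            probe = runner.test(i, tau, j, list(base) + [(k, 0)])
            if probe.p_value <= cfg.alpha:
                _demand(marks, k, j, head=k, conflicts=conflicts)
    # collider phase, contemporaneous triples: i o-o k o-o j, i -/- j
    N = len(graph.nodes)
    for k in range(N):
        nbrs = sorted(adj0[k])
        for ai in range(len(nbrs)):
            for bi in range(ai + 1, len(nbrs)):
                i, j = nbrs[ai], nbrs[bi]
                if j in adj0[i]:
                    continue
                sep = parents.sepsets.get(((i, 0), j), parents.sepsets.get(((j, 0), i)))
                if sep is None:
                    continue
                if (k, 0) not in sep:
                    _demand(marks, i, k, head=k, conflicts=conflicts)
                    _demand(marks, j, k, head=k, conflicts=conflicts)

    # rule phase: Meek propagation, avoiding new colliders and cycles
    def directed(a: int, b: int) -> bool:
        i, j = min(a, b), max(a, b)
        m = marks.get((i, j))
        return (m == DIRECTED_FWD and (a, b) == (i, j)) or (m == DIRECTED_BWD and (a, b) == (j, i))

    def undirected(a: int, b: int) -> bool:
        return marks.get((min(a, b), max(a, b))) == UNDIRECTED

    changed = True
    while changed:
        changed = False
        snapshot = dict(marks)
        for (i, j), m in sorted(snapshot.items()):
            if m != UNDIRECTED:
                continue
            for (a, b) in ((i, j), (j, i)):
                # R1: c -> a, a o-o b, c and b non-adjacent  =>  a -> b
                for c in range(N):
                    if c not in (a, b) and directed(c, a) and b not in adj0[c] and undirected(a, b):
                        _demand(marks, a, b, head=b, conflicts=conflicts)
                        changed = True
                # R2: a -> c -> b and a o-o b  =>  a -> b
                for c in range(N):
                    if c not in (a, b) and directed(a, c) and directed(c, b) and undirected(a, b):
                        _demand(marks, a, b, head=b, conflicts=conflicts)
                        changed = True

    for (i, j), m in marks.items():
        graph.contemp[(i, j)].mark = m
    return graph


def discover(
    data: ConcatenatedPanel | np.ndarray, cfg: DiscoveryConfig
) -> TimeSeriesGraph:
    """Full pipeline: select_conditions -> mci_tests -> orient_contemporaneous."""
    runner = _Runner(data, cfg)
    parents = select_conditions(data, cfg, runner)
    graph = mci_tests(data, parents, cfg, runner)
    graph = orient_contemporaneous(graph, data, parents, cfg, runner)
    graph.config = asdict(cfg)
    return graph
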