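"""Independent oracles for validating discovery output.

* :func:`var_stationary_cov` (re-exported from ``graphs``) gives closed-form
  cross-covariances of linear generative graphs via the companion-form
  Lyapunov equation; partial correlations follow from the precision matrix.
* :func:`unrolled_dag` expands a ground-truth graph into a finite
  time-unrolled DAG so conditional-independence truth can be read off with
  networkx d-separation (brute force, no estimation).

These utilities never touch the estimation path; they exist so tests can
compare discovered structure against what the generative model implies.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .graphs import GroundTruthGraph, var_stationary_cov  # noqa: F401


def partial_correlation_from_cov(cov: np.ndarray, a: int, b: int, given: list[int]) -> float:
    """Closed-form partial correlation from a covariance matrix via the
    precision matrix of the (a, b, given) sub-block."""
    idx = [a, b] + list(given)
    sub = cov[np.ix_(idx, idx)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def lagged_cov_matrix(
    graph: GroundTruthGraph, pairs: list[tuple[int, int]], max_lag: int | None = None
) -> np.ndarray:
    """Stationary covariance matrix of a list of (node, lag) columns of a
    linear generative graph.  ``cov[(a, la), (b, lb)] = G_{lb - la}[a, b]``."""
    lags = [l for (_, l) in pairs]
    top = max(lags) if max_lag is None else max(max_lag, max(lags))
    G = var_stationary_cov(graph, max_lag=top)
    m = len(pairs)
    out = np.empty((m, m))
    for x, (a, la) in enumerate(pairs):
        for y, (b, lb) in enumerate(pairs):
            h = lb - la  # cov(x_a(t - la), x_b(t - lb))
            out[x, y] = G[h][a, b] if h >= 0 else G[-h][b, a]
    return out


def unrolled_dag(graph: GroundTruthGraph, n_steps: int) -> nx.DiGraph:
    """Time-unrolled DAG over (node, t) for t in 0..n_steps-1.

    Nodes with non-zero innovation autocorrelation get an explicit latent
    innovation chain e(t) -> e(t+1) with e(t) -> x(t), since smoothing the
    innovations couples consecutive observations without a direct x -> x
    edge; d-separation must see that path.
    """
    g = nx.DiGraph()
    for t in range(n_steps):
        for n in graph.nodes:
            g.add_node((n, t))
    for t in range(n_steps):
        for ln in graph.links:
            if t - ln.lag >= 0:
                g.add_edge((ln.source, t - ln.lag), (ln.target, t))
        for n in graph.nodes:
            if graph.autocorr[n] > 0:
                g.add_node(("_e_" + n, t))
                g.add_edge(("_e_" + n, t), (n, t))
                if t > 0:
                    g.add_edge(("_e_" + n, t - 1), ("_e_" + n, t))
    return g


def dsep_independent(
    graph: GroundTruthGraph,
    i: str,
    lag: int,
    j: str,
    conds: list[tuple[str, int]],
    window: int | None = None,
) -> bool:
    """True when x_i(t - lag) is d-separated from x_j(t) given the listed
    (node, lag) conditions, on a sufficiently deep unrolled DAG."""
    depth = window if window is not None else 6 * (graph.max_lag + 1)
    g = unrolled_dag(graph, depth)
    t = depth - 1
    x = {(i, t - lag)}
    y = {(j, t)}
    z = {(k, t - l) for (k, l) in conds} - x - y
    return nx.is_d_separator(g, x, y, z)


def true_parents(graph: GroundTruthGraph) -> dict[str, list[tuple[str, int]]]:
    """Direct structural parents (node, lag) per target, from the graph."""
    out: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
    for ln in graph.links:
        out[ln.target].append((ln.source, ln.lag))
    for n in graph.nodes:
        if graph.autocorr[n] > 0:
            out[n].append((n, 1))  # innovation smoothing acts like a self-link
    return out


def expected_mci_links(graph: GroundTruthGraph, tau_max: int) -> set[tuple[str, str, int]]:
    """Brute-force d-separation truth table under MCI-style conditioning:
    the links (i, j, lag) whose pair stays dependent given parents(j) minus
    the tested link plus the lag-shifted parents(i)."""
    parents = true_parents(graph)
    links: set[tuple[str, str, int]] = set()
    for j in graph.nodes:
        for lag in range(0, tau_max + 1):
            for i in graph.nodes:
                if i == j and lag == 0:
                    continue
                conds = [(k, l) for (k, l) in parents[j] if (k, l) != (i, lag)]
                conds += [(k, l + lag) for (k, l) in parents[i] if (k, l + lag) != (j, 0)]
                if not dsep_independent(graph, i, lag, j, conds):
                    links.add((i, j, lag))
    return links


def recovery_scores(
    truth: set[tuple[str, str, int]], found: set[tuple[str, str, int]], all_pairs: set
) -> dict:
    """Adjacency-level true/false positive rates against a ground-truth set.

    Contemporaneous entries are compared as unordered pairs; lagged entries
    as ordered (source, target, lag) triples.
    """

    def canon(s):
        return {(min(a, b), max(a, b), 0) if lag == 0 else (a, b, lag) for (a, b, lag) in s}

    t, f, univ = canon(truth), canon(found), canon(all_pairs)
    tp = len(t & f)
    fp = len(f - t)
    negatives = len(univ - t)
    return {
        "tpr": tp / len(t) if t else 1.0,
        "fpr": fp / negatives if negatives else 0.0,
        "tp": tp,
        "fp": fp,
        "n_true": len(t),
        "n_negative": negatives,
    }
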