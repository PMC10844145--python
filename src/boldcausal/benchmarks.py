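"""Seeded benchmark harnesses: graph recovery scoring, CI-test size
calibration, power/sensitivity ordering, and nature-triangulation runs.

These wrap the library's own estimation path against independent ground truth
(generative graphs, closed-form nulls); every harness takes an explicit seed
and fixed problem sizes so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .citests import CITestSpec, ci_test
from .graphs import GroundTruthGraph, linear_benchmark_graph
from .oracle import recovery_scores
from .pcmci import DiscoveryConfig, TimeSeriesGraph, discover
from .simulate import SubjectSpec, simulate_panel


def single_block_panel(
    graph: GroundTruthGraph, n: int, seed: int
) -> np.ndarray:
    """One long confound-free block from a graph (matrix n x N)."""
    panel, _ = simulate_panel(
        graph, [SubjectSpec("s1", 1, n, 1.6, ("resting",))], seed=seed,
        confound_strength=0.0,
    )
    return panel.blocks[0].data


def found_links(graph: TimeSeriesGraph, nodes: list[str]) -> set[tuple[str, str, int]]:
    out = {(nodes[i], nodes[j], lag) for (i, j, lag) in graph.significant_lagged()}
    out |= {(nodes[i], nodes[j], 0) for (i, j) in graph.significant_contemp()}
    return out


def run_recovery(
    n_seeds: int = 20,
    n: int = 4000,
    seed: int = 0,
    n_permutations: int = 199,
) -> dict:
    """PCMCI+/parcorr adjacency recovery on the 9-node linear benchmark.

    Returns mean true-positive and false-positive rates over ``n_seeds``
    independent panels of length ``n``.
    """
    g = linear_benchmark_graph(seed)
    nodes = g.nodes
    truth = {(ln.source, ln.target, ln.lag) for ln in g.links}
    universe = {
        (a, b, lag) for a in nodes for b in nodes for lag in (0, 1, 2)
        if not (a == b and lag == 0)
    }
    tprs, fprs = [], []
    for r in range(n_seeds):
        X = single_block_panel(g, n, seed=seed * 1000 + r)
        cfg = DiscoveryConfig(
            tau_max=2, alpha=0.01, ci_method="parcorr",
            seed=seed * 1000 + r, n_permutations=n_permutations,
        )
        graph = discover(X, cfg)
        sc = recovery_scores(truth, found_links(graph, nodes), universe)
        tprs.append(sc["tpr"])
        fprs.append(sc["fpr"])
    return {
        "tpr": float(np.mean(tprs)),
        "fpr": float(np.mean(fprs)),
        "tpr_per_seed": tprs,
        "fpr_per_seed": fprs,
    }


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n + 50)
    x = np.empty(n + 50)
    x[0] = e[0]
    for t in range(1, n + 50):
        x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * e[t]
    return x[50:]


def run_size_calibration(
    method: str,
    n_reps: int = 500,
    n: int = 400,
    phi: float = 0.8,
    alpha: float = 0.01,
    seed: int = 0,
    n_permutations: int = 199,
    max_samples: int = 500,
) -> dict:
    """Empirical size of one CI test on independent AR(1) pairs.

    Each replicate draws two independent autocorrelated series and runs the
    unconditional lag-0 test; returns the rejection rate at ``alpha``.
    """
    rej = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed, 0xCA11B, r])
        data = np.column_stack([_ar1(n, phi, rng), _ar1(n, phi, rng)])
        spec = CITestSpec(
            i=0, j=1, lag=0, Z=[], method=method, alpha=alpha,
            n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1)),
            max_samples=max_samples,
        )
        rej += ci_test(data, spec).p_value <= alpha
    return {"size": rej / n_reps, "n_reps": n_reps, "n": n, "phi": phi}


def run_power(
    method: str,
    form: str,
    n_reps: int = 200,
    n: int = 500,
    coefficient: float | None = None,
    alpha: float = 0.01,
    seed: int = 0,
    n_permutations: int = 199,
) -> float:
    """Detection power of the unconditional lag-1 test on a single causal
    link of the given functional form (coefficient defaults chosen so power
    is interior at n = 500, making the sensitivity ordering observable)."""
    coeff = coefficient if coefficient is not None else {
        "linear": 0.17, "quadratic": 0.35, "multiplicative_noise": 1.0,
    }[form]
    g = GroundTruthGraph(
        nodes=["X", "Y"],
        links=[("X", "Y", 1, form, coeff)],
        noise_sd=1.0, autocorr=0.0,
    )
    rej = 0
    for r in range(n_reps):
        X = single_block_panel(g, n, seed=seed * 10000 + 31 * r + 7)
        spec = CITestSpec(
            i=0, j=1, lag=1, Z=[], method=method, alpha=alpha,
            n_permutations=n_permutations, seed=seed * 10000 + 31 * r + 11,
            max_samples=n,
        )
        rej += ci_test(X, spec).p_value <= alpha
    return rej / n_reps


# -- nature triangulation ---------------------------------------------------

TRI_NODES = list("ABCDEF")
TRI_LINKS = [
    ("A", "B", 1, "linear", 0.4),
    ("C", "D", 1, "quadratic", 0.45),
    ("E", "F", 1, "multiplicative_noise", 1.0),
]


def triangulation_graph() -> GroundTruthGraph:
    """Mixed-form 6-node graph: one cross link per functional form plus
    linear self-links standing in for autocorrelation."""
    links = list(TRI_LINKS) + [(n, n, 1, "linear", 0.4) for n in TRI_NODES]
    return GroundTruthGraph(nodes=list(TRI_NODES), links=links, noise_sd=1.0, autocorr=0.0)


_EXPECTED_NATURE = {"linear": "linear", "quadratic": "non_linear",
                    "multiplicative_noise": "complex"}


@dataclass
class TriangulationResult:
    match_rate: float
    per_link: dict
    n_seeds: int


def run_triangulation(n_seeds: int = 20, n: int = 4000, seed: int = 0) -> TriangulationResult:
    """Run all three discovery methods on mixed-form panels and check that
    the triangulated nature label of each true link matches its generative
    form (linear <-> PC-detected, quadratic <-> GPDC-not-PC,
    multiplicative noise <-> CMIknn-only)."""
    g = triangulation_graph()
    nodes = g.nodes
    method_opts = {
        "parcorr": dict(n_permutations=199, max_samples=None),
        "gpdc": dict(n_permutations=99, max_samples=400, gp_optimize=False),
        "cmiknn": dict(n_permutations=99, max_samples=500),
    }
    label = {"parcorr": "PC", "gpdc": "GPDC", "cmiknn": "CMIknn"}
    per_link: dict[tuple[str, str, int], list[str]] = {
        (s, t, lag): [] for (s, t, lag, _, _) in TRI_LINKS
    }
    matches = 0
    total = 0
    for r in range(n_seeds):
        X = single_block_panel(g, n, seed=seed * 777 + r)
        detected: dict[tuple[str, str, int], set[str]] = {k: set() for k in per_link}
        for method, opts in method_opts.items():
            cfg = DiscoveryConfig(
                tau_max=2, alpha=0.01, ci_method=method, seed=seed * 777 + r,
                max_conds=2, **opts,
            )
            graph = discover(X, cfg)
            found = found_links(graph, nodes)
            for key in per_link:
                if key in found:
                    detected[key].add(label[method])
        for (s, t, lag, form, _) in TRI_LINKS:
            methods = detected[(s, t, lag)]
            if not methods:
                nature = "undetected"
            elif "PC" in methods:
                nature = "linear"
            elif "GPDC" in methods:
                nature = "non_linear"
            else:
                nature = "complex"
            per_link[(s, t, lag)].append(nature)
            matches += nature == _EXPECTED_NATURE[form]
            total += 1
    return TriangulationResult(match_rate=matches / total, per_link={
        k: v for k, v in per_link.items()
    }, n_seeds=n_seeds)
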