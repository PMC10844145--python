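"""Ground-truth time-series causal graphs for the synthetic BOLD generator.

A :class:`GroundTruthGraph` is a lag-annotated directed graph over named ROIs.
Each link carries a functional form — ``linear`` (the target receives
``coeff * x_source(t - lag)``), ``quadratic`` (``coeff * x_source(t - lag)**2``,
invisible to correlation-based tests because ``corr(X, X^2) = 0`` for a
symmetric source), or ``multiplicative_noise`` (the target's innovation
standard deviation is scaled by ``1 + |coeff * x_source(t - lag)|``, a
heteroscedastic dependence that carries no signal in either the mean or a
smooth transform of the mean).  The three forms are the canonical alternatives
detectable by, respectively, partial correlation, GP/distance-correlation, and
kNN conditional mutual information.

The linear part of a graph (links of form ``linear`` plus the per-node AR(1)
innovation smoothing) defines an exact vector autoregression whose companion
matrix must have spectral radius below one; this is checked at construction
and reused by :func:`var_stationary_cov` as a closed-form oracle for
cross-covariances of simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

FORMS = ("linear", "quadratic", "multiplicative_noise")


@dataclass(frozen=True)
class Link:
    source: str
    target: str
    lag: int
    form: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown link form {self.form!r}; expected one of {FORMS}")
        if self.lag < 0:
            raise ValueError("link lag must be a non-negative integer")
        if self.lag == 0 and self.source == self.target:
            raise ValueError(f"self-link at lag 0 on node {self.source!r}")


@dataclass
class GroundTruthGraph:
    """Lag-annotated causal graph with functional-form tags.

    Parameters
    ----------
    nodes:
        ROI labels; order fixes the node indexing of simulated panels.
    links:
        ``Link`` instances (or ``(source, target, lag, form, coefficient)``
        tuples, coerced at construction).
    noise_sd:
        Per-node innovation standard deviation (scalar broadcast allowed).
    autocorr:
        Per-node AR(1) coefficient of the innovation process, in ``[0, 1)``;
        the stand-in for hemodynamic autocorrelation.
    max_lag:
        Largest admissible link lag.
    """

    nodes: list[str]
    links: list[Link] = field(default_factory=list)
    noise_sd: dict[str, float] | float = 1.0
    autocorr: dict[str, float] | float = 0.0
    max_lag: int = 2

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self.links = [ln if isinstance(ln, Link) else Link(*ln) for ln in self.links]
        known = set(self.nodes)
        for ln in self.links:
            if ln.source not in known or ln.target not in known:
                raise ValueError(f"link {ln} references unknown node")
            if ln.lag > self.max_lag:
                raise ValueError(f"link {ln} exceeds max_lag={self.max_lag}")
        if isinstance(self.noise_sd, (int, float)):
            self.noise_sd = {n: float(self.noise_sd) for n in self.nodes}
        if isinstance(self.autocorr, (int, float)):
            self.autocorr = {n: float(self.autocorr) for n in self.nodes}
        for n in self.nodes:
            if self.noise_sd[n] <= 0:
                raise ValueError(f"noise_sd must be > 0 (node {n})")
            if not 0.0 <= self.autocorr[n] < 1.0:
                raise ValueError(f"autocorr must be in [0, 1) (node {n})")
        self._check_contemporaneous_acyclic()
        self._check_no_nonlinear_feedback()
        rho = self.companion_spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"graph is non-stationary: companion spectral radius {rho:.3f} >= 1"
            )

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, label: str) -> int:
        return self.nodes.index(label)

    def contemporaneous_order(self) -> list[str]:
        """Topological order of nodes with respect to lag-0 links."""
        order: list[str] = []
        pending = set(self.nodes)
        deps = {
            n: {ln.source for ln in self.links if ln.lag == 0 and ln.target == n}
            for n in self.nodes
        }
        while pending:
            ready = sorted(n for n in pending if deps[n] <= set(order))
            if not ready:  # cannot happen once acyclicity is checked
                raise ValueError("lag-0 subgraph is cyclic")
            order.extend(ready)
            pending -= set(ready)
        return order

    def _check_contemporaneous_acyclic(self) -> None:
        self.contemporaneous_order()

    def _check_no_nonlinear_feedback(self) -> None:
        """Reject feedback loops through quadratic links: a squared variable
        feeding back onto itself (at any lag) is explosive regardless of the
        coefficient, so stationarity cannot be guaranteed."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for ln in self.links:
            if ln.form != "multiplicative_noise" and ln.source != ln.target:
                g.add_edge(ln.source, ln.target, form=ln.form)
        for comp in nx.strongly_connected_components(g):
            if len(comp) < 2:
                continue
            for ln in self.links:
                if ln.form == "quadratic" and ln.source in comp and ln.target in comp:
                    raise ValueError(
                        f"quadratic link {ln.source}->{ln.target} lies on a feedback "
                        "loop; the induced process is explosive"
                    )

    # -- linear / VAR view -------------------------------------------------

    def linear_coefficient_matrices(self) -> list[np.ndarray]:
        """``[B0, B1, ..., B_maxlag]`` with ``B_l[j, i]`` the linear effect of
        node ``i`` at lag ``l`` on node ``j``."""
        N = self.n_nodes
        mats = [np.zeros((N, N)) for _ in range(self.max_lag + 1)]
        for ln in self.links:
            if ln.form == "linear":
                mats[ln.lag][self.index(ln.target), self.index(ln.source)] += ln.coefficient
        return mats

    def reduced_var_matrices(self) -> list[np.ndarray]:
        """Reduced-form VAR matrices ``[A1, ..., A_p]`` of the full linear
        system, folding in both lag-0 structural links and the AR(1)
        innovation smoothing.

        With structural form ``x_t = B0 x_t + sum_l B_l x_{t-l} + e_t`` and
        ``e_t = Phi e_{t-1} + w_t`` (``Phi`` diagonal), substituting
        ``e_t = (I - B0) x_t - sum_l B_l x_{t-l}`` yields a VAR of order
        ``max_lag + 1`` in ``x`` driven by white noise ``w``.
        """
        N = self.n_nodes
        B = self.linear_coefficient_matrices()
        phi = np.diag([self.autocorr[n] for n in self.nodes])
        I = np.eye(N)
        inv = linalg.inv(I - B[0])
        # (I - B0) x_t = sum_l B_l x_{t-l} + Phi[(I - B0) x_{t-1} - sum_l B_l x_{t-1-l}] + w_t
        p = self.max_lag + 1
        A = [np.zeros((N, N)) for _ in range(p)]
        for l in range(1, self.max_lag + 1):
            A[l - 1] += B[l]
        A[0] += phi @ (I - B[0])
        for l in range(1, self.max_lag + 1):
            A[l] -= phi @ B[l]
        return [inv @ a for a in A]

    def companion_matrix(self) -> np.ndarray:
        A = self.reduced_var_matrices()
        N, p = self.n_nodes, len(A)
        C = np.zeros((N * p, N * p))
        C[:N, :] = np.hstack(A)
        C[N:, :-N] = np.eye(N * (p - 1))
        return C

    def companion_spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))

    def innovation_cov(self) -> np.ndarray:
        """Covariance of the white innovation ``w`` of the reduced VAR
        (ignoring multiplicative-noise scaling, i.e. its baseline level)."""
        N = self.n_nodes
        sd = np.array([self.noise_sd[n] for n in self.nodes])
        phi = np.array([self.autocorr[n] for n in self.nodes])
        w_var = sd**2 * (1.0 - phi**2)
        B0 = self.linear_coefficient_matrices()[0]
        inv = linalg.inv(np.eye(N) - B0)
        return inv @ np.diag(w_var) @ inv.T


def var_stationary_cov(graph: GroundTruthGraph, max_lag: int = 10) -> list[np.ndarray]:
    """Closed-form stationary (cross-)covariances of the linear part of a graph.

    Returns ``[G0, G1, ..., G_maxlag]`` with ``G_h[a, b] = cov(x_a(t), x_b(t - h))``,
    obtained from the discrete Lyapunov equation of the companion form.  Valid
    as a simulation oracle only for graphs whose links are all linear.
    """
    A = graph.reduced_var_matrices()
    N, p = graph.n_nodes, len(A)
    C = graph.companion_matrix()
    Q = np.zeros((N * p, N * p))
    Q[:N, :N] = graph.innovation_cov()
    S = linalg.solve_discrete_lyapunov(C, Q)
    out = [S[:N, h * N : (h + 1) * N].copy() for h in range(p)]
    while len(out) <= max_lag:
        h = len(out)
        G = sum(A[l] @ out[h - 1 - l] for l in range(p))
        out.append(G)
    return out[: max_lag + 1]


# -- study-shaped fixtures -------------------------------------------------

STUDY_ROIS = ["M1", "S1", "Cau", "Put", "GPe", "STN", "GPi", "SN", "Tal"]


def default_study_graphs(seed: int) -> dict[str, GroundTruthGraph]:
    """Two 9-node graphs (resting / motor) mimicking the thalamus-basal-ganglia
    motor circuit topology used throughout the tests.

    Both graphs contain at least one link of each functional form and each lag
    in {0, 1, 2}, plus one reciprocal lag-2 pair (an "interactive"
    relationship).  The two conditions differ in several links so that
    task-dependent rewiring is observable.  ``seed`` jitters coefficients
    mildly so repeated studies are not literally identical graphs.
    """
    rng = np.random.default_rng([int(seed), 0x51CA])
    j = lambda c: float(c * rng.uniform(0.9, 1.1))  # noqa: E731
    common = dict(noise_sd=1.0, autocorr=0.45, max_lag=2)
    resting = GroundTruthGraph(
        nodes=list(STUDY_ROIS),
        links=[
            ("M1", "S1", 0, "linear", j(0.45)),
            ("Tal", "Put", 1, "linear", j(0.40)),
            ("Tal", "Cau", 2, "linear", j(0.35)),
            ("Cau", "Tal", 2, "linear", j(0.35)),
            ("Put", "GPe", 1, "quadratic", j(0.35)),
            ("SN", "Tal", 2, "quadratic", j(0.30)),
            ("STN", "GPi", 1, "multiplicative_noise", j(0.80)),
        ],
        **common,
    )
    motor = GroundTruthGraph(
        nodes=list(STUDY_ROIS),
        links=[
            ("M1", "S1", 0, "linear", j(0.45)),
            ("M1", "Put", 1, "linear", j(0.40)),
            ("Tal", "Cau", 2, "linear", j(0.35)),
            ("Cau", "Tal", 2, "linear", j(0.35)),
            ("Put", "GPe", 1, "quadratic", j(0.35)),
            ("GPe", "STN", 0, "linear", j(0.35)),
            ("SN", "Tal", 1, "quadratic", j(0.30)),
            ("STN", "GPi", 1, "multiplicative_noise", j(0.80)),
        ],
        **common,
    )
    return {"resting": resting, "motor": motor}


def linear_benchmark_graph(seed: int = 0) -> GroundTruthGraph:
    """9-node linear-only benchmark used for graph-recovery scoring.

    Same node set as the study graphs; all links linear with coefficients
    strong enough to be recoverable at n = 4000 under alpha = 0.01.
    Autocorrelation is written as explicit self-links at lag 1 (rather than
    innovation smoothing) so the structural links coincide with the
    reduced-form VAR adjacencies and recovery can be scored link-by-link.
    """
    rng = np.random.default_rng([int(seed), 0x11EA])
    j = lambda c: float(c * rng.uniform(0.95, 1.05))  # noqa: E731
    links = [
        ("M1", "S1", 0, "linear", j(0.40)),
        ("M1", "Put", 1, "linear", j(0.35)),
        ("Put", "GPe", 1, "linear", j(0.35)),
        ("GPe", "STN", 2, "linear", j(0.35)),
        ("STN", "GPi", 1, "linear", j(0.35)),
        ("SN", "Tal", 2, "linear", j(0.35)),
        ("Tal", "Cau", 1, "linear", j(0.35)),
    ]
    links += [(n, n, 1, "linear", 0.4) for n in STUDY_ROIS]
    return GroundTruthGraph(
        nodes=list(STUDY_ROIS),
        links=links,
        noise_sd=1.0,
        autocorr=0.0,
        max_lag=2,
    )
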