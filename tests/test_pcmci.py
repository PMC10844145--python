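"""PCMCI+ discovery: determinism, time order, d-separation consistency on
small generative models, collider orientation, null calibration."""

import numpy as np
import pytest

import boldcausal as bc
from boldcausal.benchmarks import found_links, single_block_panel
from boldcausal.oracle import dsep_independent, expected_mci_links
from boldcausal.pcmci import CONFLICT, DIRECTED_BWD, UNDIRECTED, _demand


def _self_chain(nodes, extra, coeff=0.4):
    links = [(n, n, 1, "linear", coeff) for n in nodes] + extra
    return bc.GroundTruthGraph(nodes=list(nodes), links=links, noise_sd=1.0, autocorr=0.0)


def test_discovery_deterministic_bit_equal():
    g = _self_chain("AB", [("A", "B", 1, "linear", 0.5)])
    X = single_block_panel(g, 1500, seed=3)
    cfg = bc.DiscoveryConfig(ci_method="parcorr", seed=3, n_permutations=99)
    g1 = bc.discover(X, cfg)
    g2 = bc.discover(X, cfg)
    for k in g1.lagged:
        assert g1.lagged[k].statistic == g2.lagged[k].statistic
        assert g1.lagged[k].p_value == g2.lagged[k].p_value
    for k in g1.contemp:
        assert g1.contemp[k].mark == g2.contemp[k].mark


def test_no_future_to_past_links_and_no_self_parents_at_lag0():
    g = _self_chain("ABC", [("A", "B", 1, "linear", 0.5), ("B", "C", 0, "linear", 0.5)])
    X = single_block_panel(g, 2000, seed=5)
    cfg = bc.DiscoveryConfig(ci_method="parcorr", seed=5, n_permutations=99)
    parents = bc.select_conditions(X, cfg)
    for j, plist in parents.lagged.items():
        assert all(lag >= 1 for (_, lag) in plist)
    for j, plist in parents.contemp.items():
        assert (j, 0) not in plist
    graph = bc.discover(X, cfg)
    assert all(lag >= 1 for (_, _, lag) in graph.lagged)  # storage keys only lag >= 1


def test_chain_parents_match_dsep_oracle():
    """A ->1 B ->1 C: discovered links equal the brute-force d-separation
    truth (in particular no A ->2 C edge once B is conditioned)."""
    g = _self_chain("ABC", [("A", "B", 1, "linear", 0.6), ("B", "C", 1, "linear", 0.6)])
    X = single_block_panel(g, 3000, seed=11)
    graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=11, n_permutations=199))
    found = set(graph.significant_lagged())
    expected = {
        (g.nodes.index(a), g.nodes.index(b), lag)
        for (a, b, lag) in expected_mci_links(g, 2) if lag > 0
    }
    assert found == expected
    assert not graph.significant_contemp()


def test_common_driver_robustness():
    """A <- D -> B with D observed: no A-B link at any lag."""
    g = _self_chain(
        "DAB", [("D", "A", 1, "linear", 0.6), ("D", "B", 1, "linear", 0.6)]
    )
    # MCI-style conditioning (parents of both sides) renders A and B independent
    assert dsep_independent(g, "A", 0, "B", [("D", 1), ("A", 1), ("B", 1)])
    assert not dsep_independent(g, "A", 0, "B", [])  # unconditionally dependent
    X = single_block_panel(g, 3000, seed=13)
    graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=13, n_permutations=199))
    ia, ib = g.nodes.index("A"), g.nodes.index("B")
    for lag in (1, 2):
        assert not graph.lagged[(ia, ib, lag)].significant
        assert not graph.lagged[(ib, ia, lag)].significant
    assert graph.contemp_mark(ia, ib) == "absent"


def test_collider_phase_orients_contemporaneous_edge():
    """A ->1 K o-o J with A,J non-adjacent: the exhaustive d-separation
    oracle admits only the collider A -> K <- J, so the edge becomes J -> K."""
    g = _self_chain(
        "AKJ", [("A", "K", 1, "linear", 0.5), ("J", "K", 0, "linear", 0.5)]
    )
    # oracle: of the two orientations, only J -> K leaves (A_{t-1}, J_t)
    # marginally independent
    assert dsep_independent(g, "A", 1, "J", [])
    alt = _self_chain(
        "AKJ", [("A", "K", 1, "linear", 0.5), ("K", "J", 0, "linear", 0.5)]
    )
    assert not dsep_independent(alt, "A", 1, "J", [])
    X = single_block_panel(g, 4000, seed=7)
    graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=7, n_permutations=199))
    ik, ij = g.nodes.index("K"), g.nodes.index("J")
    assert graph.contemp_mark(ik, ij) == DIRECTED_BWD  # arrow into K, i.e. J -> K


def test_no_contemporaneous_links_leaves_orientation_unchanged():
    g = _self_chain("AB", [("A", "B", 1, "linear", 0.5)])
    X = single_block_panel(g, 1500, seed=17)
    cfg = bc.DiscoveryConfig(ci_method="parcorr", seed=17, n_permutations=99)
    parents = bc.select_conditions(X, cfg)
    graph = bc.mci_tests(X, parents, cfg)
    before = {k: v.mark for k, v in graph.contemp.items()}
    after = bc.orient_contemporaneous(graph, X, parents, cfg)
    assert {k: v.mark for k, v in after.contemp.items()} == before


def test_conflicting_demands_become_conflict_mark():
    marks = {(0, 1): UNDIRECTED}
    conflicts = set()
    _demand(marks, 0, 1, head=1, conflicts=conflicts)
    _demand(marks, 0, 1, head=0, conflicts=conflicts)
    assert marks[(0, 1)] == CONFLICT
    assert (0, 1) in conflicts
    # never silently overwritten afterwards
    _demand(marks, 0, 1, head=1, conflicts=conflicts)
    assert marks[(0, 1)] == CONFLICT


def test_null_panel_false_link_rate_controlled():
    """Pure-noise panels: false links stay near the alpha x tests bound."""
    g = bc.GroundTruthGraph(nodes=list("ABCDE"), links=[], noise_sd=1.0, autocorr=0.4)
    false_links = 0
    n_entries = 0
    seeds = 12
    for r in range(seeds):
        X = single_block_panel(g, 1500, seed=200 + r)
        graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=200 + r,
                                                  n_permutations=199))
        found = found_links(graph, g.nodes)
        # self lag-1 links are genuine (innovation smoothing); ignore them
        false_links += sum(1 for (a, b, lag) in found if not (a == b and lag == 1))
        n_entries += len(graph.lagged) + len(graph.contemp) - 5  # minus selves at lag 1
    rate = false_links / n_entries
    # alpha = 0.01 with binomial slack (3 sigma) over n_entries trials
    bound = 0.01 + 3 * np.sqrt(0.01 * 0.99 / n_entries)
    assert rate <= bound


def test_autocorrelation_does_not_inflate_false_links():
    """Raising innovation autocorrelation from 0 to 0.8 in the null fixture
    must not push the false-link rate above the calibrated bound."""
    rates = {}
    for phi in (0.0, 0.8):
        g = bc.GroundTruthGraph(nodes=list("ABCD"), links=[], noise_sd=1.0, autocorr=phi)
        false_links = 0
        n_entries = 0
        for r in range(8):
            X = single_block_panel(g, 1500, seed=300 + r)
            graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=300 + r,
                                                      n_permutations=199))
            found = found_links(graph, g.nodes)
            false_links += sum(1 for (a, b, lag) in found if not (a == b and lag == 1))
            n_entries += len(graph.lagged) + len(graph.contemp) - 4
        rates[phi] = false_links / n_entries
    bound = 0.01 + 3 * np.sqrt(0.01 * 0.99 / n_entries)
    assert rates[0.8] <= bound


def test_graph_serialization_roundtrip(tmp_path):
    g = _self_chain("AB", [("A", "B", 1, "linear", 0.5)])
    X = single_block_panel(g, 1200, seed=23)
    graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=23, n_permutations=99))
    path = tmp_path / "graph.json"
    graph.save(path)
    loaded = bc.TimeSeriesGraph.load(path)
    assert loaded.nodes == graph.nodes
    assert set(loaded.lagged) == set(graph.lagged)
    for k in graph.lagged:
        assert loaded.lagged[k].p_value == graph.lagged[k].p_value
    edges = graph.edge_list()
    assert set(edges.columns) == {"source", "target", "lag", "mark", "statistic", "p_value"}
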