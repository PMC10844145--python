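"""Relationship classification: lag classes, roles, triangulated nature,
normalization, and the collapse accounting."""

import pytest
from hypothesis import given, settings, strategies as st

import boldcausal as bc
from boldcausal.classify import METHOD_NAMES, MethodLink, nature_counts


def _ml(seed="M-Tal", partner="Cau", task="resting", lag=0, link="undirected",
        method="PC", stat=None):
    return MethodLink(seed, partner, task, lag, link, method, stat)


# -- elementary rules ------------------------------------------------------

@pytest.mark.parametrize("lag,expected", [
    (0, "contemporaneous"), (1, "single_delayed"), (2, "double_delayed"),
])
def test_lag_class_mapping(lag, expected):
    assert bc.lag_class(lag) == expected


def test_lag_class_out_of_range():
    with pytest.raises(ValueError):
        bc.lag_class(3)
    with pytest.raises(ValueError):
        bc.lag_class(-1)


def test_assign_role_examples():
    assert bc.assign_role([_ml(link="undirected")]) == "undefined"
    assert bc.assign_role([_ml(lag=0, link="causative", method="CMIknn")]) == "causative"
    assert bc.assign_role([_ml(lag=2, link="causative"), _ml(lag=2, link="response")]) == "interactive"
    with pytest.raises(ValueError):
        bc.assign_role([])


@pytest.mark.parametrize("methods,expected", [
    ({"PC", "GPDC", "CMIknn"}, "linear"),
    ({"GPDC"}, "non_linear"),
    ({"GPDC", "CMIknn"}, "non_linear"),
    ({"CMIknn"}, "complex"),
])
def test_assign_nature_triangulation_rule(methods, expected):
    assert bc.assign_nature(methods) == expected


def test_assign_nature_empty_rejected():
    with pytest.raises(ValueError):
        bc.assign_nature(set())


def test_normalize_statistics_examples():
    links = [_ml(stat=0.2, partner="Cau"), _ml(stat=0.4, partner="Put"),
             _ml(stat=-0.3, partner="GPe")]
    out = bc.normalize_statistics(links)
    by_partner = {ln.partner: ln.statistic_normalized for ln in out}
    assert by_partner == {"Cau": 0.5, "Put": 1.0, "GPe": pytest.approx(0.75)}
    solo = bc.normalize_statistics([_ml(stat=-0.9, method="GPDC")])
    assert solo[0].statistic_normalized == 1.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12),
       st.sampled_from(["max_abs", "minmax", "rank"]))
def test_normalized_statistics_in_unit_interval(stats, scheme):
    links = [_ml(stat=s, partner=f"P{k}") for k, s in enumerate(stats)]
    out = bc.normalize_statistics(links, scheme=scheme)
    for ln in out:
        assert ln.statistic_normalized is None or 0.0 <= ln.statistic_normalized <= 1.0


# -- collapse accounting ---------------------------------------------------

def test_interactive_requires_single_method_both_directions():
    # PC alone reports both directions -> one interactive record
    recs = bc.collapse_links([
        _ml(lag=2, link="causative"), _ml(lag=2, link="response"),
        _ml(lag=2, link="causative", method="CMIknn"),
    ])
    assert len(recs) == 1 and recs[0].role == "interactive"
    assert recs[0].methods_detecting == frozenset({"PC", "CMIknn"})
    # opposite directions from different methods -> two records
    recs = bc.collapse_links([
        _ml(lag=2, link="causative", method="CMIknn"),
        _ml(lag=2, link="response", method="GPDC"),
    ])
    assert sorted(r.role for r in recs) == ["causative", "response"]


def test_undefined_separate_from_directed_at_same_lag_class():
    recs = bc.collapse_links([
        _ml(lag=0, link="undirected", method="GPDC"),
        _ml(lag=0, link="causative", method="CMIknn"),
    ])
    roles = {r.role: r for r in recs}
    assert set(roles) == {"undefined", "causative"}
    assert roles["undefined"].nature == "non_linear"
    assert roles["causative"].nature == "complex"


def test_permanent_merge_requires_all_methods_in_both_tasks():
    full = [
        _ml(task=t, method=m) for t in ("resting", "motor") for m in METHOD_NAMES
    ]
    recs = bc.collapse_links(full)
    assert len(recs) == 1
    assert recs[0].task == "both"
    # missing one method in one task -> two per-task records
    partial = [ln for ln in full if not (ln.task == "resting" and ln.method == "GPDC")]
    recs = bc.collapse_links(partial)
    assert sorted(r.task for r in recs) == ["motor", "resting"]


def test_empty_input_gives_empty_table():
    assert bc.collapse_links([]) == []


def test_collapse_is_idempotent_on_its_own_grouping():
    links = [
        _ml(task="resting"), _ml(task="resting", method="GPDC"),
        _ml(partner="Put", lag=1, link="causative", method="GPDC", task="motor"),
    ]
    once = bc.collapse_links(links)
    again = bc.collapse_links(links)
    assert once == again


def test_every_record_has_one_nature_and_counts_partition():
    links = bc.load_link_table()
    recs = bc.collapse_links(links)
    counts = nature_counts(recs)
    assert counts["linear"] + counts["non_linear"] + counts["complex"] == counts["total"]
    for r in recs:
        assert r.nature in ("linear", "non_linear", "complex")
        assert r.role in ("undefined", "causative", "response", "interactive")


def test_records_frame_role_marks():
    links = [
        _ml(lag=1, link="causative", method="GPDC"),
        _ml(partner="Put", lag=2, link="response", method="PC"),
        _ml(partner="GPe", link="undirected", method="CMIknn"),
    ]
    df = bc.records_to_frame(bc.collapse_links(links))
    marks = dict(zip(df["role"], df["role_mark"]))
    assert marks == {"causative": "*", "response": "<", "undefined": ""}


def test_links_from_graph_extracts_seed_incident_links():
    from boldcausal.benchmarks import single_block_panel
    from boldcausal.classify import links_from_graph

    g = bc.GroundTruthGraph(
        nodes=["Tal", "Cau", "Put"],
        links=[("Tal", "Cau", 1, "linear", 0.6)]
        + [(n, n, 1, "linear", 0.4) for n in ("Tal", "Cau", "Put")],
        noise_sd=1.0, autocorr=0.0,
    )
    X = single_block_panel(g, 3000, seed=31)
    graph = bc.discover(X, bc.DiscoveryConfig(ci_method="parcorr", seed=31, n_permutations=199))
    graph.nodes = list(g.nodes)
    links = links_from_graph(graph, "Tal", "resting", "PC")
    assert any(ln.partner == "Cau" and ln.link == "causative" and ln.lag == 1 for ln in links)
    assert all(ln.seed == "Tal" for ln in links)
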