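import networkx as nx
import numpy as np
import pytest

from protraj.ddrtree import DdrtreeConfig, ddrtree_fit
from protraj.progression import (
    PrincipalTreeGraph,
    assign_states,
    build_progression_model,
    build_tree_graph,
    extract_paths,
    project_samples,
    select_root,
    select_root_by_covariate,
    state_transitions,
)


def _graph_from(coords, edges):
    g = nx.Graph()
    g.add_nodes_from(coords)
    for u, v in edges:
        g.add_edge(u, v, length=float(np.linalg.norm(
            np.asarray(coords[u]) - np.asarray(coords[v]))))
    return PrincipalTreeGraph({k: np.asarray(v, float) for k, v in coords.items()}, g)


@pytest.fixture()
def path_graph():
    return _graph_from({0: [0, 0], 1: [1, 0], 2: [2, 0]}, [(0, 1), (1, 2)])


@pytest.fixture()
def star_graph():
    return _graph_from(
        {0: [0, 0], 1: [1, 0], 2: [0, 1], 3: [-1, 0]},
        [(0, 1), (0, 2), (0, 3)],
    )


@pytest.fixture()
def seven_state_graph():
    # trunk 0-1, limbs with one side branch each: 7 segments
    coords = {
        0: [0.0, 0.0], 1: [1.0, 0.0],
        2: [2.0, -0.6], 3: [3.0, -1.0], 4: [2.2, -1.5],
        5: [2.0, 0.6], 6: [3.0, 1.0], 7: [2.2, 1.5],
    }
    edges = [(0, 1), (1, 2), (2, 3), (2, 4), (1, 5), (5, 6), (5, 7)]
    return _graph_from(coords, edges)


def test_build_tree_graph_properties(path_graph, star_graph):
    assert path_graph.leaves == [0, 2]
    assert path_graph.branch_points == []
    assert path_graph.total_length() == pytest.approx(2.0)
    assert star_graph.leaves == [1, 2, 3]
    assert star_graph.branch_points == [0]


def test_build_tree_graph_from_latent_model(rng):
    X = rng.normal(size=(6, 25))
    model = ddrtree_fit(X, DdrtreeConfig(latent_dim=2, max_iters=10))
    g = build_tree_graph(model)
    assert g.graph.number_of_nodes() == model.Z.shape[1]
    assert nx.is_tree(g.graph)


def test_select_root_geometry_and_ties(path_graph):
    assert select_root(path_graph, np.array([[0.1, 0.0]])) == 0
    # centroid beyond one end selects that end
    assert select_root(path_graph, np.array([[5.0, 0.0]])) == 2
    # exact tie resolves to the lower vertex id
    assert select_root(path_graph, np.array([[1.0, 0.0]])) == 0
    with pytest.raises(ValueError, match="no normal samples"):
        select_root(path_graph, np.empty((0, 2)))


def test_select_root_by_covariate_mixed_segment(seven_state_graph):
    g = seven_state_graph
    proj = project_samples(
        g, 0,
        np.array([[0.5, 2.5, 2.5], [0.0, -0.8, 0.8]]),
        ["mix1", "neg1", "pos1"],
    )
    states, seg = assign_states(g, 0, proj)
    cov = {"mix1": 1.0, "neg1": -1.0, "pos1": 1.0}
    # trunk holds one +1; give it a -1 partner so it is perfectly mixed
    proj2 = project_samples(
        g, 0,
        np.array([[0.5, 0.6, 2.5, 2.5], [0.0, 0.0, -0.8, 0.8]]),
        ["mix1", "mix2", "neg1", "pos1"],
    )
    states2, seg2 = assign_states(g, 0, proj2)
    cov2 = {"mix1": 1.0, "mix2": -1.0, "neg1": -1.0, "pos1": 1.0}
    root = select_root_by_covariate(g, seg2, cov2, states2)
    assert root == 0  # leaf adjoining the mixed trunk segment
    with pytest.raises(ValueError, match="both"):
        select_root_by_covariate(g, seg2, {"mix1": 1.0, "mix2": 1.0}, states2)


def test_extract_paths_counts(path_graph, star_graph, seven_state_graph):
    assert extract_paths(path_graph, 0) == {"A": [0, 1, 2]}
    assert len(extract_paths(star_graph, 1)) == 2  # degree-1 root: 2 other leaves
    paths = extract_paths(seven_state_graph, 0)
    assert len(paths) == 4  # the 7-state template yields 4 root-to-leaf paths
    for p in paths.values():
        assert p[0] == 0


def test_extract_paths_naming_by_terminal_count(seven_state_graph):
    paths = extract_paths(seven_state_graph, 0,
                          terminal_counts={3: 5, 4: 1, 6: 10, 7: 2})
    assert paths["A"][-1] == 6 and paths["B"][-1] == 3
    assert paths["C"][-1] == 7 and paths["D"][-1] == 4


def test_project_samples_hand_geometry():
    g = _graph_from({0: [0.0, 0.0], 1: [1.0, 0.0]}, [(0, 1)])
    proj = project_samples(g, 0, np.array([[0.3], [5.0]]), ["s"])
    assert np.allclose(proj[0].coordinate, [0.3, 0.0])
    assert proj[0].progression_distance == pytest.approx(0.3)


def test_project_samples_at_vertices(seven_state_graph):
    g = seven_state_graph
    proj = project_samples(
        g, 0, np.array([[0.0, 3.0], [0.0, -1.0]]), ["root_s", "leaf_s"]
    )
    assert proj[0].progression_distance == pytest.approx(0.0)
    # sample exactly at leaf 3: distance = sum of edge lengths root -> 3
    expected = nx.dijkstra_path_length(g.graph, 0, 3, weight="length")
    assert proj[1].progression_distance == pytest.approx(expected)


def test_assign_states_template_and_degenerate(path_graph, seven_state_graph):
    # path graph: single state holds everyone
    proj = project_samples(path_graph, 0, np.array([[0.5, 1.5], [0, 0]]), ["a", "b"])
    states, sample_states = assign_states(path_graph, 0, proj)
    assert len(states) == 1 and set(sample_states.values()) == {1}

    # 7-state template: exactly 7 segments, empty ones allowed
    proj7 = project_samples(
        seven_state_graph, 0, np.array([[0.5], [0.0]]), ["only"]
    )
    states7, ss7 = assign_states(seven_state_graph, 0, proj7)
    assert len(states7) == 7
    assert ss7["only"] == 1  # trunk numbered first from the root


def test_branch_point_projection_goes_root_side(seven_state_graph):
    g = seven_state_graph
    proj = project_samples(g, 0, np.array([[1.0], [0.0]]), ["at_bp"])
    states, ss = assign_states(g, 0, proj)
    # vertex 1 is a branch point; the sample joins the trunk (root-side) state
    assert ss["at_bp"] == 1


def test_distance_order_matches_position_along_path(seven_state_graph):
    g = seven_state_graph
    xs = np.array([[0.2, 0.8, 1.6, 2.8], [0.0, 0.0, -0.4, -0.9]])
    proj = project_samples(g, 0, xs, list("abcd"))
    dists = [p.progression_distance for p in proj]
    assert dists == sorted(dists)
    assert all(d >= 0 for d in dists)


def test_states_partition_edges_and_samples(seven_state_graph, rng):
    g = seven_state_graph
    pts = rng.uniform(-1.5, 3, size=(2, 40))
    proj = project_samples(g, 0, pts, [f"s{i}" for i in range(40)])
    states, ss = assign_states(g, 0, proj)
    all_edges = sorted(
        (min(u, v), max(u, v)) for u, v in g.graph.edges
    )
    covered = sorted(
        (min(u, v), max(u, v)) for run in states.values() for u, v in run
    )
    assert covered == all_edges  # union of states covers every edge once
    assert set(ss) == {f"s{i}" for i in range(40)}


def test_state_transitions_on_template(seven_state_graph):
    proj = project_samples(seven_state_graph, 0,
                           np.array([[0.5], [0.0]]), ["x"])
    states, ss = assign_states(seven_state_graph, 0, proj)
    from protraj.progression import ProgressionModel

    pm = ProgressionModel(seven_state_graph, 0,
                          extract_paths(seven_state_graph, 0), states, ss,
                          {"x": 0.5}, proj)
    trans = state_transitions(pm)
    # trunk feeds two limbs; each limb start feeds two ends: 6 transitions
    assert len(trans) == 6
    assert all(a < b or True for a, b in trans)
    starts = [t[0] for t in trans]
    assert starts.count(1) == 2


def test_full_model_round_trip_and_path_samples(small_cohort, tmp_path):
    from protraj import io as pio

    expr, annot, events, truth = small_cohort
    X = expr.subset_genes(truth.informative_genes()).values
    model = ddrtree_fit(
        X,
        DdrtreeConfig(latent_dim=5, lambda_tree=400.0, sigma=0.1,
                      n_latent_points=60),
        sample_ids=expr.sample_ids,
    )
    normals = [s for s in expr.sample_ids if s.startswith("N")]
    pm = build_progression_model(model, normal_sample_ids=normals,
                                 min_segment_samples=6)
    # every sample has exactly one state and a finite distance
    assert set(pm.sample_states) == set(expr.sample_ids)
    assert all(d >= 0 for d in pm.sample_distances.values())
    # samples on a path come back ordered by distance
    for name in pm.paths:
        samples = pm.path_samples(name)
        d = [pm.sample_distances[s] for s in samples]
        assert d == sorted(d)
    p = tmp_path / "pm.json"
    pio.save_model(pm, p)
    back = pio.load_model(p)
    assert back.sample_states == pm.sample_states
    assert back.paths == pm.paths
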