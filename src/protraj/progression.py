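"""From a fitted principal tree to a rooted progression model.

The anchors and spanning tree of a :class:`~protraj.ddrtree.LatentTreeModel`
are materialized as a geometric graph; the root is the leaf closest to the
normal-sample centroid (or, without normals, the leaf adjoining the segment
with the most mixed binary covariate).  Samples are projected onto the
closest point of the tree, progression distance is the geodesic from the
root to the projection, and progression states are the maximal segments
between branch points, numbered breadth-first from the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ddrtree import LatentTreeModel

__all__ = [
    "PrincipalTreeGraph",
    "SampleProjection",
    "ProgressionModel",
    "build_tree_graph",
    "select_root",
    "select_root_by_covariate",
    "extract_paths",
    "project_samples",
    "assign_states",
    "build_progression_model",
    "prune_small_leaf_segments",
    "state_transitions",
]

logger = logging.getLogger(__name__)


@dataclass
class PrincipalTreeGraph:
    """Geometric tree: vertex coordinates plus Euclidean edge lengths."""

    coords: dict[int, np.ndarray]
    graph: nx.Graph

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() and not nx.is_tree(self.graph):
            raise ValueError("principal tree graph must be connected and acyclic")

    @property
    def leaves(self) -> list[int]:
        return sorted(v for v in self.graph if self.graph.degree(v) == 1)

    @property
    def branch_points(self) -> list[int]:
        return sorted(v for v in self.graph if self.graph.degree(v) >= 3)

    def edge_length(self, u: int, v: int) -> float:
        return self.graph.edges[u, v]["length"]

    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))


@dataclass
class SampleProjection:
    """Closest point of the tree to a sample, with its geodesic distance."""

    sample_id: str
    edge: tuple[int, int]
    offset: float  # position along edge, in [0, 1] from edge[0] to edge[1]
    coordinate: np.ndarray
    progression_distance: float


@dataclass
class ProgressionModel:
    """Rooted tree with paths, states and per-sample progression distances."""

    tree: PrincipalTreeGraph
    root: int
    paths: dict[str, list[int]]  # path name -> ordered vertex list
    states: dict[int, list[tuple[int, int]]]  # state id -> edges
    sample_states: dict[str, int]
    sample_distances: dict[str, float]
    projections: list[SampleProjection] = field(default_factory=list)

    def path_samples(self, name: str) -> list[str]:
        """Samples projecting onto any segment of a path, ordered by
        progression distance (ties broken by sample id)."""
        path_edges = set()
        verts = self.paths[name]
        for u, v in zip(verts[:-1], verts[1:]):
            path_edges.add((min(u, v), max(u, v)))
        path_states = {
            s for s, edges in self.states.items()
            if any((min(u, v), max(u, v)) in path_edges for u, v in edges)
        }
        members = [s for s, st in self.sample_states.items() if st in path_states]
        return sorted(members, key=lambda s: (self.sample_distances[s], s))

    def to_dict(self) -> dict:
        return {
            "coords": {str(v): c for v, c in self.tree.coords.items()},
            "edges": [[u, v, self.tree.edge_length(u, v)]
                      for u, v in self.tree.graph.edges],
            "root": self.root,
            "paths": {k: list(v) for k, v in self.paths.items()},
            "states": {str(k): [list(e) for e in v] for k, v in self.states.items()},
            "sample_states": self.sample_states,
            "sample_distances": {k: float(v) for k, v in self.sample_distances.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionModel":
        coords = {int(k): np.asarray(v, dtype=float) for k, v in d["coords"].items()}
        g = nx.Graph()
        g.add_nodes_from(coords)
        for u, v, length in d["edges"]:
            g.add_edge(int(u), int(v), length=float(length))
        tree = PrincipalTreeGraph(coords, g)
        return cls(
            tree=tree,
            root=int(d["root"]),
            paths={k: [int(x) for x in v] for k, v in d["paths"].items()},
            states={int(k): [tuple(int(x) for x in e) for e in v]
                    for k, v in d["states"].items()},
            sample_states={k: int(v) for k, v in d["sample_states"].items()},
            sample_distances={k: float(v) for k, v in d["sample_distances"].items()},
        )


def build_tree_graph(model: LatentTreeModel) -> PrincipalTreeGraph:
    """Materialize the latent anchors and spanning-tree edges as a graph."""
    Z = model.Z
    coords = {j: Z[:, j].copy() for j in range(Z.shape[1])}
    g = nx.Graph()
    g.add_nodes_from(coords)
    for u, v in model.tree_edges:
        g.add_edge(u, v, length=float(np.linalg.norm(Z[:, u] - Z[:, v])))
    return PrincipalTreeGraph(coords, g)


def select_root(graph: PrincipalTreeGraph, normal_latent: np.ndarray) -> int:
    """Leaf closest to the centroid of the normal samples' latent points."""
    normal_latent = np.atleast_2d(np.asarray(normal_latent, dtype=float))
    if normal_latent.shape[0] == 0:
        raise ValueError(
            "no normal samples; use select_root_by_covariate instead"
        )
    if len(graph.leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    centroid = normal_latent.mean(axis=0)
    # ties broken by vertex id via sorted leaves + strict improvement
    best, best_d = None, np.inf
    for leaf in graph.leaves:
        d = float(np.linalg.norm(graph.coords[leaf] - centroid))
        if d < best_d - 1e-15:
            best, best_d = leaf, d
    return best


def select_root_by_covariate(
    graph: PrincipalTreeGraph,
    sample_segments: dict[str, int],
    covariate: dict[str, float],
    segments: dict[int, list[tuple[int, int]]] | None = None,
) -> int:
    """Leaf adjoining the segment whose +/-1 covariate mix is closest to parity.

    ``sample_segments`` maps samples to segment ids (a provisional
    segmentation from :func:`assign_states`); ``segments`` maps those ids to
    their edges (recomputed from the graph's own cut vertices when absent).
    The chosen leaf is the one nearest, in hops, to the most mixed segment;
    ties resolve to the lower vertex id.
    """
    labels = {s: float(v) for s, v in covariate.items()
              if not (v is None or (isinstance(v, float) and np.isnan(v)))}
    if not ({-1.0, 1.0} <= set(labels.values())):
        raise ValueError("covariate must contain both +1 and -1 labels")
    seg_means: dict[int, float] = {}
    for seg in sorted(set(sample_segments.values())):
        members = [labels[s] for s, g in sample_segments.items()
                   if g == seg and s in labels]
        if members:
            seg_means[seg] = abs(float(np.mean(members)))
    if not seg_means:
        raise ValueError("no labeled samples on any segment")
    best_seg = min(seg_means, key=lambda s: (seg_means[s], s))
    if segments is None:
        segments = _segment_edges(graph)
    verts = sorted({v for e in segments[best_seg] for v in e})
    best, best_d = None, np.inf
    for leaf in graph.leaves:
        d = min(nx.shortest_path_length(graph.graph, leaf, v) for v in verts)
        if d < best_d - 1e-15:
            best, best_d = leaf, d
    return best


def _segment_edges(
    graph: PrincipalTreeGraph, root: int | None = None
) -> dict[int, list[tuple[int, int]]]:
    """Maximal edge runs between cut vertices (leaves, branch points, root).

    Segments are numbered breadth-first from the root (or from the lowest
    leaf when no root is given); the returned ids are provisional — state
    numbering applies its own tie rule in :func:`assign_states`.
    """
    g = graph.graph
    cut = {v for v in g if g.degree(v) != 2}
    if root is not None:
        cut.add(root)
    start = root if root is not None else min(cut or g.nodes)
    segments: list[list[tuple[int, int]]] = []
    seen_edges: set[tuple[int, int]] = set()
    frontier = [start]
    visited_cut = set()
    while frontier:
        v = frontier.pop(0)
        if v in visited_cut:
            continue
        visited_cut.add(v)
        for nb in sorted(g.neighbors(v)):
            e = (min(v, nb), max(v, nb))
            if e in seen_edges:
                continue
            run = [e]
            seen_edges.add(e)
            prev, cur = v, nb
            while cur not in cut:
                nxt = [w for w in g.neighbors(cur) if w != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                e2 = (min(prev, cur), max(prev, cur))
                run.append(e2)
                seen_edges.add(e2)
            segments.append(run)
            if cur in cut and cur not in visited_cut:
                frontier.append(cur)
    return {i: run for i, run in enumerate(segments)}


def extract_paths(
    graph: PrincipalTreeGraph,
    root: int,
    terminal_counts: dict[int, int] | None = None,
) -> dict[str, list[int]]:
    """One shortest path from the root to each non-root leaf.

    Paths are named A, B, C, ... in descending count of samples at the
    terminal leaf (``terminal_counts``); without counts, by leaf id.
    """
    if graph.graph.degree(root) != 1:
        raise ValueError("root must be a leaf")
    termini = [v for v in graph.leaves if v != root]
    if terminal_counts is None:
        termini.sort()
    else:
        termini.sort(key=lambda v: (-terminal_counts.get(v, 0), v))
    names = [chr(ord("A") + i) for i in range(len(termini))]
    return {
        name: nx.shortest_path(graph.graph, root, t, weight="length")
        for name, t in zip(names, termini)
    }


def project_samples(
    graph: PrincipalTreeGraph,
    root: int,
    samples_latent: np.ndarray,
    sample_ids: list[str],
) -> list[SampleProjection]:
    """Orthogonal projection of each sample onto its closest tree edge.

    ``samples_latent`` is (d, n).  Progression distance is the geodesic
    from the root to the projected point using Euclidean edge lengths.
    """
    root_dist = nx.single_source_dijkstra_path_length(
        graph.graph, root, weight="length"
    )
    edges = sorted((min(u, v), max(u, v)) for u, v in graph.graph.edges)
    P = np.asarray(samples_latent, dtype=float)
    out: list[SampleProjection] = []
    seg_info = []
    for u, v in edges:
        a, b = graph.coords[u], graph.coords[v]
        ab = b - a
        seg_info.append((u, v, a, ab, float(ab @ ab)))
    for k, sid in enumerate(sample_ids):
        x = P[:, k]
        best = None
        for u, v, a, ab, ab2 in seg_info:
            t = 0.0 if ab2 <= 0 else float(np.clip((x - a) @ ab / ab2, 0.0, 1.0))
            point = a + t * ab
            d = float(np.linalg.norm(x - point))
            if best is None or d < best[0] - 1e-15:
                length = graph.edge_length(u, v)
                geo = min(
                    root_dist[u] + t * length,
                    root_dist[v] + (1.0 - t) * length,
                )
                best = (d, (u, v), t, point, geo)
        out.append(SampleProjection(sid, best[1], best[2], best[3], best[4]))
    return out


def assign_states(
    graph: PrincipalTreeGraph,
    root: int,
    projections: list[SampleProjection],
) -> tuple[dict[int, list[tuple[int, int]]], dict[str, int]]:
    """Segment the tree at branch points and assign each sample a state.

    States are numbered 1..S breadth-first from the root, ties at the same
    depth broken by larger sample count first, then by lowest vertex id.
    A sample projected exactly onto a branch point is assigned to the
    segment on its root side.
    """
    segments = _segment_edges(graph, root=root)
    edge_to_seg: dict[tuple[int, int], int] = {}
    for seg_id, run in segments.items():
        for e in run:
            edge_to_seg[e] = seg_id

    root_dist = nx.single_source_dijkstra_path_length(
        graph.graph, root, weight="length"
    )
    branch_points = set(graph.branch_points)

    prelim: dict[str, int] = {}
    for proj in projections:
        u, v = proj.edge
        e = (min(u, v), max(u, v))
        seg = edge_to_seg[e]
        # exactly at a branch point -> segment on the root side
        at_vertex = None
        if proj.offset <= 0.0 and u in branch_points:
            at_vertex = u
        elif proj.offset >= 1.0 and v in branch_points:
            at_vertex = v
        if at_vertex is not None:
            nbrs = list(graph.graph.neighbors(at_vertex))
            toward_root = min(
                nbrs, key=lambda w: (root_dist[w], w)
            )
            e_root = (min(at_vertex, toward_root), max(at_vertex, toward_root))
            seg = edge_to_seg[e_root]
            logger.info(
                "sample %s projected exactly at branch point %d; assigned to "
                "root-side segment", proj.sample_id, at_vertex,
            )
        prelim[proj.sample_id] = seg

    # order segments: BFS depth from root, larger sample count first, vertex id
    counts = {seg: 0 for seg in segments}
    for seg in prelim.values():
        counts[seg] += 1
    depth = {}
    for seg_id, run in segments.items():
        d = min(min(root_dist[u], root_dist[v]) for u, v in run)
        depth[seg_id] = d
    hops = {}
    for seg_id, run in segments.items():
        hops[seg_id] = min(
            min(nx.shortest_path_length(graph.graph, root, u),
                nx.shortest_path_length(graph.graph, root, v))
            for u, v in run
        )
    order = sorted(
        segments,
        key=lambda s: (hops[s], -counts[s], min(min(e) for e in segments[s])),
    )
    renumber = {old: i + 1 for i, old in enumerate(order)}
    states = {renumber[s]: segments[s] for s in segments}
    sample_states = {sid: renumber[s] for sid, s in prelim.items()}
    return states, sample_states


def prune_small_leaf_segments(
    graph: PrincipalTreeGraph,
    root: int,
    samples_latent: np.ndarray,
    sample_ids: list[str],
    min_samples: int,
) -> PrincipalTreeGraph:
    """Iteratively drop leaf twigs carrying fewer than ``min_samples``
    projected samples.

    Spurious short twigs are a known artifact of spanning trees over noisy
    anchors; removing sparsely populated ones stabilizes state segmentation.
    The segment containing the root is never pruned, and the tree always
    keeps at least two leaves.  Samples are re-projected after every
    removal, so a twig's samples flow back onto the backbone.
    """
    g = graph.graph.copy()
    coords = dict(graph.coords)
    while True:
        tree = PrincipalTreeGraph(coords, g)
        if len(tree.leaves) <= 2:
            return tree
        segs = _segment_edges(tree, root=root)
        proj = project_samples(tree, root, samples_latent, sample_ids)
        edge_to_seg = {e: s for s, run in segs.items() for e in run}
        counts = {s: 0 for s in segs}
        for p in proj:
            u, v = p.edge
            counts[edge_to_seg[(min(u, v), max(u, v))]] += 1
        candidates = []
        for seg_id, run in segs.items():
            verts = {v for e in run for v in e}
            if root in verts:
                continue
            if not any(g.degree(v) == 1 for v in verts):
                continue  # interior segment
            if counts[seg_id] < min_samples:
                candidates.append((counts[seg_id], seg_id, verts))
        if not candidates:
            return tree
        _, seg_id, verts = min(candidates)
        attach = {v for v in verts if g.degree(v) >= 3}
        for v in verts - attach:
            g.remove_node(v)
            coords.pop(v, None)


def state_transitions(model: ProgressionModel) -> list[tuple[int, int]]:
    """Successive (earlier, later) state pairs along root-to-leaf paths."""
    # adjacency between states via shared cut vertices, oriented by distance
    root_dist = nx.single_source_dijkstra_path_length(
        model.tree.graph, model.root, weight="length"
    )
    state_depth = {
        s: min(min(root_dist[u], root_dist[v]) for u, v in edges)
        for s, edges in model.states.items()
    }
    vert_states: dict[int, set[int]] = {}
    for s, edges in model.states.items():
        for u, v in edges:
            vert_states.setdefault(u, set()).add(s)
            vert_states.setdefault(v, set()).add(s)
    pairs = set()
    for verts_states in vert_states.values():
        for a in verts_states:
            for b in verts_states:
                if a != b and state_depth[a] < state_depth[b]:
                    pairs.add((a, b))
    return sorted(pairs)


def build_progression_model(
    latent_model: LatentTreeModel,
    normal_sample_ids: list[str] | None = None,
    root_covariate: dict[str, float] | None = None,
    min_segment_samples: int = 0,
    path_names: dict[str, str] | None = None,
) -> ProgressionModel:
    """End-to-end rooted model from a fitted principal tree.

    Root selection uses the normal samples when given, otherwise the most
    mixed segment of ``root_covariate``.  ``min_segment_samples`` > 0 prunes
    sparsely populated leaf twigs before segmentation.
    """
    if latent_model.sample_ids is None:
        raise ValueError("latent model carries no sample ids")
    sample_ids = latent_model.sample_ids
    graph = build_tree_graph(latent_model)
    Y = latent_model.Y

    if normal_sample_ids:
        idx = [sample_ids.index(s) for s in normal_sample_ids]
        root = select_root(graph, Y[:, idx].T)
    elif root_covariate is not None:
        provisional_root = graph.leaves[0]
        proj0 = project_samples(graph, provisional_root, Y, sample_ids)
        states0, seg0 = assign_states(graph, provisional_root, proj0)
        root = select_root_by_covariate(graph, seg0, root_covariate, states0)
    else:
        raise ValueError("need normal samples or a root covariate")

    if min_segment_samples > 0:
        graph = prune_small_leaf_segments(
            graph, root, Y, sample_ids, min_segment_samples
        )
    projections = project_samples(graph, root, Y, sample_ids)

    states, sample_states = assign_states(graph, root, projections)
    distances = {p.sample_id: p.progression_distance for p in projections}

    # terminal sample counts for path naming
    edge_to_state = {
        (min(u, v), max(u, v)): s for s, run in states.items() for u, v in run
    }
    leaf_counts: dict[int, int] = {}
    for leaf in graph.leaves:
        if leaf == root:
            continue
        nb = next(iter(graph.graph.neighbors(leaf)))
        st = edge_to_state[(min(leaf, nb), max(leaf, nb))]
        leaf_counts[leaf] = sum(1 for s in sample_states.values() if s == st)
    paths = extract_paths(graph, root, terminal_counts=leaf_counts)
    if path_names:
        paths = {path_names.get(k, k): v for k, v in paths.items()}

    return ProgressionModel(
        tree=graph, root=root, paths=paths, states=states,
        sample_states=sample_states, sample_distances=distances,
        projections=projections,
    )
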