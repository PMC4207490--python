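"""Network thresholding, the MCL implementation, and hierarchical sub-clustering."""

import random

import numpy as np
import pytest

from bmclocus import SimilarityEdge, build_network, cluster_tree, mcl, subcluster
from bmclocus.cluster import ClusterNode
from bmclocus.scoring import ScoreBreakdown


def breakdown(i, j, score):
    return ScoreBreakdown(
        locus_i=i, locus_j=j, common=frozenset(), only_i=frozenset(),
        only_j=frozenset(), positive=score, negative=0.0,
    )


def reference_mcl(edges, nodes, inflation=2.0, max_iter=200):
    """Independent dense-matrix MCL used as an oracle.

    Plain numpy loops: adjacency with max-incident self-loops, column
    normalization, expansion/inflation to a fixed point, clusters as
    connected components of the limit matrix's nonzero structure.
    """
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for e in edges:
        a[index[e.locus_i], index[e.locus_j]] = e.score
        a[index[e.locus_j], index[e.locus_i]] = e.score
    for i in range(n):
        a[i, i] = a[i].max() if a[i].max() > 0 else 1.0
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < 1e-6] = 0.0
        inflated = inflated / inflated.sum(axis=0)
        if np.abs(inflated - m).max() < 1e-8:
            m = inflated
            break
        m = inflated
    # connected components over the symmetrized support
    support = (m + m.T) > 1e-9
    seen, clusters = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, component = [start], set()
        while stack:
            node = stack.pop()
            if node in component:
                continue
            component.add(node)
            stack.extend(j for j in np.nonzero(support[node])[0] if j not in component)
        seen |= component
        clusters.append(frozenset(nodes[i] for i in component))
    return set(clusters)


def clique_edges(members, weight=1.0):
    return [
        SimilarityEdge(a, b, weight)
        for i, a in enumerate(members)
        for b in members[i + 1:]
    ]


class TestBuildNetwork:
    def test_cutoff_is_inclusive(self):
        breakdowns = [
            breakdown("A", "B", 5.0),
            breakdown("B", "C", 3.0),
            breakdown("A", "C", 2.9),
        ]
        edges, singletons = build_network(breakdowns, score_cutoff=3.0)
        assert len(edges) == 2
        assert singletons == []

    def test_looser_cutoff_gives_superset(self):
        rng = random.Random(1)
        breakdowns = [
            breakdown(f"L{i}", f"L{j}", rng.uniform(-30, 30))
            for i in range(8) for j in range(i + 1, 8)
        ]
        strict, _ = build_network(breakdowns, score_cutoff=3.0)
        loose, _ = build_network(breakdowns, score_cutoff=-20.0)
        assert {(e.locus_i, e.locus_j) for e in strict} <= {
            (e.locus_i, e.locus_j) for e in loose
        }

    def test_empty_breakdowns_give_empty_network(self):
        assert build_network([], 3.0) == ([], [])

    def test_isolated_nodes_reported_as_singletons(self):
        breakdowns = [breakdown("A", "B", 10.0), breakdown("A", "C", -5.0),
                      breakdown("B", "C", -5.0)]
        _, singletons = build_network(breakdowns, 3.0)
        assert singletons == ["C"]


class TestMCL:
    def test_two_disjoint_cliques_recovered(self):
        edges = clique_edges(["a1", "a2", "a3"]) + clique_edges(["b1", "b2", "b3"])
        clusters, converged = mcl(edges, inflation=2.0)
        assert converged
        assert set(clusters) == {
            frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})
        }

    def test_single_clique_is_one_cluster(self):
        edges = clique_edges([f"n{i}" for i in range(6)])
        clusters, _ = mcl(edges, inflation=2.0)
        assert clusters == [frozenset(f"n{i}" for i in range(6))]

    def test_barbell_splits_at_weak_bridge(self):
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        edges = (
            clique_edges(left, 1.0) + clique_edges(right, 1.0)
            + [SimilarityEdge("l0", "r0", 0.1)]
        )
        clusters, _ = mcl(edges, inflation=2.0)
        assert set(clusters) == {frozenset(left), frozenset(right)}
        expected = reference_mcl(edges, sorted(left + right))
        assert set(clusters) == expected

    def test_matches_reference_on_random_graphs(self):
        rng = random.Random(101)
        for trial in range(25):
            n = rng.randint(5, 30)
            nodes = [f"v{i:02d}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        edges.append(
                            SimilarityEdge(nodes[i], nodes[j],
                                           round(rng.uniform(0.5, 5.0), 3))
                        )
            inflation = rng.choice([1.6, 2.0, 2.5, 3.0])
            clusters, _ = mcl(edges, inflation=inflation, nodes=nodes)
            assert set(clusters) == reference_mcl(edges, nodes, inflation)

    def test_partition_covers_all_nodes_disjointly(self):
        rng = random.Random(7)
        nodes = [f"v{i}" for i in range(20)]
        edges = [
            SimilarityEdge(a, b, rng.uniform(0.5, 3.0))
            for a in nodes for b in nodes
            if a < b and rng.random() < 0.2
        ]
        clusters, _ = mcl(edges, inflation=2.0, nodes=nodes)
        seen = [n for c in clusters for n in c]
        assert sorted(seen) == sorted(nodes)

    def test_column_stochastic_through_all_iterations(self):
        rng = random.Random(13)
        nodes = [f"v{i}" for i in range(15)]
        edges = [
            SimilarityEdge(a, b, rng.uniform(0.5, 3.0))
            for a in nodes for b in nodes
            if a < b and rng.random() < 0.3
        ]
        sums = []

        def record(matrix):
            sums.append(np.asarray(matrix.sum(axis=0)).ravel())

        mcl(edges, inflation=2.0, nodes=nodes, on_iteration=record)
        assert sums, "MCL must iterate at least once"
        for s in sums:
            assert np.allclose(s, 1.0, atol=1e-9)

    def test_deterministic_across_runs(self):
        rng = random.Random(19)
        nodes = [f"v{i}" for i in range(12)]
        edges = [
            SimilarityEdge(a, b, rng.uniform(0.5, 3.0))
            for a in nodes for b in nodes
            if a < b and rng.random() < 0.4
        ]
        first, _ = mcl(edges, inflation=2.0, nodes=nodes)
        second, _ = mcl(edges, inflation=2.0, nodes=nodes)
        assert set(first) == set(second)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl([], inflation=1.0)

    def test_negative_cutoff_shifts_weights(self):
        # at an exploratory negative cut-off, weights are shifted to stay
        # positive; disconnected components must still separate
        edges = clique_edges(["a1", "a2"], -5.0) + clique_edges(["b1", "b2"], -5.0)
        clusters, _ = mcl(edges, inflation=2.0, score_cutoff=-20.0)
        assert set(clusters) == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}


class TestSubcluster:
    def _two_subtype_breakdowns(self):
        # one level-1 cluster of 6 with two planted subtypes: 3-cliques at
        # score 30 joined by cross edges at 20 (merged at the top level,
        # separable once the cut-off passes 20)
        tight_a = ["s1", "s2", "s3"]
        tight_b = ["t1", "t2", "t3"]
        out = []
        for group in (tight_a, tight_b):
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    out.append(breakdown(a, b, 30.0))
        for a in tight_a:
            for b in tight_b:
                out.append(breakdown(a, b, 20.0))
        return out, tight_a, tight_b

    def test_recovers_planted_subtypes(self):
        breakdowns, tight_a, tight_b = self._two_subtype_breakdowns()
        parent = ClusterNode(
            name="1", members=frozenset(tight_a + tight_b), level=1,
            inflation=2.0, score_cutoff=3.0,
        )
        children = subcluster(parent, breakdowns, inflation=3.0, score_cutoff=25.0)
        assert {c.members for c in children} == {
            frozenset(tight_a), frozenset(tight_b)
        }
        assert [c.name for c in children] == ["1.1", "1.2"]

    def test_no_split_when_all_scores_exceed_cutoff(self):
        breakdowns = [breakdown("A", "B", 50.0)]
        parent = ClusterNode(name="2", members=frozenset({"A", "B"}), level=1,
                             inflation=2.0, score_cutoff=3.0)
        children = subcluster(parent, breakdowns, inflation=2.0, score_cutoff=40.0)
        assert len(children) == 1
        assert children[0].members == frozenset({"A", "B"})
        assert children[0].name == "2.1"

    def test_stops_beyond_maximum_cutoff(self):
        breakdowns = [breakdown("A", "B", 50.0)]
        parent = ClusterNode(name="2", members=frozenset({"A", "B"}), level=1,
                             inflation=2.0, score_cutoff=3.0)
        assert subcluster(parent, breakdowns, inflation=2.0, score_cutoff=41.0) == []
        assert parent.children == []

    def test_looser_parameters_rejected(self):
        parent = ClusterNode(name="1", members=frozenset({"A", "B"}), level=1,
                             inflation=3.0, score_cutoff=10.0)
        with pytest.raises(ValueError, match="looser"):
            subcluster(parent, [], inflation=3.0, score_cutoff=5.0)


class TestClusterTree:
    def test_dotted_names_two_levels_deep(self):
        breakdowns, tight_a, tight_b = TestSubcluster()._two_subtype_breakdowns()
        # a second, separate top-level cluster
        breakdowns += [breakdown("u1", "u2", 30.0)]
        for a in ("u1", "u2"):
            for b in tight_a + tight_b:
                breakdowns.append(breakdown(a, b, -10.0))
        tree = cluster_tree(
            breakdowns, plan={"root": (2.0, 3.0), "1": (3.0, 25.0)}
        )
        assert [c.name for c in tree.children] == ["1", "2"]
        node1 = tree.find("1")
        assert {c.name for c in node1.children} == {"1.1", "1.2"}
        # children partition the parent
        merged = frozenset().union(*(c.members for c in node1.children))
        assert merged == node1.members

    def test_singletons_kept_as_singleton_clusters(self):
        breakdowns = [
            breakdown("A", "B", 10.0),
            breakdown("A", "C", -5.0),
            breakdown("B", "C", -5.0),
        ]
        tree = cluster_tree(breakdowns, plan={"root": (2.0, 3.0)})
        sizes = sorted(len(c.members) for c in tree.children)
        assert sizes == [1, 2]

    def test_clusters_ordered_by_size_then_smallest_member(self):
        breakdowns = (
            [breakdown(a, b, 10.0) for a, b in [("z1", "z2"), ("z1", "z3"), ("z2", "z3")]]
            + [breakdown("a1", "a2", 10.0)]
            + [breakdown(x, y, -10.0) for x in ("z1", "z2", "z3") for y in ("a1", "a2")]
        )
        tree = cluster_tree(breakdowns, plan={"root": (2.0, 3.0)})
        assert [sorted(c.members)[0] for c in tree.children] == ["z1", "a1"]
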