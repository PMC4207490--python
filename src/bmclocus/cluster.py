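"""Similarity-network construction and hierarchical Markov clustering.

Edges at or above a score cut-off form an undirected weighted network that
is clustered with the Markov Cluster Algorithm (MCL): alternating expansion
(matrix squaring) and inflation (elementwise power followed by column
renormalization) of a column-stochastic matrix until convergence, reading
clusters from the attractor rows.  Higher inflation yields finer clusters.

Clusters are sub-clustered at stricter (inflation, cut-off) pairs following
a user-supplied plan, producing dotted names that record lineage: the first
child of cluster "1" is "1.1".  Sub-clustering stops once the cut-off needed
would exceed 40 — at that tightness the members are nearly identical loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("bmclocus")

#: sub-clustering is never attempted beyond this score cut-off
MAX_SUBCLUSTER_CUTOFF = 40.0

#: default clustering plan: top level at inflation 2 / cut-off 3, with the
#: per-cluster refinement schedule used for the published hierarchy
DEFAULT_PLAN: dict[str, tuple[float, float]] = {
    "root": (2.0, 3.0),
    "1": (3.0, 10.0),
    "2": (2.5, 10.0),
    "2.1": (3.0, 20.0),
    "2.1.1": (3.0, 40.0),
    "3": (2.0, 15.0),
    "3.2": (3.0, 25.0),
    "4": (3.0, 10.0),
}


@dataclass(frozen=True)
class SimilarityEdge:
    locus_i: str
    locus_j: str
    score: float


@dataclass
class ClusterNode:
    """A node of the hierarchical clustering tree with a dotted name."""

    name: str
    members: frozenset[str]
    level: int
    inflation: Optional[float] = None
    score_cutoff: Optional[float] = None
    children: list["ClusterNode"] = field(default_factory=list)
    converged: bool = True

    def find(self, name: str) -> Optional["ClusterNode"]:
        if self.name == name:
            return self
        for child in self.children:
            found = child.find(name)
            if found is not None:
                return found
        return None

    def leaves(self) -> list["ClusterNode"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def build_network(
    breakdowns: Iterable, score_cutoff: float
) -> tuple[list[SimilarityEdge], list[str]]:
    """Threshold pairwise scores into edges; the cut-off is inclusive (>=).

    Returns the qualifying edges and the nodes left without any qualifying
    edge (singletons).
    """
    edges: list[SimilarityEdge] = []
    nodes: set[str] = set()
    connected: set[str] = set()
    for b in breakdowns:
        nodes.update((b.locus_i, b.locus_j))
        if b.score >= score_cutoff:
            edges.append(SimilarityEdge(b.locus_i, b.locus_j, b.score))
            connected.update((b.locus_i, b.locus_j))
    singletons = sorted(nodes - connected)
    return edges, singletons


def _mcl_matrix(
    edges: Sequence[SimilarityEdge], nodes: Sequence[str], score_cutoff: float
) -> sp.csc_matrix:
    """Build the column-stochastic start matrix with self-loops.

    Weights are the raw scores when the cut-off is positive; for exploratory
    non-positive cut-offs scores are shifted by (1 - cutoff) so all weights
    stay positive (MCL requires non-negative weights).  The self-loop weight
    is each node's maximum incident edge weight (1 for isolated nodes).
    """
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adjacency = sp.lil_matrix((n, n))
    for edge in edges:
        w = edge.score if score_cutoff > 0 else edge.score - score_cutoff + 1.0
        if w <= 0:
            raise ValueError(
                f"non-positive MCL weight {w} on edge ({edge.locus_i}, {edge.locus_j})"
            )
        i, j = index[edge.locus_i], index[edge.locus_j]
        adjacency[i, j] = w
        adjacency[j, i] = w
    max_incident = adjacency.tocsr().max(axis=1).toarray().ravel()
    loops = np.where(max_incident > 0, max_incident, 1.0)
    matrix = (adjacency + sp.diags(loops)).tocsc()
    # column normalization
    sums = np.asarray(matrix.sum(axis=0)).ravel()
    return (matrix @ sp.diags(1.0 / sums)).tocsc()


def _normalize_columns(matrix: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(matrix.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    return (matrix @ sp.diags(1.0 / sums)).tocsc()


def _interpret(matrix: sp.csc_matrix, nodes: Sequence[str]) -> list[frozenset[str]]:
    """Read clusters from attractor rows; overlapping rows are merged."""
    n = len(nodes)
    csr = matrix.tocsr()
    diag = csr.diagonal()
    attractors = np.nonzero(diag > 1e-9)[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    claimed = np.zeros(n, dtype=bool)
    for a in attractors:
        row = csr.getrow(a)
        for j in row.indices:
            union(int(j), int(a))
            claimed[j] = True
        claimed[a] = True
    # a node not claimed by any attractor row joins its strongest column mass
    csc = matrix.tocsc()
    for j in np.nonzero(~claimed)[0]:
        col = csc.getcol(int(j))
        if col.nnz:
            best = col.indices[np.argmax(col.data)]
            union(int(j), int(best))
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(nodes[i])
    return [frozenset(g) for g in groups.values()]


def mcl(
    edges: Sequence[SimilarityEdge],
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    convergence: float = 1e-8,
    nodes: Optional[Sequence[str]] = None,
    score_cutoff: float = 1.0,
    on_iteration=None,
) -> tuple[list[frozenset[str]], bool]:
    """Markov clustering of a weighted undirected network.

    Alternates expansion (matrix square) and inflation (elementwise power
    ``inflation`` then column renormalization), pruning entries below
    ``tol``, until the matrix changes by less than ``convergence`` in
    max-norm.  Returns the partition (every node in exactly one cluster) and
    a convergence flag; on non-convergence the current interpretation is
    returned with a warning.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    node_list = list(nodes) if nodes is not None else sorted(
        {e.locus_i for e in edges} | {e.locus_j for e in edges}
    )
    if not node_list:
        return [], True
    matrix = _mcl_matrix(edges, node_list, score_cutoff)
    converged = False
    for _ in range(max_iter):
        expanded = (matrix @ matrix).tocsc()
        inflated = expanded.power(inflation)
        inflated.data[inflated.data < tol] = 0.0
        inflated.eliminate_zeros()
        inflated = _normalize_columns(inflated)
        delta = abs(inflated - matrix)
        change = delta.max() if delta.nnz else 0.0
        matrix = inflated
        if on_iteration is not None:
            on_iteration(matrix)
        if change < convergence:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge after %d iterations", max_iter)
    return _interpret(matrix, node_list), converged


def _sorted_clusters(clusters: list[frozenset[str]]) -> list[frozenset[str]]:
    """Order clusters by descending size, then lexicographic smallest member."""
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def _cluster_members(
    breakdowns: Sequence,
    members: frozenset[str],
    inflation: float,
    score_cutoff: float,
) -> tuple[list[frozenset[str]], bool]:
    restricted = [
        b for b in breakdowns if b.locus_i in members and b.locus_j in members
    ]
    edges, singletons = build_network(restricted, score_cutoff)
    parts, converged = mcl(
        edges,
        inflation=inflation,
        nodes=sorted({e.locus_i for e in edges} | {e.locus_j for e in edges}),
        score_cutoff=score_cutoff,
    )
    parts = list(parts) + [frozenset({s}) for s in singletons]
    # nodes with no scored pair at all (restricted breakdown may miss them)
    seen = set().union(*parts) if parts else set()
    parts += [frozenset({m}) for m in sorted(members - seen)]
    return parts, converged


def subcluster(
    parent: ClusterNode,
    breakdowns: Sequence,
    inflation: float,
    score_cutoff: float,
    max_cutoff: float = MAX_SUBCLUSTER_CUTOFF,
) -> list[ClusterNode]:
    """Split a cluster at stricter parameters; children named parent.1, parent.2 ...

    The cut-off must be at least the parent's (never looser) and at most
    ``max_cutoff``; beyond that the cluster holds nearly identical loci and
    is not divided further.
    """
    if len(parent.members) < 2:
        raise ValueError(f"cluster {parent.name} has < 2 members; nothing to split")
    if parent.score_cutoff is not None and score_cutoff < parent.score_cutoff:
        raise ValueError(
            f"sub-clustering cut-off {score_cutoff} is looser than parent's "
            f"{parent.score_cutoff}"
        )
    if score_cutoff > max_cutoff:
        logger.warning(
            "cut-off %s for %s exceeds %s; cluster left undivided",
            score_cutoff, parent.name, max_cutoff,
        )
        return []
    parts, converged = _cluster_members(
        breakdowns, parent.members, inflation, score_cutoff
    )
    children = [
        ClusterNode(
            name=f"{parent.name}.{i}",
            members=part,
            level=parent.level + 1,
            inflation=inflation,
            score_cutoff=score_cutoff,
            converged=converged,
        )
        for i, part in enumerate(_sorted_clusters(parts), start=1)
    ]
    parent.children = children
    return children


def cluster_tree(
    breakdowns: Sequence,
    plan: Optional[Mapping[str, tuple[float, float]]] = None,
) -> ClusterNode:
    """Cluster the full network hierarchically following a plan.

    The plan maps cluster names to (inflation, score_cutoff); the ``root``
    entry clusters the whole network, and every named entry whose cluster
    exists and has >= 2 members is sub-divided.  Singletons are kept as
    singleton clusters at each level.
    """
    plan = dict(plan) if plan is not None else dict(DEFAULT_PLAN)
    if "root" not in plan:
        raise ValueError("clustering plan must contain a 'root' entry")
    all_nodes = frozenset(
        {b.locus_i for b in breakdowns} | {b.locus_j for b in breakdowns}
    )
    root_inflation, root_cutoff = plan["root"]
    root = ClusterNode(
        name="root", members=all_nodes, level=0,
        inflation=root_inflation, score_cutoff=root_cutoff,
    )
    parts, converged = _cluster_members(
        breakdowns, all_nodes, root_inflation, root_cutoff
    )
    root.children = [
        ClusterNode(
            name=str(i), members=part, level=1,
            inflation=root_inflation, score_cutoff=root_cutoff, converged=converged,
        )
        for i, part in enumerate(_sorted_clusters(parts), start=1)
    ]
    # refine named clusters breadth-first so dotted lineage stays consistent
    pending = list(root.children)
    while pending:
        node = pending.pop(0)
        if node.name in plan and len(node.members) >= 2:
            inflation, cutoff = plan[node.name]
            pending.extend(
                subcluster(node, breakdowns, inflation, cutoff)
            )
    return root
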