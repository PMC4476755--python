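"""Graph partitioning: connected components, modularity, Louvain.

Modularity of a partition into k communities is computed from the k x k
fraction matrix e, where e_ii is the fraction of edge weight inside
community i and each cross-community edge contributes half its fraction to
e_ij and half to e_ji:

    Q = sum_i (e_ii - a_i^2),   a_i = sum_j e_ij.

Louvain community detection is the two-phase greedy of Blondel et al.:
repeated local moves of single vertices to the neighboring community with
the largest positive modularity gain, followed by aggregation of the
partition into a weighted quotient graph, iterated until no gain remains.
The vertex sweep order is ascending index by default (bit-for-bit
reproducible runs); a seeded shuffle is available.  Because moves only
follow edges, every detected community lies inside a single connected
component — detection on the whole graph automatically refines the
component partition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .triad_graph import TriadGraph


@dataclass
class CommunityAssignment:
    """Partition of the graph's vertices with its modularity Q.

    ``level`` records the resolution: "components" (maximal connected
    subgraphs) or "louvain" (modularity-optimized communities).
    """

    samples: list[str]
    membership: np.ndarray  # (n,) consecutive integer labels from 0
    modularity: float | None
    level: str

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)
        labels = np.unique(self.membership)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValueError("community labels must be consecutive integers from 0")
        if self.modularity is not None and not -1.0 <= self.modularity <= 1.0:
            raise ValueError(f"modularity {self.modularity} outside [-1, 1]")

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_communities)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for s, c in zip(self.samples, self.membership):
                fh.write(f"{s}\t{c}\n")


def _canonical_labels(membership: np.ndarray) -> np.ndarray:
    """Relabel communities consecutively, ordered by smallest member vertex."""
    order: dict[int, int] = {}
    for lab in membership:
        if lab not in order:
            order[lab] = len(order)
    return np.asarray([order[lab] for lab in membership], dtype=np.int64)


def connected_components(g: TriadGraph) -> CommunityAssignment:
    """Unconnected components of the graph, labeled by smallest vertex index."""
    n = g.n
    if g.n_edges:
        u, v = g.edges[:, 0], g.edges[:, 1]
        adj = coo_matrix((np.ones(g.n_edges), (u, v)), shape=(n, n))
        _, labels = _cc(adj, directed=False)
    else:
        labels = np.arange(n)
    labels = _canonical_labels(labels)
    q = modularity(g, _bare_assignment(g, labels, "components")) if g.n_edges else None
    return CommunityAssignment(g.samples, labels, q, "components")


def _bare_assignment(g: TriadGraph, labels: np.ndarray, level: str) -> CommunityAssignment:
    return CommunityAssignment(g.samples, labels, None, level)


def modularity(g: TriadGraph, a: CommunityAssignment) -> float:
    """Q = sum_i (e_ii - a_i^2) over the partition's fraction matrix."""
    if g.n_edges == 0:
        raise ValueError("modularity is undefined on a graph with no edges")
    if a.membership.shape[0] != g.n:
        raise ValueError("assignment does not cover all vertices")
    w = g.weights()
    total = w.sum()
    labels = a.membership
    k = a.n_communities
    e_diag = np.zeros(k)
    a_row = np.zeros(k)
    cu, cv = labels[g.edges[:, 0]], labels[g.edges[:, 1]]
    same = cu == cv
    np.add.at(e_diag, cu[same], w[same] / total)
    # cross edges: half a fraction to each of e_ij and e_ji -> each endpoint
    # community's row sum gains w/(2*total)
    np.add.at(a_row, cu, np.where(same, w, w / 2.0) / total)
    np.add.at(a_row, cv[~same], w[~same] / 2.0 / total)
    return float(np.sum(e_diag - a_row**2))


# ---------------------------------------------------------------------------
# Louvain


def _one_level(n: int, adj: list[dict[int, float]], loops: np.ndarray,
               m2: float, order: list[int]) -> np.ndarray:
    """One local-moving phase; returns (possibly non-consecutive) labels."""
    comm = np.arange(n)
    k = np.array([sum(a.values()) for a in adj]) + 2.0 * loops
    sigma_tot = k.copy()
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = comm[i]
            # weight from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            sigma_tot[ci] -= k[i]
            base = links.get(ci, 0.0) - k[i] * sigma_tot[ci] / m2
            best_c, best_gain = ci, base
            # sorted sweep of candidate communities: on tied gains the
            # smallest label wins, and staying beats moving (strict gain)
            for c in sorted(links):
                if c == ci:
                    continue
                gain = links[c] - k[i] * sigma_tot[c] / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                comm[i] = best_c
                improved = True
    return comm


def _aggregate(adj: list[dict[int, float]], loops: np.ndarray,
               comm: np.ndarray) -> tuple[list[dict[int, float]], np.ndarray, np.ndarray]:
    labels = _canonical_labels(comm)
    k = labels.max() + 1
    new_adj: list[dict[int, float]] = [dict() for _ in range(k)]
    new_loops = np.zeros(k)
    for i, a in enumerate(adj):
        ci = labels[i]
        new_loops[ci] += loops[i]
        for j, w in a.items():
            if j <= i:
                continue
            cj = labels[j]
            if ci == cj:
                new_loops[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_loops, labels


def louvain(g: TriadGraph, seed: int | None = None, shuffle: bool = False,
            check_library: bool = True) -> CommunityAssignment:
    """Louvain community detection on the triad graph.

    Parameters
    ----------
    g
        Graph with at least one edge.
    seed
        Seeds the sweep-order shuffle when ``shuffle`` is true; otherwise
        unused (the default ascending sweep order is fully deterministic).
    shuffle
        Randomize the vertex sweep order per level.
    check_library
        Cross-check this module's modularity value against python-igraph's
        on the returned partition (cheap; on by default).
    """
    if g.n_edges == 0:
        raise ValueError("Louvain requires a graph with at least one edge")
    rng = random.Random(seed)
    adj = g.adjacency()
    loops = np.zeros(g.n)
    m2 = float(sum(sum(a.values()) for a in adj))  # = 2 * total edge weight
    mapping = np.arange(g.n)
    while True:
        n_cur = len(adj)
        order = list(range(n_cur))
        if shuffle:
            rng.shuffle(order)
        comm = _one_level(n_cur, adj, loops, m2, order)
        adj, loops, labels = _aggregate(adj, loops, comm)
        mapping = labels[mapping]
        if len(adj) == n_cur:
            break
    final = _canonical_labels(mapping)
    assignment = CommunityAssignment(g.samples, final, None, "louvain")
    q = modularity(g, assignment)
    if check_library:
        _assert_matches_igraph(g, final, q)
    assignment.modularity = q
    return assignment


def _assert_matches_igraph(g: TriadGraph, membership: np.ndarray, q: float) -> None:
    import igraph as ig

    gg = ig.Graph(n=g.n, edges=[tuple(e) for e in g.edges])
    q_ref = gg.modularity(list(membership), weights=list(g.weights()))
    if abs(q - q_ref) > 1e-9:
        raise AssertionError(
            f"modularity mismatch vs igraph: {q} != {q_ref}")
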