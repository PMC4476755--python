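"""Triad construction: rank-based closest-pair search and graph assembly.

For each individual i, all others are ranked by their covariance with i
(rank 1 = most similar; ties get the average of the tied positions).  The
triad of i is then built in two steps:

* step 1 picks the partner j minimizing ``rank_i[j] + rank_j[i]`` — a
  two-sided closeness criterion;
* step 2 picks the third member k minimizing
  ``rank_i[k] + rank_k[i] + rank_j[k] + rank_k[j]``, i.e. a k close to
  both members of the dyad.

Merging the n triangles yields a graph on n vertices with at most 3n
edges; by default duplicate edges collapse into a simple graph
(multiplicities are retained and can be used as edge weights).
Everything downstream depends on the covariances only through the ranks,
so the construction is invariant under any positive rescaling of the
similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .similarity import SimilarityMatrix


@dataclass
class RankTable:
    """Per-individual average ranks of all others by descending covariance.

    ``ranks[i, j]`` is the position of j in i's ordering (1 = highest
    covariance with i); the diagonal is +inf so that self is never a
    minimizer.
    """

    samples: list[str]
    ranks: np.ndarray  # (n, n), diagonal +inf

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    def mutual(self) -> np.ndarray:
        """Symmetric two-sided closeness ``ranks + ranks.T`` (diagonal +inf)."""
        return self.ranks + self.ranks.T


@dataclass(frozen=True)
class Triad:
    """One anchored triangle: anchor i, step-1 partner j, step-2 third k."""

    anchor: int
    partner: int
    third: int

    def __post_init__(self) -> None:
        if len({self.anchor, self.partner, self.third}) != 3:
            raise ValueError("triad members must be pairwise distinct")

    def edges(self) -> list[tuple[int, int]]:
        i, j, k = self.anchor, self.partner, self.third
        return [tuple(sorted(e)) for e in ((i, j), (j, k), (i, k))]


@dataclass
class TriadGraph:
    """Simple undirected graph on the n individuals, merged from n triads."""

    samples: list[str]
    edges: np.ndarray            # (E, 2) int, each row sorted, rows unique+sorted
    multiplicity: np.ndarray     # (E,) how many triads contributed each edge
    triads: list[Triad] = field(default_factory=list)
    weighted: bool = False       # if True, downstream uses multiplicity as weight

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def weights(self) -> np.ndarray:
        if self.weighted:
            return self.multiplicity.astype(np.float64)
        return np.ones(self.n_edges, dtype=np.float64)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> list[dict[int, float]]:
        """Adjacency as neighbor->weight dicts (no self loops)."""
        adj: list[dict[int, float]] = [dict() for _ in range(self.n)]
        w = self.weights()
        for (u, v), wt in zip(self.edges, w):
            adj[u][v] = adj[u].get(v, 0.0) + wt
            adj[v][u] = adj[v].get(u, 0.0) + wt
        return adj

    def write_edgelist(self, path: str) -> None:
        with open(path, "w") as fh:
            for u, v in self.edges:
                fh.write(f"{self.samples[u]}\t{self.samples[v]}\n")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.samples)
        for (u, v), m in zip(self.edges, self.multiplicity):
            g.add_edge(self.samples[u], self.samples[v], multiplicity=int(m))
        return g

    def write_graphml(self, path: str) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def rank_individuals(d: SimilarityMatrix) -> RankTable:
    """Rank, for each i, all j != i by descending covariance with i.

    Ties receive average ranks (so each row of ranks sums to n(n-1)/2).
    """
    n = d.n
    if n < 3:
        raise ValueError("triads require at least 3 individuals")
    ranks = np.full((n, n), np.inf)
    others_mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        vals = d.values[i, others_mask[i]]
        ranks[i, others_mask[i]] = rankdata(-vals, method="average")
    return RankTable(d.samples, ranks)


def closest_partner(i: int, r: RankTable) -> int:
    """Step 1: the j minimizing rank_i[j] + rank_j[i]; ties -> smallest index."""
    s = r.ranks[i] + r.ranks[:, i]
    return int(np.argmin(s))


def third_member(i: int, j: int, r: RankTable) -> int:
    """Step 2: the k (distinct from i, j) minimizing the four-way rank sum
    rank_i[k] + rank_k[i] + rank_j[k] + rank_k[j]; ties -> smallest index."""
    if i == j:
        raise ValueError("i and j must differ")
    t = (r.ranks[i] + r.ranks[:, i]) + (r.ranks[j] + r.ranks[:, j])
    t[i] = np.inf
    t[j] = np.inf
    return int(np.argmin(t))


def build_triad_graph(d: SimilarityMatrix, keep_multiplicity: bool = False) -> TriadGraph:
    """Build one triad per individual and merge them into the network.

    Each individual anchors its own triad (so swapping roles may give a
    different partner); the union of the 3n triangle edges is returned with
    duplicates collapsed.  With ``keep_multiplicity`` the edge
    multiplicities act as weights in downstream community detection.
    """
    r = rank_individuals(d)
    n = r.n
    s = r.mutual()
    partners = np.argmin(s, axis=1)  # ties: argmin picks the smallest index
    triads = []
    for i in range(n):
        j = int(partners[i])
        t = s[i] + s[j]
        t[i] = np.inf
        t[j] = np.inf
        k = int(np.argmin(t))
        triads.append(Triad(i, j, k))
    edge_count: dict[tuple[int, int], int] = {}
    for tr in triads:
        for e in tr.edges():
            edge_count[e] = edge_count.get(e, 0) + 1
    ordered = sorted(edge_count)
    edges = np.asarray(ordered, dtype=np.int64).reshape(-1, 2)
    mult = np.asarray([edge_count[e] for e in ordered], dtype=np.int64)
    return TriadGraph(d.samples, edges, mult, triads, weighted=keep_multiplicity)
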