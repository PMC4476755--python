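"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive the triad construction and
graph quantities from first principles (literal rank counting, exhaustive
minimization, boolean transitive closure) so tests compare two independent
routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest

from trianet.similarity import SimilarityMatrix


# ---------------------------------------------------------------------------
# triad-construction oracle: literal two-step rank minimization


def oracle_ranks(cov: np.ndarray, i: int) -> dict[int, float]:
    """Average rank of each j != i by descending covariance with i,
    computed by literal counting (1 + #greater + (#tied - 1)/2)."""
    n = cov.shape[0]
    ranks = {}
    for j in range(n):
        if j == i:
            continue
        greater = sum(1 for k in range(n) if k != i and cov[i, k] > cov[i, j])
        tied = sum(1 for k in range(n) if k != i and cov[i, k] == cov[i, j])
        ranks[j] = greater + 1 + (tied - 1) / 2.0
    return ranks

def oracle_triads(cov: np.ndarray) -> list[tuple[int, int, int]]:
    """Exhaustive two-step minimization for every anchor i."""
    n = cov.shape[0]
    all_ranks = [oracle_ranks(cov, i) for i in range(n)]
    triads = []
    for i in range(n):
        best_j, best = None, np.inf
        for j in range(n):
            if j == i:
                continue
            val = all_ranks[i][j] + all_ranks[j][i]
            if val < best:
                best_j, best = j, val
        j = best_j
        best_k, best = None, np.inf
        for k in range(n):
            if k in (i, j):
                continue
            val = (all_ranks[i][k] + all_ranks[k][i]
                   + all_ranks[j][k] + all_ranks[k][j])
            if val < best:
                best_k, best = k, val
        triads.append((i, j, best_k))
    return triads


def oracle_edges(triads) -> set[tuple[int, int]]:
    out = set()
    for i, j, k in triads:
        out |= {tuple(sorted(e)) for e in ((i, j), (j, k), (i, k))}
    return out


def oracle_components(n: int, edges) -> np.ndarray:
    """Connected components via boolean transitive closure."""
    reach = np.eye(n, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
    for _ in range(n):
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    labels = np.full(n, -1)
    nxt = 0
    for v in range(n):
        if labels[v] < 0:
            labels[np.where(reach[v])[0]] = nxt
            nxt += 1
    return labels


# ---------------------------------------------------------------------------
# helpers


def random_similarity(n: int, rng: np.random.Generator) -> SimilarityMatrix:
    a = rng.normal(size=(n, n))
    d = (a + a.T) / 2.0
    return SimilarityMatrix([f"S{i}" for i in range(n)], d)


def block_similarity(sizes, within: float, between: float,
                     jitter: float = 0.0, rng=None) -> SimilarityMatrix:
    """Block-structured covariance: strong within blocks, weak across."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.normal(scale=jitter, size=(n, n))
        d = d + (noise + noise.T) / 2.0
    np.fill_diagonal(d, within)
    return SimilarityMatrix([f"S{i}" for i in range(n)], d)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0
chr1\t300\trs3\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
chr1\t400\trs4\tGTT\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
"""


@pytest.fixture()
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return str(path)
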