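"""Experiment grid: simulate, infer structure, association-test, summarize.

``run_experiment`` reproduces the simulation-study surface: per replicate
it simulates a training study, infers population substructure from the
training SNPs (covariance -> triad graph -> connected components and
Louvain communities; principal components from the same covariance), then
streams batches of test SNPs from each category through the association
scan for every correction arm and averages the significant fractions over
replicates.

Correction arms are named ``naive`` (no covariates), ``pcs:K`` (top-K
principal components), ``components`` (connected-component dummies) and
``communities`` (Louvain-community dummies).  An arm whose covariate set
comes out empty (a single community) degrades to the naive model with a
logged notice.

``contingency`` cross-tabulates a detected partition against truth labels
and reports the majority-label precision; ``plot_network`` draws the graph
with truth-colored nodes and a convex hull around each community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (AssociationError, CovariateSet, NullModel,
                          dummy_encode, fit_null, logistic_assoc, score_scan)
from .communities import CommunityAssignment, connected_components, louvain
from .popsim import (CATEGORIES, ScenarioSpec, SimulatedStudy,
                     simulate_study, simulate_test_snps, with_seed)
from .similarity import covariance_matrix, normalize_genotypes, principal_components
from .triad_graph import build_triad_graph

logger = logging.getLogger(__name__)

KNOWN_ARMS = ("naive", "components", "communities")  # plus "pcs:K"


@dataclass
class ExperimentResult:
    """Averaged significant fractions per (method x SNP category)."""

    spec: ScenarioSpec
    table: pd.DataFrame       # method, category, prop_significant, n_flagged, reps
    per_replicate: pd.DataFrame
    alpha: float

    def proportion(self, method: str, category: str) -> float:
        t = self.table
        row = t[(t["method"] == method) & (t["category"] == category)]
        if row.empty:
            raise KeyError(f"no cell for ({method}, {category})")
        return float(row["prop_significant"].iloc[0])


def _parse_arm(arm: str) -> tuple[str, int | None]:
    if arm.startswith("pcs:"):
        return "pcs", int(arm.split(":", 1)[1])
    if arm not in KNOWN_ARMS:
        raise ValueError(f"unknown correction arm {arm!r}")
    return arm, None


def infer_structure(study: SimulatedStudy, seed: int | None = None,
                    n_pcs: int = 10,
                    want: tuple[str, ...] = ("components", "communities", "pcs")
                    ) -> dict:
    """Training SNPs -> covariance -> triad graph -> partitions and PCs.

    ``want`` restricts which derived structures are computed (the
    covariance and triad graph are always built).
    """
    x = normalize_genotypes(study.genotypes)
    d = covariance_matrix(x, study.genotypes.samples)
    graph = build_triad_graph(d)
    out = {"covariance": d, "graph": graph}
    if "components" in want:
        out["components"] = connected_components(graph)
    if "communities" in want:
        out["communities"] = louvain(graph, seed=seed)
    if "pcs" in want:
        out["pcs"] = principal_components(d, n_pcs)
    return out


def _arm_covariates(arm: str, structure: dict | None, n: int) -> CovariateSet:
    name, k = _parse_arm(arm)
    if name == "naive":
        return CovariateSet.none(n)
    if structure is None:
        raise ValueError(f"arm {arm!r} needs inferred structure")
    if name == "pcs":
        pcs = structure["pcs"]
        if k > pcs.vectors.shape[1]:
            raise ValueError(f"only {pcs.vectors.shape[1]} PCs available, need {k}")
        return CovariateSet(pcs.vectors[:, :k], kind="pcs", source=f"top {k} PCs",
                            names=[f"PC{j + 1}" for j in range(k)])
    assignment: CommunityAssignment = structure[name]
    covars = dummy_encode(assignment)
    if covars.q == 0:
        logger.info("arm %r has a single community; degrading to naive", arm)
    return covars


def _validate_scan(g: np.ndarray, y: np.ndarray, covars: CovariateSet,
                   null: NullModel, rng: np.random.Generator,
                   n_check: int = 1000) -> None:
    """Spot-check score-test p-values against per-SNP LRT fits."""
    m = g.shape[1]
    idx = rng.choice(m, size=min(n_check, m), replace=False)
    p_score, tested = score_scan(g[:, idx], y, null)
    res = logistic_assoc(g[:, idx], y, covars, method="lrt")
    ok = tested & res.table["converged"].to_numpy()
    if ok.any():
        gap = np.abs(p_score[ok] - res.table["p"].to_numpy()[ok]).max()
        logger.info("score-vs-LRT spot check on %d SNPs: max |dp| = %.2e",
                    int(ok.sum()), gap)


def run_experiment(spec: ScenarioSpec,
                   methods: list[str],
                   n_train: int = 10_000,
                   n_test: int = 200_000,
                   reps: int = 2,
                   alpha: float = 1e-4,
                   rel_risk: float = 1.5,
                   categories: tuple[str, ...] = CATEGORIES,
                   seed: int | None = None,
                   batch_size: int = 25_000,
                   n_pcs: int = 10,
                   validate: bool = True) -> ExperimentResult:
    """Run the scenario x correction-method x SNP-category grid.

    Every arm sees the same simulated studies and the same test SNPs within
    a replicate, so between-arm comparisons are paired.  Test SNPs are
    generated and scored in batches to bound memory.
    """
    for arm in methods:
        _parse_arm(arm)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = np.random.default_rng(seed)
    needs_structure = any(m != "naive" for m in methods)
    max_k = max([k for m in methods for nm, k in [_parse_arm(m)] if nm == "pcs"],
                default=0)
    rows = []
    for rep in range(reps):
        rep_seed = int(master.integers(2**31))
        study = simulate_study(with_seed(spec, rep_seed), n_train)
        structure = None
        if needs_structure:
            want = tuple(dict.fromkeys(
                _parse_arm(m)[0] for m in methods if m != "naive"))
            structure = infer_structure(study, seed=rep_seed,
                                        n_pcs=max(n_pcs, max_k), want=want)
        y = study.phenotype
        nulls: dict[str, tuple[CovariateSet, NullModel]] = {}
        for arm in methods:
            covars = _arm_covariates(arm, structure, spec.n)
            try:
                nulls[arm] = (covars, fit_null(y, covars))
            except AssociationError as exc:
                raise AssociationError(f"null fit failed for arm {arm!r}: {exc}")
        validated = not validate
        for category in categories:
            counts = {arm: 0 for arm in methods}
            flagged = {arm: 0 for arm in methods}
            tested_n = {arm: 0 for arm in methods}
            remaining = n_test
            while remaining > 0:
                m_batch = min(batch_size, remaining)
                remaining -= m_batch
                batch_seed = int(master.integers(2**31))
                gm = simulate_test_snps(category, study, m_batch,
                                        rel_risk=rel_risk, seed=batch_seed)
                g = gm.dosages.astype(np.float64)
                for arm in methods:
                    covars, null = nulls[arm]
                    p, tested = score_scan(g, y, null)
                    counts[arm] += int((p[tested] < alpha).sum())
                    tested_n[arm] += int(tested.sum())
                    flagged[arm] += int((~tested).sum())
                if not validated:
                    _validate_scan(g, y, *nulls[methods[0]],
                                   np.random.default_rng(batch_seed))
                    validated = True
            for arm in methods:
                rows.append({
                    "replicate": rep, "method": arm, "category": category,
                    "prop_significant": counts[arm] / max(tested_n[arm], 1),
                    "n_flagged": flagged[arm], "n_tested": tested_n[arm],
                })
    per_rep = pd.DataFrame(rows)
    table = (per_rep.groupby(["method", "category"], as_index=False)
             .agg(prop_significant=("prop_significant", "mean"),
                  n_flagged=("n_flagged", "sum"),
                  reps=("replicate", "nunique")))
    return ExperimentResult(spec, table, per_rep, alpha)


@dataclass
class ContingencyTable:
    """Detected communities (rows) vs truth labels (columns)."""

    counts: pd.DataFrame
    precision: float

    def __str__(self) -> str:
        return f"{self.counts}\nprecision = {self.precision:.4f}"


def contingency(a: CommunityAssignment, truth) -> ContingencyTable:
    """Cross-tabulate the partition against truth; precision is the fraction
    of individuals in their community's majority truth label."""
    truth = np.asarray(truth)
    if len(truth) != len(a.membership):
        raise ValueError("truth labels must cover all individuals")
    counts = pd.crosstab(pd.Series(a.membership, name="community"),
                         pd.Series(truth, name="truth"))
    precision = float(counts.max(axis=1).sum() / len(truth))
    return ContingencyTable(counts, precision)


def plot_network(g, a: CommunityAssignment, truth=None, path: str = "network.png",
                 seed: int = 0) -> str:
    """Force-directed plot: nodes colored by truth label, one convex-hull
    polygon per detected community, edges hidden."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx
    from scipy.spatial import ConvexHull

    nxg = g.to_networkx()
    pos = nx.spring_layout(nxg, seed=seed)
    xy = np.asarray([pos[s] for s in g.samples])
    fig, ax = plt.subplots(figsize=(7, 7))
    if truth is not None:
        truth = np.asarray(truth)
        levels = {t: i for i, t in enumerate(pd.unique(truth))}
        colors = np.asarray([levels[t] for t in truth], dtype=float)
        ax.scatter(xy[:, 0], xy[:, 1], c=colors, cmap="tab10", s=30, zorder=2)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], color="tab:blue", s=30, zorder=2)
    for c in range(a.n_communities):
        pts = xy[a.membership == c]
        if len(pts) >= 3:
            hull = ConvexHull(pts)
            poly = pts[hull.vertices]
            ax.fill(poly[:, 0], poly[:, 1], alpha=0.2, zorder=1)
        elif len(pts) == 2:
            ax.plot(pts[:, 0], pts[:, 1], alpha=0.3, lw=6, zorder=1)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
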