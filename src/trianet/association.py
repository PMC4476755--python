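"""Per-SNP logistic-regression association tests with structure covariates.

The model is logit P(Y=1) = alpha + beta * X + gamma' E, with X the additive
genotype (0/1/2) and E optional stratification covariates (community or
component indicator dummies, or principal components).  Fits use iteratively
reweighted least squares; the default per-SNP p-value is the 1-df
likelihood-ratio test of beta = 0 (a Wald p-value is also reported).

For genome-scale scans a vectorized Rao score test is provided: the null
model (covariates only) is fitted once and every SNP is scored against it in
a few matrix products.  The two tests are asymptotically equivalent; the
scan path is validated against per-SNP LRT fits on a random subsample during
experiment runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .communities import CommunityAssignment
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_LL_TOL = 1e-8
_MU_EPS = 1e-10


class AssociationError(ValueError):
    pass


@dataclass
class CovariateSet:
    """Covariate matrix for the association model (intercept excluded).

    Constant and exactly collinear columns are dropped at construction with
    a logged notice, so the design matrix [1 | E] always has full rank.
    """

    values: np.ndarray          # (n, q) after cleaning; q may be 0
    kind: str = "none"          # "none" | "dummies" | "pcs"
    source: str = ""
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if v.shape[0] == 0 or v.shape[1] == 0:
            v = v.reshape(v.shape[0] if v.ndim == 2 else 0, 0)
        if not self.names:
            self.names = [f"C{j}" for j in range(v.shape[1])]
        keep = _independent_columns(v)
        dropped = [self.names[j] for j in range(v.shape[1]) if j not in keep]
        if dropped:
            logger.info("dropping constant/collinear covariates: %s", dropped)
        self.values = v[:, keep]
        self.names = [self.names[j] for j in keep]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @classmethod
    def none(cls, n: int) -> "CovariateSet":
        return cls(np.empty((n, 0)), kind="none", source="no covariates")


def _independent_columns(v: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of columns linearly independent of the intercept and of the
    previously kept columns (greedy left-to-right QR screen)."""
    n = v.shape[0]
    basis = [np.ones(n)]
    keep: list[int] = []
    for j in range(v.shape[1]):
        b = np.column_stack(basis)
        resid = v[:, j] - b @ np.linalg.lstsq(b, v[:, j], rcond=None)[0]
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(v[:, j])):
            keep.append(j)
            basis.append(v[:, j])
    return keep


def dummy_encode(a: CommunityAssignment) -> CovariateSet:
    """Indicator covariates for community membership.

    With k communities this produces k-1 indicator columns; the reference
    (dropped) category is the largest community, ties broken toward the
    lowest label.  A single community yields an empty covariate set.
    """
    k = a.n_communities
    n = len(a.membership)
    if k == 1:
        return CovariateSet(np.empty((n, 0)), kind="dummies",
                            source=f"{a.level} (single community)")
    sizes = a.sizes()
    reference = int(np.argmax(sizes))  # argmax takes the lowest label on ties
    labels = [c for c in range(k) if c != reference]
    mat = np.column_stack([(a.membership == c).astype(np.float64) for c in labels])
    return CovariateSet(mat, kind="dummies", source=f"{a.level} membership",
                        names=[f"{a.level}_{c}" for c in labels])


@dataclass
class AssociationResult:
    """Per-SNP association summary and the significant fraction."""

    table: pd.DataFrame          # columns: id, beta, p, p_wald, converged
    alpha: float
    prop_significant: float      # fraction of converged SNPs with p < alpha
    n_flagged: int               # non-converged / degenerate SNPs

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["converged"] & (t["p"] < self.alpha)]


# ---------------------------------------------------------------------------
# IRLS core


def _loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))


def fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS fit of a logistic regression; returns (beta, loglik, converged)."""
    n, p = x.shape
    beta = np.zeros(p)
    ll_old = _loglik(y, np.full(n, 0.5))
    converged = False
    for _ in range(_MAX_ITER):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        z = eta + (y - mu) / w
        xw = x * w[:, None]
        try:
            beta = np.linalg.solve(x.T @ xw, x.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, ll_old, False
        ll = _loglik(y, 1.0 / (1.0 + np.exp(-(x @ beta))))
        if not np.isfinite(ll):
            return beta, ll_old, False
        if abs(ll - ll_old) < _LL_TOL:
            ll_old = ll
            converged = True
            break
        ll_old = ll
    # runaway coefficients signal (quasi-)complete separation
    if converged and np.abs(beta).max() > 1e3:
        converged = False
    return beta, ll_old, converged


@dataclass
class NullModel:
    """Covariates-only logistic fit reused across a scan."""

    design: np.ndarray     # (n, 1+q) [intercept | E]
    mu: np.ndarray
    loglik: float
    converged: bool

    @property
    def w(self) -> np.ndarray:
        return self.mu * (1.0 - self.mu)


def fit_null(y: np.ndarray, covars: CovariateSet) -> NullModel:
    y = np.asarray(y, dtype=np.float64)
    _check_phenotype(y, covars.values.shape[0] or len(y))
    e = np.column_stack([np.ones(len(y)), covars.values]) \
        if covars.q else np.ones((len(y), 1))
    beta, ll, conv = fit_logistic(e, y)
    if not conv:
        raise AssociationError("null (covariates-only) model did not converge")
    mu = 1.0 / (1.0 + np.exp(-(e @ beta)))
    return NullModel(e, mu, ll, conv)


def _check_phenotype(y: np.ndarray, n: int) -> None:
    if len(y) != n:
        raise AssociationError(f"phenotype length {len(y)} != n samples {n}")
    vals = np.unique(y)
    if not np.isin(vals, [0.0, 1.0]).all() or vals.size != 2:
        raise AssociationError("phenotype must be binary with both classes present")


def _impute_dosages(d: np.ndarray) -> np.ndarray:
    """Missing dosages replaced by the per-SNP mean of observed calls."""
    g = d.astype(np.float64)
    miss = d == MISSING
    if miss.any():
        called = ~miss
        means = np.where(called, g, 0.0).sum(0) / np.maximum(called.sum(0), 1)
        g = np.where(miss, means[None, :], g)
    return g


# ---------------------------------------------------------------------------
# tests


def score_scan(g: np.ndarray, y: np.ndarray, null: NullModel) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df Rao score test of beta=0 for each genotype column.

    Returns (p_values, tested) where ``tested`` is False for degenerate
    SNPs (no score variance after projecting out the covariates).
    """
    g = np.asarray(g, dtype=np.float64)
    r = y - null.mu
    w = null.w
    e = null.design
    u = g.T @ r
    wg = g * w[:, None]
    ewg = e.T @ wg                      # (1+q, m)
    ewe = e.T @ (e * w[:, None])
    t = np.linalg.solve(ewe, ewg)
    v = (g * wg).sum(axis=0) - (ewg * t).sum(axis=0)
    tested = v > 1e-12
    stat = np.zeros(g.shape[1])
    np.divide(u * u, v, out=stat, where=tested)
    p = np.ones(g.shape[1])
    p[tested] = chi2.sf(stat[tested], 1)
    return p, tested


def logistic_assoc(genotypes: GenotypeMatrix | np.ndarray,
                   phenotype: np.ndarray,
                   covars: CovariateSet | None = None,
                   alpha: float = 1e-4,
                   method: str = "lrt",
                   snp_ids: list[str] | None = None) -> AssociationResult:
    """Association-test every SNP against a binary phenotype.

    ``method="lrt"`` fits the full model per SNP and reports the 1-df
    likelihood-ratio p-value (plus Wald); ``method="score"`` uses the
    vectorized score test (beta is then reported as NaN).  Non-converged or
    degenerate SNPs are flagged and excluded from the significant fraction.
    """
    if isinstance(genotypes, GenotypeMatrix):
        ids = snp_ids or genotypes.variant_ids
        g = _impute_dosages(genotypes.dosages)
    else:
        g = _impute_dosages(np.asarray(genotypes))
        ids = snp_ids or [f"snp{j}" for j in range(g.shape[1])]
    y = np.asarray(phenotype, dtype=np.float64)
    if covars is None:
        covars = CovariateSet.none(g.shape[0])
    null = fit_null(y, covars)
    m = g.shape[1]
    if method == "score":
        p, tested = score_scan(g, y, null)
        table = pd.DataFrame({
            "id": ids, "beta": np.nan, "p": p, "p_wald": np.nan,
            "converged": tested,
        })
    elif method == "lrt":
        beta_hat = np.full(m, np.nan)
        p = np.ones(m)
        p_wald = np.ones(m)
        conv = np.zeros(m, dtype=bool)
        for j in range(m):
            gj = g[:, j]
            if np.ptp(gj) == 0.0:
                continue  # constant genotype: beta undefined
            x = np.column_stack([null.design, gj])
            b, ll, ok = fit_logistic(x, y)
            if not ok:
                continue
            stat = 2.0 * (ll - null.loglik)
            p[j] = chi2.sf(max(stat, 0.0), 1)
            beta_hat[j] = b[-1]
            # Wald from the observed information at the MLE
            mu = 1.0 / (1.0 + np.exp(-(x @ b)))
            xw = x * (mu * (1 - mu))[:, None]
            try:
                cov = np.linalg.inv(x.T @ xw)
                se = np.sqrt(cov[-1, -1])
                p_wald[j] = chi2.sf((b[-1] / se) ** 2, 1)
            except np.linalg.LinAlgError:
                pass
            conv[j] = True
        table = pd.DataFrame({"id": ids, "beta": beta_hat, "p": p,
                              "p_wald": p_wald, "converged": conv})
    else:
        raise ValueError(f"unknown method {method!r}")
    n_flagged = int((~table["converged"]).sum())
    if n_flagged:
        logger.info("%d of %d SNPs flagged (non-converged/degenerate)", n_flagged, m)
    tested_tab = table[table["converged"]]
    prop = float((tested_tab["p"] < alpha).mean()) if len(tested_tab) else 0.0
    return AssociationResult(table, alpha, prop, n_flagged)


def write_results(res: AssociationResult, path: str) -> None:
    res.table.to_csv(path, sep="\t", index=False)
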