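"""Genetic covariance between individuals and principal components.

Genotypes are normalized per SNP in the EIGENSTRAT style: each column is
mean-centered over its non-missing calls and divided by sqrt(p(1-p)) with p
the posterior allele-frequency estimate (1 + alt count) / (2 + 2 calls);
missing entries contribute zero after centering.  The covariance matrix
D = X X^T / m between individuals is the similarity measure feeding the
triad-graph construction (any similarity matrix can be substituted there;
distances must be negated by the caller so larger always means closer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """n x n symmetric similarity (covariance) matrix between individuals."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise SimilarityError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.array_equal(self.values, self.values.T):
            raise SimilarityError("similarity matrix must be exactly symmetric")
        if not np.isfinite(np.diagonal(self.values)).all():
            raise SimilarityError("non-finite diagonal entries")

    @property
    def n(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, path: str) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        v = frame.to_numpy(dtype=np.float64)
        return cls(list(frame.columns), (v + v.T) / 2.0)


@dataclass
class PrincipalComponents:
    """Top-k eigenvectors of the covariance matrix, eigenvalues descending."""

    samples: list[str]
    vectors: np.ndarray   # (n, k) column-orthonormal
    eigenvalues: np.ndarray  # (k,) nonincreasing


def normalize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Return the n x m' normalized real matrix (zero-variance columns dropped).

    Each column is centered on its non-missing mean and scaled by
    sqrt(p(1-p)), p = (1 + sum dosages) / (2 + 2 n_called); missing entries
    are set to 0 after centering.
    """
    d = g.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise SimilarityError("every variant must have at least one non-missing call")
    dd = np.where(called, d, 0).astype(np.float64)
    alt = dd.sum(axis=0)
    mean = alt / n_called
    # zero variance over non-missing entries -> uninformative, drop
    var = (np.where(called, (dd - mean) ** 2, 0.0)).sum(axis=0)
    keep = var > 0.0
    if not keep.any():
        raise SimilarityError("all variants are monomorphic after missing-data handling")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalize_genotypes dropped %d zero-variance variants", dropped)
    p_hat = (1.0 + alt[keep]) / (2.0 + 2.0 * n_called[keep])
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    x = (dd[:, keep] - mean[keep]) / scale
    x[~called[:, keep]] = 0.0
    return x


def covariance_matrix(normalized: np.ndarray,
                      samples: list[str] | None = None) -> SimilarityMatrix:
    """Covariance D = X X^T / m between individuals, exactly symmetrized."""
    x = np.asarray(normalized, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 1:
        raise SimilarityError("need a 2-d matrix with at least one column")
    if samples is None:
        samples = [f"S{i}" for i in range(x.shape[0])]
    d = x @ x.T / x.shape[1]
    d = (d + d.T) / 2.0
    return SimilarityMatrix(list(samples), d)


def principal_components(d: SimilarityMatrix, k: int) -> PrincipalComponents:
    """Top-k eigenvectors of D with a fixed sign convention.

    The sign of each component is chosen so that its largest-magnitude
    entry is positive, making PC covariates reproducible across runs.
    """
    n = d.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    w, v = np.linalg.eigh(d.values)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    for j in range(k):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
    return PrincipalComponents(d.samples, v, w)
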