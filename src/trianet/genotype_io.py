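"""Genotype matrix input/output and data cleaning.

Genotypes are biallelic SNP dosages (ALT-allele counts, 0/1/2) held in an
``n samples x m variants`` int8 array; missing calls are coded ``MISSING``
(-1).  Cleaning steps mirror standard GWAS practice: minor-allele-frequency
filtering, sliding-window LD pruning, and exclusion of long-range-LD
regions given as BED intervals.

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in dosage arrays
MISSING = np.int8(-1)

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised for malformed or empty genotype inputs."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix with sample identifiers and variant metadata.

    Parameters
    ----------
    samples
        Ordered, unique sample identifiers (length n).
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (m rows);
        ``pos`` is 0-based.
    dosages
        ``(n, m)`` int8 array of ALT-allele counts; ``MISSING`` marks
        uncalled genotypes.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-d samples x variants array")
        n, m = self.dosages.shape
        if n < 1 or m < 1:
            raise GenotypeError("need at least one sample and one variant")
        if len(self.samples) != n:
            raise GenotypeError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise GenotypeError(f"{len(self.variants)} variant rows for {m} dosage columns")
        if len(set(self.samples)) != n:
            raise GenotypeError("sample identifiers are not unique")
        bad = ~np.isin(self.dosages, [-1, 0, 1, 2])
        if bad.any():
            raise GenotypeError("dosages outside {0,1,2} / missing(-1) encountered")
        self.variants = self.variants.reset_index(drop=True)
        missing_cols = [c for c in _VARIANT_COLS if c not in self.variants.columns]
        if missing_cols:
            raise GenotypeError(f"variant table lacks columns {missing_cols}")
        ids = self.variant_ids
        if len(set(ids)) != m:
            raise GenotypeError("variant identifiers are not unique after normalization")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        """Variant ids, with '.'/'' normalized to chrom:pos1:ref:alt."""
        out = []
        for chrom, pos, vid, ref, alt in self.variants[_VARIANT_COLS].itertuples(index=False):
            if vid in (".", "", None) or (isinstance(vid, float) and np.isnan(vid)):
                vid = f"{chrom}:{int(pos) + 1}:{ref}:{alt}"
            out.append(str(vid))
        return out

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the variant columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
        )

    def allele_frequencies(self) -> np.ndarray:
        """ALT-allele frequency per variant over non-missing calls (NaN if none)."""
        d = self.dosages
        called = d != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open, e.g. long-range-LD regions."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise GenotypeError(f"empty interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Merged, sorted intervals per chromosome as (k, 2) arrays."""
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            grouped.setdefault(str(chrom), []).append((start, end))
        out = {}
        for chrom, ivals in grouped.items():
            ivals.sort()
            merged = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_vcf(path: str, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read genotype dosages from a VCF file.

    Dosage is the ALT-allele count of each call; uncalled genotypes become
    ``MISSING``.  With ``biallelic_only`` (the default) multiallelic records
    and non-SNP alleles are skipped.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise GenotypeError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        if biallelic_only:
            if len(rec.ALT) != 1:
                continue
            if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                continue
        elif len(rec.ALT) != 1:
            continue  # dosage of >1 ALT is ill-defined for a single column
        # gts012: 0/1/2 = ALT count, 3 = unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        meta.append((rec.CHROM, rec.POS - 1, rec.ID or ".", rec.REF, rec.ALT[0]))
    if not rows:
        raise GenotypeError(f"no usable variants in {path!r}")
    variants = pd.DataFrame(meta, columns=_VARIANT_COLS)
    return GenotypeMatrix(samples, variants, np.vstack(rows).T)


def read_bed(path: str) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a RegionSet."""
    tab = pd.read_csv(path, sep=r"\s+", header=None, comment="#", usecols=[0, 1, 2],
                      names=["chrom", "start", "end"], dtype={"chrom": str})
    return RegionSet([(c, int(s), int(e)) for c, s, e in tab.itertuples(index=False)])


_ID_RE = re.compile(r"^([^:]+):(\d+):([ACGTN]+):([ACGTN]+)$")


def write_matrix(g: GenotypeMatrix, path: str) -> None:
    """Write the plain tab-delimited dialect: variants as rows, samples as
    columns, first row sample IDs, first column variant IDs, missing NA."""
    d = g.dosages.T.astype(object)
    d[d == int(MISSING)] = "NA"
    frame = pd.DataFrame(d, index=g.variant_ids, columns=g.samples)
    frame.to_csv(path, sep="\t", index_label="variant")


def read_matrix(path: str) -> GenotypeMatrix:
    """Read the plain tab-delimited dialect written by :func:`write_matrix`.

    Variant metadata is reconstructed from ids of the form
    ``chrom:pos1:ref:alt`` where possible; otherwise placeholder metadata is
    attached (dosages and identifiers always round-trip exactly).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    if frame.empty:
        raise GenotypeError(f"no variants in {path!r}")
    d = frame.to_numpy()
    dos = np.where(pd.isna(d), MISSING, d).astype(np.float64).astype(np.int8)
    meta = []
    for i, vid in enumerate(frame.index.astype(str)):
        m = _ID_RE.match(vid)
        if m:
            meta.append((m.group(1), int(m.group(2)) - 1, vid, m.group(3), m.group(4)))
        else:
            meta.append(("NA", i, vid, "N", "N"))
    variants = pd.DataFrame(meta, columns=_VARIANT_COLS)
    return GenotypeMatrix(list(frame.columns), variants, dos.T)


# ---------------------------------------------------------------------------
# cleaning steps


def maf_filter(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep exactly the variants with minor allele frequency strictly above
    ``threshold`` (computed on non-missing calls)."""
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    af = g.allele_frequencies()
    maf = np.fmin(af, 1.0 - af)
    keep = np.where(np.nan_to_num(maf, nan=0.0) > threshold)[0]
    if keep.size == 0:
        raise GenotypeError(
            f"MAF filter at {threshold} removed all {g.n_variants} variants; "
            "lower the threshold")
    return g.take_variants(keep)


def _pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    ok = (col_a != MISSING) & (col_b != MISSING)
    if ok.sum() < 2:
        return 0.0
    a = col_a[ok].astype(np.float64)
    b = col_b[ok].astype(np.float64)
    a -= a.mean()
    b -= b.mean()
    va, vb = a @ a, b @ b
    if va == 0.0 or vb == 0.0:
        return 0.0
    c = a @ b
    return float(c * c / (va * vb))


def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning.

    Within each window of ``window`` successive variants (advanced by
    ``step``), for every pair still retained whose dosage r^2 exceeds
    ``r2_max`` the later variant of the pair is dropped.  Output order is
    preserved.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, m)
        idx = [j for j in range(start, stop) if keep[j]]
        for ai in range(len(idx)):
            if not keep[idx[ai]]:
                continue
            for bi in range(ai + 1, len(idx)):
                if not keep[idx[bi]]:
                    continue
                if _pairwise_r2(g.dosages[:, idx[ai]], g.dosages[:, idx[bi]]) > r2_max:
                    keep[idx[bi]] = False
        if stop >= m:
            break
        start += step
    removed = int(m - keep.sum())
    if removed:
        logger.info("ld_prune removed %d of %d variants (r2 > %g)", removed, m, r2_max)
    return g.take_variants(np.where(keep)[0])


def exclude_regions(g: GenotypeMatrix, regions: RegionSet) -> GenotypeMatrix:
    """Drop variants whose position falls inside any interval (half-open:
    start inclusive, end exclusive)."""
    if len(regions) == 0:
        return g.take_variants(np.arange(g.n_variants))
    merged = regions.by_chrom()
    pos = g.variants["pos"].to_numpy(dtype=np.int64)
    chroms = g.variants["chrom"].astype(str).to_numpy()
    drop = np.zeros(g.n_variants, dtype=bool)
    for chrom, ivals in merged.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        # position is inside a merged interval iff searchsorted over the
        # flattened [start, end) boundaries lands on an odd index
        k = np.searchsorted(ivals.ravel(), pos[sel], side="right")
        drop[sel] = (k % 2) == 1
    return g.take_variants(np.where(~drop)[0])
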