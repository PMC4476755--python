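"""Case/control genotype simulator for the stratification experiments.

Four study designs are provided, all with unlinked biallelic SNPs and
n = 1000 individuals (500 cases, 500 controls) by default:

* three *discrete* designs in which individuals come from 2 or 3
  subpopulations differentiated at Fst = 0.01 under the Balding–Nichols
  model, with case/control mixing proportions that create moderate
  (60/40 vs 40/60), extreme (50/50 vs 0/100) or three-way
  (45/35/20 vs 35/20/45) stratification; and
* an *admixed* design in which each individual has an ancestry proportion
  a ~ Uniform(0,1) between two differentiated populations and the disease
  probability is 0.5 * ln(r) * r^a / (r - 1) with ancestral risk r = 3
  (this density integrates to 1/2, so half the population is affected in
  expectation).

Test SNPs come in three categories: *random* (same generative process as
the training SNPs, no effect), *differentiated* (null SNPs with allele
frequency 0.8 in population 1 and 0.2 elsewhere — the confounding probe)
and *causal* (multiplicative per-allele relative risk r, implemented by
raising the case allele frequency to r p / (r p + 1 - p)).

All randomness flows through a single numpy Generator (PCG64) seeded per
call, so identical seeds reproduce studies bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

_FREQ_LOW, _FREQ_HIGH = 0.1, 0.9  # ancestral allele-frequency range

CATEGORIES = ("random", "differentiated", "causal")


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """Full parameterization of one simulation scenario."""

    kind: str                       # "discrete" | "admixed"
    n_cases: int = 500
    n_controls: int = 500
    n_pops: int = 2
    fst: float = 0.01
    case_props: tuple[float, ...] = ()
    control_props: tuple[float, ...] = ()
    ancestral_risk: float = 3.0     # admixed only
    seed: int = 0
    diff_freqs: tuple[float, ...] = ()  # per-population differentiated-SNP freqs

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "admixed"):
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "discrete":
            if self.n_pops not in (2, 3):
                raise ScenarioError("discrete scenarios use 2 or 3 populations")
            if not 0 < self.fst < 1:
                raise ScenarioError("fst must be in (0, 1)")
            for name, props in (("case", self.case_props), ("control", self.control_props)):
                if len(props) != self.n_pops:
                    raise ScenarioError(f"{name}_props must have {self.n_pops} entries")
                if abs(sum(props) - 1.0) > 1e-9:
                    raise ScenarioError(f"{name}_props must sum to 1")
        else:
            self.n_pops = 2
            if self.ancestral_risk <= 1:
                raise ScenarioError("ancestral risk r must exceed 1")
            pmax = disease_probability(1.0, self.ancestral_risk)
            if pmax > 1.0:
                raise ScenarioError("disease probability exceeds 1 for this r")
        if not self.diff_freqs:
            self.diff_freqs = (0.8,) + (0.2,) * (self.n_pops - 1)
        elif len(self.diff_freqs) != self.n_pops:
            raise ScenarioError(f"diff_freqs must have {self.n_pops} entries")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


def scenario(number: int, seed: int = 0, **overrides) -> ScenarioSpec:
    """The four canonical study designs (1-3 discrete, 4 admixed)."""
    presets = {
        1: dict(kind="discrete", n_pops=2,
                case_props=(0.6, 0.4), control_props=(0.4, 0.6)),
        2: dict(kind="discrete", n_pops=2,
                case_props=(0.5, 0.5), control_props=(0.0, 1.0)),
        3: dict(kind="discrete", n_pops=3,
                case_props=(0.45, 0.35, 0.20), control_props=(0.35, 0.20, 0.45)),
        4: dict(kind="admixed", ancestral_risk=3.0),
    }
    if number not in presets:
        raise ScenarioError("scenario number must be 1, 2, 3 or 4")
    kwargs = {**presets[number], "seed": seed, **overrides}
    return ScenarioSpec(**kwargs)


@dataclass
class SimulatedStudy:
    """Training genotypes, phenotype, and the per-individual truth."""

    spec: ScenarioSpec
    genotypes: GenotypeMatrix
    phenotype: np.ndarray            # (n,) 1 = case, 0 = control
    truth: np.ndarray                # population label (discrete) or ancestry a

    def __post_init__(self) -> None:
        if int(self.phenotype.sum()) != self.spec.n_cases:
            raise ScenarioError("case count does not match the scenario spec")
        if len(self.truth) != self.spec.n:
            raise ScenarioError("truth vector must cover all individuals")


def disease_probability(a, r: float = 3.0):
    """Admixed disease risk 0.5 * ln(r) * r^a / (r - 1) at ancestry a."""
    return 0.5 * math.log(r) * np.power(r, a) / (r - 1.0)


def largest_remainder(props, total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``props``.

    Uses the largest-remainder rule (ties toward the lowest index), so the
    counts are deterministic and sum exactly to ``total``.
    """
    props = np.asarray(props, dtype=np.float64)
    exact = props * total
    counts = np.floor(exact).astype(np.int64)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def balding_nichols_freqs(n_snps: int, n_pops: int, fst: float,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies.

    The ancestral frequency p is Uniform(0.1, 0.9); each population draws
    its frequency from Beta(p (1-F)/F, (1-p)(1-F)/F) — mean p, variance
    F p (1-p) — so F is the expected Wright Fst between populations.  F=0
    degenerates to all populations sharing p.

    Returns ``(p, freqs)`` with ``freqs`` of shape (n_pops, n_snps).
    """
    if not 0 <= fst < 1:
        raise ScenarioError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = rng.uniform(_FREQ_LOW, _FREQ_HIGH, size=n_snps)
    if fst == 0.0:
        return p, np.tile(p, (n_pops, 1))
    c = (1.0 - fst) / fst
    freqs = rng.beta(p * c, (1.0 - p) * c, size=(n_pops, n_snps))
    return p, freqs


def _draw_genotypes(rng: np.random.Generator, probs: np.ndarray,
                    shape: tuple[int, int] | None = None) -> np.ndarray:
    """Binomial(2, p) dosages via two Bernoulli allele draws (int8)."""
    shape = shape or probs.shape
    g = (rng.random(shape) < probs).astype(np.int8)
    g += rng.random(shape) < probs
    return g


def _snp_table(n_snps: int, prefix: str) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": "sim",
        "pos": np.arange(n_snps),
        "id": [f"{prefix}{j}" for j in range(n_snps)],
        "ref": "A",
        "alt": "G",
    })


def _assemble(spec: ScenarioSpec, dosages: np.ndarray, phenotype: np.ndarray,
              truth: np.ndarray, prefix: str) -> SimulatedStudy:
    n, m = dosages.shape
    samples = [f"case{i}" for i in range(spec.n_cases)] + \
              [f"ctrl{i}" for i in range(spec.n_controls)]
    gm = GenotypeMatrix(samples, _snp_table(m, prefix), dosages)
    return SimulatedStudy(spec, gm, phenotype, truth)


def _discrete_populations(spec: ScenarioSpec) -> np.ndarray:
    """Deterministic per-individual population labels (cases first)."""
    case_counts = largest_remainder(spec.case_props, spec.n_cases)
    ctrl_counts = largest_remainder(spec.control_props, spec.n_controls)
    return np.r_[np.repeat(np.arange(spec.n_pops), case_counts),
                 np.repeat(np.arange(spec.n_pops), ctrl_counts)]


def simulate_discrete(spec: ScenarioSpec, n_snps: int) -> SimulatedStudy:
    """Training study for a discrete-subpopulation scenario.

    Population membership follows the case/control mixing proportions
    (largest-remainder rounding); genotypes are Binomial(2, f_pop) at
    Balding–Nichols frequencies.  Training SNPs carry no phenotype effect.
    """
    if spec.kind != "discrete":
        raise ScenarioError("spec.kind must be 'discrete'")
    rng = np.random.default_rng(spec.seed)
    pops = _discrete_populations(spec)
    _, freqs = balding_nichols_freqs(n_snps, spec.n_pops, spec.fst, rng)
    dosages = _draw_genotypes(rng, freqs[pops])
    phen = np.r_[np.ones(spec.n_cases), np.zeros(spec.n_controls)]
    return _assemble(spec, dosages, phen, pops, "train")


def _draw_admixed_individuals(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Ancestry proportions for n_cases cases then n_controls controls,
    drawn by rejection until both quotas are filled."""
    cases, ctrls = [], []
    while len(cases) < spec.n_cases or len(ctrls) < spec.n_controls:
        a = rng.uniform(size=256)
        sick = rng.random(256) < disease_probability(a, spec.ancestral_risk)
        for ai, si in zip(a, sick):
            if si and len(cases) < spec.n_cases:
                cases.append(ai)
            elif not si and len(ctrls) < spec.n_controls:
                ctrls.append(ai)
    return np.r_[cases, ctrls]


def simulate_admixed(spec: ScenarioSpec, n_snps: int) -> SimulatedStudy:
    """Training study for the admixed scenario.

    Each individual's genotype probability at a SNP is a f1 + (1-a) f2 with
    (f1, f2) Balding–Nichols frequencies; affection status follows the
    ancestry-dependent risk, and sampling continues until the case and
    control quotas are filled.
    """
    if spec.kind != "admixed":
        raise ScenarioError("spec.kind must be 'admixed'")
    rng = np.random.default_rng(spec.seed)
    ancestry = _draw_admixed_individuals(spec, rng)
    _, freqs = balding_nichols_freqs(n_snps, 2, spec.fst, rng)
    probs = np.outer(ancestry, freqs[0]) + np.outer(1.0 - ancestry, freqs[1])
    dosages = _draw_genotypes(rng, probs)
    phen = np.r_[np.ones(spec.n_cases), np.zeros(spec.n_controls)]
    return _assemble(spec, dosages, phen, ancestry, "train")


def risk_allele_frequency(p, r):
    """Case allele frequency r p / (r p + 1 - p) under a multiplicative
    per-allele relative risk r."""
    p = np.asarray(p, dtype=np.float64)
    return r * p / (r * p + 1.0 - p)


def simulate_test_snps(category: str, study: SimulatedStudy, n_snps: int,
                       rel_risk: float = 1.5,
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Generate test SNPs of one category for the study's individuals.

    ``random`` SNPs repeat the training generative process with fresh
    frequencies; ``differentiated`` SNPs are null markers at the scenario's
    per-population frequencies (0.8 / 0.2 by default; ancestry-weighted in
    the admixed design); ``causal`` SNPs draw a base frequency like a
    random SNP and raise the case allele frequency by the multiplicative
    relative risk.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown test-SNP category {category!r}")
    spec = study.spec
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = spec.n
    is_case = study.phenotype == 1
    if spec.kind == "discrete":
        pops = study.truth.astype(np.int64)
        if category == "differentiated":
            f = np.asarray(spec.diff_freqs)
            probs = np.broadcast_to(f[pops][:, None], (n, n_snps))
        else:
            _, freqs = balding_nichols_freqs(n_snps, spec.n_pops, spec.fst, rng)
            probs = freqs[pops]
            if category == "causal":
                probs = np.where(is_case[:, None],
                                 risk_allele_frequency(probs, rel_risk), probs)
    else:
        a = study.truth
        if category == "differentiated":
            f1, f2 = spec.diff_freqs
            per_ind = a * f1 + (1.0 - a) * f2
            probs = np.broadcast_to(per_ind[:, None], (n, n_snps))
        else:
            _, freqs = balding_nichols_freqs(n_snps, 2, spec.fst, rng)
            probs = np.outer(a, freqs[0]) + np.outer(1.0 - a, freqs[1])
            if category == "causal":
                probs = np.where(is_case[:, None],
                                 risk_allele_frequency(probs, rel_risk), probs)
    dosages = _draw_genotypes(rng, probs, shape=(n, n_snps))
    gm = GenotypeMatrix(study.genotypes.samples, _snp_table(n_snps, category[:4]),
                        dosages)
    return gm


def simulate_study(spec: ScenarioSpec, n_snps: int) -> SimulatedStudy:
    """Dispatch to the discrete or admixed training simulator."""
    if spec.kind == "discrete":
        return simulate_discrete(spec, n_snps)
    return simulate_admixed(spec, n_snps)


def with_seed(spec: ScenarioSpec, seed: int) -> ScenarioSpec:
    return replace(spec, seed=int(seed))


# ---------------------------------------------------------------------------
# scenario config files (key = value text)


def write_scenario(spec: ScenarioSpec, path: str) -> None:
    with open(path, "w") as fh:
        for key, val in vars(spec).items():
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            fh.write(f"{key} = {val}\n")


def read_scenario(path: str) -> ScenarioSpec:
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
    kwargs: dict = {"kind": raw["kind"]}
    for key in ("n_cases", "n_controls", "n_pops", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("fst", "ancestral_risk"):
        if key in raw:
            kwargs[key] = float(raw[key])
    for key in ("case_props", "control_props", "diff_freqs"):
        if key in raw and raw[key]:
            kwargs[key] = tuple(float(v) for v in raw[key].split(","))
    return ScenarioSpec(**kwargs)
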