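# Methods

## Similarity and normalization

Genotypes are ALT-dosages in {0,1,2}; missing calls are tracked explicitly
and survive filtering. For the covariance matrix each SNP column is
centered on its observed mean and divided by √(p̂(1−p̂)), where
p̂ = (1 + Σg)/(2 + 2·n_called) is the posterior allele-frequency estimate;
missing entries contribute 0 after centering, and monomorphic columns are
dropped with a log notice. D = X Xᵀ/m. The 1/m scaling is a convention
choice: the triad construction consumes only within-row *ranks* of D, which
are invariant to any positive rescaling, so the scaling matters only for
cross-panel comparability of exported matrices. The plain sample frequency
could replace the posterior estimate; ranks are insensitive in practice,
and the posterior variant is the default because it never degenerates at
monomorphic-in-sample columns retained by upstream filters.

Any similarity matrix can be passed to the graph builder; distance-type
measures must be negated by the caller so that larger always means more
similar. Covariance is the only measure shipped.

## Triad construction

Ranks within each row use average ranks for exact covariance ties (no
epsilon): equality is bitwise, which keeps the construction deterministic.
Every individual anchors exactly one triad, so swapping the roles of i and
j can change the triad — that reading yields the advertised n-vertex /
≤ 3n-edge graph. Ties in the step-1 and step-2 minimizations break toward
the smallest sample index. Duplicate edges collapse into a simple graph by
default; multiplicities are retained and can be used as Louvain edge
weights (`keep_multiplicity`), which matters only when many triads
coincide.

## Community detection

Connected components come from scipy's csgraph; labels are renumbered by
the smallest member index. Louvain is implemented in-package: local moves
sweep vertices in ascending index order (optionally a seeded shuffle) and a
move requires strictly positive modularity gain, ties breaking toward the
smaller community label; phases aggregate until the vertex count stops
shrinking. The deterministic sweep order makes repeated runs bit-for-bit
identical — important because the memberships become regression covariates.
Modularity Q = Σᵢ(eᵢᵢ − aᵢ²) is computed by this module's own code (each
edge counted once, cross edges split between the two row sums) and is
asserted against python-igraph's value on every `louvain()` call; igraph's
`community_multilevel` additionally serves as an independent oracle in the
test suite. Because moves only follow edges, every community lies inside
one connected component, so the Louvain partition always refines the
component partition.

## Association testing

The model is logit P(Y=1) = α + β·X + γᵀE with additive genotype X and
covariates E (community/component indicator dummies with the largest
community as reference, or principal components). Fits use Newton/IRLS
(max 50 iterations, log-likelihood tolerance 1e-8, no Firth correction);
non-convergence, runaway coefficients (|β| > 10³, a separation symptom)
and constant genotypes are flagged and excluded from the significant
fraction rather than repaired. The default p-value is the 1-df
likelihood-ratio test (a Wald p-value is reported alongside); whether the
original analyses used Wald or LRT is not documented, and the two agree to
well within the reported precision at these sample sizes.

For genome-scale scans the package uses a vectorized Rao score test: the
covariates-only null is fitted once and each SNP's statistic
U²/V with U = gᵀ(y−μ̂) and V = gᵀWg − gᵀWE(EᵀWE)⁻¹EᵀWg is computed in a
few matrix products. During experiment runs the scan is spot-checked
against per-SNP LRT fits on up to 1000 random SNPs and the maximum
|p_LRT − p_score| is logged (typically < 10⁻³ at n = 1000).

Constant or exactly collinear covariate columns are dropped at
`CovariateSet` construction with a notice; a single-community assignment
yields an empty covariate set, so that arm degrades to the naive model —
the behavior the admixed design exercises.

## Simulation designs

All SNPs are unlinked (no LD within simulated panels) and frequencies
follow the Balding–Nichols model: ancestral p ~ U(0.1, 0.9), population
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) at F = Fst = 0.01. Defaults:
1000 individuals (500 cases / 500 controls).

* Scenario 1 (moderate mismatch): cases 60%/40% across two populations.
  Only the case proportions are documented in the source design; controls
  default to the mirrored 40%/60% following the classic EIGENSTRAT
  evaluation design this setting replicates (configurable via
  `control_props`). A pre-build check confirmed the mirrored design
  reproduces the reported uncorrected differentiated-SNP rate (~0.85).
* Scenario 2 (extreme mismatch): cases 50%/50%, controls 100% from
  population 2.
* Scenario 3: three populations; cases 45/35/20, controls 35/20/45.
* Admixed: each individual draws ancestry a ~ U(0,1) between two
  populations differentiated at Fst = 0.01 (the source design is silent on
  this Fst; 0.01 matches the discrete settings), per-SNP genotype
  probability a·f₁ + (1−a)·f₂, disease probability ½·ln(r)·rᵃ/(r−1) with
  r = 3. The density integrates to ½, so sampling until the 500/500 quotas
  fill is efficient.

Subgroup counts use largest-remainder apportionment, so they are
deterministic and exact (e.g. 500 cases × (0.45, 0.35, 0.20) →
225/175/100). Test SNPs: *random* repeats the training process with fresh
frequencies for the same individuals (the training individuals are fixed;
frequencies and genotypes are redrawn); *differentiated* uses frequency
0.8 in population 1 and 0.2 elsewhere (ancestry-weighted when admixed;
with three populations, populations 2 and 3 both sit at 0.2 —
configurable); *causal* draws a base frequency like a random SNP and
raises the case allele frequency to r·p/(r·p + 1 − p), r = 1.5.

Randomness flows through `numpy.random.default_rng` (PCG64) exclusively;
identical seeds reproduce studies bit-for-bit.

What the generator does **not** emulate: linkage disequilibrium, genotype
missingness, batch effects, family structure, and continuous clines other
than two-way admixture. Passing tests therefore demonstrate correctness of
the pipeline under idealized unlinked-SNP stratification, not robustness
to the artifacts of real sequencing panels.

## Experiment grid and problem sizes

`run_experiment` pairs all correction arms on identical replicates and
identical test SNPs, streaming SNPs in 25k batches to bound memory. The
package's default evaluation sizes are 10k training SNPs, 200k test SNPs
per category and 2 replicates — a desk-scale rendition of the original
100k / 1M / 10 design that keeps each scenario to about 1–2 minutes while
holding the Monte-Carlo error on proportions near 10⁻⁴ to ~30%.

Two quantities need different sizing. The admixed differentiated-SNP
proportion has between-replicate sd ≈ 0.16: the confounding strength is
set by the realized case/control mean-ancestry difference (expectation
0.179, sampling sd 0.016 at n = 1000), so replicate count — not SNP count
— controls its precision; the acceptance script averages 10 replicates of
100k SNPs for that cell. Conversely, component-level separation of three
populations at Fst = 0.01 needs the full 100k training panel (at 10k SNPs
a single spurious cross-population triad merges two components in roughly
half of runs), so the component-precision property is checked at the
100k training scale.

At the desk scale the component partition of scenarios 1–2 and the Louvain
communities of all discrete scenarios recover the true populations with
precision ≥ 0.99, and the corrected arms hold the 10⁻⁴ level while the
naive arm shows the expected inflation (≈ 0.85 for scenario 1
differentiated SNPs, 1.0 for scenario 2).

The contingency-table *precision* used throughout is the fraction of
individuals whose detected community's majority truth label matches their
own — the natural cluster-purity reading of the published tables, which
state no formula.

## Known limitations

* The ADMIXTURE comparator arm of the original evaluation is not
  reproduced (its published values are near-duplicates of the PC arm).
* Long-range-LD region lists are user-supplied BED files; no default list
  ships with the package, and LD-pruning parameters (window 50, step 5,
  r² 0.2) are community defaults, not values documented by the source
  analyses.
* `plot_network` reads "scale-free plots" as a force-directed
  (spring/Fruchterman–Reingold) layout; the original layout algorithm is
  not documented.
* Louvain is run on the whole graph; per-component re-runs would give the
  same refinement by construction but are not exposed separately.
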