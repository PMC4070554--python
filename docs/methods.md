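# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of `mlcqtl`.

## The disconnected multiple-line cross model

All scans operate on line entry means (BLUEs) `Y` of N doubled-haploid
lines from P biparental families.  At a tested position q,

    Y = J M + Σ_c X_c B_c + X_q B_q + ε,     ε ~ N(0, σ² I)

with `J` the family-indicator matrix, `M` the family means, and `X_q` the
expected parent-A allele counts at q arranged family-wise: row i has its
count in the column of line i's family and zeros elsewhere, so `B_q` holds
one allele-substitution effect per family ("disconnected": no allele
identity is assumed across families, only position).  Cofactor markers
enter as identical blocks `X_c B_c`.

A consequence used throughout the implementation: every design column is
supported on exactly one family, so the pooled least-squares fit decomposes
into P independent per-family regressions whose residual sums of squares
add.  The engine keeps one orthonormal basis per family and evaluates the
whole grid with rank-one (Frisch–Waugh) updates: the RSS reduction from
adding column x to a model with basis Q and residual r is `(x⊥ᵀr)²/‖x⊥‖²`
with `x⊥ = x − QQᵀx`.  This is exact, and it is what makes cofactor
re-selection inside every permutation replicate affordable.

### Test statistic

`LR = N ln(RSS0/RSS1)` under the Gaussian profile likelihood, reported as
`LOD = LR/(2 ln 10) = (N/2) log10(RSS0/RSS1)`.  RSS0 is the model with
family means and the admissible cofactors; RSS1 adds the tested block.
Families in which the tested count column is constant (the locus does not
segregate there, or the column is collinear with the model) are dropped
from the tested block with the degrees of freedom reduced accordingly;
LOD profiles are invariant under affine transformation of Y.

### Expected allele counts

Counts at off-marker positions are conditional expectations given the
nearest non-missing flanking markers.  Along a DH chromatid the parental
origin is a two-state Markov chain (no interference); map distance d cM
converts to a recombination fraction by the Haldane function
`r = 0.5(1 − e^(−2d/100))`.  With both flanks observed,

    P(A | aL, aR) = t(aL→A; rL) t(A→aR; rR) / Σ_state t t

with `t(same) = 1 − r`; one-sided conditioning when a flank is missing,
0.5 when a group carries no genotyped marker for the line.  The
nearest-informative-flank rule is exact under the Markov chain when the
skipped markers are missing, and it is deterministic; full multipoint
smoothing would matter only for genotyping-error modelling, which is out
of scope.  The test suite checks the counts against exhaustive enumeration
of DH classes to 1e-10.

### Cofactor selection

Forward search over marker blocks minimizing the Schwarz criterion
`N ln(RSS/N) + k ln N`, starting from the family-means model; k counts the
actually fitted (segregating) columns, so a marker monomorphic in some
family costs fewer parameters there.  Selection stops when the criterion
stops improving or at `max_cofactors` (default 10).  During a scan,
cofactors within 10 cM (strictly) of the tested position are excluded.

### Thresholds, declaration, support

Genome-wide LOD thresholds are empirical (1 − α) quantiles (type-7
interpolation) of the max-LOD distribution over permutations of Y *within
family* — the family structure is never broken — with cofactors re-selected
on every permuted phenotype so the null distribution reflects the entire
procedure.  The default is α = 0.10 with 200 replicates at desk scale
(2000 supported via the `n_perm` argument).

QTL are declared at above-threshold local maxima.  Two peaks on one group
are distinct only if more than 20 cM apart *and* separated by a valley at
least 1 LOD below the lower peak; otherwise the lower is merged into the
higher.  (The 20 cM rule is this package's choice — twice the overlap
window; peak-merging needs *some* rule and composite interval mapping with
cofactors already suppresses most ghost peaks between linked QTL.)  The
support interval extends from the peak to the outermost contiguous grid
positions within 1 LOD of it, so its resolution is one grid step.

### Explained genotypic variance

For the declared QTL jointly, `p_G = 100 · R²_adj / h²`, where R² is taken
against the grand-mean baseline with family means in the model,
`R²_adj = 1 − (1 − R²)(N − 1)/(N − k − 1)`, and k counts all fitted
non-intercept parameters (P − 1 family contrasts plus the segregating QTL
columns).  Per-QTL shares are drop-one partials floored at 0.  Dividing by
the entry-mean heritability converts "share of phenotypic variance of the
means" into "share of genotypic variance".  Drop-one partials of
correlated loci need not sum exactly to the joint value; dropping a block
also relaxes the adjustment penalty by ~(1 − R²)/(N − k) per parameter.

### Cross-validation

Replicated stratified fivefold cross-validation: folds hold ~1/5 of every
family (fold sizes within ±1).  Per run, cofactor selection and the scan
are repeated on the estimation set (ES) with the fixed full-data threshold
(re-permuting per fold would multiply the cost ~200-fold for little
benefit, since the threshold is a property of map and design, not of the
fold).  `p_G(ES)` comes from the simultaneous multi-QTL model on the ES;
test-set lines are predicted from ES-estimated family means and QTL
effects, and `p_G(TS) = 100 r²(ŷ, y_TS)/h²`, set to 0 when r < 0 or no
QTL was declared.  The relative bias `100(p_G(ES) − p_G(TS))/p_G(ES)`
measures how much same-data estimation overstates predictive value;
detection frequencies are binned at 10 cM.  Defaults: 20 replicates
(100 runs); the bundled pipeline uses 4 at desk scale.

### Cross-stage overlap

QTL from different stages overlap if they lie on the same group within
10 cM (boundary inclusive); overlap is transitively closed into clusters
and each cluster is labelled with the set of stages present (the Venn
counts).  A locus × stage matrix of drop-one p_G values over the cluster
representatives summarizes the temporal dynamics.

### Epistasis

The two-locus model adds a second main-effect block and an interaction
block whose per-family column is the product of within-family *centered*
counts (centering decorrelates the product from the main effects; the
parameterization of the interaction column is this package's choice).  The
interaction block is tested with a pooled F test, full vs the same model
without the block, with numerator df equal to the number of families
contributing an informative interaction column.  Under Gaussian OLS this
is equivalent to the LR test and numerically stabler at small RSS.  The
α = 0.05 level is Bonferroni-divided by the number of chromosome-region
pairs, two regions per group: `α / C(2G, 2)`.  Same-group pairs closer
than 20 cM are not tested (collinearity guard).  Significant pairs with
both loci within 10 cM are clustered; the best pair per cluster is
reported with its interaction effects and drop-one `p_G` share.  Dense
landscapes of −log10 P for a chromosome pair are available as matrices.

**Known property of the region-pair correction.**  The correction assumes
a genome behaves like 2 independent regions per chromosome.  On a dense
grid over 21 × 150 cM that assumption fails: the single-pair test is
exactly calibrated (verified uniform under the null), yet null 2-D scans
at the region-pair threshold produce several false clusters per scan
because the effective number of independent pairs far exceeds C(42, 2).
Users who need strict family-wise control should treat the prescribed
threshold as lenient and either raise the correction to the number of
effectively independent grid pairs or validate interaction calls by
cross-validation.  The test suite measures this property and documents the
observed false-cluster rate rather than hiding it.

## The synthetic-data generator

The generator emulates a four-family DH study of one trait measured at
three developmental stages (BM1–BM3) in four environments (2 locations ×
2 years) with 2 replicates:

* **Families** — 131/120/200/196 lines (647 total), each an F1 gamete
  doubled: first allele Bernoulli(0.5), switches between adjacent loci with
  Haldane probability; genotypes 0/2; optional missing-at-random injection.
* **Map** — default 21 groups × 150 cM with 5 cM marker spacing (the map
  density of the emulated design is configurable; nothing in the method
  depends on the exact spacing).
* **Architecture** — one dwarfing-type major QTL segregating only in
  family 4, with stage profile 0.35/1.0/0.6 so the family's distribution
  runs unimodal → bimodal → attenuated across stages; nine minor QTL
  (some stable, some rising or declining with development, several
  family-specific); three epistatic pairs whose weight declines after the
  first stage; and a polygenic background of 42 small loci (~30–40% of the
  genetic variance) representing the part of a quantitative trait that
  individually escapes detection.  At the middle stage the major QTL
  carries ~27% of the genetic variance and the ten mappable QTL together
  ~65%.  Family 4's minor and background effects are kept small so the
  major locus dominates that family, as a dwarfing locus does.  Stage
  correlations arise mechanistically from shared loci and stage profiles,
  not from an imposed correlation matrix.
* **Phenotypes** — genetic value g per line (family mean + additive +
  epistatic terms; additive coding effect × (count − 1)); σ²_G is measured
  from the realized g, σ²_GE = σ²_G / `ge_ratio`, and the plot error
  solved from the entry-mean heritability identity
  `h² = σ²_G / (σ²_G + σ²_GE/E + σ²_e/(E r))` — unreachable combinations
  raise an error.  Defaults per stage: h² = 0.81/0.91/0.87 and
  σ²_G:σ²_GE = 3/7/5, spanning the range typical of well-replicated
  multi-environment cereal trials.

What the generator does **not** emulate: partially replicated (lattice)
field layouts with checks and spatial trends — the trial is balanced, so
method-of-moments components equal REML and per-line means equal BLUEs;
genotyping error; segregation distortion; interference in meiosis.
Passing tests therefore demonstrate correctness of the mapping machinery
under a clean design, not robustness to field-trial artifacts.

## Phenotype statistics

Variance components use the balanced two-way expected-mean-squares
solution (σ²_e = MS_err, σ²_GE = (MS_GE − MS_err)/r, σ²_G =
(MS_G − MS_GE)/(rE)), truncated at 0 with a logged warning; with one rep
per environment σ²_e is confounded with σ²_GE and reported as 0.  BLUEs
are per-line means (missing cells averaged over available cells, a logged
count; all-missing lines excluded).  Stage correlations are Pearson with
P values.  The family-vs-midparent orthogonal contrast treats the parent
values as known constants (replicated checks in a real trial; their SE is
ignored — conservative for the trial sizes in question), with a t test on
n − 1 df; significance is starred at P < 0.01.  Multimodality of
within-family distributions is assessed by counting Gaussian-KDE modes,
requiring a relative valley depth ≥ 0.05 between retained modes.

## Numerical choices

* Orthonormal bases by pivoted QR; columns with |R_ii| below
  `max(m, n)·eps·|R_00|` are dropped (rank-deficient blocks, monomorphic
  loci).
* Informative-column guard for rank-one updates: residual squared norm
  > 1e-9 × (raw squared norm + 1).
* Saturated fits (RSS1 → 0) cap the LOD via an RSS floor of 1e-12 × RSS0,
  with a logged warning; the epistasis F test returns P = 1 when the
  full-model residual falls below 1e-10 × (‖y‖² + 1).
* Permutation quantiles use linear (type-7) interpolation; `alpha` is
  accepted in (0, 1].
* Grids contain every marker position plus a regular lattice; positions
  are rounded to 1e-6 cM for uniqueness; intervals are closed.
* All simulation and permutation randomness flows through
  `numpy.random.default_rng` seeds; identical seeds give bit-identical
  populations, phenotypes, folds and thresholds.

## Problem sizes in the bundled runs

The packaged pipeline and the acceptance script run the emulation at
647 lines on the 21-group map with a 5 cM scan grid, 200 permutation
replicates, 4 cross-validation replicates (20 runs) per stage, a 5 cM
2-D epistasis grid, and a 50-run null experiment for the empirical
experiment-wise error rate; the statistical test suite uses 20–100
simulation replicates per property.  These sizes are the package's
desk-scale defaults; all are arguments, and the full-scale settings
(2000 permutations, 20 CV replicates) are one flag away.

## Limitations

* The balanced-design surrogate cannot reproduce analyses that depend on
  the original unbalanced layout; heritabilities and BLUEs from real
  lattice trials should be computed with a mixed-model package and fed in
  as entry means.
* Support intervals are grid-quantized; use a 1–2 cM step when interval
  precision matters.
* The disconnected model estimates one effect per family per locus; it
  does not pool allele effects across families (no connected/IBD variant)
  and fits no dominance (DH material has none).
* p_G partitions among linked QTL via drop-one partials are
  order-dependent in pathological collinear cases; the engine reports the
  joint value alongside.
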