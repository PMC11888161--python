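# Methods

## Shuffle-enrichment statistic

For a query peak set *P* and an annotation family *A* on a genome given by a
chrom.sizes table, the observed statistic is the coverage-union overlap
`O = |union(A) ∩ union(P)|` in base pairs. Both sets are merged before
intersection, so the statistic is invariant to within-set redundancy
(duplicate or overlapping elements); the identical treatment is applied to
observed and null sets, preserving comparability. Coordinates are 0-based
half-open throughout; strand is ignored; bookended intervals count as
contiguous coverage (bp totals are unaffected by that convention).

The null relocates each element of *A* independently to a uniform start in
`[0, L − len]` on its own chromosome (chromosome and length preserved;
collisions between relocated elements are allowed). Placements are clamped
to lie wholly inside the chromosome so element length — which the statistic
depends on — is preserved. Elements longer than their chromosome are
skipped with a warning by default (`oversize_policy="error"` raises); this
arises only when a catalog built on a larger genome is used with a subset
layout. Assembly gaps are not modeled: all positions are valid placements.

With `n_shuffles` replicates (default 20, matching the replicate count the
pipeline was designed around; ≥100 is recommended for a stable null sd and
the calibration tests use 100), the z-score is
`z = (O_obs − mean) / sd` with the sample standard deviation (n−1
denominator). A degenerate null (sd = 0 with O_obs ≠ mean) is reported with
a `degenerate` flag and NaN z, never ±∞; a constant null that equals the
observed value yields z = 0. No empirical p-value is attached — the score
is the z itself — and no multiple-testing correction is applied across
families in a screen, which reports raw z-scores only.

**Seeding.** A master seed plus a sha256-derived substream per family name,
with one spawned child stream per replicate. Results are therefore
bit-reproducible and independent of the order in which families are
processed (verified by test).

**Batch screens.** A catalog is either a UCSC RepeatMasker dump grouped by
`repClass`/`repFamily`, or a directory of narrowPeak files with one family
per file (file stem = family name) — the screen used for histone-mark track
collections. Every family yields exactly one table row; degenerate and
empty families are kept explicit rather than dropped. Output is a TSV with
fixed formatting (z to 4 decimals) so reruns diff cleanly.

## IP-MS differential stage

Input is an already-quantified proteins × samples matrix of log2
intensities (blank = missing) plus a sample→group map
(treatment/control, ≥2 samples each). Values are treated as log2 on input;
no internal transform — both the imputation normal and log2 fold change are
only coherent on a log scale.

**Imputation.** Each missing cell is drawn from
`N(μ − shift·σ, (width·σ)²)`, defaults shift = 1.8, width = 0.8. The scope
of μ, σ is each sample column by default (the common practice for
down-shifted imputation, since depth and dynamic range differ per run); a
`global` scope is exposed. Observed cells are never altered; the missing
mask is kept as provenance; a scope with fewer than two observed values is
a hard error.

**Testing.** Per protein, `log2FC = mean(treatment) − mean(control)`. The
ordinary mode is the textbook pooled-variance two-sample t with
`n1 + n2 − 2` df. The moderated mode shrinks each per-protein pooled
variance s² toward a prior: posterior `(d·s² + d0·s0²) / (d + d0)`,
referred to a t distribution with `d + d0` df. The prior `(s0², d0)` is fit
by method of moments on the marginal of s², which under the standard
hierarchical model (scaled inverse-chi-square prior on the true variances)
is `s0²·F(d, d0)`: matching the squared coefficient of variation
`CV² = 2(d + d0 − 2)/(d(d0 − 4))` gives d0, and s0² follows from the mean.
When the observed variances are under-dispersed relative to chi-square
sampling alone (CV²·d ≤ 2), d0 → ∞ and every protein uses the common
variance with normal reference; when the moment solution falls at or below
d0 = 4 (where the F variance diverges) it is clamped just above 4. This
moment fit differs from limma's fitFDist, which matches moments of log s²;
on simulated matrices the two produce t statistics with correlation > 0.99
(cross-checked in the test suite), and the ordinary test remains available
as an unambiguous fallback. Zero-variance proteins get t = 0, p = 1,
flagged — never a division error.

**Correction and filtering.** Benjamini–Hochberg q-values follow the
step-up definition `q_i = min_{j: p_(j) ≥ p_(i)} p_(j)·n/rank(j)`, capped
at 1 (verified against a brute-force evaluation and statsmodels). The hit
flag requires `log2FC > 2` **and raw `p` < 0.05**, both strict; q is
reported alongside but does not gate the default filter, and thresholds are
overridable (e.g. `fc_threshold = log2(50)` for a natural-scale fold-change
cut of 50). Filtering marks rows; it never deletes them.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the geometry the enrichment method is sensitive
to, with all parameters fixed once as study conditions:

- **Genome**: one 1 Mb chromosome. Satellite coverage is exactly 5% of the
  chromosome, split into 5 arrays laid out consecutively (small random
  gaps) around a centromere coordinate drawn near mid-chromosome —
  clustered pericentromeric geometry. 100 LINE elements with lengths
  uniform on 0.5–6 kb are placed uniformly (≈25% coverage after union,
  near real mammalian LINE density). No sequence content is generated.
- **Peaks**: 200 peaks of 200 bp. Midpoint density is ρ inside the bias
  family's coverage and 1 outside (normalized), so the expected
  in-coverage midpoint fraction is `ρf / (ρf + 1 − f)` for coverage
  fraction f; ρ = 1 is exactly uniform. Sampling is exact via cumulative
  base counts, not rejection.
- **Intensities**: 500 proteins × (3 + 3) samples; baseline per-protein
  means `N(20, 2²)` (log2 iBAQ-like scale), within-group noise sd 0.5; the
  first 50 proteins carry +3 log2 units in the treatment group (the
  large-effect variants use +5). Missingness is Bernoulli with probability
  `logistic(16.5 − value)` — intensity-dependent (MNAR), the regime
  down-shifted imputation presumes — giving ≈10% missing cells at the
  default baseline; slope 0 provides an MCAR switch.

Passing tests on these data show the statistics behave correctly under the
stated geometry and noise model. They do not establish performance on real
data, where peak placement is constrained by mappability and assembly gaps,
repeat annotations are far denser and length-heterogeneous, ChIP efficiency
varies, and proteomics missingness mixes MNAR with stochastic peptide
sampling. In particular the shuffle null ignores assembly gaps (as does the
implementation, by design), so on a real genome z-scores are conservative
or anticonservative depending on how gaps intersect the query peaks.

## Numerical and design notes

- Overlap/merge use sorted integer arrays and an event sweep; equality with
  a per-base brute-force count is property-tested on ≤10 kb genomes.
- Null moments use float accumulation of integer overlaps; z is computed
  exactly from (O, mean, sd) with the degenerate cases handled before
  division.
- Enrichment tables sort by descending z with NaN-z rows last and family
  name as the tie-break, so output order is total and deterministic.
- Problem sizes in the test and acceptance workloads (10,000-replicate
  moment checks, 200-instance calibration, 50-simulation recovery) were
  chosen to keep the full suite under a minute on one CPU while leaving
  each statistical assertion at least 3-sigma margins.
- The CLI is a thin layer over the library; config YAML supplies defaults
  and explicit flags win. Analysis drivers under `analysis/` are narrative
  wrappers over the same library calls the tests exercise.

## Known limitations

- The moderated-test prior fit assumes a common residual df d across
  proteins (true after imputation, which completes the matrix).
- The shuffle null is the per-element uniform relocation model only: no
  GC-matching, length-binned placement, gap awareness, or circular
  rotation nulls.
- A directory screen treats each file as one family with no replicate
  grouping or cross-file correction.
- The generators plant a single bias family and additive group effects;
  correlated proteins, batch effects, and peak-width heterogeneity are out
  of scope.
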