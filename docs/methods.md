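# Methods

This note documents the models and procedures implemented in `corepanel`, the
parameter choices that matter, the numerical details, and what the synthetic
test data can and cannot demonstrate.

## Core-set selection

Candidate amplicon markers carry a missing rate, a minor allele frequency
(MAF), and an ordinal mapping-quality class (1 = cleanest; higher classes show
increasing off-target or homoeologous interference, an acute problem in
hexaploid wheat).  Filtering keeps candidates with missing rate strictly
below `max_missing` (default 0.3) and class in `allowed_classes` (default
{1, 2, 3}).  The boundary is deliberately strict (< 0.3, not ≤), and the
class set is open-ended so catalogs with more than five classes work
unchanged.

Selection tiles each chromosome into consecutive windows of
`target_spacing_mb` (default 6 Mb) and picks, per non-empty window, the
highest-MAF candidate passing a MAF floor.  The floor is location dependent:
windows holding at least `dense_min_candidates` candidates (default 3) use
`min_maf_dense` (default 0.2); sparser windows fall back to `min_maf_sparse`
(default 0.05).  This trades polymorphism for coverage exactly where
candidates are scarce, which keeps the panel genome-wide instead of
concentrating in polymorphic regions.  Ties on MAF break by lower missing
rate, then lower class, then lower position — a total order, so the selected
set is invariant to catalog row order.  The first and last candidates of
every chromosome are always retained: terminal markers define the covered
span, so dropping them would cost coverage disproportionately.  Windows whose
candidates all fail the floor are left empty with a warning naming the gap.

The exact MAF floors and window width any given published panel used are
generally not recoverable from the panel alone; these defaults produce
panels with the same density and coverage characteristics but are not claimed
to reproduce any particular panel marker-for-marker.

### Platform summary arithmetic

Per chromosome with n ≥ 2 markers: covered span = last − first position
(Mb); mean interval = span / (n − 1); maximum interval = largest adjacent
gap; coverage = 100 · span / reference length.  Totals: unplaced ("Un")
markers count toward the panel size but contribute no intervals; total
coverage divides the summed spans by the full reference length including
unplaced scaffolds; the overall mean interval is Σ span / Σ (n − 1) over
placed chromosomes.  Reported values are rounded **half-up** to one decimal
(the convention of published platform tables), not half-even.  These
conventions were fixed by verifying that they reproduce the released barley
and wheat panel tables (HvCoreSet_v1, TaCoreSet_v1) to the printed decimal —
see `tests/test_acceptance.py`.

## Genotype QC

Input is a VCF (GT field; multi-allelic records dropped with a count;
phasing ignored) or a tab-separated dosage table.  Dosages count the
alternate allele (0/1/2, NaN missing).

The site filter removes sites with missing rate > 0.5 **or** heterozygous
call rate > 0.2, both strict.  For essentially inbred material an OR
combination is the reading under which the heterozygosity criterion does any
work (a site failing it is suspect regardless of missingness); a stricter
AND combination is available via `combine="and"` for compatibility with
pipelines that filter only jointly-bad sites.

MAF is allele-count based: a heterozygote contributes one alternate allele;
missing calls are excluded from numerator and denominator.  Sites with zero
non-missing calls get NaN statistics and a warning rather than an error, so
one dead site cannot abort a run.

### MAF chromosome profiles

The smoother is a local-linear regression with tri-cube weights over the
`span` (default 0.3) nearest fraction of sites, evaluated on a 200-point
grid per chromosome.  Because the fit is a linear smoother
fit(x₀) = l(x₀)ᵀy, the pointwise variance is σ²‖l(x₀)‖² with σ² estimated
from in-sample residuals (denominator n − tr(L)); the 95% band is ±1.96 SE.
Fitted values are clipped to the attainable MAF range [0, 0.5].  Chromosomes
with fewer than `min_sites` (default 10) sites get raw points only.  Local
polynomial degree, weight kernel, and span are conventional defaults; none
is claimed to match any specific external smoother implementation.

## Diversity

PCA is computed on the covariance matrix: per-site mean imputation of
missing dosages, column centering, no variance scaling.  Percent explained
is per-component variance over the trace, so a full decomposition sums
to 100%.  `sklearn.decomposition.PCA` performs the factorization; a test
cross-checks scores and eigenvalues against a direct covariance
eigendecomposition.

LD uses the squared Pearson correlation of dosage vectors over accessions
non-missing at both sites, intra-chromosomal pairs only.  For inbred
material this genotype-correlation r² coincides with the haplotype r²; on
heterozygous material it is a different estimator than EM-haplotype-based
r², which is a documented deviation risk when comparing against tools that
phase.  Pairs with fewer than 20 complete observations or a monomorphic
member are skipped.  Chromosomes with no missing data use a single
correlation-matrix evaluation; pair subsampling (`max_pairs_per_chrom`,
seeded) caps the O(m²) cost, with full enumeration as the default.

Distance classes are half-open in bp — [0, 1), [1, 5), [5, 10), [10, 50),
[50, 100), [100, 200), [200, 400), [400, ∞) Mb — so every pair lands in
exactly one class.  Class comparison is one-way ANOVA followed by Tukey HSD
at α = 0.05 (statsmodels), with a hand-rolled insert-and-absorb compact
letter display; the Tukey test is applied to raw r² values despite their
non-normality, which matches common practice for this figure type but means
the letters should be read as descriptive, not strictly inferential.  The
`ld_threshold_percentile` statistic is the empirical percentile rank of a
threshold (default r² = 0.1) in the pooled r² distribution: 100 × fraction
of pairs at or below it.

## Genomic prediction

### Group scaling

Trait values are z-scaled within each (station, year) group: subtract the
group mean, divide by the group sample SD (n − 1).  This removes
location/scale differences due to growth conditions, evaluation procedures
and equipment, making accuracies comparable across stations.  Groups with
fewer than two records or zero spread are centered only, with a warning.
Scaling is always within a (station, year) cell, so no information leaks
across the years that cross-year validation separates.

### RR-BLUP

Model: y = 1μ + Zu + e with u ~ N(0, Iσ²_u), e ~ N(0, Iσ²_e), Z the
column-centered (training means) dosage matrix; missing dosages are imputed
with the training column means, identically at prediction time.

λ = σ²_e/σ²_u is estimated by REML profiled on the spectrum of ZZᵀ: project
out the intercept with S = I − 11ᵀ/n, eigendecompose SZZᵀS, and maximize

    l_R(λ) = ½ [ q log(q/2π) − q − q log Σ η²ᵢ/(ξᵢ+λ) − Σ log(ξᵢ+λ) ]

over q = n − 1 spectral components, where η = Uᵀ(y − ȳ).  η must be computed
from the *centered* phenotype: the null space of the projected kinship can
have high multiplicity (rank-deficient genotype matrices are routine in
closed breeding populations), and its arbitrary eigenbasis mixes in the
intercept direction, so uncentered projections contaminate the residual
spectrum.  The search runs on a 101-point grid over log₁₀λ ∈ [−5, 5]
(covering heritabilities ≈ 0.001–0.999 for standardized phenotypes) followed
by bounded Brent refinement between the best grid point's neighbours.  Given
λ: μ is the GLS intercept 1ᵀH⁻¹y / 1ᵀH⁻¹1 with H = ZZᵀ + λI, and
u = ZᵀH⁻¹(y − μ1) — numerically identical (tested to 1e−8 relative) to the
primal ridge solution (ZᵀZ + λI)⁻¹Zᵀ(y − μ1).  The genomic heritability
reported is σ̂²_u·c / (σ̂²_u·c + σ̂²_e) with c the mean diagonal of ZZᵀ.
A constant phenotype short-circuits to a flagged intercept-only model.

The implementation is self-contained by design: the mixed-model math is the
package's core computation, not a wrapper, and its agreement with the primal
ridge oracle and its parameter recovery on simulated data are part of the
test suite.

### Validation protocols

`cross_validate` default scheme holds out one random fifth per repetition
(train on the remaining four fifths, correlate predicted with observed on
the fifth), repeated `reps` times (default 100) with mean and SD reported.
A rotating k-fold scheme (every fold predicted once per repetition) is
available via `scheme="rotating"`; the repeated single hold-out is the
default because it is the protocol described for this panel class.
Accuracy is the Pearson correlation (Spearman by flag).  Splits are drawn
from one seeded generator, making any run bit-reproducible given
(seed, reps, k); a held-out set with constant observed values is redrawn.

`cross_year_predict` trains on one harvest year and predicts the other, both
directions, plus their arithmetic mean.

## The simulator: what it emulates and what it does not

Defaults describe a barley-like national program: 7 chromosomes at published
reference sizes (total 4584 Mb placed), a 768-marker panel (mean spacing
≈ 6 Mb), 1,000 accessions from 8 breeding stations over harvest years
2018/2019.  The wheat-like preset scales to 21 chromosomes, 960 markers,
1,800 accessions.

- **Structure**: station founder allele frequencies follow a Balding–Nichols
  model, p_s ~ Beta(p(1−F)/F, (1−p)(1−F)/F), around an ancestral frequency
  p ~ Beta(0.8, 0.8) clipped to (0.02, 0.98); F defaults to 0.08, enough for
  PCA to separate stations without making them disjoint gene pools.
- **Crossing**: founders are fully inbred; each accession is an F1 of two
  distinct same-station founders followed by 6 selfing generations.  Gametes
  recombine under the Haldane map (no interference) at an **effective**
  1 cM/Mb.  This rate is deliberately above the physical genome-wide average
  for cereals: the handful of simulated meioses stands in for many breeding
  cycles of historical recombination, and at 1 cM/Mb the simulated r² decays
  over the 5–50 Mb distance classes as real breeding panels do.  Residual
  heterozygosity halves per selfing generation (≈ 2⁻⁶ of the F1 level), a
  closed form the test suite checks.
- **Phenotypes**: y = g + station shift + (station, year) shift + e with
  g = Ma over 100 QTL drawn among panel markers (effects N(0, 1)); σ_e is
  set so var(g)/(var(g)+σ²_e) hits the target h²; shifts are expressed in
  units of the trait's within-group SD (defaults 1.0 station, 0.5 year) and
  each (station, year) cell inflates the residual scale by a lognormal
  factor (σ = 0.15 on the log scale) — together these reproduce the
  location/scale differences between station-year boxplots that motivate
  group scaling.  The realized h² = var(g)/(var(g)+var(e)) is recorded.
- **Missingness**: 2% completely at random; ~20% of amplicons carry a
  secondary polymorphism (Poisson mean 0.24), matching the census of
  multi-polymorphism amplicons reported for released cereal panels.

Not modeled: mutation, migration or germplasm exchange between stations,
selection during line development, genotyping error beyond missingness,
shared haplotypes across stations (founder haplotypes are drawn
independently given station frequencies, so pooled-population LD is weaker
than within-station LD), and genotype-by-environment interaction beyond
location/scale shifts.  Consequently, passing tests demonstrate that the
*algorithms* behave correctly under known truth — QTL recovery, heritability
recovery, structure recovery, decay monotonicity — not that real barley or
wheat panels will show any particular accuracy.  Published real-data
accuracies (hold-out correlations roughly 0.55–0.74 for barley traits,
0.44–0.83 for wheat) depend on germplasm, trait architecture and trial
quality that no simulator default reproduces; the package therefore checks
protocol properties (null traits score ≈ 0, noiseless traits ≳ 1, accuracy
monotone in h², bit-reproducibility) instead of chasing those numbers.

## Numerical choices and degenerate inputs

- Rounding of reported platform statistics: decimal half-up via the
  `decimal` module (string round-trip), avoiding float-representation
  surprises at .x5 boundaries.
- LOESS windows with zero bandwidth (duplicate positions) fall back to the
  full data range; the weighted normal matrix carries a 1e−12 ridge.
- REML eigenvalues are clipped at zero before logs; a non-finite restricted
  likelihood over the whole grid raises.
- `select_core_set` errors on chromosomes absent from the size table;
  windows with candidates but no floor-passers warn and leave a gap.
- Sites with zero variance or < 20 complete pairs are skipped in LD, not
  zero-filled.
- `cross_validate` redraws degenerate splits at most 20 times, then raises.

## Problem sizes used in the checks

The bundled tests and the acceptance script run at reduced scale chosen to
exercise every code path with stable statistics: populations of 200–800
accessions on the full 768-marker panel, 20 seeds for heritability recovery,
100 repetitions for cross-validation properties, and 40–50k records for
distribution-level LD checks.  These sizes are the package's own choices for
routine verification; all analyses accept full-scale inputs unchanged.
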