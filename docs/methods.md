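# Methods

This note documents the statistical machinery implemented in `pleioscan`:
the models and estimators, the conventions chosen where the standard
methods leave room, the synthetic-data generator and what passing tests on
it do and do not demonstrate, and known limitations.

## Input model and harmonization

A summary-statistics table carries, per SNP: identifier, chromosome (1–22),
1-based position, effect allele A1, other allele A2, the signed z-score of
the A1 dosage association, the two-sided p-value, and the effective sample
size. If only beta and SE are present, z = beta/SE; if p is absent,
p = 2·Φ(−|z|). Records violating the invariants (duplicate ids, p ∉ (0,1],
identical or non-ACGT alleles, |2·Φ(−|z|) − p| > 0.1·p) are dropped with
logged counts — the 10% relative band accommodates the rounding of printed
tables while catching genuinely mismatched z/p pairs.

Two traits are aligned by intersecting on SNP id; when the second trait's
alleles are recorded in the swapped orientation its z is negated, and
strand-ambiguous (A/T, C/G) SNPs are removed outright because no
allele-frequency column is assumed that could resolve them. Positions are
nominal hg19 labels; no liftover is attempted.

The LD reference is deliberately minimal: either explicit pairwise r²
(blocks = connected components of the r² > 0.1 graph, computed with
scipy's sparse connected-components routine) or a block assignment with a
single within-block r². Absent pairs are r² = 0.

## Quality control

Two regions of extended LD are excluded before any cross-trait FDR work —
the MHC (chr6:25,119,106–33,854,733) and the 8p23.1 inversion
(chr8:7,200,000–12,500,000), both hg19, boundaries inclusive because the
coordinates are printed as closed ranges.

Genomic control estimates λGC = median(z²)/median(χ²₁) on all
post-exclusion SNPs (no attempt to isolate an intergenic subset), floors it
at 1 so deflated statistics are never inflated, and rescales z ← z/√λGC so
that z and p remain mutually consistent. The correction is a projection:
applied twice, the second λGC is exactly 1. It is applied per trait,
independently, after taking the two-trait SNP intersection. Note the
well-known caveat that under true polygenicity λGC conflates signal with
inflation; the mixture model's σ0 parameter is the model-based alternative.

## Random pruning

All conditional Q–Q and condFDR estimation is performed on randomly pruned
SNP subsets: one SNP drawn uniformly from every LD block per iteration
(default 100 iterations), which removes the LD redundancy that would
otherwise manufacture spurious enrichment. Within a block, members are
ordered by SNP id before sampling, so results depend only on the SNP *set*,
not on input row order.

## Stratified conditional Q–Q curves

For each conditioning threshold t ∈ {1, 0.1, 0.01, 0.001}, the curve
records the averaged exceedance Ĝ_t(c) — the fraction of pruned SNPs with
conditioning p < t whose primary p ≤ c — on a fixed grid of
−log₁₀ c ∈ [0, 7.3) with step 0.01 (capped at 7.3, i.e. p = 5×10⁻⁸, to focus
on sub-genome-wide polygenic signal). Exceedances are averaged across
pruning iterations at fixed grid points because different iterations hold
different SNP subsets; a stratum empty in any iteration is dropped with a
warning.

Curves are plotted in the conventional orientation — nominal −log₁₀ p on
the vertical axis against the empirical quantile −log₁₀ Ĝ on the horizontal
axis — so pleiotropic enrichment appears as a leftward deflection of
tighter strata from the identity line. Two scalar readouts are exposed:
`nominal_at(x)`, the curve height at empirical coordinate x (identity under
the null), and the exceedance at a fixed nominal level, whose strict
increase across tightening strata is the enrichment statistic used in the
tests. The latter is preferred for monotonicity checks because under strong
enrichment the tight strata's tail quantiles saturate at the 7.3 cap.

## Conditional and conjunctional FDR

The per-SNP conditional FDR uses the conservative π0 = 1 estimator

    condFDR(p₁ | p₂ ≤ t) = min(1, p₁ / F̂(p₁ | p₂ ≤ t)),

tabulated on a 101 × 101 grid: −log₁₀ p₁ ∈ [0, 10] step 0.1 crossed with
cumulative conditioning thresholds −log₁₀ t on the same grid. Per pruning
iteration, the 2-D exceedance counts #(−log₁₀ p₁ ≥ eᵢ, −log₁₀ p₂ ≥ eⱼ) give
every cell in O(m + G²); cells are averaged across iterations, then
monotonized along the primary axis by a running maximum from smallest to
largest p₁ (no smoothing across conditioning thresholds). Every SNP —
pruned or not — receives values by bilinear interpolation at its own
(−log₁₀ p₁, −log₁₀ p₂), clamped to the grid at the boundary. Ties in p share
one ECDF value (≤ convention). The conjunctional FDR is exactly
max(condFDR_A|B, condFDR_B|A) per SNP, and 0.05 is the reporting threshold
for both statistics.

Two numerical conventions protect the deep joint tail, where naive
empirical estimation breaks down:

* **Constant extrapolation below the deepest observation.** Grid cells with
  primary p below the smallest observed p in their stratum have ECDF 0; per
  iteration those cells inherit the deepest *observed* cell value rather
  than a rank-1 floor. A rank-1 floor (F̂ ≥ 1/n) lets a SNP with jointly
  small (p₁, p₂) vouch for itself inside its own near-empty stratum — a 2-D
  scan-statistic selection effect that manufactures ≈ 0.65 false
  conjunctional loci per pure-null dataset of 100k SNPs. With
  pruning-averaging and constant extrapolation, a SNP absent from an
  iteration's subset no longer supports its own corner cell, and pure-null
  data yield zero loci.
* **Minimum stratum size.** Conditioning columns backed by fewer than 10
  pruned SNPs in an iteration are treated as undefined and inherit the
  nearest looser column (the same mechanism used for empty columns); an
  ECDF on a handful of points cannot produce a condFDR below p·n_stratum
  and is dominated by self-rank noise.

Both conventions only ever raise condFDR values, i.e. they are
conservative.

**Calibration.** The conditional FDR is a *cumulative* quantity —
P(null | P₁ ≤ p₁, P₂ ≤ p₂) — and thresholding it does not strictly control
the false-discovery proportion of the resulting call set: the cumulative
stratum mixes strongly enriched deep-p₂ slices with the boundary slice, so
the aggregate FDP of {condFDR < q} exceeds q by a factor that grows with
the strength of cross-trait sharing (Liley & Wallace 2015 analyse this for
cFDR and propose a corrected procedure, which is out of scope here). On
synthetic data where half of the primary trait's causal SNPs are shared and
the conditioning trait is near-fully powered, calls at condFDR < 0.05 show
a true FDP of ≈ 0.12; with no shared component the same code gives ≈ 0.06.
Per-cell accuracy of the estimator itself was verified against brute-force
enumeration. Users should read condFDR values as per-SNP posterior bounds
under the stratification, not as set-level FDP guarantees under strong
pleiotropy.

## Locus definition

Clumping is deterministic: significant SNPs (statistic < 0.05) are ranked
by (statistic, chromosome, position, id); greedy selection removes SNPs
with r² ≥ 0.6 to an already chosen one (independent significant SNPs), and
a second pass at r² < 0.1 yields lead SNPs. Candidate SNPs are all SNPs in
the harmonized pair with r² ≥ 0.6 to a lead, regardless of their own FDR
value. Locus borders span the candidate positions; loci on one chromosome
whose borders lie less than 250 kb apart are merged, keeping the
best-statistic lead (border-to-border distance, not lead-to-lead, since the
merge rule concerns candidate regions). Direction is concordant iff the
lead's two z-scores share a sign (zero z → undetermined). A locus is novel
iff its lead is significant, its original primary-GWAS p exceeds 5×10⁻⁸,
and it is both independent (r² < 0.6) of and more than 250 kb away from
every catalog SNP (lead-to-catalog distance).

## Causal-mixture overlap model

Stage one fits each trait's pruned z-scores with the two-component scale
mixture z ~ (1−π)·N(0, σ0²) + π·N(0, σ0² + n·σβ²). The likelihood omits the
LD/heterozygosity convolution of full summary-statistic mixture solvers by
design: it is intended for pruned SNP sets, where that convolution is
removed by construction, and acceptance is parameter recovery on the
matching generator, not numerical equality with any released solver.
Optimization is multistart Nelder–Mead in transformed coordinates
(logit π, log σβ², log σ0; 5 starts spanning π ∈ 10⁻⁴…5×10⁻², σβ² start
matched to the observed excess variance, seeded jitter). Because (π → 0)
and (σβ² → 0) are an equivalent ridge on null-like data, the reported
solution is the smallest-π fit within 2 log-likelihood units of the best —
a deterministic, AIC-window parsimony rule that leaves signal-rich fits
untouched.

Stage two fixes the margins at the univariate estimates (π₁ₛ + π₁₂ = π̂₁,
etc.) and maximizes the four-component bivariate likelihood over the two
free parameters: π₁₂ ∈ [max(0, π̂₁+π̂₂−1), min(π̂₁, π̂₂)] (sigmoid-bounded) and
ρ₁₂ (tanh-bounded), again multistart Nelder–Mead. Standard errors come from
a SNP-level bootstrap (default 20 resamples) that refits the bivariate
stage with margins held at the point estimates — faster and stable, at the
cost of ignoring margin uncertainty in the SEs.

Derived quantities: counts = π·m; Dice = 2·π₁₂/(π₁+π₂);
r_g = ρ₁₂·π₁₂/√(π₁·π₂) (|r_g| ≤ |ρ₁₂| always; undefined when a trait has no
causal component); and n90 = π·m·q90, where q90 ≈ 0.4446 is the smallest
fraction of i.i.d. Gaussian causal effects whose expected summed squared
effects reach 90% of the total — computed exactly from the χ² tail-mean
identity E[X·1(X>x)] = P(χ²₃ > x) for X ~ χ²₁, and cross-checked against
Monte-Carlo sorting in the tests. The no-overlap comparison refits with
π₁₂ = 0 (zero free parameters given the margins) and reports
ΔAIC = AIC(constrained) − AIC(full); positive values favor the overlap
model.

## Colocalization

Per SNP, log ABF = ½(log(1−r) + r·z²) with r = w/(v+w). The effect-estimate
variance v is SE² when available and otherwise approximated as 2/n on the
standardized-trait scale (a logged, declared approximation). Prior effect
SDs default to 0.15 for the case-control trait (log-odds scale) and 0.20
for the quantitative molecular trait, configurable. Hypothesis sums are
computed in log space with log-sum-exp; the H3 cross-sum uses
(Σ·Σ − Σdiag) in log space for O(m) cost, guarded with log1p/expm1 so
regions of two SNPs remain exact. Priors default to p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵ (warning if p12 > min(p1, p2)); the sensitivity analysis re-runs
with p12 = 5×10⁻⁶ and flags stability when every run reaching the 0.80
support level supports the same hypothesis. The 0.80 threshold is a
reporting flag, never a filter. Regions are lead ± 250 kb intersections of
the trait and QTL tables. The implementation is tested for exact (1e-10)
agreement with explicit enumeration over all causal configurations on
small regions.

## Synthetic-data generator

The generator is the package's test bed and defines the study conditions
under which everything downstream is validated. Per LD block (default: five
SNPs at r² = 0.7; disjoint equicorrelated blocks, not a realistic LD
matrix), a causal component is drawn from
(1−π₁ₛ−π₂ₛ−π₁₂, π₁ₛ, π₂ₛ, π₁₂); anchor effects are Gaussian on the
standardized-genotype scale with correlation ρ₁₂ inside the shared
component; tag SNPs inherit the block's component label with
β_tag = √r²·β_anchor (a tag of a causal block genuinely carries
association signal, so calling it is a true discovery in the locus-tagging
sense). Observed z = √n·β + ε with block-equicorrelated noise
(variance σ0², correlation r² within a block — so null SNPs in a block are
correlated, stressing the pruning machinery), independent across traits.

Defaults: m = 100,000 SNPs, π₁ₛ = π₂ₛ = π₁₂ = 0.005, n·σβ² = 40 per trait
(n = 100,000, σβ² = 4×10⁻⁴), ρ₁₂ = 0.8 (a mostly concordant shared
component), σ0 = 1 (no uniform inflation). These are two symmetric,
moderately polygenic, well-powered traits with half of each trait's causal
variants shared — a deliberately strong-sharing regime. Where a validation
needs a different architecture it is stated with the check (e.g. the
no-sharing configuration π₁₂ = 0 with a symmetric π₂ₛ = 0.005 for
calibration; a null primary trait with π₂ₛ = 0.03 at m = 10⁶ for the
Q–Q strata-coincidence check, sized so the tightest stratum holds tens of
thousands of SNPs and the 0.1 vertical-gap tolerance is a ≥3σ bound).

What the generator does **not** emulate: allele-frequency spectra and
heterozygosity weighting (effects are on the standardized scale throughout,
which is also why the mixture likelihood needs no frequency terms),
realistic LD decay, population structure or relatedness, sample overlap
between the two GWAS (which would correlate the null noise across traits),
and uniform inflation beyond a scalar σ0. Passing tests therefore
demonstrate internal correctness and statistical behavior under the stated
mixture model — not performance on real GWAS with complex LD and shared
controls.

## Pipeline and reproducibility

`run_pipeline` executes ingest/simulate → harmonize → exclusion → genomic
control → conditional Q–Q → condFDR/conjFDR → loci (both statistics, with
novelty if a catalog is given) → mixture fit, writing every intermediate
table (TSV), a JSON report, and a manifest of per-stage parameters and
SHA-256 output hashes. Every stage's seed derives from the single run seed
and the stage name via SHA-256, so stages are independently re-runnable and
a config + seed pair reproduces all outputs bit-identically. When the run
is simulation-backed, the report also scores the condFDR calls against the
generator truth (false = null or other-trait-specific).

Problem sizes in the shipped validation suite were chosen to make each
check statistically meaningful at desk scale: 20 replicates of m = 10⁵ for
calibration, 10 seeds of m = 2×10⁵ independent SNPs for mixture recovery,
exhaustive z-grids on regions of ≤ 6 SNPs for coloc, and m = 10⁶ for the
Q–Q null geometry.

## Known limitations

* condFDR/conjFDR thresholding is not a set-level FDP guarantee under
  strong cross-trait sharing (see Calibration above); a corrected cFDR
  procedure is not implemented.
* The mixture likelihood ignores residual LD in the pruned set (r² ≤ 0.1
  leakage) and fixes margins before the bivariate stage, so bivariate SEs
  understate total uncertainty.
* λGC-based correction conflates polygenic signal with inflation; no
  LD-score-intercept alternative is provided (out of scope).
* Colocalization assumes a single causal variant per trait per region; no
  multi-causal (SuSiE-style) extension.
* Novelty classification is only as good as the supplied catalog; the
  built-in two-SNP catalog is a synthetic stand-in for the worked example,
  not a curated resource.
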