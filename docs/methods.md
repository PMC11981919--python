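# Methods

This note records the models implemented in `gastroclone`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Synthetic cohort generator (`cohortsim`)

The generator emulates the statistical structure of a microdissection WGS
cohort rather than reads or alignments.

**Burden model.** Per gland, the true SNV count is Poisson with mean
`snv_rate × age + donor intercept`, the intercept drawn once per donor
from N(0, `donor_sd`).  Defaults: `snv_rate = 27.8`/year,
`indel_rate = 2.0`/year, `donor_sd = 60` SNVs (the indel intercept is
scaled by the rate ratio).  Poisson is the maximum-entropy choice given
only a linear mean; the donor intercept standard deviation is a free
parameter — the per-gland variance structure beyond donor effects is not
otherwise constrained.  A zero rate admits no donor offset, so zero-rate
configurations generate empty cohorts.

**Signature mixture.** Channels are drawn from synthetic reference
signatures (below).  Baseline mix: SBS1 0.2, SBS5/40 0.6, SBS18 0.2.
Metaplastic glands re-weight signatures by the accelerations
SBS1 × 3, SBS18 × 8, SBS5/40 × 1 and rescale so the total burden
multiplier equals `metaplasia_snv_fold = 2.8`.  The baseline mix was
chosen so the accelerations integrate exactly to that overall fold
(0.2·3 + 0.6·1 + 0.2·8 = 2.8), keeping the two documented quantities
mutually consistent.  Indels scale by `metaplasia_indel_fold = 4.4` with
the mix shifted toward 1-bp deletions (ID2), so the ID2:ID1 ratio rises
in metaplastic glands.

**Reads.** Depth is negative-binomial with dispersion `depth_shape = 15`
and the mean calibrated so the distribution's median equals
`depth_median = 23`.  NV | NR is binomial at the expected VAF:
`g/2` for diploid somatic variants, `g·2/3` and `g/3` for duplicated and
non-duplicated variants on a trisomic chromosome, and 0.5 for germline
heterozygous sites, where `g = clonal_fraction × (1 − contamination)`
(defaults: clonal fraction uniform on 0.75–1, contamination 0.1, so VAF
peaks land in the observed 0.34–0.45 range).  Stromal contamination does
*not* shift germline VAFs — contaminating stroma is host tissue with the
same genotype; on a trisomic chromosome germline VAFs are the linear
cell-fraction mixtures `g·2/3 + (1−g)/2` and `g/3 + (1−g)/2`.

**Trisomy.** With probability `trisomy_prob` a gland carries a trisomy of
`trisomy_chrom` (default chromosome 20) with one parental copy duplicated
at timing fraction `trisomy_timing` of the lineage's mutation time.  With
two chromosome copies before the gain and three after, a mutation on the
gained chromosome is duplicated with probability `t/(3−t)`, which makes
the timing formula an identity (T(t) = t) and gives equal duplicated and
non-duplicated counts at t = 1.  Coverage inflation on the trisomic
chromosome (~1.5× reads) is **not** simulated; depth and copy number are
independent in this generator.

**Artifacts and calling.** Recurrent artifacts appear in every sample of
a donor with a shared error VAF ~ U(0.02, 0.15) and binomial counts —
i.e. minimal cross-sample overdispersion, which is exactly the signal the
ρ filter keys on.  About 30% of artifacts are additionally given failing
mapping-quality annotations (ASMD < 140 or CLPM > 0); real variants are
drawn with passing annotations.  Variants whose maximum per-sample NV is
below 4 are never emitted as "called", emulating the caller's minimum
support and creating the detection-sensitivity deficit the burden
correction must undo.

**Fields beyond the obvious.**  `n_metaplastic` appends extra metaplastic
glands round-robin over donors; `n_phased_snps` adds heterozygous SNPs on
the trisomy chromosome whose parental haplotype is recorded as phasing
truth; `driver_prob`, `area_mean`/`area_sigma` give glands driver
mutations and lognormal microdissection areas for the epithelium-fraction
stage.

**What the generator does not emulate:** alignment and mapping error
structure, copy-number/coverage coupling, subclonal architecture beyond a
single dominant clone, shared early-development mutations between glands
(each gland's somatic mutations are private), site- or donor-specific
artifact spectra, and sex chromosomes.  Passing tests therefore show the
statistical machinery is correct and calibrated under these assumptions,
not that it is robust to every failure mode of real sequencing data.

## Synthetic reference signatures (`refsigs`)

COSMIC v3.4 tables are licensed downloads and are not bundled.  The
package constructs deterministic *synthetic* stand-ins with the
qualitative character of the processes: SBS1 concentrated on N[C>T]G
(5-methylcytosine deamination), SBS18 on C>A with peaks at oxidative-damage
contexts, SBS5/40 flat with a mild T>C tilt, SBS17b with T>G peaks;
ID1/ID2 as 1-bp T insertions/deletions at long homopolymer runs, ID5 as
diffuse 1-bp deletions.  Channel weights are invented; channel labels and
ordering follow the COSMIC conventions, and `read_cosmic_tsv` accepts real
tables in the standard layout.  Because the generator draws channels from
the same catalog the fitter uses, exposure and fold-recovery tests are
genuine round trips through catalog construction and EM, not table
lookups.

## Filtering (`postfilter`)

Stage order and precedence: quality_fail > germline > artifact > pass;
classification is idempotent.  "Largely diploid samples" is a per-cell
mask on the count matrix (the generator marks trisomic-chromosome cells
non-diploid; real-data adapters may derive the mask from copy-number
calls).  The germline test is lower-tail: somatic variants are absent
from most samples, depressing the aggregate VAF below 0.5.  The
beta-binomial mean is fixed at the pooled VAF, keeping the grid search
one-dimensional; the grid log₁₀(ρ) ∈ {−6, …, −0.05} in steps of 0.05 is
evaluated in full (120 points) with a vectorised gammaln implementation —
tests assert exact argmax agreement with `scipy.stats.betabinom` on a
dense grid.  BH families are per donor and per test type.  Variants
assessable in fewer than two samples pass the ρ stage flagged
`single_sample`; pooled VAF 0 or 1 pins ρ at the upper grid boundary
flagged `degenerate`.

## Clonality, sensitivity and rate models (`clonality_burden`)

The truncated binomial mixture is fitted by EM with the M-step solved by
bounded scalar maximisation; the log-likelihood is asserted non-decreasing
per iteration, and at `min_reads = 0` the component likelihood reduces
exactly to the plain binomial.  K ∈ {1, 2, 3} is scanned in increasing
order with BIC; the scan stops as soon as adding a component stops
lowering BIC, and a run whose components merge (peak gap < 10⁻³) or die
(weight < 10⁻³) is terminated early as equivalent to the K−1 fit.  Four
restarts (one quantile-based, three jittered) are used per K — recovery
was indistinguishable from larger restart counts while keeping
whole-cohort runs tractable.  In the per-sample pipeline the mixture is
fitted on a deterministic subsample of at most 300 detected SNVs (the
peak's standard error at depth ~23 is already ≈ 0.006 there); raw burdens
count all detected variants.

Sensitivity uses the empirical depths at the sample's detected passing
sites (not genome-wide coverage), so it is computable from the count
matrix alone; this slightly over-estimates S (detected sites are
depth-biased), producing a small downward bias in corrected burdens that
stays well inside the acceptance tolerances.  Clonality: median VAF
strictly above 0.25 is monoclonal.

Rate models are MixedLM fits by maximum likelihood (never REML when
models are compared); "ANOVA" comparisons are likelihood-ratio χ² tests
with degrees of freedom equal to the parameter-count difference.
Chronic inflammation enters as a binary absent/mild vs moderate/severe
indicator.  Fold changes divide corrected burdens by the fixed-effects
expectation at the sample's age from the non-metaplastic model.

## Signatures (`signatures`)

Exposure fitting is a multinomial-mixture EM; the log-likelihood is
concave in the weights, so no restarts are needed and convergence is
declared at Δloglik < 10⁻⁸.  Catalogs below 50 mutations trigger a
warning (exposures get noisy), not an error.  SBS5 and SBS40 are reported
combined as SBS5/40 (their flat spectra are not separable at these
mutation counts).  Deconvolution of an externally extracted spectrum is
the same EM on a pseudo-catalog followed by the cosine ≥ 0.90 acceptance
rule.  Indel classification from alleles is implemented for 1-bp
insertions/deletions at annotated homopolymers; other indels count as
unclassified with a warning (a precomputed channel column is honoured
when present).  The ID2:ID1 ratio uses attributed counts when given, or
the long-homopolymer defining channels (run ≥ 5) of a catalog.

## Copy-number timing (`cnv_timing`)

Cluster means are fixed at the copy-number expectations scaled by sample
clonality (`clonal_scaling × CN_dup/CN_total` and `× 1/CN_total`) and only
the mixing weight is estimated — with tens to hundreds of SNVs per region,
free means are not reliably identifiable.  Posterior ties go to
non-duplicated so timing is never inflated by ties.  T above 1 (sampling
noise) is clamped with a flag.  The confidence interval conditions the
two counts on their total (exact Poisson-ratio ≡ conditional binomial),
takes Clopper–Pearson bounds on the duplicated proportion and maps them
through the timing formula.  `timing_to_age` converts T to an approximate
age via the sample's corrected burden and the fitted per-year rate; this
is an interpretation layer (without phylogenies the gain can only be
bounded within the sample's lineage), and is clearly separated from the
core estimate.

## Trisomy detection (`trisomy_phase`)

Phasing: within each trisomic WGS sample, SNPs with VAF > 0.5 lie on the
duplicated haplotype; labels are harmonised across samples by orientation
flips (different glands may duplicate different parental copies) and
fixed by majority vote, with the mean agreement reported as concordance
(a warning below 0.9 signals absent trisomy signal).  The LRT null uses
the pooled-count MLE Σnv/Σnr across both haplotype groups
(likelihood-consistent; `pooled_null=False` switches to the mean of
per-site VAFs), the alternative one binomial per group; the statistic is
referred to χ²(1).  Sites need strictly more than five reads (NR ≥ 6).
BH runs across the donor's panel samples; a call needs q < 0.05 (the
significance level is configurable — no specific value is canonical) and
a haplotype mean-VAF difference ≥ 0.1.  The r×c Fisher test enumerates
all margin-consistent tables (multivariate hypergeometric) and sums the
probabilities ≤ that of the observed table; empty rows/columns are
dropped first, and a single remaining row or column gives p = 1.

## Mutant epithelium fraction (`mutant_fraction`)

Cell fractions above 1 are capped with a flag.  Multiple drivers in one
microdissection combine by the maximum cell fraction (clones assumed
nested/overlapping); `combine="capped_sum"` provides the additive
alternative.  Regression runs on donor-level aggregated proportions to
avoid pseudo-replication.  Driver-free contaminant reads depress VAFs and
hence the estimate — the estimator is deliberately conservative under
contamination.

## Numerical choices

- Binomial tail probabilities P(X ≥ m) for small m use the closed-form
  polynomial in p/(1−p) with binomial coefficients built by recurrence;
  tests assert agreement with `scipy.stats.binom.sf` to 10⁻¹⁰.
- Beta-binomial grid log-likelihoods are computed chunk-wise with
  `scipy.special.gammaln`; ρ-independent binomial coefficients are added
  once so reported log-likelihoods are complete.
- Mixed models fall back from L-BFGS to the default optimiser on
  non-finite likelihoods; perfectly deterministic fits (zero residual
  variance) report degenerate confidence intervals at the estimate.
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical configurations are bit-reproducible.

## Problem sizes

The test suite and the acceptance script run cohorts of 12 donors ×
~7 glands (plus 19 metaplastic glands), about 1.3–1.5 × 10⁵ variants per
cohort, with 20 seeded replicates for recovery summaries; property
simulations use 100–500 replicates of small count-level draws.  These
sizes give Monte-Carlo error comfortably inside the stated tolerances
(±15% on rates and burden folds, ±20% on signature folds) while keeping a
full run in the tens of minutes on a single CPU.

## Known limitations

- The generator's independence of depth and copy number means timing
  estimates are slightly easier than on real trisomies (no coverage
  shift); conversely its artifacts are idealised (exactly shared error
  rates), making the ρ filter's ROC an upper bound on real performance.
- Sensitivity correction ignores the depth bias of detected sites
  (≈1–3% downward bias on corrected burdens at 23× coverage).
- Exposure fitting assumes the reference catalog spans the true spectra;
  with the synthetic catalog this holds by construction, with real COSMIC
  tables it is the user's modelling decision which subset to fit.
- The mutant-epithelium estimate assumes microdissected areas are pure
  epithelium; contamination biases it downward, not upward.
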