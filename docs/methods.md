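# Methods

## The simulated study design

The generator reproduces the structure of a barley NAM population of the
HEB-25 type. One inbred recurrent parent (alleles coded 0 at every marker)
is crossed to 25 donor accessions; each donor is polymorphic at any given
marker with probability 0.5, independently per marker and family, which
matches the reported 40–54% simple-matching similarity between donors and
the recurrent parent. The F1 is backcrossed once to the recurrent parent
(20 BC1 plants per cross) and selfed three times by single seed descent;
each of the 1,420 lines (24 families of 57, one of 52) descends from one
BC1 plant through three private selfing generations. Meiosis uses the
Haldane map function without crossover interference — the simplest standard
choice — on a uniform stand-in genome of 7 chromosomes × 150 cM with 2,000
markers by default (configurable up to chip scale). The closed-form
expectation for a segregating locus after one backcross and s selfings is
obtained by halving the heterozygote class per generation; for BC1S3 it is
0.71875 : 0.0625 : 0.21875, which the simulator reproduces to Monte-Carlo
error.

## Trait architecture and calibration

The default flowering-time architecture plants:

- seven additive QTL with wild-minus-cultivated effects of −1.4, −3.0,
  −3.1, +3.2, +2.2, +3.8 and +4.1 days at fixed map anchors, each
  segregating in 23–25 families (families drawn once from a fixed stream);
- a 12-haplotype locus at the *Ppd-H1* anchor (2H, 23 cM). Eleven exotic
  haplotypes carry effects from −8.6 to −11.1 days (earliest: H-6), one
  exotic haplotype (H-45) carries no effect, and one donor carries the
  elite haplotype H-2, so the locus segregates in 24 of 25 families. The
  per-donor effects average exactly −9.5 days, which is the additive effect
  the locus presents to a biallelic scan. A line's genetic contribution is
  (dosage/2) × its family's haplotype effect; heterozygous lines carry both
  sequences and are therefore excluded from haplotype grouping (their
  haplotype label is missing), a choice that keeps the haplotype contrasts
  unbiased;
- two di-genic interactions, 3.0 days (4H×5H, mirroring the vernalisation-
  gene pair of the study system) and 2.0 days (3H×7H), coded as centred
  dosage products (d_j − 0.5)(d_l − 0.5), consistent with the point-wise
  product design of the epistatic prediction model;
- a polygenic background of 300 markers (drawn away from the QTL anchors)
  with normal effects.

Calibration proceeds in the order: major-locus variance is whatever the
planted effects realise in the simulated genotypes; the polygenic component
is then rescaled (solving a quadratic in the scale factor, so covariance
with the major loci is accounted for) to make the realised genotypic
variance exactly σ²_G = h²·SD² = 0.916 × 6.5² = 38.70 days². If the major
loci alone exceed σ²_G the generator raises an infeasible-calibration
error. Non-genetic variance follows from the entry-mean identity
SD² = σ²_G + σ²_GE/l + σ²_R/(l·r): the deficit SD²(1 − h²) is split 40:60
between genotype-by-environment interaction and plot residual (the real
data give no basis for this split; it is a declared default and does not
affect the entry-mean calibration). Environment main effects have SD 4
days — year-to-year shifts of a few days are typical for flowering dates —
and do not enter h². Three environments × two replicates are emulated as
complete randomized blocks; the first trial year's variable plot structure
is not reproduced.

What the generator does *not* emulate: family-specific (including
opposing-sign) allelic series at loci other than *Ppd-H1*, genotyping
error, selection during population development, and real LD between donor
genomes (donor alleles are independent across markers, so parent-panel LD
is pure noise; within-population LD still arises from the breeding design).
Consequences for interpretation are noted under Limitations.

## Trial analysis

Variance components of the two-way random model with interaction are
estimated by REML. Balanced tables are solved in closed form from the
ANOVA expected mean squares — on balanced data this *is* the REML solution
whenever the estimates are interior, with negative solutions truncated at
zero. Unbalanced tables go through an EM-REML iteration on the dense
mixed-model equations (method-of-moments start, relative change < 1e-10 or
500 iterations); this path is intended for modest problem sizes, while the
simulator always emits balanced data. Unreplicated data confound the
interaction and residual; the residual is then reported as zero and the
interaction absorbs both. Entry-mean heritability uses the standard form
h² = σ²_G/(σ²_G + σ²_GE/l + σ²_R/(l·r)). BLUEs come from the two-way fixed
model (genotype + environment, sum-to-zero environment contrasts); on
balanced data this reduces to the per-line mean, and a disconnected
line-environment design is rejected.

## Model-B association scan

The base model is BLUE ~ intercept + family (25-level fixed factor) +
cofactors. Cofactors are markers selected by forward stepwise search with
backward elimination checks, minimising SBC = n·ln(SSE/n) + k·ln(n), capped
at 50 to bound runtime. Forward steps use a Gram-Schmidt-updated
residualisation so each step is O(n·m); the backward check computes all
single-cofactor drop costs at once from the fitted model's coefficient
covariance. Note that with thousands of candidate markers the best
candidate's χ² typically exceeds the ln(n) entry penalty even under a pure
null, so a handful of spurious cofactors is the expected behaviour of
SBC-minimising selection at this scale, not a defect.

Each marker is then tested by the partial t-test of its dosage slope in the
base model, excluding cofactors mapped within 1 cM of the tested marker
(the tested marker's own cofactor copy is thereby always excluded); markers
constant after family-monomorphism recoding get an undefined effect and
P = 1. The reported additive effect is twice the slope (homozygous donor
minus homozygous recurrent). Per-family effects are within-family simple
regressions, reported only where the marker segregates in that family.
P-values are Holm-adjusted genome-wide; significant markers closer than
5 cM with same-sign effects are chained into QTL, with the minimum-adjusted-P
marker (ties: smaller position) as peak. The two-dimensional scan adds both
main effects and the product term per pair, tests the product, and applies
Holm over the tested pair set only (the pair universe — by default a 5 cM
grid plus significant markers — is a declared choice). The haplotype
variant replaces the anchor SNP by a qualitative haplotype factor; level
means are population-marginal adjusted means and all pairwise comparisons
use the Tukey–Kramer studentized-range test with model-based standard
errors, so single-line levels are retained with large standard errors.

## Genomic prediction

RR-BLUP fixes the ridge penalty from the trial variance components,
λ = (σ²_R/l)/(σ²_G/m), and solves the centred normal equations — in marker
space when m ≤ n, otherwise through the algebraically identical Woodbury
(line-space) form. BayesCπ places a point mass at zero (probability π,
uniform prior) and a common-variance normal on each marker effect, with
scaled inverse-χ² priors (ν = 4.2) whose modes are set to σ²_G/(0.5·m) for
the effect variance and σ²_R/l for the residual; π is sampled from its
Beta(m−k+1, k+1) conditional. The Gibbs sampler (numba-compiled,
residual-update form) runs 10,000 cycles with 1,000 burn-in by default and
averages post-burn-in effect draws; a fixed seed makes chains bit
reproducible. Some presentations of this sampler attach the point mass to
the effect *variance* rather than the effect; the standard construction
(point mass on the effect, common variance) is implemented here. The epistatic extension appends raw
(uncentred) dosage-product columns for the declared pairs with separate
penalties from σ²_g = p_G·σ²_G/m and σ²_f = (1−p_G)·σ²_G/p; with no pairs
it reduces exactly to RR-BLUP, and the simulator's centred product coding
is absorbed by the intercept and main effects.

## Cross-validation

Five-fold CV stratified within family: per family, fold sizes differ by at
most one and remainder lines go to folds drawn without replacement. Each
run fits on 80% and predicts the held-out 20%;
p_G = r²(predicted, test BLUEs)/h², with h² estimated once from the full
trial and values above 1 reported as-is with a warning. The default record
is the mean over 100 runs (20 × five-fold). Scan-based runners redo
cofactor selection and Holm correction inside every estimation set and
predict from the per-run QTL-group peak markers; the epistatic runner also
rebuilds its pair set per run from those peaks (all peak-marker pairs — the
full significant-marker pair universe is out of desk scale) with the
additive RR-BLUP mean p_G as its variance split. Fixed-marker runners are
plain OLS on the chosen markers without family terms, so a set of random
markers carries essentially no predictive information rather than
inheriting family means. "Observed genotypic values" in the test set are
taken to be the test lines' BLUEs.

## Problem sizes and numerical choices

Default analyses run at 1,420 lines × 2,000 markers, the package's chosen
desk scale for a 5,709-SNP chip. The test suite evaluates the CV ladder at
5 runs (one five-fold replication, identical folds across models so
comparisons are paired) with shortened BayesCπ chains (2,500 cycles), and
the full 100-run record for the peak-marker models and detection rates.
Loess smoothing for LD decay uses span 0.5, tricube weights, locally
quadratic fits, a 0.1 cM evaluation grid and linear interpolation at the
baseline crossing. Chi-square placement compares log survival probabilities
(ties only for numerically identical log P, in which case the tied markers'
min/max positions are averaged), avoiding spurious ties from P-value
underflow at n = 1,420. All stage randomness descends from a master seed
through named substreams.

## Known limitations

- The peak-effect estimator of the scan carries the linked polygenic
  background within the long-range LD of a BC1S3 design; across simulation
  seeds its spread around the planted −9.5-day effect is roughly ±0.6 days,
  and single-locus p_G varies accordingly. This is a property of the study
  conditions, not of the estimator implementation — a real NAM population
  carries family-specific allelic series at every locus, so a biallelic
  marker represents a smaller share of its local genetic variance than a
  uniform-effect simulation planted with the same marginal effect produces.
- Parent-panel LD is structureless by construction, so LD-decay estimates
  on simulated parents are only exercised against planted synthetic decay
  curves, not emergent ones.
- EM-REML for unbalanced trials is dense and intended for small designs.
- No genotyping-error or selection models; no sequence-level simulation —
  markers are abstract biallelic sites.
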