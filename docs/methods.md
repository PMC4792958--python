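# Methods

## Scope and data model

fibromark reimplements the statistical chain of a small case/control
methylation-array study — QC and normalization of beta values, per-CpG
beta-regression differential methylation, candidate filtering, a
partial-correlation protein network, and Bliss-independence drug-synergy
scoring — as a library operating on plain probes × samples tables. Patient
data of the motivating design (24 primary fibroblast cultures, 12 with
radiation-induced fibrosis and 12 fibrosis-free, profiled on 450K arrays)
are controlled-access; the package therefore ships first-class synthetic
generators whose planted ground truth drives all recovery and calibration
tests.

## Synthetic cohorts

Beta values are drawn per probe j and sample i from
Beta(μφ, (1−μ)φ) with logit μ_ij = logit(m_j) + δ_j·case_i + covariate
terms. Design choices and defaults:

- **Design size** 12 cases vs 12 controls, 20,000 probes — the array study's
  sample size at a probe count scaled for desk-size runs; gene loci of 1–4
  CpGs cover the probes, the remainder is intergenic.
- **Baseline means** m_j from a 50/50 mixture of Beta(1.5, 6) and
  Beta(6, 1.5) — the bimodal (mostly un-/mostly methylated) marginal
  distribution typical of genome-wide CpG panels.
- **Precision** φ = 50, giving a cross-sample s.d. of ≈ 0.07 at μ = 0.5 —
  the order of inter-individual variability seen on methylation arrays.
- **Planted DMRs**: effects are planted on the logit-mean scale (matching
  the regression link) so the implied beta-scale difference is available in
  closed form via the inverse logit; `dmr_study_config` draws 10 loci with
  2–4 affected CpGs and 0.12–0.20 beta-scale hypomethylation at mid-range
  baselines (0.45–0.65), the magnitude and direction the screen design
  targets.
- **Covariates**: age ~ U(40, 70), ever-smoker ~ Bernoulli(0.4),
  chemotherapy ~ Bernoulli(0.5), independent of group; logit-scale
  coefficients default to 0.004/year, 0.05 and 0.05 — present so the
  adjustment is exercised, small so they do not dominate.
- **Array artifacts**: 70% Infinium type II probes whose betas are
  compressed toward 0.5 by factor 0.85 (the reduced dynamic range of the
  type II chemistry); a multiplicative 1.15 gain on the red channel
  (type I probes read both signals in one channel, type II read M in green
  and U in red, so the bias distorts type II betas and is recoverable by
  colour correction); detection failures at rate 0.002 (beta replaced by
  uniform noise, detection p > 0.01) and low-bead wells at rate 0.005 —
  realistic single-digit-per-mille rates for a passing array.
- Intensities are total-lognormal: T ~ exp N(log 5000, 0.25), M = βT,
  U = (1−β)T; observed betas are M/(M+U+100), so the conventional offset's
  slight compression is present in the simulated data too.

What the generator does **not** emulate: probe-probe spatial correlation,
chip/position batch effects, cell-type composition, SNP-driven trimodality.
Passing recovery tests therefore show the statistics behave as designed
under the model's own assumptions, not that they are robust to every
artifact of real arrays.

The protein generator draws proteins × samples panels from N(0, Ω⁻¹) with a
user-specified symmetric positive-definite precision Ω; the truth records
−ω_ij/√(ω_ii ω_jj). The dose-grid generator produces replicate viabilities
(1−fa)(1−fb) − interaction + N(0, σ²) clamped to [0, 1]. The qPCR generator
emits ct tables in which the treatment ct of a target is lowered by
log2(fold change) against three stable housekeepers.

## Preprocessing

Stages run in the order: bead filter → detection mask → missingness drop →
SNP drop → kNN imputation → colour correction → BMIQ → variance filter,
with defaults min_beads 3, detection p 0.01 (strict >), missingness 0.3
(strict >), k = 10, s.d. 0.05 (strict <). Numerical and design choices:

- **kNN imputation** treats probes as items and samples as features;
  distances are NaN-aware Euclidean scaled by the co-observation count and
  neighbour weights are inverse distance. The implementation is a
  BLAS-blocked rewrite of the standard array-imputation scheme and is
  verified against scikit-learn's `KNNImputer` to ≤ 1e-12 in the tests;
  a probe with no reachable donor falls back to its own mean.
- **Colour correction** maps, per sample, each channel onto the pooled
  average quantile function: a value at ECDF position p becomes the mean of
  itself and the other channel's p-quantile. The map is monotone within
  channels and a channel pair with identical distributions is an exact
  fixed point. Betas are recomputed as M/(M+U+100) (offset configurable)
  for cells whose values came from intensities; imputed cells keep their
  imputed values.
- **BMIQ** fits, per sample, a 3-state beta mixture (unmethylated /
  hemimethylated / methylated; EM initialized by the 0.25/0.75 thresholds,
  weighted-moment M-step, tolerance 1e-4, ≤ 100 iterations) to the type I
  and the type II values, then transforms type II values by the monotone
  probability-integral map F_I⁻¹(F_II(x)) between the two fitted mixture
  CDFs. Mapping through the full mixture CDFs (rather than class-wise with
  boundary stitching) is this package's choice: it is monotone by
  construction and free of class-boundary discontinuities. EM fits use a
  deterministic quantile-stratified subsample of ≤ 4000 values; the map is
  applied to all values. Samples with < 50 probes of either design type are
  left untouched with a warning.
- **Idempotence**: the cleaned cohort records which normalization stages
  ran and stamps imputed cells as resolved (detection p → 0, bead count
  floored), so a second pass of `run_preprocess` is an exact no-op. The QC
  report's per-stage counts add up to (probes in − probes out).
- Whether the s.d. filter acts on raw or normalized betas is a genuinely
  open choice; it runs last (on normalized values) here, and both the s.d.
  cut and the detection/missingness cuts use the strict inequalities their
  printed thresholds suggest.

## Differential methylation

Betas are clamped to [1e-6, 1−1e-6] (boundary values carry no usable
likelihood information under the beta model; dropping them instead is a
config away but discards data). Each probe is fitted by maximum likelihood
with logit mean link and an intercept-only log-link precision. Because all
probes share one design matrix, the fitter is a Fisher-scoring Newton
iteration vectorized across probes (score and expected-information tensors
assembled by einsum, step-halving on the log-likelihood, design columns
scaled to O(1)); 20,000 probes fit in about a second. Standard errors come
from the expected information.

Two finite-sample adjustments keep the Wald test calibrated at n = 24:
the ML precision estimate is rescaled by (n−k)/n (the beta-regression
analogue of the Gaussian variance-bias correction; ML overestimates φ and
hence understates the standard errors), and the Wald statistic is referred
to a t distribution with n−k degrees of freedom instead of the normal.
The pairing was chosen by measuring the empirical null on 200,000
simulated probes at this design size: the plain asymptotic z is ~20×
liberal at p = 1e-4, while the corrected t reference is calibrated to
within ~25% down to that tail; per-run Kolmogorov–Smirnov tests against
uniformity pass at 5,000 probes. Probes that are constant before clamping, or whose fit fails to
converge (gradient criterion after step-halving), are reported with missing
p-values and excluded from the BH adjustment.

The candidate filter keeps BH-significant probes with |model-estimated
difference| ≥ 0.10 — the difference is the inverse-logit contrast at cohort
-mean covariates, not a raw group-mean difference — or probes whose
annotated gene carries ≥ 2 significant CpGs; a probe annotated to several
genes counts toward each, and intergenic probes form singleton loci
reachable only through the difference rule. The locus rule's significance
criterion is the same adjusted-p threshold. The ≥ (rather than >) reading
of the 10% cut follows the running-text statement of the filter.

## Protein network

Panels are log-transformed when all entries are positive (ratio data;
already-log panels pass through). The correlation matrix is shrunk toward
the identity with the analytic optimal intensity
λ* = Σ var̂(r_ij) / Σ r_ij² (clamped to [0, 1]), guaranteeing positive
definiteness at n ≪ p; partial correlations follow by inversion. The
off-diagonal partial correlations are then modelled as the two-component
mixture η0·f0(r; κ) + (1−η0)·½ with f0(r; κ) ∝ (1−r²)^((κ−3)/2); η0
(through a logistic transform) and κ are fitted by maximum likelihood from
a small grid of starts. κ is fitted rather than fixed at n−p−1 because
shrinkage concentrates the null far beyond the nominal degrees of freedom
(which are negative at p = 22, n = 7). Per-edge posterior of presence =
(1−η0)·½ / f; local FDR = 1 − posterior; edges enter the network at
posterior ≥ 0.6 — the reading of the "0.6 bound" consistent with local
FDR = 1 − posterior and a sparse result; the opposite reading (≤) is one
argument away in `select_edges`. Two-sided p-values per edge use the
fitted-κ null; the p < 0.1 annotation threshold is reported alongside, not
used for selection. An all-zero partial-correlation vector short-circuits
to η0 = 1 with all posteriors 0.

At the study's size (12 vs 12, φ = 50), a single CpG with a 0.12–0.15
beta-scale difference has only moderate power against genome-wide BH
thresholds; DMR recovery is therefore assessed at the locus level — a
planted locus counts as recovered when at least one of its CpGs enters the
candidate set — which is also what the gene-locus rule of the candidate
filter is designed to exploit. Site-level sensitivity is reported
alongside.

## Synergy

Fractions affected are computed per well against the mean untreated
control and averaged over replicates; the untreated combination's own
fraction affected is 0 by definition, which also forces delta = 0 on the
single-agent margins (they are their own expectation). The Bliss
expectation at (a, b) uses the observed single-agent marginals; delta =
observed − expected, with the standard error propagated from the
combination's and both marginals' replicate s.e. — fa is averaged first
and the s.e. propagated, rather than computing per-replicate deltas.
Positive delta means stronger growth suppression than independence
predicts; the viability-scale surface (−delta) is exposed for display.
Per-combination one-sample t-tests (df = replicates − 1) with Holm–Šidák
correction flag synergistic/antagonistic cells; with a single replicate
flags are withheld. Cells with zero replicate variance are flagged only if
|delta| exceeds float round-off (1e-10). One measurement-model caveat:
well signals are clamped to [0, 1], so the untreated control mean sits
slightly below its true value (≈ σ/√(2π) for noise σ), which biases
recovered deltas upward by roughly σ/2 at typical grids — well inside the
per-replicate 3-s.e. band, but visible when averaging many seeds.

## Small quantifications

2^−ΔΔct is computed per housekeeper (ACTB, GAPDH, HPRT1) and the three
normalized expression values are averaged arithmetically — the literal
averaging rule; a geometric mode is available. The result is invariant to
plate-wide ct shifts. SRM ratios background-subtract per transition,
floor at zero, then sum; ChIP signals are ip/input times a configurable
dilution factor. BH and Holm–Šidák adjustments wrap
`statsmodels.stats.multitest` with NaN propagation handled by the wrapper;
both are brute-force-verified in the tests.

## Problem sizes and determinism

Recovery tests run at the study design (12 vs 12, 20,000 probes, 25 seeds
for DMR recovery; 5,000 probes, 20 seeds for null calibration; p = 22
panels at n = 200 and n = 7; quadruplicate 5 × 4 dose grids) — sizes chosen
so the whole suite completes on a laptop-class single core in minutes.
Every generator is a pure function of (config, seed); the pipeline itself
is deterministic (kNN has no randomness, EM and the mixture fits use
deterministic initialization), so identical configs reproduce results
bit-for-bit.

## Known limitations

- The beta regression assumes conditionally independent probes; no
  spatial/regional smoothing or cell-type deconvolution is attempted.
- The empirical-Bayes alternative component is uniform; sharply bimodal
  alternatives would be better served by a nonparametric alternative.
- The synergy model is Bliss-only (no Loewe/HSA/ZIP), and plate spatial
  effects are out of scope.
- IDAT parsing and raw-intensity background correction are out of scope;
  the pipeline starts from exported matrices.
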