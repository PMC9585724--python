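# Methods

This note documents the statistical models implemented in `bpmeth`, the
choices made where the design was genuinely open, and what the synthetic
cohorts used for verification do and do not establish.

## Blood-pressure summarization (`bpmeth.bp`)

**Indicators.** From each systolic/diastolic reading (mmHg) we derive mean
arterial pressure MAP = SBP/3 + 2·DBP/3 (the steady, perfusion-related
component) and pulse pressure PP = SBP − DBP (the pulsatile component).
MAP − DBP = PP/3 holds identically and is enforced by a property test.
Each indicator series is processed independently; in particular PP is
detrended as its own series rather than derived from detrended SBP/DBP.

**Plausibility bounds.** Readings with SBP > 260 mmHg, DBP > 200 mmHg,
SBP ≤ DBP, or weeks outside (0, 43] are dropped, with a logged count.

**Trend and detrending.** Population BP follows a non-linear gestational
trajectory (a mid-pregnancy dip followed by a rise toward term). Because
visits are sparse and irregular, raw per-subject averages over a time
window would be confounded by visit timing. We estimate the pooled mean
trajectory with a cubic penalized regression spline (8 interior knots at
week quantiles, second-difference coefficient penalty, smoothing parameter
selected by generalized cross-validation on a log-spaced grid from 1e−3 to
1e7) and replace each reading by
`value − trend(week) + grand_mean`, where the grand mean is the average of
the fitted curve over weeks 8–41. Values therefore remain on the mmHg
scale. Weeks outside the fitted range use a linear extension of the curve
and emit a warning. A small fixed spline basis was chosen deliberately:
full-knot GCV smoothing splines can pick near-interpolating smoothing
parameters on pooled visit data and produce wild excursions; the 8-knot
basis cannot represent them. Detrending is idempotent up to the smoother's
statistical wiggle (< 0.001 mmHg in tests), not exactly, since a refit on
detrended data is never the constant function.

**Time windows.** Early pregnancy is week ≤ 27 (the boundary week counts
as early), late is > 27; "whole" uses all readings. The boundary is a
fixed constant; no trajectory clustering or functional PCA is performed,
because downstream stages consume only the detrended window summaries.

**Two-stage model.** Within a window, detrended values follow an
intercept-only mixed model: `y_ij = mu + b_i + e_ij`, with subject random
intercepts `b_i ~ N(0, sigma_b^2)` and continuous-time AR(1) residuals,
`corr(e_ij, e_ik) = rho^|t_ij − t_ik|` (per-week lag; the continuous-time
form is required because visits are irregular). Variance components are
estimated by REML — the intercept is profiled out in closed form by GLS,
and the three transformed parameters (log variances, logit rho) are
optimized by Nelder-Mead from a moment-based start plus one fallback
start. Subjects are batched by visit count so the objective uses stacked
Cholesky factorizations. The per-subject exposure passed to the EWAS is
the shrunken estimate `bp_hat_i = mu + sigma_b^2 1'V_i^{-1}(y_i − mu)`
(the empirical BLUP). Degenerate inputs short-circuit: if all values are
equal, every `bp_hat` is that value; if every subject's readings are
constant, `bp_hat` equals the subject mean (the sigma_e → 0 limit).

The BLUP shrinks toward mu from the *GLS-weighted* subject mean; with
AR(1) weights this can differ slightly from the raw mean, so the
"estimate lies between grand mean and subject mean" property is exact in
the GLS sense and only approximate for raw means.

**Attainable recovery.** At the default noise settings (sigma_b = 6,
sigma_e = 8 mmHg, rho = 0.5) with 5–13 visits per subject, the correlation
between `bp_hat` and the true subject offset is capped by the information
in the data: the reliability of a subject mean is
`sigma_b^2 / (sigma_b^2 + v_i)` with `v_i` the AR(1)-inflated variance of
the subject's mean error, giving a ceiling of ≈ 0.88 even for the oracle
BLUP computed with the true trend and true variance components (≈ 0.93
under continuous monitoring). The implementation tracks that oracle to
within ≈ 0.005. Any expectation above 0.9 at these settings is not
achievable by any estimator.

**Uncertainty propagation.** Only the point estimates `bp_hat` enter the
second stage; first-stage uncertainty is not propagated. This mirrors the
two-stage design the pipeline implements and is a known limitation.

## Methylation QC (`bpmeth.qc`)

Beta-values (methylated fraction in [0,1]) are assumed already normalized;
normalization is an upstream concern. M-values are `log2(beta/(1−beta))`
after clipping beta to [1e−6, 1−1e−6]; the inverse is `2^M/(1+2^M)`.
Outliers are masked per probe: values outside [Q1 − 3·IQR, Q3 + 3·IQR]
become missing (quartiles by linear/type-7 interpolation — the numpy
default; with a 3-IQR margin the quantile convention is immaterial in
practice). Rows with fewer than 10 observed values are left untouched.
Probe filtering removes user-supplied blocklists (SNP-adjacent,
cross-reactive) and optionally chrX/chrY probes; filters commute. Missing
values propagate into the EWAS, where each probe is fitted on complete
cases.

## Probe-wise EWAS (`bpmeth.ewas`)

Per CpG j: `M_ij = alpha_0j + alpha_BPj bp_hat_i + alpha_Zj' Z_i + eps_ij`,
fitted by Huber M-estimation: tuning constant 1.345, scale re-estimated
each iteration as MAD/0.6745 of the residuals, IRLS iterated to relative
coefficient change < 1e−8 or 100 iterations. Standard errors use the
Huber sandwich with the standard finite-sample correction
`kappa = 1 + (k/n)·var(psi')/mean(psi')^2`; on data where no residual is
downweighted this reduces exactly to OLS. P-values use a t reference with
residual degrees of freedom (conservative at these sample sizes). The
IRLS is vectorized across probes sharing one design matrix, which is what
makes replicate-level calibration studies affordable; agreement with
statsmodels' `RLM` (coefficients and standard errors to ≈ 1e−5) is pinned
by tests. Categorical covariates are dummy-coded; rank-deficient designs
raise an error naming the collinear columns.

Beta-scale effects use the intercept method: with `s` the M-to-beta
transform, `effect_beta = s(alpha_0* + 10·alpha_BP) − s(alpha_0*)`, where
`alpha_0*` is the fitted value at the means of all regressors — i.e. the
methylation change per +10 mmHg for an average subject. Benjamini-
Hochberg FDR is applied across all tested probes.

**Inflation/bias diagnostic.** Signed z-scores are modeled as a
three-component Gaussian mixture (empirical null plus two signal tails)
fitted by EM. To keep the tails from absorbing the null's shoulders their
means are constrained at least two null-SDs from the null mean and their
SDs at least the null's. The reported BIF is the null component's SD and
the bias its mean. No correction is applied to p-values; the quantity is
a diagnostic only. The EM replaces the Gibbs sampler of the method that
inspired it; for a diagnostic that should sit near (1, 0) the point
estimate suffices.

**Candidate look-up.** A candidate CpG replicates when the effect sign
matches the expected direction and the uncorrected p < 0.05;
significant-but-opposite hits are flagged separately; absent probes are
"untested".

## DMR detection (`bpmeth.dmr`)

Probe z-scores `z = Phi^{-1}(1−p)` are correlated across the genome at
short range. Their correlation is estimated in distance bins (50 bp wide
up to a 1000 bp lag; bins with fewer than 200 pairs are merged; estimates
clipped below at 0) and used everywhere a dependence-aware combination is
needed (Stouffer-Liptak: `z_c = sum(z)/sqrt(1' Sigma 1)`, with an
eigenvalue-clipping nearest-PSD repair when a mapped correlation matrix is
indefinite).

Calling proceeds comb-p style: (1) each probe's p is smoothed by
Stouffer-Liptak over neighbors within a 300 bp window — the smoothing
window is deliberately narrower than the correlation lag, matching the
comb-p/ENmix convention (bin size ≈ 310 vs lag 1000); a 1000 bp smoothing
window systematically drags called boundaries past true region edges.
(2) Regions are seeded where smoothed p < 1e−3 and extended through
consecutive probes while the inter-probe gap is ≤ 500 bp and the smoothed
p < 0.05; a candidate needs ≥ 3 probes. (3) Each candidate region is
scored by Stouffer-Liptak over its members' *raw* p-values with the
distance-mapped correlation matrix. (4) Multiplicity: the region p is
first Sidak-corrected for the genome searched,
`p_sidak = 1 − (1 − p)^(total tested bp / region width)`, and BH-FDR is
then applied across candidate regions *on the Sidak-corrected values*.
The Sidak step is essential: candidate regions are selected by the
seeding, so BH on raw region p-values would be strongly anticonservative
under the null, while the genome-width exponent accounts for the search.
Under a global uniform null the family-wise rate of the default filter is
far below 5% (measured in the evaluation suite). Both `p_sidak` and `fdr`
are reported; the significance filter (`fdr`, `sidak`, or none) is
configurable.

Coordinates are 1-based inclusive internally (array-manifest convention);
BED export converts to 0-based half-open. Regions are annotated to an
overlapping gene (ties broken by distance to the TSS, then
lexicographically), else the nearest gene within 10 kb, else
"intergenic". Location-class enrichment of DMR membership uses Fisher
exact tests with BH across classes.

## Cell-type deconvolution (`bpmeth.celltypes`)

Bulk placental methylation is modeled as a non-negative mixture of six
reference profiles (Syncytiotrophoblast, Stromal, Endothelial,
Trophoblast, Hofbauer, nRBC). Feature selection takes, per cell type, the
50 probes (default) with the largest |beta_type − mean(beta_others)|
margin; with noiseless synthetic references, margin ranking replaces the
t-statistic ranking used with replicate-level reference data.
Proportions solve `min ||beta_bulk − R'w||^2, w ≥ 0, sum w = 1` via
non-negative least squares on an augmented system whose final row enforces
the sum constraint with weight 1000 — deterministic, solver-free, and
exact to ≈ 1e−6 on noiseless mixtures. Samples need ≥ 20 usable probes.

**Association with BP.** The global test maps compositions (after
multiplicative zero replacement, delta = 1e−4) to five isometric
log-ratio coordinates and compares the multivariate regression with and
without BP by Wilks' lambda with Rao's F (exact for a one-column
hypothesis). The ilr basis is a fixed sequential binary partition whose
first coordinate is `sqrt(1/2)·log(Stromal/SCT)` — the contrast of
interest — followed by {Stromal,SCT} vs the minor types, the two
epithelial/vascular splits, and Hofbauer vs nRBC. The test statistic is
invariant to the basis choice. The focused model regresses
log(Stromal/SCT) on BP by OLS with Wald intervals. Per-cell-type linear
fits are provided as descriptive companions (proportions are not
independent outcomes). Compositional PCA is an SVD of centered clr
coordinates.

## Mediation (`bpmeth.mediation`)

For probe M-values the BP effect is decomposed with three least-squares
fits sharing the confounders: mediator ~ BP + Z (slopes `a`), outcome
~ BP + mediator + Z (direct `c'`, mediator slopes `b`), and marginal
outcome ~ BP + Z (total `c`). In linear no-interaction models
`c − c' = a'b` exactly, so total = direct + indirect to machine precision
and the per-coordinate products `a_k b_k` sum to the indirect effect —
both identities are asserted on every fixture. The mediator block is
either the five ilr coordinates (the multivariate compositional analysis;
component-wise indirect effects are reported per ilr coordinate, the
Stromal/SCT contrast first) or the single log(Stromal/SCT) ratio.
Uncertainty comes from a nonparametric bootstrap over subjects (seeded
`default_rng`, percentile 95% intervals, default 1000 draws, ≥ 200
enforced); rank-deficient resamples are redrawn up to 10 times. The
bootstrap replaces the quasi-Bayesian simulation of the usual univariate
package and the Bayesian machinery of the compositional one: for linear
models the estimands coincide, one mechanism serves both analyses, and
the procedure is exactly reproducible under a seed. Significance = 95%
interval excluding zero. Probe-level calls aggregate per DMR into `All`
/ `Some` / `No` classes for direct and indirect effects separately.
Mediation runs on the M-value scale (the EWAS outcome scale); the
intercept method can re-express effects on the beta scale for reporting.

Not modeled: exposure-mediator interactions, unmeasured mediator-outcome
confounding, reverse causation.

## Synthetic cohorts (`bpmeth.synthetic`)

The generator reproduces the structure the analysis assumes, with every
parameter in a `TruthLedger`:

* **BP trends**: cubic polynomials with zero derivative at week 22
  (minimum) anchored at 112/63 mmHg, rising ≈ 5–6 mmHg toward term.
* **Visits**: uniform integer 5–13 per subject (median 9, a typical
  abstracted prenatal-care record), weeks uniform on [8, 41].
* **Noise**: sigma_b = 6, sigma_e = 8 mmHg, rho = 0.5 per week; DBP
  shares the subject intercept and residual scale × 0.6.
* **Compositions**: logistic-normal around
  (0.63, 0.10, 0.09, 0.10, 0.02, 0.02) for (SCT, Stromal, Endothelial,
  Trophoblast, Hofbauer, nRBC), log-scale SD 0.25; the Stromal-vs-SCT
  log-contrast is shifted by `gamma_comp` (default −0.02 per mmHg) ×
  latent BP, so a linear BP → log-ratio path exists exactly and the
  mediator model is well-specified (this is why logistic-normal was
  chosen over Dirichlet).
* **Reference profiles**: bimodal baselines shared across types; each
  type gets 50 probes with ≥ 0.4 beta separation from all others.
* **Bulk methylation**: mixture of reference profiles, then a direct
  M-scale shift `direct_effect_j × BP_i` plus N(0, 0.2) M-scale noise,
  back-transformed and clipped. Direct effects (default 0.025 M per mmHg
  ≈ 0.04 beta per 10 mmHg near beta = 0.5) are planted on contiguous
  blocks of ≥ 3 probes with gaps ≤ 500 bp, preferentially on whole
  gap-bounded clusters of exactly the block size so the true region
  boundaries are unambiguous; deconvolution marker probes are kept
  disjoint from planted blocks.
* **Probe layout**: CpG-island-like clusters of 1–14 probes (gaps
  30–200 bp) separated by 2–50 kb, over two chromosomes.

A separate helper builds single-probe mediation fixtures in which only
the Stromal/SCT ilr coordinate responds to BP and the outcome is linear
in it, so the true direct and indirect effects are known in closed form
(planting effects through the nonlinear mixture would leave the true
indirect effect without a closed form).

**What the synthetic checks do not show.** Generated data are Gaussian on
the M scale, have no batch/chip/plate structure, no genuine biological
correlation beyond cell-composition mixing, exact linear mediator paths,
and noiseless reference profiles. Passing recovery and calibration tests
therefore validates the estimators under their own assumptions; it does
not certify performance under array artifacts, model misspecification, or
reference-panel error.

## Evaluation suite sizes (`bpmeth.benchmarks`)

Problem sizes were fixed once so the whole suite runs in minutes on a
single core: deconvolution 100 mixtures at logit noise 0.02; EWAS type-I
calibration on one null cohort (n = 300, 2000 probes); DMR recovery over
50 replicates (n = 600, 1000 probes, one planted 8-probe block at 0.0289
M per mmHg ≈ 0.05 beta per 10 mmHg); region-caller null calibration over
200 replicates of 5000 uniform-null probe p-values on an array-like
layout (the caller, not the probe-level regression, is the object under
test there); mediation recovery and null coverage over 50 replicates each
(n = 600, 300 bootstrap draws); two-stage BP recovery at n = 600. The
two-stage correlation reported there (~0.87) sits at the information
ceiling discussed above. Two caveats on reading the replicate rates: the
mediation point estimates carry relative standard errors of roughly
15% under these noise settings, so the fraction of replicates landing
within a 30% relative-error band is itself close to 0.8 in expectation
and fluctuates noticeably across seed chains at 50 replicates; and the
region-caller null calibration feeds the caller uniform probe p-values
directly — it measures the caller's family-wise behavior, not the
probe-level regression, whose calibration is measured separately.
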