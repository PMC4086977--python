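# Methods

This note documents the models, the numerical choices and the synthetic
study design behind `grazefd`, and what the test suite does and does not
establish about real data.

## Trait coding and species values

Raw database-style entries are coded per trait: categorical attributes map to
ordinal scores (life-form 0–1 by bud height, canopy structure rosette 0 /
hemirosette 0.5 / erosulate 1, leafing period and the two vegetative-spread
attributes 0/1, life-span 0/0.5/1), flowering start is kept as the month
(1–12), LDMC (mg g⁻¹) and SLA (mm² mg⁻¹) stay in measurement units, and
canopy height (m) and leaf size (mm²) are natural-log transformed before
averaging. The log base is a free choice — any fixed base only rescales the
coded axis, and the Gower distance renormalises by the pool range anyway —
and is recorded in the trait-table sidecar (`log_base: e`). Species values
are replication-weighted means over entries and are frozen after table
construction: community-level trait change over years comes from abundance
change only. Missing (species, trait) cells are a hard error listing every
gap; no imputation is attempted. The two vegetative-spread attributes carry
weight 0.5 each so the trait as a whole weighs the same as any other.

## Distances and diversity metrics

Species dissimilarity is the weighted Gower distance: per-trait absolute
differences divided by the trait's range over the *full pool* (not per
community), averaged with the trait weights. Pool-level ranges keep
distances comparable across plot-years. Because Gower divides by the range,
any affine rescaling of a trait axis — including mapping flowering months
onto [0, 1] — cancels exactly, so months are stored raw. Traits constant
across the pool carry no signal; they are dropped from the sum and reported.

Rao's Q uses the ordered-pair convention Q = p·D·pᵀ (equal to 2·Σ_{i<j});
single-trait Q is reported both range-normalised and in raw trait units.
FEve follows the MST construction: branch weights EW = d/(pᵢ+pⱼ) on the
minimum spanning tree of the species present, partial weights capped at
1/(S−1), rescaled to [0, 1]. Ties between equal-length candidate edges are
broken lexicographically by species-pair index (Kruskal over edges sorted by
(length, i, j)) — FEve is tie-sensitive, so determinism matters. For a
single trait the MST is the sorted-neighbour chain, which is used directly.
Fewer than three species with positive abundance (operationally, abundance
above 1e−12) makes FEve undefined; the undefined flag is carried through
every downstream table, and analyses consuming the metric drop exactly those
rows (refitting the comparison model on the same rows where a likelihood
ratio is involved).

## The productivity model

The response is stocking density, livestock units ha⁻¹ yr⁻¹. LDMC enters
the mean structure through the exponential decay e^(−k·CWM_LDMC). k is
estimated once on the pooled plot-year records by nonlinear least squares
and then frozen, making the transform an ordinary covariate inside linear
mixed models; joint nonlinear mixed estimation is out of scope. The nls is
implemented as profiled separable least squares: for a candidate k the
intercept(s) and amplitude are an exact linear solve, and k is found by a
bounded golden-section-type search on log k within [1e−4, 0.2] per mg g⁻¹
(the upper bound is far steeper than any credible leaf-economics response).
This reproduces what a self-starting asymptotic-regression fit achieves
without delicate initialisation. The pipeline requests one intercept per
experiment in this fit; site-level productivity offsets are large relative
to within-site scatter, and absorbing them roughly halves the sampling error
of k at the default design while remaining a plain fixed-effects pooled fit.

Mixed models are fitted with statsmodels MixedLM (random intercepts for
experiments; plot — and block, where distinct — as variance components).
Model development follows the standard two-stage protocol: the random
structure is chosen first under REML with the full fixed model, comparing
AIC = −2·logLik + 2·(fixed + variance parameters) across the nested ladder
{experiment/block/plot, experiment/plot, experiment, none}, ties resolving
to the simpler structure. The "none" candidate uses the closed-form OLS
restricted likelihood, which is on the same scale as MixedLM's REML
likelihood. When the block and plot partitions coincide (one block per
plot) the block component is unidentifiable; the plot model is fitted and
the extra component reported at the zero boundary with its AIC penalty. A
random slope of time within plot is a recorded configuration extension, not
part of the ladder: nested random intercepts are the supported contract.

Fixed-model simplification runs backwards under ML: at each step all
admissible single-term deletions are evaluated (marginality respected — the
linear rainfall term is not removable while rainfall² is present); among the
deletions whose likelihood-ratio test is non-significant at α = 0.05 the one
with the lowest AIC is applied; elimination stops when every remaining term
is LRT-significant. The final model is re-estimated by REML. LRTs (ML) are
the normative inference for fixed-term comparisons; Wald t probabilities at
nested-grouping denominator df are reported for display only, since
denominator-df conventions differ across mixed-model implementations.

Degenerate variance components at the zero boundary are reported and flagged
(`singular`), never errors. Two numerical guards matter in replicate loops:
the L-BFGS optimizer can return a non-finite restricted likelihood at a
boundary optimum, so optimizers are retried in a fixed order until the fit is
finite; and the Hessian-based fixed-effect standard errors can fail there,
in which case the exact GLS covariance (X′V⁻¹X)⁻¹ at the estimated variances
is used. Conditional fitted values (including predicted random effects) fall
back to sequentially shrunk level means when the random-effect covariance is
singular — exact at a zero boundary.

Residual temporal structure is checked by pooling within-plot lag-1 residual
pairs (years sorted) and flagging |r₁| > 1.96/√n_pairs; fewer than three
years in every plot, or zero residual variance, yields an undefined flag.
Conditional residuals carry a small negative serial correlation of order
−1/(years per plot) from the predicted plot intercepts, so on short panels
the check runs slightly anticonservative against negative lags; strong
positive autocorrelation (the case that matters for the weather-dependence
question) is detected reliably.

## Hypothesis tests

**H1 (diversity → mean productivity).** Each candidate metric (FEve and
Rao's Q, full suite and LDMC-only) is added singly to the combined model
under ML and judged by LRT p and ΔAIC. Candidates numerically collinear
with an existing covariate (|r| > 0.999) are refused with a note.

**H2 (diversity → resilience).** The absolute raw (conditional) residuals of
the combined REML fit are regressed on one metric at a time, with the same
random structure, by REML. Because the response is the output of a previous
fit, the slope's t statistic is referred to the nominal nested-grouping
denominator df minus one — the adjustment is exactly one df, which strictly
reduces significance. Raw p-values are primary; a Holm-corrected column is
available behind a flag, as is a squared-residual response for sensitivity
analysis. The companion mean-level analysis regresses per-plot multi-year
mean productivity on mean FD with experiment random intercepts (falling back
to the fixed-effects fit if the single variance component cannot be
estimated).

A property worth stating plainly: the two-stage procedure is mildly
*conservative* under the null. Conditional residuals within a plot share the
error of the predicted plot intercept, so |residual| rows are positively
dependent within plots; the dispersion model picks this up as a small plot
variance component and widens the slope's standard error beyond its actual
sampling spread (about 15% at the default design, measured by simulation
against an oracle that regresses the true |ε| on the metric — the oracle's
p-values are uniform, the pipeline's are right-shifted). The one-df
adjustment does not remove this. Consequently the test's null rejection rate
sits near 4% rather than 5%, and its null p-value distribution deviates
detectably from uniform in large replicate batches. This is a property of
residual-reuse dispersion tests generally, not of this implementation.

## The synthetic study

The generator emulates a nine-experiment grazing panel: 3 plots per
experiment (one block each), 4–15 years per experiment, a 40-species pool.
Trait marginals are grassland-plausible: LDMC truncated-normal (mean 250,
SD 60, floor 80 mg g⁻¹); SLA lognormal around 20 mm² mg⁻¹ and negatively
coupled to LDMC; height and leaf size lognormal; categorical attributes from
fixed marginals dominated by hemicryptophyte perennials.

Communities are Dirichlet draws (concentration 10) around per-plot softmax
preferences. The low concentration encodes the large year-to-year
composition turnover that point-quadrat records show; pin-hit sampling is
not simulated explicitly because the analysis consumes relative abundances
only. Each plot samples a fertility score around its experiment mean
(SD 0.5 within, 1 between — soil-scale variation within sites). Fertility
acts twice, scaled by one coupling parameter c: it tilts preferences toward
low-LDMC species (saturating at min(c/2, 1) z-units — composition cannot
shift past the fast end of the pool) and multiplies the preference spread by
e^(0.35·c·f), so fertile plots are dominated by few fast species and carry
less LDMC diversity. The saturation keeps the fertility→diversity relation
monotone: at the default c = 2 the plot-level Spearman correlation between
fertility and RaoQ-LDMC is ≈ −0.3, reaching ≤ −0.5 by c = 6. c = 0 switches
the mechanism off.

Productivity is β₀ + β₁·e^(−k·CWM_LDMC) + β₂·rain + u_exp + u_plot + ε with
defaults β₀ = −0.687, β₁ = 95.31, k = 0.0170, β₂ = 0.0018 (the reference
combined-model coefficients), SD(u_exp) = 0.20, SD(u_plot) = 0.15 LU, and
sd(ε) = σ₀·e^(−γ·RaoQ_LDMC) with σ₀ = 0.20 and γ = 0 by default (γ > 0
switches on the resilience signal). Rainfall means are drawn per experiment
on 300–800 mm (SD 80 within); temperature is generated (13.5 ± 1.5 °C) but
carries no effect, giving model simplification a true-negative term.
Negative productivity draws are truncated at zero; the default variances
keep the truncation rate below 1% so the linear model stays well specified.

`calibrate_resilience` chooses the (γ, σ₀) pair for power studies: the
expected |residual|-on-RaoQ slope pins only the product, so γ is tuned to a
requested one-sided power (default 0.90 at α = 0.05) with σ₀ re-solved at
each step to hold the slope magnitude at its target (default 0.104). The
closed-form half-normal prediction for the t statistic overstates what the
two-stage pipeline delivers (transform error and random-effect prediction
noise dilute it), so the calibration measures the t response by a short
Monte-Carlo probe of the actual pipeline (30 replicates per iteration, up to
4 iterations, all seeds derived from the calibration seed).

What passing tests show — and do not. The generator shares the analysis
model's mean structure, so parameter-recovery results certify the estimation
machinery, not the model's adequacy for real swards; real data add
intraspecific trait variation, observation error in abundances and
productivity, spatial structure, and grazing feedbacks on composition, none
of which are emulated. Problem sizes in the replicate tests (100–500
replicates at the 9 × 3 × 4–15 design) were chosen to make the binomial
noise on the checked rates small relative to their acceptance margins.

## Known limitations

- k is frozen after the pooled fit; its sampling error (median ≈ 8% at the
  default design) propagates into the combined model's coefficients and is
  the main reason transform-induced residual curvature can leak into the H1
  screens on small noisy designs.
- The H2 test's conservatism under the null (above) and the single-df
  adjustment are inherited from the two-stage design; a joint mean–variance
  model would calibrate better but is deliberately out of scope.
- FEve's tie-break is deterministic but arbitrary where trait space is
  exactly degenerate; identical species configurations can in principle have
  several valid MSTs with different FEve.
- The livestock-unit conversion coefficients that turn grazing days of mixed
  animal species into LU are site metadata, not computed here; records are
  expected already converted.
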