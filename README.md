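# grazefd

Trait-based analysis of grassland secondary productivity: does livestock
production depend on the functional *identity* of the sward, on its
functional *diversity*, or does diversity instead buy *resilience* — less
year-to-year divergence from the productivity the weather and the vegetation
would predict?

`grazefd` implements the full analysis pipeline for multi-site, multi-year
grazing studies, together with a seeded synthetic-data generator that
reproduces the statistical structure such studies have, so every stage can be
tested against known ground truth.

## What it computes

**Functional composition.** From a coded species × trait table (leaf dry
matter content LDMC in mg g⁻¹, specific leaf area SLA in mm² mg⁻¹, logged
canopy height and leaf size, and ordinal-coded life-form, canopy structure,
phenology, life-span and vegetative spread, the two spread attributes
weighted 0.5 each) and plot-year relative abundances *p*:

- CWM (community-weighted mean): Σᵢ *p*ᵢ *x*ᵢ
- Rao's quadratic entropy: *Q* = Σᵢ Σⱼ *p*ᵢ *p*ⱼ *d*ᵢⱼ, with *d*ᵢⱼ the
  weighted Gower dissimilarity (per-trait ranges over the full species pool)
- FEve: abundance-weighted evenness of the minimum spanning tree of the
  present species in trait space, on [0, 1], undefined below 3 species

**Productivity model.** Productivity (livestock units ha⁻¹ yr⁻¹ needed to
hold the sward at a set height) is modelled as

    y = β₀ + β₁·e^(−k·CWM_LDMC) + β₂·YearRain + (1|experiment/plot) + ε

The decay rate *k* is estimated once by pooled nonlinear least squares and
frozen; the random-intercept structure is chosen by REML/AIC over the nested
ladder (experiment/block/plot → … → none); the fixed model (rainfall,
rainfall², temperature, transformed LDMC) is simplified backwards under ML
with likelihood-ratio tests; the final model is re-estimated by REML and its
residuals checked for within-plot lag-1 autocorrelation.

**Hypothesis tests.** (H1) each FD metric — FEve and Rao's Q for the full
trait suite and for LDMC alone — is offered to the mean model by single-term
forward selection under ML. (H2, resilience) the absolute raw residuals of
the combined model are regressed on each FD metric with the same random
structure; because the response is the output of a previous fit, the slope's
t test loses one denominator degree of freedom. A companion regression
relates per-plot multi-year mean productivity to mean FD (random experiment
intercepts).

## Worked example

`examples/04_resilience.py` generates a study in which LDMC diversity damps
the residual spread of productivity (γ = 3, σ₀ = 0.10) but has no effect on
its mean, and runs both hypothesis tests:

```
H1 forward selection (mean model):
candidate  lrt_p  delta_aic  significant
 feve_all  0.593      1.714        False
  rao_all  0.479      1.500        False
feve_ldmc  0.685      1.835        False
 rao_ldmc  0.974      1.999        False

H2 dispersion tests (|residual| ~ FD metric, adjusted df):
predictor   slope  nominal_df  adjusted_df  p_value
 feve_all -0.0543         203          202   0.0525
  rao_all -0.0884         203          202   0.0277
feve_ldmc  0.0197         203          202   0.5405
 rao_ldmc -0.1157         203          202   0.0117
```

No diversity term improves the mean model (all LRT p ≥ 0.48, every ΔAIC
positive), yet the absolute residuals fall significantly with the Rao's Q of
LDMC (slope −0.116, p = 0.012 at the adjusted df): diversity predicts the
*variability* of the service, not its level. The other examples cover trait
coding (`01`), the FD metrics (`02`), the model ladder (`03`) — which on a
default synthetic study recovers k ≈ 0.0172 against a true 0.0170, selects
`experiment/plot`, drops the null temperature and rainfall² terms and returns
coefficients (−0.59, 95.8, 0.0017) against the true (−0.687, 95.31, 0.0018)
— and the end-to-end pipeline (`05`).

A thin CLI wraps the same calls:

```bash
grazefd simulate --seed 1 --out data/
grazefd full --seed 1 --out results/
```

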