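"""Resilience of productivity: dispersion-vs-diversity tests and mean-level regressions.

The resilience hypothesis: functionally diverse swards deviate less from
their weather- and trait-based productivity expectation.  It is tested in two
stages: take the absolute raw residuals of the combined trait + weather mixed
model, then regress them on a functional-diversity metric with the same
random structure.  Because the residuals come from a previously fitted model,
the denominator degrees of freedom of the slope's t test are revised
downwards by one, making the test deliberately conservative.

A complementary mean-level analysis regresses per-plot multi-year mean
productivity on mean functional diversity (random experiment intercepts),
probing whether long-term grazing intensity and diversity trade off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats

from . import prodmodel
from .prodmodel import FitError, ModelFit, fit_mixed

__all__ = [
    "ResilienceResult",
    "resilience_test",
    "resilience_table",
    "mean_level_regression",
    "run_full_analysis",
]


@dataclass
class ResilienceResult:
    """Slope of |residual| on one FD metric with adjusted-df inference."""

    predictor: str
    intercept: float
    slope: float
    slope_se: float
    nominal_df: int
    adjusted_df: int
    t_stat: float
    p_value: float            # two-sided at the adjusted df
    p_one_sided_negative: float
    mode: str
    direction: str            # 'negative' | 'positive'

    def __post_init__(self):
        assert self.adjusted_df == self.nominal_df - 1


def adjusted_p_value(t_stat: float, nominal_df: int, two_sided: bool = True) -> float:
    """p-value of a t statistic after subtracting one denominator df.

    The lost df accounts for the slope having been estimated on residuals of
    a previously fitted model; p(adjusted) >= p(nominal) for any |t|.
    """
    df = nominal_df - 1
    if df < 1:
        raise ValueError(f"adjusted df must be >= 1, got {df}")
    sf = scipy.stats.t.sf(abs(t_stat), df=df)
    return float(2 * sf if two_sided else sf)


def resilience_test(
    base_fit: ModelFit,
    predictor: str,
    mode: str = "REML",
    dispersion: str = "absolute",
) -> ResilienceResult:
    """Regress the base model's absolute residuals on one FD metric.

    The dispersion response is |raw residual| by default (``dispersion=
    'squared'`` is available for sensitivity analysis only).  The random
    structure is inherited from the base fit; the slope's t test uses the
    nominal denominator df minus one.
    """
    if dispersion not in ("absolute", "squared"):
        raise ValueError(f"unknown dispersion response {dispersion!r}")
    data = base_fit.data.copy()
    if predictor not in data.columns:
        raise KeyError(f"predictor {predictor!r} not in base-fit data")
    r = np.abs(base_fit.resid)
    data["_dispersion"] = r if dispersion == "absolute" else r**2
    data = data.loc[data[predictor].notna()]  # undefined-metric rows excluded
    x = data[predictor].to_numpy(dtype=float)
    if x.size == 0 or np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant or empty; slope undefined")
    fit = fit_mixed(data, (predictor,), random=base_fit.random, mode=mode,
                    response="_dispersion")

    slope = float(fit.params[predictor])
    se = float(fit.bse[predictor])
    t = slope / se
    nominal = fit.denominator_df
    return ResilienceResult(
        predictor=predictor,
        intercept=float(fit.params.get("Intercept", np.nan)),
        slope=slope,
        slope_se=se,
        nominal_df=nominal,
        adjusted_df=nominal - 1,
        t_stat=t,
        p_value=adjusted_p_value(t, nominal),
        p_one_sided_negative=float(scipy.stats.t.cdf(t, df=nominal - 1)),
        mode=mode,
        direction="negative" if slope < 0 else "positive",
    )


def resilience_table(
    base_fit: ModelFit,
    predictors: tuple[str, ...] = ("feve_all", "rao_all", "feve_ldmc", "rao_ldmc"),
    holm: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Per-predictor resilience results (raw p primary; optional Holm column)."""
    results = [resilience_test(base_fit, p, **kwargs) for p in predictors]
    table = pd.DataFrame([asdict(r) for r in results])
    if holm:
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        table["p_holm"] = adj
    return table


def mean_level_regression(records: pd.DataFrame, fd_metric: str) -> dict:
    """Per-plot multi-year means: productivity regressed on an FD metric.

    Means are taken across years within each plot; mean productivity is then
    regressed on the mean metric in a linear mixed model with experiment
    random intercepts, asking whether plots held at high stocking rates carry
    less functional diversity in the long run.
    """
    cols = {"experiment", "block", "plot", "productivity_lu", fd_metric}
    missing = cols - set(records.columns)
    if missing:
        raise KeyError(f"records lack columns {sorted(missing)}")
    grp = records.groupby(["experiment", "block", "plot"], sort=True)
    means = grp[["productivity_lu", fd_metric]].mean().reset_index()
    if len(means) < 2:
        raise ValueError("need at least two plots for a mean-level regression")
    if means[fd_metric].std() == 0:
        raise ValueError(f"mean {fd_metric!r} constant across plots")
    means["plot_uid"] = (means["experiment"].astype(str) + ":" +
                         means["block"].astype(str) + ":" + means["plot"].astype(str))
    means = means.rename(columns={"productivity_lu": "_mean_prod"})

    try:
        fit = fit_mixed(means, (fd_metric,), random="experiment", mode="REML",
                        response="_mean_prod")
    except FitError:
        # singular experiment variance on tiny designs: fall back to OLS scale
        fit = fit_mixed(means, (fd_metric,), random="none", mode="REML",
                        response="_mean_prod")

    slope = float(fit.params[fd_metric])
    se = float(fit.bse[fd_metric])
    df = max(fit.denominator_df, 1)
    p = float(2 * scipy.stats.t.sf(abs(slope / se), df=df))
    return {"fd_metric": fd_metric, "slope": slope, "slope_se": se,
            "intercept": float(fit.params.get("Intercept", np.nan)),
            "df": df, "p_value": p, "n_plots": int(len(means)),
            "random": fit.random}


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full_analysis(
    community: pd.DataFrame,
    traits,
    records: pd.DataFrame,
    alpha: float = 0.05,
    fd_predictors: tuple[str, ...] = ("feve_all", "rao_all", "feve_ldmc", "rao_ldmc"),
    mean_level_metrics: tuple[str, ...] = ("rao_all", "rao_ldmc"),
    start_terms: tuple[str, ...] = ("exp_ldmc", "rain_mm", "rain_sq", "temp_c"),
    holm: bool = False,
) -> dict:
    """Run the full pipeline: transform fit, model ladders, H1 and H2 tests.

    Stages, in order: (0) join FD metrics onto the plot-year records if absent
    and estimate the LDMC decay transform; (1) choose the random structure by
    REML/AIC and simplify the fixed model under ML; check residual temporal
    autocorrelation; (2) forward-select FD terms against the combined model
    and run the mean-level regressions; (3) regress absolute residuals on
    each FD metric with adjusted df.  Returns a report bundle of DataFrames
    plus a JSON-serialisable summary; any stage failure raises with the stage
    named.
    """
    from . import fdmetrics  # local import to avoid cycles

    bundle: dict = {}
    stage = "fd-metrics"
    try:
        if "rao_ldmc" not in records.columns:
            profiles = fdmetrics.fd_profile(
                community, traits,
                cwm_traits=("ldmc_mg_per_g", "sla_mm2_per_mg"),
            )
            fd = fdmetrics.profiles_to_frame(profiles)
            fd.index = community.index
            records = records.merge(
                fd.rename(columns={
                    "cwm_ldmc_mg_per_g": "cwm_ldmc_mg_per_g",
                    "rao_ldmc_mg_per_g": "rao_ldmc",
                    "rao_sla_mm2_per_mg": "rao_sla",
                    "feve_ldmc_mg_per_g": "feve_ldmc",
                }),
                left_on=["experiment", "block", "plot", "year"],
                right_index=True,
            )
        stage = "decay-transform"
        transform = prodmodel.fit_decay_transform(records, group_intercepts="experiment")
        data = prodmodel.prepare_records(records, transform.k)

        stage = "random-structure"
        random, random_table = prodmodel.simplify_random(data, start_terms)

        stage = "fixed-structure"
        base_fit, fixed_trace = prodmodel.simplify_fixed(data, random, start_terms, alpha=alpha)

        stage = "temporal-acf"
        acf = prodmodel.check_temporal_acf(base_fit)

        stage = "h1-forward-selection"
        h1 = prodmodel.forward_select_fd(data, base_fit, candidates=fd_predictors, alpha=alpha)

        stage = "mean-level"
        mean_level = [mean_level_regression(data, m) for m in mean_level_metrics]

        stage = "h2-resilience"
        h2 = resilience_table(base_fit, predictors=fd_predictors, holm=holm)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle.update(
        transform=transform, random=random, random_table=random_table,
        base_fit=base_fit, fixed_trace=fixed_trace, acf=acf,
        h1=h1, mean_level=pd.DataFrame(mean_level), h2=h2, data=data,
    )
    summary = {
        "decay_k": transform.k,
        "random_structure": random,
        "fixed_terms": list(base_fit.fixed_terms),
        "coefficients": {k: float(v) for k, v in base_fit.params.items()},
        "variance_components": base_fit.vc,
        "aic": base_fit.aic,
        "llf": base_fit.llf,
        "denominator_df": base_fit.denominator_df,
        "acf": acf,
        "h1": h1.drop(columns=["note"]).to_dict(orient="records"),
        "mean_level": mean_level,
        "h2": [
            {k: v for k, v in row.items()}
            for row in h2.to_dict(orient="records")
        ],
    }
    bundle["summary"] = _round_floats(summary)
    bundle["summary_json"] = json.dumps(bundle["summary"], indent=2, sort_keys=True)
    return bundle
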