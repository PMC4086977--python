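"""Hierarchical models of grassland secondary productivity.

Productivity (livestock units ha-1 yr-1 needed to hold the sward at a set
height) is modelled on the community-weighted mean of leaf dry matter content
(LDMC) and growing-season weather (May-September rainfall and temperature).
LDMC enters through an exponential-decay transform e^(-k * LDMC): k is
estimated once by pooled nonlinear least squares and then frozen, so the
transform acts as an ordinary covariate inside linear mixed models with
nested random intercepts (plots within experiments).

Model development follows the standard two-stage mixed-model protocol: the
random structure is chosen first by REML/AIC over a nested-intercept ladder,
the fixed structure is then simplified backwards under ML using likelihood
ratios and AIC, and the final model is re-estimated by REML.  Functional
diversity terms are screened afterwards by single-term forward selection
against the combined trait + weather baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DecayTransform",
    "ModelFit",
    "RANDOM_LADDER",
    "fit_decay_transform",
    "fit_mixed",
    "simplify_random",
    "simplify_fixed",
    "check_temporal_acf",
    "forward_select_fd",
    "prepare_records",
]

#: Candidate random-intercept structures, most complex first.  Ties in AIC
#: resolve toward the later (simpler) entry.
RANDOM_LADDER = ("experiment/block/plot", "experiment/plot", "experiment", "none")

RESPONSE = "productivity_lu"


class FitError(RuntimeError):
    """A model fit failed to converge or returned an inadmissible optimum."""


@dataclass
class DecayTransform:
    """Exponential-decay LDMC transform x -> e^(-k x), k in 1/(mg g-1)."""

    k: float
    a: float = 0.0
    b: float = 0.0
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if not self.k > 0:
            raise FitError(f"decay rate k must be positive, got {self.k}")

    def __call__(self, ldmc: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-self.k * np.asarray(ldmc, dtype=float)) if np.ndim(ldmc) else float(
            np.exp(-self.k * ldmc)
        )


def fit_decay_transform(
    records: pd.DataFrame,
    min_records: int = 10,
    group_intercepts: str | None = None,
    k_bounds: tuple[float, float] = (1e-4, 0.2),
) -> DecayTransform:
    """Estimate the LDMC decay rate k by pooled nonlinear least squares.

    Fits productivity = a + b * e^(-k * LDMC) to the pooled plot-year records
    (random effects are not modelled at this stage; k is frozen afterwards
    and the hierarchy handled by the mixed models).  The fit is separable:
    for each candidate k the intercept(s) and amplitude solve a linear
    least-squares problem exactly, and k itself is found by a bounded 1-D
    search on log k — the self-starting asymptotic-regression estimate is the
    profile optimum, so no delicate initialisation is needed.

    ``group_intercepts`` may name a column (e.g. ``"experiment"``): one
    intercept per level then absorbs coarse site offsets, which sharpens k
    when between-site level differences are large; ``a`` reports their mean.
    ``k_bounds`` brackets plausible decay rates per mg g-1 (the default upper
    bound halves productivity every ~3.5 mg g-1, far steeper than any
    credible leaf-economics response).
    """
    y = records[RESPONSE].to_numpy(dtype=float)
    x = records["cwm_ldmc_mg_per_g"].to_numpy(dtype=float)
    if y.size < min_records:
        raise ValueError(f"need at least {min_records} records, got {y.size}")
    if x.max() - x.min() <= 0:
        raise ValueError("cwm_ldmc spans zero range; k is unidentifiable")

    if group_intercepts is None:
        G = np.ones((y.size, 1))
    else:
        codes = pd.factorize(records[group_intercepts])[0]
        G = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)

    def profile_rss(logk: float) -> float:
        X = np.column_stack([G, np.exp(-np.exp(logk) * x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    res = scipy.optimize.minimize_scalar(
        profile_rss,
        bounds=(np.log(k_bounds[0]), np.log(k_bounds[1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise FitError(f"decay-transform profile search failed: {res.message}")
    k = float(np.exp(res.x))
    X = np.column_stack([G, np.exp(-k * x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(beta[:-1].mean()), float(beta[-1])
    rss = float(((y - X @ beta) ** 2).sum())
    if b <= 0:
        raise FitError(f"decay-transform amplitude b={b:.4g} <= 0: no decay signal")
    return DecayTransform(k=k, a=a, b=b, rss=rss)


def prepare_records(records: pd.DataFrame, k: float) -> pd.DataFrame:
    """Add derived model columns: exp_ldmc, rain_sq and nested group ids."""
    out = records.copy()
    out["exp_ldmc"] = np.exp(-k * out["cwm_ldmc_mg_per_g"].to_numpy(dtype=float))
    out["rain_sq"] = out["rain_mm"].to_numpy(dtype=float) ** 2
    out["block_uid"] = out["experiment"].astype(str) + ":" + out["block"].astype(str)
    out["plot_uid"] = out["block_uid"] + ":" + out["plot"].astype(str)
    return out


@dataclass
class ModelFit:
    """A fitted (mixed) productivity model with its bookkeeping.

    ``aic`` is -2 logLik + 2 * n_params under the fit's own estimation mode
    (ML or REML); n_params counts fixed coefficients, variance components and
    the residual variance.  ``denominator_df`` follows the nested-grouping
    convention: observations minus innermost groups minus observation-level
    slopes.
    """

    fixed_terms: tuple[str, ...]
    random: str
    mode: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    vc: dict[str, float]
    llf: float
    n_params: int
    fitted: np.ndarray
    resid: np.ndarray
    n_obs: int
    n_groups: dict[str, int]
    converged: bool
    singular: bool = False
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def denominator_df(self) -> int:
        inner = {
            "experiment/block/plot": "plot",
            "experiment/plot": "plot",
            "experiment": "experiment",
            "none": None,
        }[self.random]
        m = self.n_groups.get(inner, 0) if inner else 0
        p_obs = len(self.fixed_terms)  # non-intercept terms vary within groups
        return self.n_obs - m - p_obs

    def wald_pvalues(self) -> pd.Series:
        t = self.params / self.bse
        return pd.Series(
            2 * scipy.stats.t.sf(np.abs(t), df=max(self.denominator_df, 1)),
            index=self.params.index,
        )


def _formula(fixed_terms: tuple[str, ...], response: str) -> str:
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    return f"{response} ~ {rhs}"


def _ols_reml(
    records: pd.DataFrame, fixed_terms: tuple[str, ...], mode: str, response: str
) -> ModelFit:
    """Fixed-effects-only fit on the mixed-model likelihood scale.

    The REML log-likelihood is the closed form for V = sigma^2 I, which is on
    the same scale as MixedLM's restricted likelihood, so the 'none' random
    structure can compete on AIC in the ladder.
    """
    res = smf.ols(_formula(fixed_terms, response), data=records).fit()
    n, p = int(res.nobs), len(res.params)
    rss = float(res.ssr)
    if mode == "REML":
        s2 = rss / (n - p)
        X = res.model.exog
        sign, logdet = np.linalg.slogdet(X.T @ X)
        llf = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(s2) + logdet + (n - p))
    else:
        llf = float(res.llf)
        s2 = rss / n
    return ModelFit(
        fixed_terms=fixed_terms,
        random="none",
        mode=mode,
        params=res.params,
        bse=res.bse,
        conf_int=res.conf_int(),
        vc={"residual": s2},
        llf=float(llf),
        n_params=p + 1,
        fitted=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
        n_obs=n,
        n_groups={"experiment": records["experiment"].nunique()},
        converged=True,
        data=records,
    )


def _gls_fe_se(
    records: pd.DataFrame,
    fixed_terms: tuple[str, ...],
    vc: dict[str, float],
    random: str,
    res,
) -> np.ndarray:
    """SEs of the fixed effects from (X' V^-1 X)^-1 at the estimated variances."""
    X = np.asarray(res.model.exog, dtype=float)
    n = X.shape[0]
    V = vc["residual"] * np.eye(n)
    level_cols = {"experiment": "experiment", "block": "block_uid", "plot": "plot_uid"}
    for name, col in level_cols.items():
        s2 = vc.get(name, 0.0)
        if s2 <= 0 or col not in records.columns:
            continue
        codes = pd.factorize(records[col])[0]
        Z = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)
        V += s2 * (Z @ Z.T)
    Vi_X = np.linalg.solve(V, X)
    cov = np.linalg.inv(X.T @ Vi_X)
    return np.sqrt(np.diag(cov))


def _approx_conditional_fitted(
    res, records: pd.DataFrame, y: np.ndarray, vc: dict[str, float], random: str
) -> np.ndarray:
    """Fixed fit plus sequentially shrunk nested intercept BLUPs.

    Level means of the running residual are shrunk by s2_level /
    (s2_level + s2_below/n); a zero variance component shrinks fully to
    zero, matching the exact BLUP at the boundary.
    """
    fitted = np.asarray(res.model.exog @ res.fe_params)
    resid = y - fitted
    levels = [("experiment", ["experiment"])]
    if random == "experiment/block/plot":
        levels += [("block", ["block_uid"]), ("plot", ["plot_uid"])]
    elif random == "experiment/plot":
        levels += [("plot", ["plot_uid"])]
    remaining = dict(vc)
    for name, cols in levels:
        s2 = remaining.pop(name, 0.0)
        below = sum(remaining.values())
        g = records.groupby(cols[0], sort=False)
        n = g[cols[0]].transform("size").to_numpy(dtype=float)
        gm = pd.Series(resid, index=records.index).groupby(records[cols[0]], sort=False)
        mean = gm.transform("mean").to_numpy(dtype=float)
        blup = np.zeros_like(resid) if s2 <= 0 else s2 / (s2 + below / n) * mean
        fitted = fitted + blup
        resid = resid - blup
    return fitted


def fit_mixed(
    records: pd.DataFrame,
    fixed_terms: tuple[str, ...] | list[str],
    random: str = "experiment/plot",
    mode: str = "REML",
    response: str = RESPONSE,
) -> ModelFit:
    """Fit ``response`` on the given fixed terms with nested random intercepts.

    ``fixed_terms`` are column names of the prepared record table (intercept
    implicit); ``random`` is one of :data:`RANDOM_LADDER`.  Variance
    components estimated at the zero boundary are reported and flagged
    ``singular``, not treated as errors.
    """
    fixed_terms = tuple(fixed_terms)
    if mode not in ("ML", "REML"):
        raise ValueError(f"mode must be ML or REML, got {mode!r}")
    if random not in RANDOM_LADDER:
        raise ValueError(f"unsupported random structure {random!r}")
    if random == "none":
        return _ols_reml(records, fixed_terms, mode, response)

    vc_formula = {}
    if random == "experiment/block/plot":
        if records.groupby("plot_uid")["block_uid"].nunique().max() == 1 and \
           records.groupby("block_uid")["plot_uid"].nunique().max() == 1:
            # block and plot partitions coincide (one block per plot): the
            # block variance is unidentifiable; fit the plot model and report
            # the extra component at the zero boundary with its AIC penalty
            fit = fit_mixed(records, fixed_terms, "experiment/plot", mode, response)
            fit.random = "experiment/block/plot"
            fit.vc = {"experiment": fit.vc["experiment"], "block": 0.0,
                      "plot": fit.vc["plot"], "residual": fit.vc["residual"]}
            fit.n_params += 1
            fit.singular = True
            return fit
        vc_formula = {"block": "0 + C(block_uid)", "plot": "0 + C(plot_uid)"}
    elif random == "experiment/plot":
        vc_formula = {"plot": "0 + C(plot_uid)"}

    model = smf.mixedlm(
        _formula(fixed_terms, response),
        data=records,
        groups="experiment",
        re_formula="1",
        vc_formula=vc_formula or None,
    )
    res, last_exc = None, None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs can return a non-finite likelihood at a boundary optimum;
        # fall through the optimizers until the fit is finite
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                cand = model.fit(reml=(mode == "REML"), method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if np.isfinite(cand.llf) and np.all(np.isfinite(cand.fe_params)):
                res = cand
                if np.all(np.isfinite(np.asarray(cand.bse_fe))):
                    break
    if res is None:
        raise FitError(f"mixed fit failed for random={random!r}: {last_exc}")

    fe = res.fe_params
    vc = {"experiment": float(res.cov_re.iloc[0, 0])}
    for name in vc_formula:
        vc[name] = float(res.vcomp[list(vc_formula).index(name)])
    vc["residual"] = float(res.scale)
    singular = any(v < 1e-10 for v in vc.values())

    y = records[response].to_numpy(dtype=float)
    try:
        fitted = np.asarray(res.fittedvalues)  # fixed part + predicted random effects
    except (ValueError, np.linalg.LinAlgError):
        # boundary (zero) variance makes the RE covariance singular; predict
        # intercept BLUPs by sequential shrinkage, which is exact at zero
        fitted = _approx_conditional_fitted(res, records, y, vc, random)
    resid = y - fitted
    n_params = len(fe) + 1 + len(vc_formula) + 1  # fe + exp var + vcs + residual

    bse = res.bse_fe
    if not np.all(np.isfinite(np.asarray(bse))):
        # Hessian-based SEs can fail at a boundary optimum; fall back to the
        # exact GLS covariance of the fixed effects at the estimated variances
        bse = pd.Series(_gls_fe_se(records, fixed_terms, vc, random, res), index=fe.index)
        z = scipy.stats.norm.ppf(0.975)
        ci_fe = pd.DataFrame({0: fe - z * bse, 1: fe + z * bse})
    else:
        ci_fe = res.conf_int().loc[fe.index]
    groups = {"experiment": records["experiment"].nunique()}
    for level, col in (("block", "block_uid"), ("plot", "plot_uid")):
        if col in records.columns:
            groups[level] = records[col].nunique()
    return ModelFit(
        fixed_terms=fixed_terms,
        random=random,
        mode=mode,
        params=fe,
        bse=bse,
        conf_int=ci_fe,
        vc=vc,
        llf=float(res.llf),
        n_params=n_params,
        fitted=fitted,
        resid=resid,
        n_obs=int(res.nobs),
        n_groups=groups,
        converged=bool(res.converged),
        singular=singular,
        data=records,
    )


def lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p)."""
    if full.mode != "ML" or reduced.mode != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    stat = 2.0 * (full.llf - reduced.llf)
    df = full.n_params - reduced.n_params
    p = float(scipy.stats.chi2.sf(max(stat, 0.0), df=max(df, 1)))
    return float(stat), df, p


def simplify_random(
    records: pd.DataFrame,
    full_fixed: tuple[str, ...] | list[str],
    ladder: tuple[str, ...] = RANDOM_LADDER,
) -> tuple[str, pd.DataFrame]:
    """Choose the random-intercept structure by REML AIC under the full fixed model.

    Returns the AIC-minimal descriptor (ties resolve to the simpler, later
    ladder entry) and the per-candidate comparison table.
    """
    rows = []
    fits: dict[str, ModelFit] = {}
    for cand in ladder:
        try:
            f = fit_mixed(records, full_fixed, random=cand, mode="REML")
        except FitError:
            continue
        fits[cand] = f
        rows.append({"random": cand, "llf": f.llf, "aic": f.aic,
                     "n_params": f.n_params, "converged": f.converged})
    if not fits:
        raise FitError("no random-structure candidate converged")
    table = pd.DataFrame(rows)
    # iterate in ladder order so later (simpler) candidates win AIC ties
    best, best_aic = None, np.inf
    for cand in ladder:
        if cand in fits and fits[cand].aic <= best_aic + 1e-9:
            best, best_aic = cand, min(best_aic, fits[cand].aic)
    return best, table


# terms that must outlive derived terms: rain must stay while rain^2 is in
_HIERARCHY = {"rain_mm": ("rain_sq",)}


def simplify_fixed(
    records: pd.DataFrame,
    random: str,
    start_terms: tuple[str, ...] | list[str],
    alpha: float = 0.05,
) -> tuple[ModelFit, pd.DataFrame]:
    """Backward-eliminate fixed terms under ML, then refit the winner by REML.

    At each step every admissible single-term deletion is evaluated; among
    deletions whose likelihood-ratio test is non-significant (p >= alpha) the
    one with the lowest AIC is applied.  Marginality is respected (the linear
    rainfall term is not removable while its square is present).  Stops when
    every remaining term is LRT-significant.  Returns the REML refit and the
    elimination trace.
    """
    terms = tuple(start_terms)
    current = fit_mixed(records, terms, random=random, mode="ML")
    trace = [{"step": 0, "action": "start", "terms": "+".join(terms),
              "aic": current.aic, "llf": current.llf, "lrt_p": np.nan}]
    step = 0
    while terms:
        protected = {parent for parent, children in _HIERARCHY.items()
                     if any(c in terms for c in children)}
        candidates = []
        for t in terms:
            if t in protected:
                continue
            reduced_terms = tuple(x for x in terms if x != t)
            try:
                reduced = fit_mixed(records, reduced_terms, random=random, mode="ML")
            except FitError:
                continue
            stat, dfree, p = lrt(current, reduced)
            candidates.append((t, reduced, p))
        droppable = [(t, r, p) for t, r, p in candidates if p >= alpha]
        if not droppable:
            break
        t, reduced, p = min(droppable, key=lambda c: c[1].aic)
        step += 1
        trace.append({"step": step, "action": f"drop {t}", "terms": "+".join(reduced.fixed_terms),
                      "aic": reduced.aic, "llf": reduced.llf, "lrt_p": p})
        terms, current = reduced.fixed_terms, reduced
    final = fit_mixed(records, terms, random=random, mode="REML")
    return final, pd.DataFrame(trace)


def check_temporal_acf(fit: ModelFit) -> dict:
    """Within-plot lag-1 autocorrelation of residuals with a normal-bound test.

    Residuals are ordered by year within plot; lag-1 pairs are pooled across
    plots and the autocorrelation judged significant when |r1| exceeds
    1.96/sqrt(n_pairs).  Returns r1 = None (undefined) when no plot has three
    years or residual variance is zero.
    """
    df = fit.data.assign(_resid=fit.resid)
    group_col = "plot_uid" if "plot_uid" in df.columns else "plot"
    lag0, lag1 = [], []
    max_years = 0
    for _, g in df.groupby(group_col, sort=True):
        g = g.sort_values("year")
        e = g["_resid"].to_numpy(dtype=float)
        max_years = max(max_years, e.size)
        if e.size >= 2:
            lag0.append(e[:-1])
            lag1.append(e[1:])
    if max_years < 3 or not lag0:
        return {"r1": None, "n_pairs": 0, "significant": False, "defined": False}
    e0, e1 = np.concatenate(lag0), np.concatenate(lag1)
    mu, sd = df["_resid"].mean(), df["_resid"].std(ddof=0)
    if sd == 0:
        return {"r1": None, "n_pairs": int(e0.size), "significant": False, "defined": False}
    r1 = float(((e0 - mu) * (e1 - mu)).mean() / sd**2)
    bound = 1.96 / np.sqrt(e0.size)
    return {"r1": r1, "n_pairs": int(e0.size), "significant": bool(abs(r1) > bound),
            "bound": float(bound), "defined": True}


def forward_select_fd(
    records: pd.DataFrame,
    base_fit: ModelFit,
    candidates: tuple[str, ...] = ("feve_all", "rao_all", "feve_ldmc", "rao_ldmc"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen functional-diversity terms one at a time against the base model.

    Each candidate column is added singly to the base fixed model and tested
    by an ML likelihood ratio; the report carries the LRT p, delta-AIC and a
    significance flag per candidate.  A candidate numerically collinear with
    an existing covariate (|r| > 0.999) is refused with a warning entry.
    """
    base_ml = fit_mixed(records, base_fit.fixed_terms, random=base_fit.random, mode="ML")
    rows = []
    for cand in candidates:
        mask = records[cand].notna().to_numpy()
        sub = records.loc[mask]
        x = sub[cand].to_numpy(dtype=float)
        collinear = None
        if np.std(x) == 0:
            collinear = "constant"
        else:
            for t in base_ml.fixed_terms:
                r = np.corrcoef(x, sub[t].to_numpy(dtype=float))[0, 1]
                if abs(r) > 0.999:
                    collinear = t
                    break
        if collinear:
            rows.append({"candidate": cand, "lrt_stat": np.nan, "lrt_p": np.nan,
                         "delta_aic": np.nan, "significant": False, "n_used": int(mask.sum()),
                         "note": f"collinear with {collinear}"})
            continue
        # undefined metric rows (e.g. FEve with < 3 species) are excluded;
        # the base model is refit on the same rows so the LRT stays nested
        base_sub = base_ml if mask.all() else fit_mixed(
            sub, base_ml.fixed_terms, random=base_ml.random, mode="ML")
        aug = fit_mixed(sub, base_ml.fixed_terms + (cand,),
                        random=base_ml.random, mode="ML")
        stat, _, p = lrt(aug, base_sub)
        rows.append({"candidate": cand, "lrt_stat": stat, "lrt_p": p,
                     "delta_aic": aug.aic - base_sub.aic,
                     "significant": bool(p < alpha), "n_used": int(mask.sum()),
                     "note": "" if mask.all() else "undefined rows excluded"})
    return pd.DataFrame(rows)
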