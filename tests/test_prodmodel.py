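import numpy as np
import pandas as pd
import pytest

from grazefd import prodmodel, synth
from grazefd.prodmodel import (
    DecayTransform,
    fit_decay_transform,
    fit_mixed,
    forward_select_fd,
    check_temporal_acf,
    prepare_records,
    simplify_fixed,
    simplify_random,
)


def make_records(n_per_plot=8, n_exp=4, plots=3, k=0.017, beta=(0.0, 90.0, 0.0),
                 noise=0.0, seed=0, ldmc_span=(150.0, 380.0)):
    """Deterministic-mean plot-year records with controllable noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_exp):
        for p in range(plots):
            for y in range(n_per_plot):
                ldmc = rng.uniform(*ldmc_span)
                rain = rng.uniform(300, 800)
                mu = beta[0] + beta[1] * np.exp(-k * ldmc) + beta[2] * rain
                rows.append({
                    "experiment": f"E{e}", "block": f"B{p}", "plot": f"P{p}",
                    "year": 2000 + y, "cwm_ldmc_mg_per_g": ldmc, "rain_mm": rain,
                    "temp_c": rng.normal(13, 1),
                    "productivity_lu": mu + rng.normal(0, noise),
                })
    return pd.DataFrame(rows)


class TestDecayTransform:
    def test_noiseless_recovery_to_machine_precision(self):
        rec = make_records(noise=0.0)
        t = fit_decay_transform(rec)
        assert t.k == pytest.approx(0.017, rel=1e-6)
        assert t.rss < 1e-12

    def test_transform_values(self):
        t = DecayTransform(k=0.01704)
        assert t(200.0) == pytest.approx(np.exp(-3.408), rel=1e-6)
        assert t(0.0) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        t = fit_decay_transform(make_records(noise=0.2, seed=3))
        grid = np.linspace(100, 400, 50)
        vals = t(grid)
        assert (np.diff(vals) < 0).all()

    def test_k_must_be_positive(self):
        with pytest.raises(Exception):
            DecayTransform(k=-0.01)

    def test_requires_spread_and_enough_records(self):
        rec = make_records(n_per_plot=1, n_exp=1, plots=1)
        with pytest.raises(ValueError, match="at least"):
            fit_decay_transform(rec)
        rec = make_records(noise=0.0)
        rec["cwm_ldmc_mg_per_g"] = 250.0
        with pytest.raises(ValueError, match="zero range"):
            fit_decay_transform(rec)

    def test_group_intercepts_absorb_site_offsets(self):
        rec = make_records(noise=0.0)
        offsets = {f"E{e}": o for e, o in enumerate([1.0, -0.5, 0.25, 2.0])}
        rec["productivity_lu"] += rec["experiment"].map(offsets)
        t = fit_decay_transform(rec, group_intercepts="experiment")
        assert t.k == pytest.approx(0.017, rel=1e-6)


class TestFitMixed:
    def test_zero_group_variance_matches_ols(self):
        rec = prepare_records(make_records(noise=0.3, beta=(0.0, 90.0, 0.002), seed=5), 0.017)
        # remove the realised group structure (iteratively demean residuals
        # within plots) so the hierarchy is degenerate by construction
        for _ in range(6):
            ols = fit_mixed(rec, ("exp_ldmc", "rain_mm"), random="none", mode="ML")
            gm = pd.Series(ols.resid, index=rec.index).groupby(rec["plot_uid"]).transform("mean")
            rec["productivity_lu"] -= gm
            if gm.abs().max() < 1e-13:
                break
        mixed = fit_mixed(rec, ("exp_ldmc", "rain_mm"), random="experiment/plot", mode="ML")
        ols = fit_mixed(rec, ("exp_ldmc", "rain_mm"), random="none", mode="ML")
        for term in ("Intercept", "exp_ldmc", "rain_mm"):
            assert mixed.params[term] == pytest.approx(ols.params[term], rel=1e-4, abs=1e-6)
        # variance components collapse toward the boundary, never negative
        assert 0 <= mixed.vc["plot"] < 0.2 * mixed.vc["residual"]
        assert 0 <= mixed.vc["experiment"] < 0.2 * mixed.vc["residual"]

    def test_prediction_from_fitted_coefficients(self):
        # -0.687 + 95.31*exp(-0.017*200) + 0.0018*600 ~ 3.574 LU/ha/yr
        mu = -0.687 + 95.31 * np.exp(-0.0170 * 200.0) + 0.0018 * 600.0
        assert mu == pytest.approx(3.574, abs=5e-3)

    def test_quadratic_rain_vertex(self):
        # marginal rain effect of 0.00234*r - 1.47e-6*r^2 vanishes at ~796 mm
        vertex = 0.00234 / (2 * 1.47e-6)
        assert vertex == pytest.approx(796, abs=1.0)

    def test_aic_consistent_with_llf_and_params(self, fast_dataset):
        data = prepare_records(fast_dataset.records, 0.017)
        fit = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot", mode="ML")
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.n_params)

    def test_residuals_are_observed_minus_fitted(self, fast_dataset):
        data = prepare_records(fast_dataset.records, 0.017)
        fit = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot")
        np.testing.assert_allclose(
            fit.resid, data["productivity_lu"].to_numpy() - fit.fitted, atol=1e-10
        )
        assert abs(fit.resid.mean()) < 0.05

    def test_reml_and_ml_agree_on_large_balanced_design(self):
        cfg = synth.GeneratorConfig(seed=77, n_experiments=20, plots_per_experiment=4,
                                    years_min=10, years_max=10, compute_feve=False)
        data = prepare_records(synth.generate_dataset(cfg).records, 0.017)
        ml = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot", mode="ML")
        reml = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot", mode="REML")
        for term in ("exp_ldmc", "rain_mm"):
            assert ml.params[term] == pytest.approx(reml.params[term], rel=0.01)

    def test_nested_submodel_aic_never_far_below_truth(self):
        """On a large design, dropping a true term can beat the true model's
        ML AIC by at most the parameter penalty (2), and dropping a strong
        term is far worse."""
        cfg = synth.GeneratorConfig(seed=55, n_experiments=30, plots_per_experiment=4,
                                    years_min=10, years_max=10, compute_feve=False)
        data = prepare_records(synth.generate_dataset(cfg).records, 0.017)
        true_fit = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot",
                             mode="ML")
        no_rain = fit_mixed(data, ("exp_ldmc",), random="experiment/plot", mode="ML")
        no_ldmc = fit_mixed(data, ("rain_mm",), random="experiment/plot", mode="ML")
        assert no_rain.aic >= true_fit.aic - 2.0
        assert no_ldmc.aic > true_fit.aic + 50.0

    def test_unsupported_arguments_rejected(self, fast_dataset):
        data = prepare_records(fast_dataset.records, 0.017)
        with pytest.raises(ValueError):
            fit_mixed(data, ("exp_ldmc",), random="plot/experiment")
        with pytest.raises(ValueError):
            fit_mixed(data, ("exp_ldmc",), mode="FIML")


class TestSimplify:
    def test_random_ladder_reports_all_candidates(self, fast_dataset):
        data = prepare_records(fast_dataset.records, 0.017)
        best, table = simplify_random(data, ("exp_ldmc", "rain_mm"))
        assert best in prodmodel.RANDOM_LADDER
        assert set(table["random"]) == set(prodmodel.RANDOM_LADDER)

    def test_no_grouping_variance_prefers_simple_structure(self):
        rec = prepare_records(
            make_records(noise=0.3, beta=(0.0, 90.0, 0.002), seed=11), 0.017
        )
        best, _ = simplify_random(rec, ("exp_ldmc", "rain_mm"))
        assert best in ("none", "experiment")

    def test_intercept_only_truth_drops_all_slopes(self):
        # pure-intercept truth with a tiny noise floor (an exactly constant
        # response makes the Gaussian likelihood degenerate)
        rec = make_records(noise=0.01, beta=(2.0, 0.0, 0.0), seed=0)
        data = prepare_records(rec, 0.017)
        fit, trace = simplify_fixed(data, "none", ("exp_ldmc", "rain_mm", "temp_c"))
        assert fit.fixed_terms == ()

    def test_marginality_rain_kept_while_square_present(self):
        # response built on rain^2 alone: the linear term must survive until
        # the square is dropped, so the hierarchy is respected in the trace
        rec = make_records(noise=0.05, beta=(0.0, 90.0, 0.0), seed=13)
        rec["productivity_lu"] += 1e-6 * rec["rain_mm"] ** 2
        data = prepare_records(rec, 0.017)
        fit, trace = simplify_fixed(data, "none", ("exp_ldmc", "rain_mm", "rain_sq"))
        for _, row in trace.iterrows():
            terms = row["terms"].split("+")
            if "rain_sq" in terms:
                assert "rain_mm" in terms


class TestTemporalAcf:
    def test_independent_residuals_rarely_flagged(self):
        """Type-I behaviour: with serially independent errors the lag-1
        check flags only a small fraction of seeded replicates.  Fixed-only
        fits are used so the residuals are free of the small negative serial
        correlation that predicted plot intercepts induce."""
        flagged = 0
        for s in range(40):
            rec = make_records(noise=0.2, beta=(1.0, 20.0, 0.001), seed=1500 + s)
            data = prepare_records(rec, 0.017)
            fit = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="none")
            out = check_temporal_acf(fit)
            assert out["defined"]
            flagged += out["significant"]
        assert flagged <= 6  # ~5% nominal rate, generous margin

    def test_ar1_residuals_flagged(self):
        rec = make_records(n_per_plot=12, noise=0.0, beta=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(5)
        e = np.zeros(len(rec))
        for plot, idx in rec.groupby(["experiment", "plot"]).groups.items():
            z = rng.normal(0, 0.3, len(idx))
            for t in range(1, len(z)):
                z[t] += 0.85 * z[t - 1]
            e[np.asarray(idx)] = z
        rec["productivity_lu"] = 1.0 + e
        data = prepare_records(rec, 0.017)
        fit = fit_mixed(data, (), random="none")
        out = check_temporal_acf(fit)
        assert out["defined"] and out["significant"]

    def test_constant_residuals_undefined_not_crash(self):
        rec = make_records(noise=0.0, beta=(2.0, 0.0, 0.0))
        rec["productivity_lu"] = 2.0
        data = prepare_records(rec, 0.017)
        fit = fit_mixed(data, (), random="none")
        out = check_temporal_acf(fit)
        assert out["defined"] is False and out["significant"] is False


class TestForwardSelectFd:
    def test_collinear_candidate_refused(self, fast_dataset):
        data = prepare_records(fast_dataset.records, 0.017)
        data["fd_clone"] = data["exp_ldmc"] * 1.0
        base = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot")
        report = forward_select_fd(data, base, candidates=("fd_clone",))
        assert "collinear" in report.loc[0, "note"]
        assert not report.loc[0, "significant"]

    def test_strong_injected_fd_effect_detected(self):
        cfg = synth.GeneratorConfig(seed=21, compute_feve=False)
        ds = synth.generate_dataset(cfg)
        rec = ds.records.copy()
        rec["productivity_lu"] = rec["productivity_lu"] + 8.0 * rec["rao_ldmc"]
        data = prepare_records(rec, 0.017)
        base = fit_mixed(data, ("exp_ldmc", "rain_mm"), random="experiment/plot")
        report = forward_select_fd(data, base, candidates=("rao_ldmc", "rao_sla"))
        row = report.set_index("candidate").loc["rao_ldmc"]
        assert row["significant"] and row["delta_aic"] < 0
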