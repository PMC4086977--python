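"""Seeded synthetic grazing-experiment datasets with known ground truth.

The generator emulates the structure of a multi-site upland grazing study:
several experiments, each with a few plots followed for 4-15 years, with
point-quadrat-style relative abundances over a shared species pool, growing
season weather, and a productivity response (livestock units ha-1 yr-1)
built from the hierarchical model the analysis assumes:

    productivity = b0 + b1 * e^(-k * CWM_LDMC) + b2 * rain
                   + u_experiment + u_plot + eps,
    sd(eps) = sigma0 * exp(-gamma * RaoQ_LDMC).

An experiment-level fertility score couples composition to diversity: high
fertility shifts abundance toward low-LDMC (fast, digestible) species and
increases dominance, lowering Rao's Q of LDMC — the mechanism behind the
productivity/diversity trade-off the analysis is designed to detect.  gamma
controls the resilience signal (residual spread shrinking with functional
diversity); gamma = 0 gives a homoscedastic null.

Every stochastic choice flows from the single ``seed``.  Temperature is
generated but carries no effect, so fixed-model simplification always has a
true-negative term to drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats

from . import fdmetrics
from .traits import DEFAULT_SCHEMES, RawTraitEntry, TraitTable, build_trait_table

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_species_pool",
    "generate_communities",
    "generate_records",
    "generate_dataset",
    "calibrate_resilience",
]


@dataclass
class GeneratorConfig:
    """Design and model parameters for the synthetic study.

    Defaults mirror the reference study design (9 experiments, 4-15 years)
    and its fitted combined-model coefficients; variance components and the
    abundance model are the generator's own, documented choices.
    """

    n_experiments: int = 9
    plots_per_experiment: int = 3
    years_min: int = 4
    years_max: int = 15
    n_species: int = 40

    # fixed effects of the productivity model
    beta0: float = -0.687
    beta1: float = 95.31
    k: float = 0.0170
    beta_rain: float = 0.0018
    beta_temp: float = 0.0

    # variance components (LU ha-1 yr-1 scale); kept modest so that the
    # zero-truncation of productivity stays rare (< 1%) at the default design
    sd_experiment: float = 0.20
    sd_plot: float = 0.15
    sigma0: float = 0.20          # residual base SD
    gamma: float = 0.0            # resilience coupling: sd = sigma0*exp(-gamma*RaoQ_LDMC)

    # trait marginals
    ldmc_mean: float = 250.0      # mg g-1
    ldmc_sd: float = 60.0
    ldmc_min: float = 80.0

    # community model
    fertility_diversity_coupling: float = 2.0  # 0 = none; ~6 = maximal documented
    plot_fertility_sd: float = 0.5  # within-experiment (soil-scale) fertility spread
    logit_sd: float = 1.0         # spread of per-plot species preferences
    dirichlet_concentration: float = 10.0  # low: point-quadrat composition turnover is large

    # weather
    rain_mean_range: tuple[float, float] = (300.0, 800.0)  # per-experiment means, mm
    rain_sd: float = 80.0
    temp_mean: float = 13.5       # degC, May-September
    temp_sd: float = 1.5

    seed: int = 0
    compute_feve: bool = True

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name in ("sd_experiment", "sd_plot", "sigma0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (1 <= self.years_min <= self.years_max):
            raise ValueError("invalid years range")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth needed to score recovery."""

    traits: TraitTable
    community: pd.DataFrame
    records: pd.DataFrame
    truth: dict = field(default_factory=dict)


_CATEGORICAL_MARGINALS = {
    "life_form": (["Hemicryptophyte", "Geophyte", "Therophyte", "Chamaephyte", "Phanerophyte"],
                  [0.60, 0.10, 0.15, 0.10, 0.05]),
    "canopy_structure": (["Rosette", "Hemirosette", "Erosulate"], [0.25, 0.45, 0.30]),
    "leafing_period": (["Evergreen", "Summer green"], [0.40, 0.60]),
    "life_span": (["Annual", "Biennial", "Perennial"], [0.15, 0.10, 0.75]),
    "veg_spread_rhizome": (["Not rhizomatous", "Rhizomatous"], [0.60, 0.40]),
    "veg_spread_stolon": (["Not stoloniferous", "Stoloniferous"], [0.75, 0.25]),
}


def generate_species_pool(config: GeneratorConfig, rng: np.random.Generator) -> TraitTable:
    """Draw a grassland-plausible coded species pool.

    LDMC is truncated-normal (mean 250, SD 60 mg g-1 by default); SLA is
    lognormal and negatively coupled to LDMC (structural leaves have low area
    per mass); height and leaf size are lognormal and log-coded by their
    schemes; categorical attributes follow fixed grassland marginals.
    """
    n = config.n_species
    if n < 5:
        raise ValueError("species pool must have at least 5 species")
    species = [f"sp{i:03d}" for i in range(n)]

    a = (config.ldmc_min - config.ldmc_mean) / config.ldmc_sd
    z = scipy.stats.truncnorm.rvs(a, np.inf, size=n, random_state=rng)
    ldmc = config.ldmc_mean + config.ldmc_sd * z
    sla = np.exp(np.log(20.0) - 0.25 * z + rng.normal(0, 0.25, n))
    height = np.exp(np.log(0.30) + rng.normal(0, 0.5, n))
    leaf_size = np.exp(np.log(300.0) + rng.normal(0, 0.8, n))
    flowering = rng.integers(4, 9, size=n)

    entries: list[RawTraitEntry] = []
    for i, sp in enumerate(species):
        entries += [
            RawTraitEntry(sp, "ldmc_mg_per_g", float(ldmc[i])),
            RawTraitEntry(sp, "sla_mm2_per_mg", float(sla[i])),
            RawTraitEntry(sp, "canopy_height_m", float(height[i])),
            RawTraitEntry(sp, "leaf_size_mm2", float(leaf_size[i])),
            RawTraitEntry(sp, "flowering_start_month", float(flowering[i])),
        ]
        for trait, (labels, probs) in _CATEGORICAL_MARGINALS.items():
            entries.append(RawTraitEntry(sp, trait, labels[rng.choice(len(labels), p=probs)]))
    return build_trait_table(entries, DEFAULT_SCHEMES)


def generate_communities(
    pool: TraitTable, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw plot-year relative abundances and the design table.

    Each plot holds a latent species-preference vector; yearly compositions
    are Dirichlet draws around its softmax weights.  Plots sample a
    soil-scale fertility gradient around their experiment's mean score
    (``plot_fertility_sd``), and the plot fertility f acts twice: it tilts preferences toward low-LDMC species
    (min(coupling/2, 1) * f in LDMC z-units — the tilt saturates, since
    composition cannot shift past the fast end of the pool) and scales the
    preference spread by exp(coupling * 0.35 * f), so higher fertility means
    stronger dominance and hence lower LDMC diversity, monotonically in the
    coupling.  Returns (community matrix, design frame with
    experiment/block/plot/year keys and the fertility scores).
    """
    ldmc = pool.values_for("ldmc_mg_per_g").to_numpy(dtype=float)
    aff = -(ldmc - ldmc.mean()) / ldmc.std(ddof=0)  # low LDMC = fertile-site affinity
    c = config.fertility_diversity_coupling
    tilt = min(c / 2.0, 1.0)

    rows, keys = [], []
    fert_by_plot = {}
    for e in range(config.n_experiments):
        exp_id = f"E{e + 1:02d}"
        fert_exp = float(rng.normal())
        n_years = int(rng.integers(config.years_min, config.years_max + 1))
        for p in range(config.plots_per_experiment):
            # one block per plot: keeps the experiment/block/plot ladder exercisable
            block_id = f"B{p + 1}"
            plot_id = f"P{p + 1}"
            # plots sample a soil-scale fertility gradient around the site mean
            fert = fert_exp + config.plot_fertility_sd * float(rng.normal())
            fert_by_plot[(exp_id, block_id, plot_id)] = fert
            base = rng.normal(0, config.logit_sd, pool.data.shape[0])
            logits = np.exp(0.35 * c * fert) * base + tilt * fert * aff
            w = np.exp(logits - logits.max())
            w /= w.sum()
            alpha = np.maximum(config.dirichlet_concentration * w, 1e-3)
            for y in range(n_years):
                abund = rng.dirichlet(alpha)
                rows.append(abund / abund.sum())
                keys.append((exp_id, block_id, plot_id, 2000 + y))

    idx = pd.MultiIndex.from_tuples(keys, names=["experiment", "block", "plot", "year"])
    community = pd.DataFrame(np.vstack(rows), index=idx, columns=pool.species)
    design = community.index.to_frame(index=False)
    design["fertility"] = [
        fert_by_plot[(e, b, p)]
        for e, b, p in zip(design["experiment"], design["block"], design["plot"])
    ]
    return community, design


def generate_records(
    community: pd.DataFrame,
    design: pd.DataFrame,
    pool: TraitTable,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Attach weather, random effects and the productivity response.

    Productivity draws below zero are truncated at zero (stocking densities
    cannot be negative); the truncation count is reported in the ground
    truth.  Functional-diversity columns come from :mod:`grazefd.fdmetrics`
    on the generated community.
    """
    profiles = fdmetrics.fd_profile(
        community, pool,
        single_traits=("sla_mm2_per_mg", "ldmc_mg_per_g"),
        cwm_traits=("ldmc_mg_per_g", "sla_mm2_per_mg"),
        compute_feve=config.compute_feve,
    )
    fd = fdmetrics.profiles_to_frame(profiles)
    fd.index = community.index

    rec = design.copy()
    rec["cwm_ldmc_mg_per_g"] = fd["cwm_ldmc_mg_per_g"].to_numpy()
    rec["cwm_sla_mm2_per_mg"] = fd["cwm_sla_mm2_per_mg"].to_numpy()
    rec["rao_all"] = fd["rao_all"].to_numpy()
    rec["rao_ldmc"] = fd["rao_ldmc_mg_per_g"].to_numpy()
    rec["rao_sla"] = fd["rao_sla_mm2_per_mg"].to_numpy()
    rec["feve_all"] = fd["feve_all"].to_numpy()
    rec["feve_ldmc"] = fd["feve_ldmc_mg_per_g"].to_numpy()

    experiments = sorted(rec["experiment"].unique())
    lo, hi = config.rain_mean_range
    rain_means = {e: float(rng.uniform(lo, hi)) for e in experiments}
    u_exp = {e: float(rng.normal(0, config.sd_experiment)) for e in experiments}
    plots = sorted(set(zip(rec["experiment"], rec["block"], rec["plot"])))
    u_plot = {pl: float(rng.normal(0, config.sd_plot)) for pl in plots}

    ey = rec[["experiment", "year"]].drop_duplicates()
    rain_map = {
        (e, y): max(float(rng.normal(rain_means[e], config.rain_sd)), 0.0)
        for e, y in ey.itertuples(index=False)
    }
    rec["rain_mm"] = [rain_map[(e, y)] for e, y in zip(rec["experiment"], rec["year"])]
    rec["temp_c"] = rng.normal(config.temp_mean, config.temp_sd, len(rec))

    mean = (
        config.beta0
        + config.beta1 * np.exp(-config.k * rec["cwm_ldmc_mg_per_g"].to_numpy())
        + config.beta_rain * rec["rain_mm"].to_numpy()
        + config.beta_temp * rec["temp_c"].to_numpy()
    )
    u_e = rec["experiment"].map(u_exp).to_numpy()
    u_p = np.array([u_plot[pl] for pl in zip(rec["experiment"], rec["block"], rec["plot"])])
    sd_eps = config.sigma0 * np.exp(-config.gamma * rec["rao_ldmc"].to_numpy())
    eps = rng.normal(0, 1, len(rec)) * sd_eps
    raw = mean + u_e + u_p + eps
    truncated = int((raw < 0).sum())
    rec["productivity_lu"] = np.maximum(raw, 0.0)

    truth = {
        "beta0": config.beta0, "beta1": config.beta1, "k": config.k,
        "beta_rain": config.beta_rain, "beta_temp": config.beta_temp,
        "sd_experiment": config.sd_experiment, "sd_plot": config.sd_plot,
        "sigma0": config.sigma0, "gamma": config.gamma,
        "u_experiment": u_exp,
        "u_plot": {":".join(pl): v for pl, v in u_plot.items()},
        "true_sd_eps": sd_eps.tolist(),
        "n_truncated": truncated,
    }
    return rec, truth


def generate_dataset(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a full dataset (trait table, community, records, ground truth)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pool = generate_species_pool(config, rng)
    community, design = generate_communities(pool, config, rng)
    records, truth = generate_records(community, design, pool, config, rng)
    truth["config"] = {k: v for k, v in asdict(config).items()}
    return SyntheticDataset(traits=pool, community=community, records=records, truth=truth)


def _sigma0_for_slope(gamma: float, q_mean: float, target_slope: float) -> float:
    # E|eps| = sigma(q) * sqrt(2/pi); d E|eps| / dq at q_mean = -target_slope
    return float(target_slope / (np.sqrt(2 / np.pi) * gamma * np.exp(-gamma * q_mean)))


def calibrate_resilience(
    config: GeneratorConfig,
    target_slope: float = 0.104,
    power: float = 0.90,
    alpha: float = 0.05,
    seed: int = 0,
    n_probe: int = 30,
    n_iter: int = 4,
) -> GeneratorConfig:
    """Choose (gamma, sigma0) giving a resilience signal of a stated size.

    The dispersion model sd(eps) = sigma0*exp(-gamma*q), q = RaoQ_LDMC, pins
    only the product of gamma and sigma0 through the expected |residual|-on-q
    slope (-sigma0*sqrt(2/pi)*gamma*exp(-gamma*q)).  The pair is resolved by
    a power condition: gamma is tuned so the resilience test's expected t
    statistic matches the one-sided power request, with sigma0 re-solved at
    each step to hold the slope magnitude at ``target_slope``.  Because the
    base-model residuals carry estimation noise (the frozen-k transform and
    the random-effect predictions), the t-vs-gamma response is measured by a
    small Monte-Carlo probe of the actual two-stage pipeline rather than
    taken from the half-normal closed form, which overstates it.
    """
    from . import prodmodel, resilience  # deferred: avoids an import cycle

    probe_cfg = GeneratorConfig(**{**asdict(config), "gamma": 0.0, "compute_feve": False})
    probe = generate_dataset(probe_cfg, seed=seed)
    q = probe.records["rao_ldmc"].to_numpy(dtype=float)
    q_mean, q_sd = float(q.mean()), float(q.std(ddof=0))
    if q_sd <= 0:
        raise ValueError("RaoQ_LDMC has zero spread; cannot calibrate gamma")

    ratio = np.sqrt(2 / np.pi) / np.sqrt(1 - 2 / np.pi)  # ~1.3236
    z_need = float(scipy.stats.norm.ppf(1 - alpha) + scipy.stats.norm.ppf(power))
    gamma = float(z_need / (ratio * q_sd * np.sqrt(q.size)))  # closed-form start

    rng = np.random.default_rng(seed)
    slope_corr = 1.0
    sigma0 = _sigma0_for_slope(gamma, q_mean, target_slope)
    for _ in range(n_iter):
        sigma0 = _sigma0_for_slope(gamma, q_mean, target_slope) * slope_corr
        tstats, slopes = [], []
        for _ in range(n_probe):
            rep_seed = int(rng.integers(2**31 - 1))
            rep_cfg = GeneratorConfig(**{
                **asdict(config), "gamma": gamma, "sigma0": sigma0,
                "compute_feve": False, "seed": rep_seed,
            })
            ds = generate_dataset(rep_cfg)
            k = prodmodel.fit_decay_transform(ds.records, group_intercepts="experiment").k
            data = prodmodel.prepare_records(ds.records, k)
            base = prodmodel.fit_mixed(data, ("exp_ldmc", "rain_mm"),
                                       random="experiment/plot", mode="REML")
            r = resilience.resilience_test(base, "rao_ldmc")
            tstats.append(r.t_stat)
            slopes.append(r.slope)
        mean_t, mean_slope = float(np.mean(tstats)), float(np.mean(slopes))
        if mean_t >= 0 or mean_slope >= 0:  # no detectable signal yet
            gamma *= 2.0
            continue
        slope_corr *= target_slope / abs(mean_slope)
        g_adj = z_need / abs(mean_t)
        if abs(g_adj - 1.0) < 0.07 and abs(target_slope / mean_slope + 1.0) < 0.07:
            break
        gamma *= float(np.clip(g_adj, 0.4, 2.5))
    return GeneratorConfig(**{**asdict(config), "gamma": float(gamma), "sigma0": float(sigma0)})
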