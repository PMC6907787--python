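"""Model grid, Gibbs sampler, convergence diagnostics and DIC selection."""

import numpy as np
import pandas as pd
import pytest

from vaxbiome import bayes
from vaxbiome.errors import ConfigError, DataError


def _toy_data(n=60, seed=0, coef=(2.0, 1.5), noise=1.0, n_treat=2, n_mice=2):
    """Data from a degree-1 global-trend model with per-treatment labels."""
    rng = np.random.default_rng(seed)
    weeks = np.tile([0, 2, 4, 6, 8, 10], n // 6 + 1)[:n]
    x = (weeks - 5.0) / 5.0
    treatments = [f"T{i % n_treat}" for i in range(n)]
    mice = [f"{t}.m{i % n_mice}" for i, t in enumerate(treatments)]
    y = coef[0] + coef[1] * x + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"value": y, "treatment": treatments, "mouse": mice, "week": weeks}
    )


def _fake_draws(arrays: dict, names=None) -> bayes.PosteriorDraws:
    """PosteriorDraws wrapper around externally constructed chains."""
    names = names or list(arrays)
    stacked = np.stack([np.column_stack([arrays[n][c] for n in names])
                        for c in range(len(next(iter(arrays.values()))))])
    model = bayes.ModelSpec(0, "global", "none")
    p = len(names) - 3
    return bayes.PosteriorDraws(
        draws=stacked, names=names, codes=np.zeros(p, dtype=np.int64),
        model=model, treatments=["T0"], mice=["m0"], week_mid=5.0, week_half=5.0,
        y=np.zeros(1), Z=np.ones((1, p)), chains=bayes.ChainConfig.smoke_profile(),
    )


# ------------------------------------------------------------- model grid
def test_enumeration_contains_described_members():
    models = bayes.enumerate_models()
    assert len(set(models)) == len(models)
    assert bayes.ModelSpec(1, "per_treatment_and_mouse", "global") in models
    assert bayes.ModelSpec(3, "per_treatment_and_mouse", "per_treatment_and_mouse") in models
    assert bayes.ModelSpec(0, "global", "none") in models
    degree0 = [m for m in models if m.degree == 0]
    assert len(degree0) == 3 and all(m.trend == "none" for m in degree0)
    with pytest.raises(ConfigError):
        bayes.ModelSpec(0, "global", "global")
    with pytest.raises(ConfigError):
        bayes.ModelSpec(2, "global", "none")


def test_design_matrix_scaling_and_rank():
    d0 = bayes.design_matrix([0, 2, 4], 0)
    np.testing.assert_array_equal(d0, np.ones((3, 1)))
    d1 = bayes.design_matrix(list(range(0, 12, 2)), 1)
    assert d1[:, 1].min() == -1.0 and d1[:, 1].max() == 1.0
    d3 = bayes.design_matrix([0, 2, 4, 6, 8, 10], 3)
    assert np.linalg.matrix_rank(d3) == 4
    with pytest.raises(DataError):
        bayes.design_matrix([0, 2, 4], 3)


def test_chain_schedule_bookkeeping():
    full = bayes.ChainConfig.full_profile()
    assert full.retained_per_chain == 600
    assert full.retained_total == 1800
    test = bayes.ChainConfig.test_profile()
    assert test.retained_per_chain == 600
    with pytest.raises(ConfigError):
        bayes.ChainConfig(n_iter=100, burn_in=100).validate()


# ------------------------------------------------------------------ Gibbs
def test_gibbs_recovers_global_linear_model():
    data = _toy_data(n=600, seed=1, coef=(2.0, 1.5), noise=1.0)
    draws = bayes.gibbs_fit(
        data, bayes.ModelSpec(1, "global", "global"),
        chains=bayes.ChainConfig.smoke_profile(seed=4),
    )
    assert draws.draws.shape == (2, 300, draws.n_coef + 3)
    for name, true in (("intercept", 2.0), ("beta1", 1.5)):
        sample = draws.parameter(name)
        assert abs(sample.mean() - true) < 3 * sample.std()
    sigma2 = draws.parameter("sigma2")
    assert 0.8 < sigma2.mean() < 1.25
    # seeded determinism
    draws2 = bayes.gibbs_fit(
        data, bayes.ModelSpec(1, "global", "global"),
        chains=bayes.ChainConfig.smoke_profile(seed=4),
    )
    np.testing.assert_array_equal(draws.draws, draws2.draws)


def test_gibbs_matches_brute_force_grid_posterior():
    """Marginal posterior of the mean in the intercept-only model agrees
    with a dense-grid evaluation of the exact posterior (TV < 0.05)."""
    rng = np.random.default_rng(7)
    y = rng.normal(1.5, 1.0, 20)
    data = pd.DataFrame(
        {"value": y, "treatment": "T0", "mouse": "m0", "week": np.tile([0, 2], 10)}
    )
    chains = bayes.ChainConfig(n_chains=2, n_iter=12_000, burn_in=2_000, thin=2, seed=9)
    draws = bayes.gibbs_fit(data, bayes.ModelSpec(0, "global", "none"), chains=chains)
    mu_draws = draws.parameter("intercept")
    assert len(mu_draws) == 10_000

    priors = bayes.Priors()
    tau2 = priors.tau2_scale * np.var(y)
    mu_grid = np.linspace(y.mean() - 2.5, y.mean() + 2.5, 201)
    s2_grid = np.linspace(1e-3, 8.0, 400)
    log_post = np.empty((len(mu_grid), len(s2_grid)))
    n = len(y)
    for i, mu in enumerate(mu_grid):
        ssr = ((y - mu) ** 2).sum()
        log_post[i] = (
            -0.5 * n * np.log(s2_grid)
            - ssr / (2 * s2_grid)
            - 0.5 * mu**2 / tau2
            + (-priors.ig_shape - 1) * np.log(s2_grid)
            - priors.ig_rate / s2_grid
        )
    post = np.exp(log_post - log_post.max())
    marginal = post.sum(axis=1)
    marginal /= marginal.sum()
    bins = np.concatenate([[-np.inf], (mu_grid[1:] + mu_grid[:-1]) / 2, [np.inf]])
    hist = np.histogram(mu_draws, bins=bins)[0] / len(mu_draws)
    tv = 0.5 * np.abs(hist - marginal).sum()
    assert tv < 0.05


def test_gibbs_rejects_rank_deficient_design():
    data = _toy_data(n=24)
    data["week"] = 0  # single week cannot support a trend
    with pytest.raises(DataError):
        bayes.gibbs_fit(data, bayes.ModelSpec(1, "global", "global"),
                        chains=bayes.ChainConfig.smoke_profile())


# ----------------------------------------------------------- Gelman-Rubin
def test_gelman_rubin_reference_cases():
    rng = np.random.default_rng(11)
    m = 600
    base = {
        "theta": [rng.normal(0, 1, m) for _ in range(3)],
        "sigma2": [np.abs(rng.normal(1, 0.1, m)) for _ in range(3)],
        "sigma2_mouse_intercept": [np.full(m, np.nan)] * 3,
        "sigma2_mouse_trend": [np.full(m, np.nan)] * 3,
    }
    same = _fake_draws(base)
    assert bayes.gelman_rubin(same)["theta"] < 1.05

    apart = dict(base)
    apart["theta"] = [rng.normal(mu, 1, m) for mu in (0.0, 10.0, 0.0)]
    assert bayes.gelman_rubin(_fake_draws(apart))["theta"] > 3.0

    copied = dict(base)
    copied["theta"] = [base["theta"][0]] * 3
    rhat = bayes.gelman_rubin(_fake_draws(copied))["theta"]
    assert rhat == pytest.approx(np.sqrt((m - 1) / m), abs=1e-12)


# --------------------------------------------------------------------- DIC
def test_dic_degenerate_posterior_has_zero_pd():
    y = np.array([1.0, 2.0, 3.0])
    m = 50
    theta = np.full(m, 2.0)
    arrays = {
        "intercept": [theta, theta],
        "sigma2": [np.full(m, 1.3)] * 2,
        "sigma2_mouse_intercept": [np.full(m, np.nan)] * 2,
        "sigma2_mouse_trend": [np.full(m, np.nan)] * 2,
    }
    draws = _fake_draws(arrays)
    draws.y = y
    draws.Z = np.ones((3, 1))
    dbar, d_at_mean, p_d, dic_val = bayes.dic(draws)
    assert p_d == pytest.approx(0.0, abs=1e-9)
    assert dic_val == pytest.approx(dbar, abs=1e-9)
    expected_dev = 3 * np.log(2 * np.pi * 1.3) + ((y - 2.0) ** 2).sum() / 1.3
    assert dbar == pytest.approx(expected_dev, abs=1e-9)


def test_pd_counts_one_effective_parameter_with_known_variance():
    """Gaussian-mean model with sigma^2 held fixed: pD ~ 1."""
    rng = np.random.default_rng(15)
    pds = []
    for rep in range(20):
        y = rng.normal(0.5, 1.0, 50)
        data = pd.DataFrame(
            {"value": y, "treatment": "T0", "mouse": "m0",
             "week": np.tile([0, 2], 25)}
        )
        draws = bayes.gibbs_fit(
            data, bayes.ModelSpec(0, "global", "none"),
            chains=bayes.ChainConfig.smoke_profile(seed=rep),
            sigma2_fixed=1.0,
        )
        pds.append(bayes.dic(draws)[2])
    assert abs(np.mean(pds) - 1.0) < 0.2


def test_dic_prefers_smaller_nested_model():
    rng = np.random.default_rng(23)
    wins = 0
    for rep in range(50):
        data = _toy_data(n=42, seed=1000 + rep, coef=(1.0, 0.0), noise=1.0)
        chains = bayes.ChainConfig.smoke_profile(seed=rep)
        small = bayes.fit_summary(
            bayes.gibbs_fit(data, bayes.ModelSpec(0, "global", "none"), chains=chains)
        )
        large = bayes.fit_summary(
            bayes.gibbs_fit(data, bayes.ModelSpec(1, "global", "global"), chains=chains)
        )
        wins += small.dic <= large.dic
    assert wins >= 40  # >= 80% of replicates


# --------------------------------------------------------------- selection
def test_select_model_tie_breaking_and_errors():
    data = _toy_data(n=36, seed=3)
    chains = bayes.ChainConfig.smoke_profile(seed=1)
    f_small = bayes.fit_summary(
        bayes.gibbs_fit(data, bayes.ModelSpec(0, "global", "none"), chains=chains)
    )
    f_large = bayes.fit_summary(
        bayes.gibbs_fit(data, bayes.ModelSpec(0, "per_treatment", "none"), chains=chains)
    )
    assert bayes.select_model([f_small]) is f_small
    f_large.dic = f_small.dic  # forced tie -> fewer parameters wins
    assert bayes.select_model([f_large, f_small]) is f_small
    f_small.converged = False
    f_large.converged = False
    with pytest.raises(DataError):
        bayes.select_model([f_small, f_large])


def test_selection_recovers_cubic_family():
    """Strong cubic per-treatment/mouse signal: a cubic model wins the DIC
    comparison in >= 70% of replicates at reduced chain settings."""
    weeks = [0, 2, 4, 6, 8, 10]
    chains_cfg = dict(n_chains=2, n_iter=1200, burn_in=400, thin=2)
    wins = 0
    n_rep = 25
    for rep in range(n_rep):
        rng = np.random.default_rng(500 + rep)
        rows = []
        for ti, t in enumerate(["A", "B", "C"]):
            coef = np.array([1.0, 2.0, 1.0, 1.5]) * (1 + 0.5 * ti)
            for mi in range(4):
                b = rng.normal(0, 0.3)
                for w in weeks:
                    x = (w - 5) / 5
                    mu = coef @ np.array([1, x, x**2, x**3]) + b
                    rows.append((mu + rng.normal(0, 0.3), t, f"{t}.m{mi}", w))
        data = pd.DataFrame(rows, columns=["value", "treatment", "mouse", "week"])
        fits = [
            bayes.fit_summary(
                bayes.gibbs_fit(data, spec,
                                chains=bayes.ChainConfig(seed=rep, **chains_cfg))
            )
            for spec in bayes.enumerate_models()
        ]
        best = bayes.select_model(fits)
        wins += best.model.degree == 3
    assert wins >= int(0.7 * n_rep)


# --------------------------------------------------------- credibility CIs
def test_expected_response_ci_properties():
    data = _toy_data(n=120, seed=5, coef=(3.0, 2.0), noise=0.2)
    draws = bayes.gibbs_fit(
        data, bayes.ModelSpec(1, "per_treatment", "per_treatment"),
        chains=bayes.ChainConfig.smoke_profile(seed=2),
    )
    lo95, med, hi95 = bayes.expected_response_ci(draws, "T0", 6.0, level=0.95)
    lo50, _, hi50 = bayes.expected_response_ci(draws, "T0", 6.0, level=0.50)
    assert lo95 <= lo50 <= med <= hi50 <= hi95
    with pytest.raises(DataError):
        bayes.expected_response_ci(draws, "nope", 6.0)

    # degenerate posterior: all draws identical
    one = draws.draws[0, 0, :]
    draws.draws = np.broadcast_to(one, draws.draws.shape).copy()
    lo, med2, hi = bayes.expected_response_ci(draws, "T0", 6.0)
    assert lo == med2 == hi
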