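"""Hierarchical Bayesian temporal-trend models with DIC selection.

A family of 30 candidate models describes a Gaussian response (an alpha
diversity index, or total / log-transformed antigen-specific IgA) as a
polynomial in time of degree 0-3.  Intercepts are global, per-treatment, or
per-treatment with exchangeable per-mouse deviations; for degree >= 1 the
trend coefficients carry the same three structures.  That grid contains
3 intercept-only models plus 3 degrees x 3 intercept x 3 trend structures,
30 specifications in total.

Week is centered at mid-range and scaled by half-range to [-1, 1] before the
polynomial expansion, which stabilizes cubic fits; fitted curves are
reported back on the week scale by the caller evaluating at scaled weeks.

Fitting is by Gibbs sampling under conjugate Normal / inverse-gamma priors:
all regression coefficients are drawn jointly from their Gaussian full
conditional, then the residual variance and the mouse-level variances from
their inverse-gamma full conditionals, in a fixed scan order.  Models are
compared by the deviance information criterion DIC = Dbar + pD with
pD = Dbar - D(posterior mean); convergence is checked with the
Gelman-Rubin potential scale reduction factor over parallel chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._rng import substream
from .errors import ConfigError, DataError

__all__ = [
    "ModelSpec",
    "Priors",
    "ChainConfig",
    "PosteriorDraws",
    "FitSummary",
    "enumerate_models",
    "design_matrix",
    "gibbs_fit",
    "gelman_rubin",
    "dic",
    "fit_summary",
    "select_model",
    "expected_response_ci",
]

STRUCTURES = ("global", "per_treatment", "per_treatment_and_mouse")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: polynomial degree + intercept/trend structure."""

    degree: int
    intercept: str
    trend: str

    def __post_init__(self):
        if self.degree not in (0, 1, 2, 3):
            raise ConfigError("degree must be in {0, 1, 2, 3}")
        if self.intercept not in STRUCTURES:
            raise ConfigError(f"unknown intercept structure {self.intercept!r}")
        if self.degree == 0 and self.trend != "none":
            raise ConfigError("degree-0 models have no trend structure")
        if self.degree >= 1 and self.trend not in STRUCTURES:
            raise ConfigError("degree >= 1 requires a trend structure")

    def n_parameters(self, n_treatments: int, n_mice: int) -> int:
        """Number of regression coefficients (fixed plus random)."""
        sizes = {"global": 1, "per_treatment": n_treatments,
                 "per_treatment_and_mouse": n_treatments + n_mice}
        p = sizes[self.intercept]
        if self.degree >= 1:
            p += self.degree * sizes[self.trend]
        return p

    def label(self) -> str:
        if self.degree == 0:
            return f"deg0/int={self.intercept}"
        return f"deg{self.degree}/int={self.intercept}/trend={self.trend}"


def enumerate_models() -> list[ModelSpec]:
    """The 30-model grid used for model comparison."""
    specs = [ModelSpec(0, s, "none") for s in STRUCTURES]
    for degree in (1, 2, 3):
        for intercept in STRUCTURES:
            for trend in STRUCTURES:
                specs.append(ModelSpec(degree, intercept, trend))
    return specs


@dataclass
class Priors:
    """Weakly-informative conjugate priors.

    Coefficients are N(0, tau2_scale * var(y)); the residual and mouse-level
    variances carry inverse-gamma(shape, rate) priors.
    """

    tau2_scale: float = 1e4
    ig_shape: float = 1e-3
    ig_rate: float = 1e-3

    def validate(self):
        if min(self.tau2_scale, self.ig_shape, self.ig_rate) <= 0:
            raise ConfigError("all prior hyperparameters must be strictly positive")


@dataclass
class ChainConfig:
    """MCMC schedule.  The default reproduces 3 chains of 500,000 iterations
    with 200,000 burn-in and thinning at 500, i.e. 600 retained draws per
    chain and 1,800 in total."""

    n_chains: int = 3
    n_iter: int = 500_000
    burn_in: int = 200_000
    thin: int = 500
    seed: int = 0

    def validate(self):
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ConfigError("thin and n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def retained_total(self) -> int:
        return self.retained_per_chain * self.n_chains

    @classmethod
    def full_profile(cls, seed: int = 0) -> "ChainConfig":
        return cls(seed=seed)

    @classmethod
    def test_profile(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_chains=3, n_iter=20_000, burn_in=8_000, thin=20, seed=seed)

    @classmethod
    def smoke_profile(cls, seed: int = 0) -> "ChainConfig":
        return cls(n_chains=2, n_iter=2_000, burn_in=800, thin=4, seed=seed)


def design_matrix(weeks: Sequence[float], degree: int) -> np.ndarray:
    """Powers 0..degree of centered-and-scaled week.

    Week is mapped to (week - mid-range) / half-range; the matrix has full
    column rank whenever there are at least degree+1 distinct weeks.
    """
    if degree not in (0, 1, 2, 3):
        raise ConfigError("degree must be in {0, 1, 2, 3}")
    w = np.asarray(weeks, dtype=float)
    distinct = np.unique(w)
    if len(distinct) < degree + 1:
        raise DataError(
            f"need at least {degree + 1} distinct weeks for degree {degree}, got {len(distinct)}"
        )
    lo, hi = distinct.min(), distinct.max()
    half = (hi - lo) / 2.0 if hi > lo else 1.0
    x = (w - (lo + hi) / 2.0) / half
    return np.vander(x, degree + 1, increasing=True)


# ----------------------------------------------------------------------
# design construction

@dataclass
class _Design:
    Z: np.ndarray
    codes: np.ndarray  # 0 fixed, 1 mouse intercept, 2 mouse trend
    names: list
    treatments: list
    mice: list
    week_mid: float
    week_half: float


def _build_design(data: pd.DataFrame, model: ModelSpec) -> _Design:
    for col in ("value", "treatment", "mouse", "week"):
        if col not in data.columns:
            raise DataError(f"outcome table lacks required column {col!r}")
    treatments = sorted(data["treatment"].unique())
    mice = sorted(data["mouse"].unique())
    w = data["week"].to_numpy(dtype=float)
    distinct = np.unique(w)
    if len(distinct) < model.degree + 1:
        raise DataError(
            f"model {model.label()} needs {model.degree + 1} distinct weeks, got {len(distinct)}"
        )
    lo, hi = distinct.min(), distinct.max()
    half = (hi - lo) / 2.0 if hi > lo else 1.0
    mid = (lo + hi) / 2.0
    x = (w - mid) / half

    n = len(data)
    t_idx = pd.Categorical(data["treatment"], categories=treatments).codes
    m_idx = pd.Categorical(data["mouse"], categories=mice).codes
    cols, codes, names = [], [], []

    def add(col, code, name):
        cols.append(col)
        codes.append(code)
        names.append(name)

    if model.intercept == "global":
        add(np.ones(n), 0, "intercept")
    else:
        for j, t in enumerate(treatments):
            add((t_idx == j).astype(float), 0, f"intercept[{t}]")
        if model.intercept == "per_treatment_and_mouse":
            for j, m in enumerate(mice):
                add((m_idx == j).astype(float), 1, f"u_int[{m}]")

    for p in range(1, model.degree + 1):
        xp = x**p
        if model.trend == "global":
            add(xp, 0, f"beta{p}")
        elif model.trend in ("per_treatment", "per_treatment_and_mouse"):
            for j, t in enumerate(treatments):
                add(xp * (t_idx == j), 0, f"beta{p}[{t}]")
        if model.trend == "per_treatment_and_mouse":
            for j, m in enumerate(mice):
                add(xp * (m_idx == j), 2, f"u{p}[{m}]")

    Z = np.column_stack(cols)
    codes = np.asarray(codes, dtype=np.int64)
    fixed = Z[:, codes == 0]
    if np.linalg.matrix_rank(fixed) < fixed.shape[1]:
        raise DataError(f"rank-deficient design for model {model.label()}")
    return _Design(Z, codes, names, treatments, mice, mid, half)


# ----------------------------------------------------------------------
# Gibbs kernel

@njit(cache=False)
def _chol_solve(L, b):
    p = L.shape[0]
    w = np.empty(p)
    for i in range(p):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * w[j]
        w[i] = s / L[i, i]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = w[i]
        for j in range(i + 1, p):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def _upper_solve(L, z):
    # solve L.T x = z
    p = L.shape[0]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, p):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def _gibbs_chain(
    ZtZ, Zty, yty, n, codes, tau2, a0, b0,
    n_iter, burn_in, thin, seed, sigma2_init, sample_sigma, sigma2_fixed,
):
    """One chain; returns retained draws of (coefficients, sigma2, s2a, s2b)."""
    np.random.seed(seed)
    p = ZtZ.shape[0]
    n_ret = (n_iter - burn_in) // thin
    out = np.empty((n_ret, p + 3))

    theta = np.zeros(p)
    sigma2 = sigma2_init
    s2a = sigma2_init
    s2b = sigma2_init
    qa = 0
    qb = 0
    for j in range(p):
        if codes[j] == 1:
            qa += 1
        elif codes[j] == 2:
            qb += 1

    Q = np.empty((p, p))
    r = 0
    for it in range(1, n_iter + 1):
        # --- coefficients | variances: joint Gaussian full conditional
        for i in range(p):
            for j in range(p):
                Q[i, j] = ZtZ[i, j] / sigma2
        for j in range(p):
            if codes[j] == 0:
                Q[j, j] += 1.0 / tau2
            elif codes[j] == 1:
                Q[j, j] += 1.0 / s2a
            else:
                Q[j, j] += 1.0 / s2b
        L = np.linalg.cholesky(Q)
        mu = _chol_solve(L, Zty / sigma2)
        z = np.random.standard_normal(p)
        theta = mu + _upper_solve(L, z)

        # --- residual variance
        ssr = yty - 2.0 * np.dot(theta, Zty) + np.dot(theta, np.dot(ZtZ, theta))
        if ssr < 0.0:
            ssr = 0.0
        if sample_sigma:
            sigma2 = (b0 + ssr / 2.0) / np.random.gamma(a0 + n / 2.0, 1.0)
        else:
            sigma2 = sigma2_fixed

        # --- mouse-level variances
        if qa > 0:
            ssa = 0.0
            for j in range(p):
                if codes[j] == 1:
                    ssa += theta[j] * theta[j]
            s2a = (b0 + ssa / 2.0) / np.random.gamma(a0 + qa / 2.0, 1.0)
        if qb > 0:
            ssb = 0.0
            for j in range(p):
                if codes[j] == 2:
                    ssb += theta[j] * theta[j]
            s2b = (b0 + ssb / 2.0) / np.random.gamma(a0 + qb / 2.0, 1.0)

        if it > burn_in and (it - burn_in) % thin == 0:
            out[r, :p] = theta
            out[r, p] = sigma2
            out[r, p + 1] = s2a if qa > 0 else np.nan
            out[r, p + 2] = s2b if qb > 0 else np.nan
            r += 1
    return out


@dataclass
class PosteriorDraws:
    """Retained draws, per chain and per parameter."""

    draws: np.ndarray  # chains x retained x (p + 3)
    names: list  # coefficient names + variance names
    codes: np.ndarray
    model: ModelSpec
    treatments: list
    mice: list
    week_mid: float
    week_half: float
    y: np.ndarray
    Z: np.ndarray
    chains: ChainConfig
    sample_sigma: bool = True

    @property
    def n_coef(self) -> int:
        return self.Z.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, stacked over chains."""
        j = self.names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])


def gibbs_fit(
    data: pd.DataFrame,
    model: ModelSpec,
    priors: Priors | None = None,
    chains: ChainConfig | None = None,
    sigma2_fixed: float | None = None,
) -> PosteriorDraws:
    """Fit one model by Gibbs sampling.

    ``data`` needs columns value/treatment/mouse/week.  With ``sigma2_fixed``
    the residual variance is held at the given value instead of sampled
    (used for conjugate checks).  Same seed, same data => identical draws.
    """
    priors = priors or Priors()
    chains = chains or ChainConfig()
    priors.validate()
    chains.validate()
    design = _build_design(data, model)
    y = data["value"].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise DataError("response contains non-finite values")
    Z = design.Z
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)
    var_y = float(np.var(y)) or 1.0
    tau2 = priors.tau2_scale * var_y

    seeds = substream(chains.seed, "gibbs").integers(0, 2**31 - 1, size=chains.n_chains)
    inits = var_y * (2.0 ** np.arange(chains.n_chains) / 2.0 ** (chains.n_chains // 2))
    all_draws = []
    for c in range(chains.n_chains):
        draws = _gibbs_chain(
            ZtZ, Zty, yty, len(y), design.codes, tau2,
            priors.ig_shape, priors.ig_rate,
            chains.n_iter, chains.burn_in, chains.thin,
            int(seeds[c]),
            float(inits[c]) if sigma2_fixed is None else float(sigma2_fixed),
            sigma2_fixed is None,
            0.0 if sigma2_fixed is None else float(sigma2_fixed),
        )
        all_draws.append(draws)
    names = design.names + ["sigma2", "sigma2_mouse_intercept", "sigma2_mouse_trend"]
    return PosteriorDraws(
        draws=np.stack(all_draws),
        names=names,
        codes=design.codes,
        model=model,
        treatments=design.treatments,
        mice=design.mice,
        week_mid=design.week_mid,
        week_half=design.week_half,
        y=y,
        Z=Z,
        chains=chains,
        sample_sigma=sigma2_fixed is None,
    )


# ----------------------------------------------------------------------
def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Potential scale reduction factor per parameter.

    R-hat = sqrt(((m-1)/m W + B/m) / W) with W the mean within-chain
    variance, B the between-chain variance of chain means times the number
    of draws per chain m.  Parameters with zero within-chain variance are
    flagged NaN (undefined).
    """
    arr = draws.draws
    n_chains, m, _ = arr.shape
    if n_chains < 2:
        raise DataError("Gelman-Rubin requires at least two chains")
    if m < 10:
        raise DataError("Gelman-Rubin requires at least 10 draws per chain")
    active = [j for j, name in enumerate(draws.names) if not np.isnan(arr[:, :, j]).all()]
    out = {}
    for j in active:
        x = arr[:, :, j]
        w = x.var(axis=1, ddof=1).mean()
        b = m * x.mean(axis=1).var(ddof=1)
        if w == 0:
            out[draws.names[j]] = math.sqrt((m - 1) / m) if b == 0 else np.nan
        else:
            out[draws.names[j]] = math.sqrt(((m - 1) / m * w + b / m) / w)
    return pd.Series(out)


def _deviance(theta: np.ndarray, sigma2: float, y, Z, ZtZ, Zty, yty) -> float:
    n = len(y)
    ssr = yty - 2.0 * float(theta @ Zty) + float(theta @ ZtZ @ theta)
    ssr = max(ssr, 0.0)
    return n * math.log(2.0 * math.pi * sigma2) + ssr / sigma2


def dic(draws: PosteriorDraws) -> tuple[float, float, float, float]:
    """(Dbar, D_at_mean, pD, DIC) under the Gaussian likelihood.

    Dbar averages the deviance -2 log L over all retained draws; D_at_mean
    evaluates it at the posterior-mean parameters; pD = Dbar - D_at_mean and
    DIC = Dbar + pD.
    """
    flat = draws.flat()
    p = draws.n_coef
    theta = flat[:, :p]
    sigma2 = flat[:, p]
    y, Z = draws.y, draws.Z
    n = len(y)
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)
    ssr = (
        yty
        - 2.0 * theta @ Zty
        + np.einsum("ij,jk,ik->i", theta, ZtZ, theta)
    )
    ssr = np.clip(ssr, 0.0, None)
    if not np.isfinite(sigma2).all() or (sigma2 <= 0).any():
        raise DataError("non-finite likelihood: invalid variance draws")
    devs = n * np.log(2.0 * math.pi * sigma2) + ssr / sigma2
    dbar = float(devs.mean())
    d_at_mean = _deviance(theta.mean(axis=0), float(sigma2.mean()), y, Z, ZtZ, Zty, yty)
    pd_eff = dbar - d_at_mean
    return dbar, d_at_mean, pd_eff, dbar + pd_eff


@dataclass
class FitSummary:
    """Model-comparison record for one fitted model."""

    model: ModelSpec
    dbar: float
    d_at_mean: float
    p_d: float
    dic: float
    rhat: pd.Series
    n_parameters: int
    converged: bool
    draws: PosteriorDraws | None = field(default=None, repr=False)


def fit_summary(draws: PosteriorDraws, rhat_threshold: float = 1.1) -> FitSummary:
    dbar, d_at_mean, p_d, dic_val = dic(draws)
    rhat = gelman_rubin(draws)
    finite = rhat.dropna()
    converged = bool((finite <= rhat_threshold).all())
    return FitSummary(
        model=draws.model,
        dbar=dbar,
        d_at_mean=d_at_mean,
        p_d=p_d,
        dic=dic_val,
        rhat=rhat,
        n_parameters=draws.model.n_parameters(len(draws.treatments), len(draws.mice)),
        converged=converged,
        draws=draws,
    )


def select_model(fits: Sequence[FitSummary]) -> FitSummary:
    """Minimum-DIC model among converged fits.

    Ties are broken by fewer parameters, then by input (enumeration) order.
    Raises if every fit failed convergence, listing the diagnostics.
    """
    if not fits:
        raise DataError("no fits to select from")
    converged = [f for f in fits if f.converged]
    if not converged:
        diag = "; ".join(
            f"{f.model.label()}: max R-hat = {f.rhat.dropna().max():.3f}" for f in fits
        )
        raise DataError(f"no converged fits ({diag})")
    order = {id(f): i for i, f in enumerate(fits)}
    return min(converged, key=lambda f: (f.dic, f.n_parameters, order[id(f)]))


def expected_response_ci(
    draws: PosteriorDraws,
    treatment: str,
    week: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Equal-tailed credibility interval of the expected response.

    The expected response at (treatment, week) is computed per retained draw
    from that draw's coefficients, with mouse effects marginalized at their
    mean of zero.  Returns (lower, median, upper).
    """
    if treatment not in draws.treatments and draws.model.intercept != "global":
        raise DataError(f"unknown treatment {treatment!r}")
    if not (0 <= level < 1):
        raise ConfigError("level must lie in [0, 1)")
    x = (week - draws.week_mid) / draws.week_half
    flat = draws.flat()
    mu = np.zeros(flat.shape[0])

    def col(name):
        return flat[:, draws.names.index(name)]

    if draws.model.intercept == "global":
        mu += col("intercept")
    else:
        mu += col(f"intercept[{treatment}]")
    for p in range(1, draws.model.degree + 1):
        if draws.model.trend == "global":
            mu += col(f"beta{p}") * x**p
        else:
            mu += col(f"beta{p}[{treatment}]") * x**p
    lo, med, hi = np.quantile(mu, [(1 - level) / 2, 0.5, (1 + level) / 2])
    return float(lo), float(med), float(hi)
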