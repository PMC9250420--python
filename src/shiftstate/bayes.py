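"""Bayesian skew-normal modelling of per-nucleus chemical-shift ensembles.

Each (nucleus, state, prediction-method) ensemble of predicted shifts is
modelled independently with a skew-normal likelihood

    L(d | mu, sigma, alpha) = (2/sigma) * phi(z) * Phi(alpha * z),   z = (d - mu)/sigma,

where phi and Phi are the standard normal pdf and cdf.  Priors are weakly
informative: mu ~ Normal(mean(d), 10 ppm), sigma ~ HalfCauchy(beta=10 ppm),
alpha ~ Normal(0, 10).  The quantity ascribed to the NMR peak position is the
*distribution mean*

    mean = mu + sigma * sqrt(2/pi) * alpha / sqrt(1 + alpha^2),

a posterior-distributed quantity summarised by its 94% highest-density
interval; the distribution variance is

    var = sigma^2 * (1 - (2/pi) * alpha^2 / (1 + alpha^2)).

The posterior is sampled with a seeded adaptive random-walk Metropolis
sampler (four chains, joint proposal over (mu, log sigma, alpha) with
covariance adaptation during warmup).  Sampling is performed on mean-centred
data, which makes the fit translation-equivariant: adding a constant to every
data point shifts the location draws by that constant and leaves scale and
skewness draws unchanged — the property that makes difference shifts immune
to referencing offsets downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy import stats
from scipy.special import log_ndtr

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)
_NORM_CONST = -0.5 * np.log(2.0 * np.pi)
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


# ---------------------------------------------------------------------------
# density and closed-form moments


@dataclass(frozen=True)
class SkewNormalParams:
    """Location mu (ppm), scale sigma (ppm, > 0) and skewness alpha."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")

    @property
    def mean(self) -> float:
        return float(skewnorm_mean(self.mu, self.sigma, self.alpha))

    @property
    def variance(self) -> float:
        return float(skewnorm_variance(self.sigma, self.alpha))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return stats.skewnorm.rvs(
            a=self.alpha, loc=self.mu, scale=self.sigma, size=size, random_state=rng
        )


def skewnormal_logdensity(d, params: SkewNormalParams | None = None, *,
                          mu: float | None = None, sigma: float | None = None,
                          alpha: float | None = None):
    """Log of the skew-normal density, vectorised over ``d``.

    Accepts either a :class:`SkewNormalParams` or explicit keyword parameters.
    """
    if params is not None:
        mu, sigma, alpha = params.mu, params.sigma, params.alpha
    if sigma is None or sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    d = np.asarray(d, dtype=float)
    z = (d - mu) / sigma
    return _LOG2 - np.log(sigma) + _NORM_CONST - 0.5 * z * z + log_ndtr(alpha * z)


def skewnorm_mean(mu, sigma, alpha):
    """Distribution mean: mu + sigma*sqrt(2/pi)*alpha/sqrt(1+alpha^2)."""
    alpha = np.asarray(alpha, dtype=float)
    delta = alpha / np.sqrt(1.0 + alpha * alpha)
    return mu + sigma * _SQRT_2_OVER_PI * delta


def skewnorm_variance(sigma, alpha):
    """Distribution variance: sigma^2 * (1 - (2/pi)*alpha^2/(1+alpha^2))."""
    alpha = np.asarray(alpha, dtype=float)
    delta2 = alpha * alpha / (1.0 + alpha * alpha)
    return sigma * sigma * (1.0 - (2.0 / np.pi) * delta2)


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters: mu ~ N(mu_loc, mu_scale), sigma ~ HalfCauchy(sigma_beta),
    alpha ~ N(0, alpha_scale).  mu_loc is centred on the sample mean of the data."""

    mu_loc: float
    mu_scale: float = 10.0
    sigma_beta: float = 10.0
    alpha_scale: float = 10.0


def build_priors(data) -> PriorSpec:
    """Priors for one ensemble: the mu prior is centred on the data average."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot build priors from empty data")
    return PriorSpec(mu_loc=float(np.mean(data)))


# ---------------------------------------------------------------------------
# posterior container and credible intervals


@dataclass(frozen=True)
class CredibleInterval:
    """An interval holding ``mass`` posterior probability, reported as its
    centre (interval midpoint) plus/minus the distance to the bounds."""

    lower: float
    upper: float
    center: float
    mass: float

    def __post_init__(self) -> None:
        if not self.lower <= self.center <= self.upper:
            raise ValueError("require lower <= center <= upper")
        if not 0 < self.mass < 1:
            raise ValueError("mass must lie in (0, 1)")

    @property
    def half_width(self) -> float:
        return 0.5 * (self.upper - self.lower)

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def credible_interval(draws, mass: float = 0.94, kind: str = "hdi") -> CredibleInterval:
    """Credible interval of posterior draws.

    ``kind="hdi"`` (default) gives the highest-density interval — the
    shortest interval holding ``mass`` probability; ``kind="eti"`` gives the
    equal-tailed quantile interval.  The centre is the interval midpoint.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    if np.ptp(draws) == 0:
        c = float(draws[0])
        return CredibleInterval(c, c, c, mass)
    if kind == "hdi":
        lo, hi = az.hdi(draws, hdi_prob=mass)
    elif kind == "eti":
        tail = 0.5 * (1.0 - mass)
        lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    else:
        raise ValueError(f"unknown interval kind {kind!r}")
    lo, hi = float(lo), float(hi)
    return CredibleInterval(lo, hi, 0.5 * (lo + hi), mass)


@dataclass
class PosteriorDraws:
    """Posterior samples of (mu, sigma, alpha) for one ensemble.

    Arrays have shape (n_chains, n_draws); flattened views concatenate the
    chains.  ``diagnostics`` holds split-Rhat and bulk ESS per parameter.
    """

    mu: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray
    seed: int
    config: "SamplerConfig"
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    key: object = None
    state: str | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if not (self.mu.shape == self.sigma.shape == self.alpha.shape):
            raise ValueError("draw arrays must share shape")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma draws must be positive")

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def mu_draws(self) -> np.ndarray:
        return self.mu.ravel()

    @property
    def sigma_draws(self) -> np.ndarray:
        return self.sigma.ravel()

    @property
    def alpha_draws(self) -> np.ndarray:
        return self.alpha.ravel()


def mean_draws(post: PosteriorDraws) -> np.ndarray:
    """Posterior draws of the distribution mean (the simulated peak position)."""
    return skewnorm_mean(post.mu_draws, post.sigma_draws, post.alpha_draws)


def variance_draws(post: PosteriorDraws) -> np.ndarray:
    """Posterior draws of the distribution variance."""
    return skewnorm_variance(post.sigma_draws, post.alpha_draws)


# ---------------------------------------------------------------------------
# sampler


@dataclass(frozen=True)
class SamplerConfig:
    """Random-walk Metropolis settings: 4 chains by default, 1000 warmup
    iterations (scale + covariance adaptation) then 1000 retained draws per
    chain, targeting ~30% acceptance (near-optimal for a 3-d RWM)."""

    n_chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.3
    thin: int = 4
    rhat_warn: float = 1.01
    ess_warn: float = 400.0


def _moment_init(data_c: np.ndarray) -> np.ndarray:
    """Method-of-moments starting point (mu_c, log sigma, alpha) on centred data."""
    s = float(np.std(data_c))
    g1 = float(stats.skew(data_c))
    # invert the skewness formula for delta, capping inside the valid range
    b = (4.0 - np.pi) / 2.0
    c = abs(g1) ** (2.0 / 3.0)
    delta2 = (np.pi / 2.0) * c / (c + b ** (2.0 / 3.0))
    delta = np.sign(g1) * np.sqrt(min(delta2, 0.995**2))
    alpha0 = delta / np.sqrt(1.0 - delta * delta)
    var_factor = 1.0 - 2.0 * delta * delta / np.pi
    sigma0 = s / np.sqrt(max(var_factor, 1e-3))
    mu0 = -sigma0 * delta * _SQRT_2_OVER_PI  # centred data have mean ~0
    return np.array([mu0, np.log(sigma0), alpha0])


def _log_posterior(theta: np.ndarray, data_c: np.ndarray, prior: PriorSpec,
                   prior_mu_loc_c: float) -> np.ndarray:
    """Unnormalised log posterior for each chain row of ``theta`` (C, 3)."""
    muc = theta[:, 0]
    logs = theta[:, 1]
    alpha = theta[:, 2]
    sigma = np.exp(logs)
    z = (data_c[None, :] - muc[:, None]) / sigma[:, None]
    ll = np.sum(
        _LOG2 - logs[:, None] + _NORM_CONST - 0.5 * z * z + log_ndtr(alpha[:, None] * z),
        axis=1,
    )
    lp = -0.5 * ((muc - prior_mu_loc_c) / prior.mu_scale) ** 2
    # half-Cauchy on sigma plus the log-sigma Jacobian
    lp += -np.log1p((sigma / prior.sigma_beta) ** 2) + logs
    lp += -0.5 * (alpha / prior.alpha_scale) ** 2
    return ll + lp


def fit_posterior(
    samples,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    *,
    key=None,
    state: str | None = None,
    method: str | None = None,
) -> PosteriorDraws:
    """Fit the skew-normal model to one ensemble of predicted shifts.

    Requires at least 10 data points (below that the posterior geometry is
    degenerate) and non-constant data.  Diagnostics (split-Rhat, bulk ESS) are
    always computed; a warning string is attached when Rhat exceeds 1.01 or
    the effective sample size falls below 400.  Fully reproducible for a
    fixed seed.
    """
    data = np.asarray(samples, dtype=float).ravel()
    if data.size < 10:
        raise ValueError(f"need >= 10 data points to fit, got {data.size}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    if np.ptp(data) == 0.0:
        raise ValueError("constant data: skew-normal scale is degenerate (sigma -> 0)")
    cfg = config or SamplerConfig()
    prior = priors or build_priors(data)

    # centre the data; sampling happens in (mu - dbar, log sigma, alpha)
    dbar = float(np.mean(data))
    data_c = data - dbar
    prior_mu_loc_c = prior.mu_loc - dbar

    rng = np.random.default_rng(cfg.seed)
    C = cfg.n_chains
    x0 = _moment_init(data_c)
    jitter_scale = np.array([np.std(data_c) / np.sqrt(data.size) + 1e-12, 0.05, 0.2])
    x = x0[None, :] + rng.normal(size=(C, 3)) * jitter_scale[None, :]

    # initial diagonal proposal, adapted during warmup
    n = data.size
    base = np.array([3.0 * np.std(data_c) / np.sqrt(n), 3.0 / np.sqrt(n), 30.0 / np.sqrt(n)])
    L = np.diag(base)
    log_step = np.zeros(C)

    lp = _log_posterior(x, data_c, prior, prior_mu_loc_c)
    warm_hist = np.empty((C, cfg.warmup, 3))
    out = np.empty((C, cfg.draws, 3))
    accept_count = 0

    total = cfg.warmup + cfg.draws
    for t in range(total):
        # several Metropolis updates per retained draw (internal thinning)
        n_inner = 1 if t < cfg.warmup else max(1, cfg.thin)
        for _ in range(n_inner):
            step = np.exp(log_step)[:, None]
            prop = x + step * (rng.standard_normal(size=(C, 3)) @ L.T)
            lp_prop = _log_posterior(prop, data_c, prior, prior_mu_loc_c)
            log_u = np.log(rng.uniform(size=C))
            acc = log_u < (lp_prop - lp)
            x = np.where(acc[:, None], prop, x)
            lp = np.where(acc, lp_prop, lp)

        if t < cfg.warmup:
            warm_hist[:, t, :] = x
            # Robbins-Monro scale adaptation toward the target acceptance rate
            gamma = (t + 1) ** -0.6
            log_step += gamma * (acc.astype(float) - cfg.target_accept)
            # covariance adaptation from the pooled recent warmup history;
            # never in the last quarter of warmup, so the scalar step always
            # has time to re-equilibrate before draws are retained
            if (t + 1) % 100 == 0 and 200 <= t + 1 <= 3 * cfg.warmup // 4:
                lo = (t + 1) // 2
                pooled = warm_hist[:, lo : t + 1, :].reshape(-1, 3)
                cov = np.cov(pooled, rowvar=False)
                cov = (2.38**2 / 3.0) * cov + 1e-12 * np.eye(3)
                try:
                    L = np.linalg.cholesky(cov)
                    log_step[:] = 0.0  # L already carries the optimal scaling
                except np.linalg.LinAlgError:
                    pass
        else:
            out[:, t - cfg.warmup, :] = x
            accept_count += int(acc.sum())

    mu = out[:, :, 0] + dbar
    sigma = np.exp(out[:, :, 1])
    alpha = out[:, :, 2]

    diagnostics = {}
    warns: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in (("mu", mu), ("sigma", sigma), ("alpha", alpha)):
            diagnostics[f"rhat_{name}"] = float(az.rhat(arr))
            diagnostics[f"ess_{name}"] = float(az.ess(arr))
    diagnostics["accept_rate"] = accept_count / (C * cfg.draws)
    max_rhat = max(diagnostics[f"rhat_{p}"] for p in ("mu", "sigma", "alpha"))
    min_ess = min(diagnostics[f"ess_{p}"] for p in ("mu", "sigma", "alpha"))
    if max_rhat > cfg.rhat_warn:
        warns.append(f"convergence: max Rhat {max_rhat:.4f} > {cfg.rhat_warn}")
    if min_ess < cfg.ess_warn:
        warns.append(f"convergence: min ESS {min_ess:.0f} < {cfg.ess_warn:.0f}")
    if warns:
        logger.debug("fit %s/%s/%s: %s", key, state, method, "; ".join(warns))

    return PosteriorDraws(
        mu=mu, sigma=sigma, alpha=alpha, seed=cfg.seed, config=cfg,
        diagnostics=diagnostics, warnings=warns, key=key, state=state, method=method,
    )


def fit_mle_bootstrap(
    samples,
    n_boot: int = 500,
    seed: int = 0,
    *,
    key=None,
    state: str | None = None,
    method: str | None = None,
) -> PosteriorDraws:
    """Deterministic non-Bayesian fallback: maximum-likelihood fit plus a
    parametric bootstrap of the parameter estimates.

    Returned in the :class:`PosteriorDraws` container for interface parity,
    but these are bootstrap replicates, not posterior draws — the canonical
    route is :func:`fit_posterior`.  Intended for quick smoke runs.
    """
    data = np.asarray(samples, dtype=float).ravel()
    if data.size < 10:
        raise ValueError(f"need >= 10 data points to fit, got {data.size}")
    a0, loc0, scale0 = stats.skewnorm.fit(data)
    rng = np.random.default_rng(seed)
    reps = np.empty((1, n_boot, 3))
    for i in range(n_boot):
        rep = stats.skewnorm.rvs(a=a0, loc=loc0, scale=scale0, size=data.size, random_state=rng)
        a, loc, scale = stats.skewnorm.fit(rep, a0, loc=loc0, scale=scale0)
        reps[0, i] = (loc, scale, a)
    cfg = SamplerConfig(n_chains=1, draws=n_boot, warmup=0, seed=seed)
    return PosteriorDraws(
        mu=reps[:, :, 0], sigma=np.maximum(reps[:, :, 1], 1e-12), alpha=reps[:, :, 2],
        seed=seed, config=cfg, diagnostics={"mle": True},
        warnings=["non-canonical MLE/bootstrap fit"], key=key, state=state, method=method,
    )


# ---------------------------------------------------------------------------
# posterior predictive check


@dataclass(frozen=True)
class PPCSummary:
    """Pointwise posterior-predictive envelope over a shift grid.

    ``coverage`` is the fraction of empirical histogram bins whose density
    falls inside the 94% envelope of replicated densities.
    """

    bin_edges: np.ndarray
    empirical: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    coverage: float


def posterior_predictive_check(
    post: PosteriorDraws,
    data,
    n_replicates: int = 200,
    n_bins: int = 30,
    mass: float = 0.94,
    seed: int = 0,
) -> PPCSummary:
    """Simulate replicate datasets from the posterior and compare histograms.

    For each of ``n_replicates`` posterior draws a replicate dataset of the
    observed size is simulated; per-bin density quantiles give a pointwise
    94% envelope, against which the empirical histogram is scored.
    """
    data = np.asarray(data, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    mu, sg, al = post.mu_draws, post.sigma_draws, post.alpha_draws
    idx = rng.choice(mu.size, size=min(n_replicates, mu.size), replace=False)

    pad = 0.1 * np.ptp(data) + 1e-6
    edges = np.linspace(data.min() - pad, data.max() + pad, n_bins + 1)
    emp, _ = np.histogram(data, bins=edges, density=True)

    rep_densities = np.empty((idx.size, n_bins))
    for i, j in enumerate(idx):
        rep = stats.skewnorm.rvs(a=al[j], loc=mu[j], scale=sg[j], size=data.size,
                                 random_state=rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            dens, _ = np.histogram(rep, bins=edges, density=True)
        rep_densities[i] = np.nan_to_num(dens)  # replicate may miss the grid entirely
    tail = 0.5 * (1.0 - mass)
    lo = np.quantile(rep_densities, tail, axis=0)
    hi = np.quantile(rep_densities, 1.0 - tail, axis=0)
    inside = (emp >= lo) & (emp <= hi)
    return PPCSummary(edges, emp, lo, hi, float(inside.mean()))
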