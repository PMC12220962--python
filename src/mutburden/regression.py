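"""Weighted heteroscedastic Bayesian regression of mutation burden.

The model behind every "increase of X in mutation burden (95%CI ...)"
statement: per-sample burden estimates ``y_i`` (mutations per duplex base)
are regressed on age and exposure group with additive terms and no
interaction,

    y_i ~ Normal(alpha + beta_age * age_i + delta * 1[exposed_i],
                 sqrt(se_i^2 + sigma_{group(i)}^2))

where ``se_i`` is the known per-sample standard error derived from the exact
Poisson confidence interval (measurement-error weighting, analogous to a
random-effects meta-analysis) and ``sigma_group`` is a per-group residual SD
capturing the extra between-sample variability of the exposed group.

Priors follow the distributional-regression convention: Student-t(3) on the
intercept (data-located by default), flat on the age and group coefficients,
Student-t(3, 0, 2.5) on each log residual SD. Sampling is per-parameter
adaptive random-walk Metropolis over multiple independent chains;
convergence is assessed with split-R-hat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PARAM_NAMES = ("alpha", "beta_age", "delta", "sigma_control", "sigma_exposed")


@dataclass
class RegressionSpec:
    """Sampler and prior settings for :func:`fit_group_effect`.

    ``response_scale`` rescales rates internally (default: per-gigabase,
    i.e. y * 1e9) for conditioning; all reported quantities are transformed
    back to the per-base scale.
    """

    response_scale: float = 1e9
    intercept_prior_df: float = 3.0
    intercept_prior_loc: float | None = None  # default: median(y) on the rescaled axis
    intercept_prior_scale: float | None = None  # default: max(1.4826*MAD(y), 2.5)
    log_sigma_prior_scale: float = 2.5
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    rhat_threshold: float = 1.05
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")
        if not self.warmup < self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if not self.rhat_threshold > 1.0:
            raise ValueError("rhat_threshold must exceed 1")


@dataclass
class ParameterSummary:
    mean: float
    q2_5: float
    q97_5: float
    rhat: float


@dataclass
class PosteriorSummary:
    """Posterior means, 95% credible bounds and split-R-hat per parameter."""

    parameters: dict[str, ParameterSummary]
    n_posterior_draws: int
    converged: bool
    rhat_threshold: float
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "mean": p.mean,
                    "q2.5": p.q2_5,
                    "q97.5": p.q97_5,
                    "rhat": p.rhat,
                }
                for name, p in self.parameters.items()
            }
        ).T


def split_rhat(draws: np.ndarray) -> float:
    """Split Gelman-Rubin potential scale reduction statistic.

    ``draws`` has shape (chains, n) with post-warmup draws. Each chain is
    split in half (an odd trailing draw is dropped); with W the mean
    within-half-chain variance and B the between-half-chain variance of
    means, R-hat = sqrt(((n-1)/n * W + B/n) / W).

    Degenerate cases: identical constants everywhere return 1.0 (zero total
    variance); separated constant chains (W = 0, B > 0) return +inf.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("split_rhat needs draws of shape (chains >= 2, n)")
    n = draws.shape[1]
    if n < 4:
        raise ValueError("split_rhat needs at least 4 draws per chain")
    half = n // 2
    halves = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m = halves.shape[1]
    W = halves.var(axis=1, ddof=1).mean()
    B = m * halves.mean(axis=1).var(ddof=0) * halves.shape[0] / (halves.shape[0] - 1)
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_hat = (m - 1) / m * W + B / m
    return float(np.sqrt(var_hat / W))


def posterior_summary(
    draws: np.ndarray, probs: tuple[float, float] = (0.025, 0.975)
) -> tuple[float, float, float]:
    """Empirical mean and linear-interpolated percentiles of pooled draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("posterior_summary requires at least one draw")
    lo, hi = np.quantile(draws, probs, method="linear")
    return float(draws.mean()), float(lo), float(hi)


def _student_t_logpdf(x: np.ndarray, df: float, loc: float, scale: float) -> np.ndarray:
    # unnormalized is fine for MCMC, but keep the df-dependent shape exact
    z = (x - loc) / scale
    return -0.5 * (df + 1.0) * np.log1p(z * z / df) - np.log(scale)


@dataclass
class _Model:
    y: np.ndarray
    age: np.ndarray  # centered age covariate
    exposed: np.ndarray  # centered group covariate
    is_exposed: np.ndarray  # boolean mask for the variance term
    se: np.ndarray
    prior_loc: float
    prior_scale: float
    prior_df: float
    log_sigma_scale: float
    sigma_fixed: tuple[float, float] | None = None

    def log_post(self, theta: np.ndarray) -> np.ndarray:
        """theta: (5, C) -> log posterior per chain, flat priors on slopes."""
        alpha, beta, delta, ls_c, ls_e = theta
        mu = (
            alpha[None, :]
            + self.age[:, None] * beta[None, :]
            + self.exposed[:, None] * delta[None, :]
        )
        if self.sigma_fixed is not None:
            s2c = np.full_like(ls_c, self.sigma_fixed[0] ** 2)
            s2e = np.full_like(ls_e, self.sigma_fixed[1] ** 2)
        else:
            s2c = np.exp(2.0 * ls_c)
            s2e = np.exp(2.0 * ls_e)
        sig2 = np.where(self.is_exposed[:, None], s2e[None, :], s2c[None, :])
        v = self.se[:, None] ** 2 + sig2
        resid = self.y[:, None] - mu
        ll = -0.5 * np.sum(np.log(v) + resid * resid / v, axis=0)
        lp = ll + _student_t_logpdf(alpha, self.prior_df, self.prior_loc, self.prior_scale)
        if self.sigma_fixed is None:
            lp = lp + _student_t_logpdf(ls_c, 3.0, 0.0, self.log_sigma_scale)
            lp = lp + _student_t_logpdf(ls_e, 3.0, 0.0, self.log_sigma_scale)
        return lp


def fit_group_effect(
    burdens: pd.DataFrame,
    meta: pd.DataFrame,
    spec: RegressionSpec | None = None,
    sigma_fixed: tuple[float, float] | None = None,
) -> tuple[PosteriorSummary, dict[str, np.ndarray]]:
    """Sample the posterior of the age + group heteroscedastic model.

    Parameters
    ----------
    burdens:
        Table with ``sample_id``, ``rate`` and ``se`` columns (per-base
        scale), as produced by :func:`mutburden.burden.estimate_burden_table`.
    meta:
        Sample metadata with ``sample_id``, ``age`` and ``group`` columns
        (group in {"control", "exposed"}).
    spec:
        Prior/sampler settings; defaults follow the module docstring
        (4 chains x 5,000 iterations, 2,500 warmup => 10,000 kept draws).
    sigma_fixed:
        Optionally pin (sigma_control, sigma_exposed) on the per-base scale
        instead of sampling them — used for the weighted-least-squares limit
        contract and for degenerate designs.

    Returns
    -------
    (summary, draws)
        ``summary`` is a :class:`PosteriorSummary` over
        alpha, beta_age, delta, sigma_control, sigma_exposed (per-base
        scale). ``draws`` maps each parameter name to a (chains, kept)
        array of back-transformed draws.

    Non-convergence (any split-R-hat at or above the threshold) is flagged
    via ``summary.converged`` but summaries are still returned.
    """
    spec = spec or RegressionSpec()
    df = burdens.merge(meta[["sample_id", "age", "group"]], on="sample_id")
    if len(df) != len(burdens):
        raise ValueError("burdens and metadata sample_ids do not match")
    counts = df["group"].value_counts()
    for g in ("control", "exposed"):
        if counts.get(g, 0) < 2:
            raise ValueError(f"need at least 2 samples in group {g!r}")
    if not np.isfinite(df["se"]).all():
        raise ValueError("non-finite standard errors")

    df = df.sort_values("sample_id").reset_index(drop=True)  # canonical order
    scale = spec.response_scale
    y = df["rate"].to_numpy() * scale
    se = df["se"].to_numpy() * scale
    age_raw = df["age"].to_numpy(dtype=float)
    exposed_raw = (df["group"] == "exposed").to_numpy(dtype=float)
    # center predictors so the intercept decorrelates from the slopes; the
    # reported intercept is transformed back to the age-0 / control origin
    age_mean = float(age_raw.mean())
    exp_mean = float(exposed_raw.mean())
    age = age_raw - age_mean
    exposed = exposed_raw - exp_mean

    loc = spec.intercept_prior_loc
    if loc is None:
        loc = float(np.median(y))
    psc = spec.intercept_prior_scale
    if psc is None:
        mad = float(np.median(np.abs(y - np.median(y))))
        psc = max(1.4826 * mad, 2.5)

    model = _Model(
        y=y,
        age=age,
        exposed=exposed,
        is_exposed=exposed_raw == 1.0,
        se=se,
        prior_loc=loc,
        prior_scale=psc,
        prior_df=spec.intercept_prior_df,
        log_sigma_scale=spec.log_sigma_prior_scale,
        sigma_fixed=None
        if sigma_fixed is None
        else (sigma_fixed[0] * scale, sigma_fixed[1] * scale),
    )

    C = spec.chains
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 5)))

    # data-based start: least squares on [1, age, exposed], residual SD per group
    X = np.column_stack([np.ones_like(age), age, exposed])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd_c = max(resid[exposed_raw == 0].std(ddof=1), 0.05)
    sd_e = max(resid[exposed_raw == 1].std(ddof=1), 0.05)
    start = np.array([coef[0], coef[1], coef[2], np.log(sd_c), np.log(sd_e)])
    # coefficient SEs from the least-squares fit set the scale of dispersed
    # initial points and of the random-walk proposals
    resid_var = max(float(resid.var(ddof=1)), float(np.mean(se**2)), 1e-12)
    coef_se = np.sqrt(resid_var * np.diag(np.linalg.inv(X.T @ X)))
    jitter_scale = np.array([coef_se[0], coef_se[1], coef_se[2], 0.5, 0.5])
    theta = start[:, None] + rng.normal(size=(5, C)) * jitter_scale[:, None] * 2.0

    lp = model.log_post(theta)
    prop_scale = np.tile(
        np.array([coef_se[0], coef_se[1], coef_se[2], 0.3, 0.3])[:, None] * 2.4,
        (1, C),
    )
    kept_n = spec.iterations - spec.warmup
    kept = np.empty((C, kept_n, 5))
    acc = np.zeros((5, C))
    window = 0
    active = [0, 1, 2] if sigma_fixed is not None else [0, 1, 2, 3, 4]
    for it in range(spec.iterations):
        for j in active:
            prop = theta.copy()
            prop[j] += rng.normal(size=C) * prop_scale[j]
            lp_prop = model.log_post(prop)
            accept = np.log(rng.uniform(size=C)) < lp_prop - lp
            theta[:, accept] = prop[:, accept]
            lp[accept] = lp_prop[accept]
            acc[j] += accept
        window += 1
        if it < spec.warmup and window == 50:
            rate = acc / window
            prop_scale *= np.where(rate < 0.2, 0.7, np.where(rate > 0.4, 1.4, 1.0))
            acc[:] = 0.0
            window = 0
        if it >= spec.warmup:
            kept[:, it - spec.warmup] = theta.T

    alpha_origin = kept[:, :, 0] - kept[:, :, 1] * age_mean - kept[:, :, 2] * exp_mean
    draws = {
        "alpha": alpha_origin / scale,
        "beta_age": kept[:, :, 1] / scale,
        "delta": kept[:, :, 2] / scale,
    }
    if sigma_fixed is not None:
        draws["sigma_control"] = np.full((C, kept_n), sigma_fixed[0])
        draws["sigma_exposed"] = np.full((C, kept_n), sigma_fixed[1])
    else:
        draws["sigma_control"] = np.exp(kept[:, :, 3]) / scale
        draws["sigma_exposed"] = np.exp(kept[:, :, 4]) / scale

    parameters = {}
    for name in PARAM_NAMES:
        mean, lo, hi = posterior_summary(draws[name])
        parameters[name] = ParameterSummary(mean, lo, hi, split_rhat(draws[name]))
    converged = all(p.rhat < spec.rhat_threshold for p in parameters.values())
    summary = PosteriorSummary(
        parameters=parameters,
        n_posterior_draws=C * kept_n,
        converged=converged,
        rhat_threshold=spec.rhat_threshold,
        seed=spec.seed,
    )
    return summary, draws


def sample_prior_intercept(
    spec: RegressionSpec, loc: float, scale: float, n: int = 20000
) -> np.ndarray:
    """Draws from the intercept prior (Student-t), for prior-sanity checks."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7)))
    return loc + scale * rng.standard_t(spec.intercept_prior_df, size=n)
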