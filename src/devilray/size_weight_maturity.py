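"""Bayesian disc-width–weight regression and logistic maturity ogives.

The width–weight model is the allometric power law fit on natural logs,

    ln W = log_a + b * ln DW + eps,  eps ~ Normal(0, sigma^2),

with normal priors on b and log_a and a (very) weakly informative half-Cauchy
prior on sigma^2. DW is in centimetres and W in kilograms, the convention in
which the priors were elicited.

Maturity is a Bayesian logistic regression of binary maturity status on age
(years) or disc width (cm): logit P(mature) = a + beta * x. The "strong"
intercept prior centres the ogive midpoint on a prior guess of the 50%
maturity point: a | beta ~ Normal(-beta * x50_guess, 10). The 50% point is
summarised per draw as x50 = -a / beta (never as a ratio of posterior means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bayes import (
    McmcSettings,
    SampleResult,
    half_cauchy_logpdf,
    normal_logpdf,
    sample_posterior,
    summary_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# width-weight


def allometric_weight(log_a: float, b: float, dw_cm: float) -> float:
    """Mean weight (kg) from the power law W = exp(log_a) * DW^b (DW in cm)."""
    return float(np.exp(log_a + b * np.log(dw_cm)))


@dataclass(frozen=True)
class LWPriorSet:
    b_mean: float = 3.0
    b_sd: float = 0.5
    log_a_mean: float = -5.0
    log_a_sd: float = 1.0
    sigma2_scale: float = 30000.0

    def __post_init__(self):
        if self.b_sd <= 0 or self.log_a_sd <= 0 or self.sigma2_scale <= 0:
            raise ValueError("prior scales must be positive")

    @classmethod
    def strong(cls) -> "LWPriorSet":
        return cls()

    @classmethod
    def weaker(cls) -> "LWPriorSet":
        return cls(b_sd=1.0, log_a_sd=3.0)


@dataclass
class LWPosterior:
    result: SampleResult

    @property
    def b_draws(self):
        return self.result.flat("b")

    @property
    def log_a_draws(self):
        return self.result.flat("log_a")

    @property
    def sigma2_draws(self):
        return self.result.flat("sigma2")

    def predict_weight(self, dw_cm: float) -> float:
        """Posterior-mean-parameter point prediction of weight (kg) at dw_cm."""
        return float(
            np.exp(np.mean(self.log_a_draws) + np.mean(self.b_draws) * np.log(dw_cm))
        )

    def summary(self):
        return summary_table(self.result)


def fit_lw(
    dw_cm,
    weight_kg,
    priors: LWPriorSet | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    check_convergence: bool = True,
) -> LWPosterior:
    """Fit the log-linear width–weight regression."""
    dw_cm = np.asarray(dw_cm, float)
    weight_kg = np.asarray(weight_kg, float)
    if dw_cm.size != weight_kg.size:
        raise ValueError("dw and weight must have equal length")
    if dw_cm.size < 5:
        raise ValueError("need at least 5 records")
    if np.any(dw_cm <= 0) or np.any(weight_kg <= 0):
        raise ValueError("disc widths and weights must be positive")
    priors = priors or LWPriorSet.strong()
    mcmc = mcmc or McmcSettings()

    x = np.log(dw_cm)
    y = np.log(weight_kg)

    # sigma^2 is sampled on the log scale (with the Jacobian term) so the
    # sampler mixes even when the posterior concentrates near zero variance;
    # the stated half-Cauchy prior applies to sigma^2 itself.
    def log_prob(theta):
        theta = np.atleast_2d(theta)
        log_a, b, ls2 = theta[:, 0], theta[:, 1], theta[:, 2]
        lp = np.full(theta.shape[0], -np.inf)
        ok = (ls2 > -40.0) & (ls2 < 30.0)
        if not ok.any():
            return lp
        s2 = np.exp(ls2[ok])
        lp[ok] = (
            normal_logpdf(log_a[ok], priors.log_a_mean, priors.log_a_sd**2)
            + normal_logpdf(b[ok], priors.b_mean, priors.b_sd**2)
            + half_cauchy_logpdf(s2, priors.sigma2_scale)
            + ls2[ok]  # Jacobian of sigma2 = exp(ls2)
        )
        resid = y[None, :] - (log_a[ok, None] + b[ok, None] * x[None, :])
        s2col = s2[:, None]
        lp[ok] += np.sum(-0.5 * (np.log(2 * np.pi * s2col) + resid**2 / s2col), axis=1)
        return lp

    # start near the OLS solution, jittered at the scale of its standard errors
    slope, intercept = np.polyfit(x, y, 1)
    resid_var = float(np.var(y - (intercept + slope * x))) or 1e-12
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_slope = np.sqrt(resid_var / sxx)
    se_intercept = np.sqrt(resid_var * (1.0 / n + x.mean() ** 2 / sxx))
    result = sample_posterior(
        log_prob,
        ["log_a", "b", "sigma2"],
        center=[intercept, slope, np.log(resid_var)],
        scale=[3 * se_intercept + 1e-8, 3 * se_slope + 1e-8, 0.5],
        settings=mcmc,
        seed=seed,
        check_convergence=check_convergence,
    )
    result.chains["sigma2"] = np.exp(result.chains["sigma2"])
    return LWPosterior(result=result)


# ---------------------------------------------------------------------------
# maturity ogive


@dataclass(frozen=True)
class MaturityPriorSet:
    """Priors for logit P(mature) = a + beta * x.

    ``x50_guess`` switches on the strong conditional intercept prior
    a | beta ~ Normal(-beta * x50_guess, intercept_sd); with ``x50_guess=None``
    the intercept prior is the weaker unconditional Normal(0, intercept_sd).
    """

    beta_sd: float = 10.0
    intercept_sd: float = 10.0
    x50_guess: float | None = None

    @classmethod
    def strong_age(cls, x50_guess: float = 5.5) -> "MaturityPriorSet":
        return cls(x50_guess=x50_guess)

    @classmethod
    def strong_dw(cls, x50_guess: float = 200.0) -> "MaturityPriorSet":
        return cls(x50_guess=x50_guess)

    @classmethod
    def weaker(cls) -> "MaturityPriorSet":
        return cls(x50_guess=None)


@dataclass
class MaturityPosterior:
    result: SampleResult
    unreliable: bool  # flagged when one maturity class has < 3 observations

    @property
    def a_draws(self):
        return self.result.flat("a")

    @property
    def beta_draws(self):
        return self.result.flat("beta")

    @property
    def x50_draws(self):
        return -self.a_draws / self.beta_draws

    def summary(self):
        return summary_table(self.result)


def fit_maturity(
    x,
    status,
    priors: MaturityPriorSet | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    check_convergence: bool = True,
) -> MaturityPosterior:
    """Fit the logistic maturity ogive; x is age (years) or DW (cm)."""
    x = np.asarray(x, float)
    status = np.asarray(status, int)
    if x.size != status.size:
        raise ValueError("x and status must have equal length")
    if set(np.unique(status)) - {0, 1}:
        raise ValueError("maturity status must be coded 0 (immature) / 1 (mature)")
    n_mat = int(status.sum())
    n_imm = int(status.size - n_mat)
    if n_mat == 0 or n_imm == 0:
        raise ValueError("both maturity classes must be present")
    unreliable = min(n_mat, n_imm) < 3
    if unreliable:
        logger.warning(
            "maturity fit flagged unreliable: smallest class has %d observation(s)",
            min(n_mat, n_imm),
        )
    priors = priors or MaturityPriorSet.weaker()
    mcmc = mcmc or McmcSettings()
    y = status.astype(float)

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        a, beta = theta[:, 0], theta[:, 1]
        lp = normal_logpdf(beta, 0.0, priors.beta_sd**2)
        if priors.x50_guess is not None:
            lp = lp + normal_logpdf(a, -beta * priors.x50_guess, priors.intercept_sd**2)
        else:
            lp = lp + normal_logpdf(a, 0.0, priors.intercept_sd**2)
        eta = a[:, None] + beta[:, None] * x[None, :]
        # stable Bernoulli log likelihood: y*eta - log(1 + e^eta)
        lp = lp + np.sum(y[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
        return lp

    x_scale = float(np.std(x)) or 1.0
    result = sample_posterior(
        log_prob,
        ["a", "beta"],
        center=[0.0, 0.5 / x_scale],
        scale=[0.5, 0.2 / x_scale],
        settings=mcmc,
        seed=seed,
        check_convergence=check_convergence,
    )
    return MaturityPosterior(result=result, unreliable=unreliable)


@dataclass
class X50Summary:
    mean: float
    ci_low: float
    ci_high: float
    frac_nonpositive_slope: float
    flagged: bool


def x50_summary(posterior: MaturityPosterior) -> X50Summary:
    """Mean and equal-tailed 95% credible interval of the 50%-maturity point.

    Computed per draw as -a/beta. Draws with beta <= 0 produce sign-flipped
    x50 values; if more than 5% of draws have beta <= 0 the summary is flagged.
    """
    x50 = posterior.x50_draws
    if x50.size < 100:
        raise ValueError("need at least 100 retained draws")
    frac_bad = float(np.mean(posterior.beta_draws <= 0))
    return X50Summary(
        mean=float(np.mean(x50)),
        ci_low=float(np.percentile(x50, 2.5)),
        ci_high=float(np.percentile(x50, 97.5)),
        frac_nonpositive_slope=frac_bad,
        flagged=frac_bad > 0.05,
    )
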