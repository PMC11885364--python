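"""Bayesian multi-model growth estimation from disc-width-at-age data.

Four mean functions are supported — von Bertalanffy, Gompertz, logistic, and
the biphasic Lester model — all fit on the log scale with additive normal
error (i.e. multiplicative lognormal error on disc width):

    ln DW_i ~ Normal(ln f(t_i; theta), sigma^2)

The asymptotic-size prior is hierarchical: DWinf ~ Normal(kappa * DWmax_ref,
sd), with kappa a gamma-distributed hyperparameter truncated to [0.7, 1.3]
that scales a literature maximum size into an asymptotic-size prior mean.
Model comparison uses PSIS-LOO (LOOIC) with exponential LOOIC-difference
weights.

Disc widths are millimetres throughout this module.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
from scipy import stats

from .bayes import (
    McmcSettings,
    SampleResult,
    half_cauchy_logpdf,
    normal_logpdf,
    sample_posterior,
    summary_table,
)

ASYMPTOTIC_MODELS = ("vb", "gompertz", "logistic")
ALL_MODELS = ASYMPTOTIC_MODELS + ("lester",)


# ---------------------------------------------------------------------------
# deterministic mean functions and inverses


def dwinf_from_dwmax(dw_max_cm: float) -> float:
    """Asymptotic size from maximum size (empirical allometry, cm in/out).

    DWinf = 10^(0.044 + 0.9841 * log10(DWmax)); close to but slightly above
    DWmax for sizes in the devil-ray range.
    """
    if dw_max_cm <= 0:
        raise ValueError("dw_max must be positive")
    return 10.0 ** (0.044 + 0.9841 * np.log10(dw_max_cm))


def _lester_t0(h: float, t1: float, T: float, k: float, dwinf: float) -> float:
    """Anchor age of the adult branch so the two Lester phases meet at T."""
    juvenile_at_T = h * (T - t1)
    if not (0 < juvenile_at_T < dwinf):
        raise ValueError("juvenile size at breakpoint must lie in (0, DWinf)")
    return T + np.log(1.0 - juvenile_at_T / dwinf) / k


def growth_mean(model: str, params: dict, t):
    """Deterministic mean disc width (mm) at age ``t`` (years) for ``model``.

    params keys: vb -> k, dw0, dwinf; gompertz/logistic -> g, dw0, dwinf;
    lester -> h, t1, T, k, dwinf.
    """
    t = np.asarray(t, dtype=float)
    if model == "vb":
        k, dw0, dwinf = params["k"], params["dw0"], params["dwinf"]
        if not dwinf > dw0:
            raise ValueError("require DWinf > DW0")
        return dwinf - (dwinf - dw0) * np.exp(-k * t)
    if model == "gompertz":
        g, dw0, dwinf = params["g"], params["dw0"], params["dwinf"]
        if dw0 <= 0:
            raise ValueError("Gompertz requires DW0 > 0")
        return dw0 * np.exp(np.log(dwinf / dw0) * (1.0 - np.exp(-g * t)))
    if model == "logistic":
        g, dw0, dwinf = params["g"], params["dw0"], params["dwinf"]
        if dw0 <= 0:
            raise ValueError("logistic requires DW0 > 0")
        egt = np.exp(g * t)
        return dwinf * dw0 * egt / (dwinf + dw0 * (egt - 1.0))
    if model == "lester":
        h, t1, T, k, dwinf = (
            params["h"],
            params["t1"],
            params["T"],
            params["k"],
            params["dwinf"],
        )
        t0 = _lester_t0(h, t1, T, k, dwinf)
        juvenile = h * (t - t1)
        adult = dwinf * (1.0 - np.exp(-k * (t - t0)))
        return np.where(t <= T, juvenile, adult)
    raise ValueError(f"unknown growth model {model!r}")


def age_at_size(model: str, params: dict, dw_mm: float) -> float:
    """Exact analytic inverse of the asymptotic growth curves (years at dw_mm)."""
    dw0, dwinf = params["dw0"], params["dwinf"]
    if not (dw0 < dw_mm < dwinf):
        raise ValueError(
            f"disc width {dw_mm} outside the invertible range ({dw0}, {dwinf})"
        )
    if model == "vb":
        return -np.log((dwinf - dw_mm) / (dwinf - dw0)) / params["k"]
    if model == "logistic":
        return np.log(dw_mm * (dwinf - dw0) / (dw0 * (dwinf - dw_mm))) / params["g"]
    if model == "gompertz":
        return -np.log(1.0 - np.log(dw_mm / dw0) / np.log(dwinf / dw0)) / params["g"]
    raise ValueError(f"no analytic inverse for model {model!r}")


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class LesterPriors:
    T_mean: float = 4.0
    T_sd: float = 1.0
    h_mean: float = 500.0
    h_sd: float = 1000.0
    t1_mean: float = 0.0
    t1_sd: float = 20.0


@dataclass(frozen=True)
class GrowthPriorSet:
    """Hyperparameters of the growth-model priors (all sizes mm).

    ``dwmax_ref`` is the literature maximum size; the DWinf prior mean is
    kappa * dwmax_ref with sd ``dwinf_prior_sd`` and kappa ~ gamma(shape, rate)
    hard-truncated to ``kappa_bounds``.
    """

    k_lo: float = 0.0
    k_hi: float = 2.0
    dw0_mean: float = 900.0
    dw0_sd: float = 200.0
    kappa_shape: float = 1000.0
    kappa_rate: float = 990.0
    kappa_bounds: tuple = (0.7, 1.3)
    dwmax_ref: float = 3500.0
    dwinf_prior_sd: float = 100.0
    sigma2_scale: float = 30000.0
    lester: LesterPriors = field(default_factory=LesterPriors)

    def __post_init__(self):
        if not self.k_lo < self.k_hi:
            raise ValueError("k prior bounds must satisfy lo < hi")
        if self.dwmax_ref <= 0:
            raise ValueError("dwmax_ref must be positive")

    @classmethod
    def mobular_strong(cls) -> "GrowthPriorSet":
        return cls()

    @classmethod
    def mobular_weaker(cls) -> "GrowthPriorSet":
        return cls(
            dw0_sd=300.0,
            kappa_shape=200.0,
            kappa_rate=198.0,
            dwinf_prior_sd=400.0,
            lester=LesterPriors(T_sd=4.0, t1_sd=10.0),
        )

    @classmethod
    def thurstoni_strong(cls) -> "GrowthPriorSet":
        return cls(
            dw0_mean=700.0,
            kappa_rate=980.0,
            dwmax_ref=1970.0,
            lester=LesterPriors(t1_sd=5.0),
        )

    @classmethod
    def thurstoni_weaker(cls) -> "GrowthPriorSet":
        return cls(
            dw0_mean=700.0,
            dw0_sd=300.0,
            kappa_shape=200.0,
            kappa_rate=196.0,
            dwmax_ref=1970.0,
            dwinf_prior_sd=400.0,
            lester=LesterPriors(T_sd=4.0, t1_sd=10.0),
        )

    def rescaled(self, factor: float) -> "GrowthPriorSet":
        """Priors converted to another length unit (e.g. 0.1 for mm -> cm)."""
        return replace(
            self,
            dw0_mean=self.dw0_mean * factor,
            dw0_sd=self.dw0_sd * factor,
            dwmax_ref=self.dwmax_ref * factor,
            dwinf_prior_sd=self.dwinf_prior_sd * factor,
            sigma2_scale=self.sigma2_scale,
            lester=replace(self.lester, h_mean=self.lester.h_mean * factor,
                           h_sd=self.lester.h_sd * factor),
        )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GrowthPosterior:
    model: str
    prior_label: str
    result: SampleResult
    log_lik: np.ndarray  # (n_draws, n_obs) pointwise log likelihood
    data_fingerprint: str
    n_obs: int

    @property
    def names(self):
        return self.result.names

    def draws(self, name: str) -> np.ndarray:
        return self.result.flat(name)

    def posterior_means(self) -> dict:
        return {nm: float(np.mean(self.result.flat(nm))) for nm in self.result.names}

    def mean_params(self) -> dict:
        """Posterior-mean growth parameters, keyed for growth_mean()."""
        means = self.posterior_means()
        if self.model == "vb":
            return {"k": means["k"], "dw0": means["dw0"], "dwinf": means["dwinf"]}
        if self.model in ("gompertz", "logistic"):
            return {"g": means["g"], "dw0": means["dw0"], "dwinf": means["dwinf"]}
        return {k: means[k] for k in ("h", "t1", "T", "k", "dwinf")}

    def dwinf_exceeds_dw0_fraction(self) -> float:
        return float(np.mean(self.draws("dwinf") > self.draws("dw0")))

    def summary(self):
        return summary_table(self.result)

    def to_inference_data(self, max_draws_per_chain: int = 150) -> az.InferenceData:
        chains = self.result.chains
        n_chain, n_draw = chains[self.names[0]].shape
        step = max(1, n_draw // max_draws_per_chain)
        ll = self.log_lik.reshape(n_chain, n_draw, self.n_obs)[:, ::step, :]
        post = {nm: arr[:, ::step] for nm, arr in chains.items()}
        return az.from_dict(posterior=post, log_likelihood={"dw": ll})


def data_fingerprint(ages, dw_mm) -> str:
    a = np.round(np.asarray(ages, float), 6)
    d = np.round(np.asarray(dw_mm, float), 6)
    return hashlib.sha1(a.tobytes() + d.tobytes()).hexdigest()


def _truncated_gamma_logpdf(x, shape, rate, bounds):
    lo, hi = bounds
    out = np.full(np.shape(x), -np.inf)
    ok = (x > lo) & (x < hi)
    # normalisation over [lo, hi] is a constant; omit (MCMC invariant)
    out[ok] = stats.gamma.logpdf(np.asarray(x)[ok], a=shape, scale=1.0 / rate)
    return out


def _growth_log_prob(model, ages, log_dw, priors: GrowthPriorSet):
    """Vectorised log posterior over a (n_walkers, ndim) parameter block."""
    lp_names = _param_names(model)
    idx = {nm: i for i, nm in enumerate(lp_names)}
    lo_k, hi_k = priors.k_lo, priors.k_hi
    kb = priors.kappa_bounds
    lest = priors.lester

    # sigma^2 sampled on the log scale (Jacobian added); prior stays on sigma^2
    def log_prob(theta):
        theta = np.atleast_2d(theta)
        n = theta.shape[0]
        lp = np.zeros(n)
        dw0 = theta[:, idx["dw0"]]
        dwinf = theta[:, idx["dwinf"]]
        kappa = theta[:, idx["kappa"]]
        ls2 = theta[:, idx["sigma2"]]
        sigma2 = np.exp(np.clip(ls2, -60.0, 60.0))

        bad = (ls2 <= -40.0) | (ls2 >= 30.0) | (dw0 <= 0) | (dwinf <= dw0)
        bad |= (kappa <= kb[0]) | (kappa >= kb[1])
        if model == "lester":
            h = theta[:, idx["h"]]
            t1 = theta[:, idx["t1"]]
            T = theta[:, idx["T"]]
            k = theta[:, idx["k"]]
            bad |= (k <= lo_k) | (k >= hi_k) | (h <= 0) | (T <= 0)
            juv_T = h * (T - t1)
            bad |= (juv_T <= 0) | (juv_T >= dwinf)
        else:
            coef = theta[:, idx["k" if model == "vb" else "g"]]
            bad |= (coef <= lo_k) | (coef >= hi_k)

        lp[bad] = -np.inf
        ok = ~bad
        if not ok.any():
            return lp

        # priors
        lp[ok] += normal_logpdf(dw0[ok], priors.dw0_mean, priors.dw0_sd**2)
        lp[ok] += normal_logpdf(
            dwinf[ok], kappa[ok] * priors.dwmax_ref, priors.dwinf_prior_sd**2
        )
        lp[ok] += _truncated_gamma_logpdf(
            kappa[ok], priors.kappa_shape, priors.kappa_rate, kb
        )
        lp[ok] += half_cauchy_logpdf(sigma2[ok], priors.sigma2_scale) + ls2[ok]
        if model == "lester":
            lp[ok] += normal_logpdf(theta[ok, idx["h"]], lest.h_mean, lest.h_sd**2)
            lp[ok] += normal_logpdf(theta[ok, idx["t1"]], lest.t1_mean, lest.t1_sd**2)
            lp[ok] += normal_logpdf(theta[ok, idx["T"]], lest.T_mean, lest.T_sd**2)

        # likelihood on the log scale
        mu = _mean_matrix(model, theta[ok], idx, ages)
        good_mu = np.all(mu > 0, axis=1)
        ll = np.full(int(ok.sum()), -np.inf)
        if good_mu.any():
            resid = log_dw[None, :] - np.log(mu[good_mu])
            s2 = sigma2[ok][good_mu][:, None]
            ll[good_mu] = np.sum(
                -0.5 * (np.log(2 * np.pi * s2) + resid**2 / s2), axis=1
            )
        lp[ok] += ll
        return lp

    return log_prob, lp_names, idx


def _mean_matrix(model, theta, idx, ages):
    """Growth mean for each walker row x each age (broadcasted)."""
    t = ages[None, :]
    dw0 = theta[:, idx["dw0"]][:, None]
    dwinf = theta[:, idx["dwinf"]][:, None]
    if model == "vb":
        k = theta[:, idx["k"]][:, None]
        return dwinf - (dwinf - dw0) * np.exp(-k * t)
    if model == "gompertz":
        g = theta[:, idx["g"]][:, None]
        return dw0 * np.exp(np.log(dwinf / dw0) * (1.0 - np.exp(-g * t)))
    if model == "logistic":
        g = theta[:, idx["g"]][:, None]
        egt = np.exp(g * t)
        return dwinf * dw0 * egt / (dwinf + dw0 * (egt - 1.0))
    # lester
    h = theta[:, idx["h"]][:, None]
    t1 = theta[:, idx["t1"]][:, None]
    T = theta[:, idx["T"]][:, None]
    k = theta[:, idx["k"]][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = T + np.log(1.0 - h * (T - t1) / dwinf) / k
        adult = dwinf * (1.0 - np.exp(-k * (t - t0)))
    juvenile = h * (t - t1)
    return np.where(t <= T, juvenile, adult)


def _param_names(model):
    if model == "vb":
        return ["k", "dw0", "dwinf", "kappa", "sigma2"]
    if model in ("gompertz", "logistic"):
        return ["g", "dw0", "dwinf", "kappa", "sigma2"]
    if model == "lester":
        return ["h", "t1", "T", "k", "dw0", "dwinf", "kappa", "sigma2"]
    raise ValueError(f"unknown growth model {model!r}")


def fit_growth(
    ages,
    dw_mm,
    model: str,
    priors: GrowthPriorSet,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    prior_label: str = "strong",
    check_convergence: bool = True,
) -> GrowthPosterior:
    """Fit one growth model; returns draws plus the pointwise log-likelihood."""
    ages = np.asarray(ages, dtype=float)
    dw_mm = np.asarray(dw_mm, dtype=float)
    if ages.size < 10:
        raise ValueError("need at least 10 (age, DW) pairs")
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    if np.any(dw_mm <= 0):
        raise ValueError("disc widths must be positive")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate input: all observations at a single age")
    mcmc = mcmc or McmcSettings()
    log_dw = np.log(dw_mm)

    log_prob, names, idx = _growth_log_prob(model, ages, log_dw, priors)

    kappa0 = np.clip(priors.kappa_shape / priors.kappa_rate, 0.75, 1.25)
    dwinf0 = kappa0 * priors.dwmax_ref
    ls2_0 = np.log(0.1)
    if model == "lester":
        center = [500.0, -1.0, priors.lester.T_mean, 0.2, priors.dw0_mean, dwinf0, kappa0, ls2_0]
        scale = [50.0, 0.3, 0.3, 0.05, 40.0, 50.0, 0.01, 0.5]
    else:
        center = [0.2, priors.dw0_mean, dwinf0, kappa0, ls2_0]
        scale = [0.05, 40.0, 50.0, 0.01, 0.5]

    result = sample_posterior(
        log_prob, names, center, scale, mcmc, seed, check_convergence=check_convergence
    )
    result.chains["sigma2"] = np.exp(result.chains["sigma2"])

    # pointwise log likelihood for every retained draw
    theta = result.stacked()
    mu = _mean_matrix(model, theta, {nm: i for i, nm in enumerate(names)}, ages)
    s2 = theta[:, names.index("sigma2")][:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = -0.5 * (np.log(2 * np.pi * s2) + (log_dw[None, :] - np.log(mu)) ** 2 / s2)

    # lester has no dw0 in the likelihood mean but keeps the prior-driven draw;
    # asymptotic models store dw0 directly. Either way names carry it.
    return GrowthPosterior(
        model=model,
        prior_label=prior_label,
        result=result,
        log_lik=log_lik,
        data_fingerprint=data_fingerprint(ages, dw_mm),
        n_obs=ages.size,
    )


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    table: "object"  # DataFrame: model, prior, looic, looic_se, weight, n_high_k

    def best(self) -> str:
        return self.table.sort_values("looic").iloc[0]["model"]


def compare_models(posteriors) -> ModelComparison:
    """PSIS-LOO comparison; weights are exp(-0.5 * dLOOIC) normalised."""
    import pandas as pd

    fps = {p.data_fingerprint for p in posteriors}
    if len(fps) != 1:
        raise ValueError("posteriors were fit on different data sets")

    rows = []
    for p in posteriors:
        idata = p.to_inference_data()
        loo = az.loo(idata, pointwise=True, scale="deviance")
        n_high = int(np.sum(loo.pareto_k.values > 0.7))
        rows.append(
            {
                "model": p.model,
                "prior": p.prior_label,
                "looic": float(loo.elpd_loo),
                "looic_se": float(loo.se),
                "n_high_pareto_k": n_high,
            }
        )
    tab = pd.DataFrame(rows)
    delta = tab["looic"] - tab["looic"].min()
    w = np.exp(-0.5 * delta)
    tab["weight"] = w / w.sum()
    return ModelComparison(table=tab)
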