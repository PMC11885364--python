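"""Shared MCMC machinery.

All Bayesian fits in the package run through :func:`sample_posterior`, a thin
wrapper around the affine-invariant ensemble sampler (emcee) with convergence
diagnostics (split R-hat and bulk ESS via arviz) computed on the post-burn-in
chain, treating walkers as parallel chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import arviz as az
import emcee
import numpy as np


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration shared by every model fit.

    Defaults give ~24k retained draws, comfortably exceeding the ESS floor for
    the smooth, low-dimensional posteriors fit here.
    """

    n_walkers: int = 32
    n_steps: int = 4000
    n_burn: int = 1500
    thin: int = 2
    rhat_max: float = 1.05
    ess_min: float = 400.0

    def scaled(self, factor: float) -> "McmcSettings":
        """A cheaper copy with step counts scaled by ``factor`` (testing aid)."""
        return McmcSettings(
            n_walkers=self.n_walkers,
            n_steps=max(200, int(self.n_steps * factor)),
            n_burn=max(100, int(self.n_burn * factor)),
            thin=self.thin,
            rhat_max=self.rhat_max,
            ess_min=self.ess_min,
        )


class ConvergenceError(RuntimeError):
    """Raised when a sampler fails its diagnostic thresholds."""

    def __init__(self, param: str, rhat: float, ess: float, settings: McmcSettings):
        self.param = param
        self.rhat = rhat
        self.ess = ess
        super().__init__(
            f"MCMC did not converge for parameter '{param}': "
            f"R-hat={rhat:.3f} (max {settings.rhat_max}), "
            f"ESS={ess:.0f} (min {settings.ess_min})"
        )


@dataclass
class SampleResult:
    """Posterior draws in (chain, draw) layout plus diagnostics."""

    names: list[str]
    chains: dict[str, np.ndarray]  # each (n_chain, n_draw)
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    @property
    def n_draws(self) -> int:
        first = self.chains[self.names[0]]
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.chains[name].reshape(-1)

    def stacked(self) -> np.ndarray:
        """Draws as a (n_total_draws, n_param) matrix in ``names`` order."""
        return np.column_stack([self.flat(n) for n in self.names])


def _initial_ball(
    log_prob: Callable[[np.ndarray], np.ndarray],
    center: np.ndarray,
    scale: np.ndarray,
    n_walkers: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jitter walkers around ``center``, resampling any with -inf log prob."""
    ndim = center.size
    p0 = center + scale * rng.standard_normal((n_walkers, ndim))
    lp = log_prob(p0)
    for _ in range(200):
        bad = ~np.isfinite(lp)
        if not bad.any():
            return p0
        p0[bad] = center + scale * 0.3 * rng.standard_normal((int(bad.sum()), ndim))
        lp[bad] = log_prob(p0[bad])
    raise ValueError("could not find valid starting points; check priors/data")


def sample_posterior(
    log_prob: Callable[[np.ndarray], np.ndarray],
    names: Sequence[str],
    center: Sequence[float],
    scale: Sequence[float],
    settings: McmcSettings,
    seed: int,
    check_convergence: bool = True,
) -> SampleResult:
    """Run the ensemble sampler on a vectorised log posterior.

    ``log_prob`` must accept a (n_walkers, n_dim) array and return a
    (n_walkers,) array of log densities (-inf outside the support).
    """
    names = list(names)
    center = np.asarray(center, dtype=float)
    scale = np.asarray(scale, dtype=float)
    rng = np.random.default_rng(seed)

    p0 = _initial_ball(log_prob, center, scale, settings.n_walkers, rng)
    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    sampler = emcee.EnsembleSampler(
        settings.n_walkers, center.size, log_prob, vectorize=True, moves=moves
    )
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, settings.n_steps, progress=False)

    chain = sampler.get_chain(discard=settings.n_burn, thin=settings.thin)
    # (steps, walkers, dim) -> per-parameter (walkers, steps)
    chains = {nm: chain[:, :, i].T.copy() for i, nm in enumerate(names)}
    idata = az.from_dict(posterior=chains)
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {nm: float(rhat_ds[nm].values) for nm in names}
    ess = {nm: float(ess_ds[nm].values) for nm in names}

    converged = all(
        rhat[nm] < settings.rhat_max and ess[nm] > settings.ess_min for nm in names
    )
    if check_convergence and not converged:
        worst = max(names, key=lambda nm: (rhat[nm], -ess[nm]))
        raise ConvergenceError(worst, rhat[worst], ess[worst], settings)

    return SampleResult(names=names, chains=chains, rhat=rhat, ess=ess, converged=converged)


def half_cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    """Log density of a half-Cauchy(0, scale) on x > 0 (vectorised, -inf below 0)."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, -np.inf)
    ok = x > 0
    out[ok] = np.log(2.0 / (np.pi * scale)) - np.log1p((x[ok] / scale) ** 2)
    return out


def normal_logpdf(x: np.ndarray, mean, var) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def summary_table(result: SampleResult):
    """Posterior mean and equal-tailed 95% interval per parameter (DataFrame)."""
    import pandas as pd

    rows = []
    for nm in result.names:
        d = result.flat(nm)
        rows.append(
            {
                "parameter": nm,
                "mean": float(np.mean(d)),
                "q2.5": float(np.percentile(d, 2.5)),
                "q97.5": float(np.percentile(d, 97.5)),
                "rhat": result.rhat[nm],
                "ess": result.ess[nm],
            }
        )
    return pd.DataFrame(rows)
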