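"""Seeded adaptive random-walk Metropolis sampler.

Shared MCMC machinery for GUTS calibration and the ordinal regression
models.  Multiple independent chains are run from jittered starting points;
during burn-in each chain adapts a multivariate normal proposal to the
empirical covariance of its own history (scaled by 2.38^2/d), after which
the proposal is frozen so the retained draws target the exact posterior.
All randomness flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MCMCResult", "adaptive_metropolis"]


@dataclass
class MCMCResult:
    """Raw sampler output.

    chains : draws with shape (n_chains, n_keep, dim)
    logps  : log posterior per draw, shape (n_chains, n_keep)
    acceptance_rates : per chain
    """

    chains: np.ndarray
    logps: np.ndarray
    acceptance_rates: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    @property
    def flat_logps(self) -> np.ndarray:
        return self.logps.reshape(-1)


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    *,
    n_chains: int = 4,
    n_burn: int = 1000,
    n_keep: int = 500,
    rng: np.random.Generator,
    init_scale: float = 0.1,
    adapt_interval: int = 50,
) -> MCMCResult:
    """Run ``n_chains`` adaptive Metropolis chains targeting ``log_post``.

    Chains start at ``x0`` plus Gaussian jitter of scale ``init_scale``.
    Returns the post-burn-in draws only.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    scale = 2.38**2 / d
    n_total = n_burn + n_keep
    chains = np.empty((n_chains, n_keep, d))
    logps = np.empty((n_chains, n_keep))
    acc_rates = np.empty(n_chains)

    for c in range(n_chains):
        x = x0 + init_scale * rng.standard_normal(d)
        lp = log_post(x)
        tries = 0
        while not np.isfinite(lp) and tries < 100:
            x = x0 + init_scale * rng.standard_normal(d)
            lp = log_post(x)
            tries += 1
        if not np.isfinite(lp):
            raise RuntimeError("could not find a finite-posterior starting point")
        cov = np.eye(d) * init_scale**2
        chol = np.linalg.cholesky(cov * scale)
        history = np.empty((n_total, d))
        accepted = 0
        for i in range(n_total):
            prop = x + chol @ rng.standard_normal(d)
            lp_prop = log_post(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
            history[i] = x
            if i < n_burn and (i + 1) % adapt_interval == 0 and i >= 2 * d:
                emp = np.cov(history[: i + 1].T)
                emp = np.atleast_2d(emp) + 1e-9 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(emp * scale)
                except np.linalg.LinAlgError:
                    pass
            if i >= n_burn:
                chains[c, i - n_burn] = x
                logps[c, i - n_burn] = lp
        acc_rates[c] = accepted / n_total
    return MCMCResult(chains=chains, logps=logps, acceptance_rates=acc_rates)
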