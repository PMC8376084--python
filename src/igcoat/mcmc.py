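"""Gradient-based MCMC engine and convergence diagnostics.

A compact Hamiltonian Monte Carlo sampler (diagonal mass-matrix
adaptation, dual-averaging step size, jittered path length) drives both
hierarchical models. Split-chain potential scale reduction and
autocorrelation-based effective sample sizes follow the standard
split-R-hat / Geyer initial-monotone-sequence constructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class PosteriorDraws:
    """chains x iterations x parameters array of posterior draws."""

    draws: np.ndarray
    parameter_names: list[str]
    sampler_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names length mismatch")
        if not np.isfinite(self.draws).all():
            raise ValueError("non-finite draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def _index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """(chains, iterations) array for one named parameter."""
        return self.draws[:, :, self._index(name)]

    def stacked(self, name: str) -> np.ndarray:
        """All draws for one parameter, chains concatenated."""
        return self.get(name).reshape(-1)

    def stacked_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(total draws, parameters) matrix, chains concatenated."""
        if names is None:
            return self.draws.reshape(-1, self.draws.shape[2])
        idx = [self._index(n) for n in names]
        return self.draws.reshape(-1, self.draws.shape[2])[:, idx]

    def summary(self, interval: float = 0.90):
        import pandas as pd

        alpha = (1.0 - interval) / 2.0
        flat = self.draws.reshape(-1, self.draws.shape[2])
        rhat = gelman_rubin(self)
        ess = effective_sample_size(self)
        return pd.DataFrame(
            {
                "median": np.median(flat, axis=0),
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                f"lo{int(round(interval * 100))}": np.quantile(flat, alpha, axis=0),
                f"hi{int(round(interval * 100))}": np.quantile(flat, 1 - alpha, axis=0),
                "rhat": [rhat[n] for n in self.parameter_names],
                "ess": [ess[n] for n in self.parameter_names],
            },
            index=self.parameter_names,
        )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, n) -> (2*chains, n//2), dropping an odd trailing draw."""
    c, n = x.shape
    half = n // 2
    return np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)


def _rhat_single(x: np.ndarray) -> float:
    s = _split_chains(np.asarray(x, dtype=float))
    m, n = s.shape
    if n < 2:
        raise ValueError("need at least 4 iterations per chain")
    chain_means = s.mean(axis=1)
    chain_vars = s.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0.0 or not np.isfinite(w):
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Zero-variance (constant) parameters yield NaN rather than an error.
    """
    if draws.n_chains < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    if draws.n_iterations < 4:
        raise ValueError("gelman_rubin requires at least 4 iterations")
    return {
        name: _rhat_single(draws.get(name)) for name in draws.parameter_names
    }


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of a 1-D series via FFT."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def _ess_single(x: np.ndarray) -> float:
    s = _split_chains(np.asarray(x, dtype=float))
    m, n = s.shape
    if n < 2:
        raise ValueError("need at least 4 iterations per chain")
    chain_vars = s.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w <= 0.0 or not np.isfinite(w):
        return float("nan")
    b = n * s.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b / n

    acov = np.mean([_autocovariance(s[i]) for i in range(m)], axis=0)
    rho = 1.0 - (w - acov) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 0.0
    prev_pair = np.inf
    t = 1
    pair_sum0 = rho[0] + (rho[1] if n > 1 else 0.0)
    tau = min(pair_sum0, prev_pair)
    prev_pair = tau
    t = 2
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        pair = min(pair, prev_pair)
        tau += pair
        prev_pair = pair
        t += 2
    tau = max(2.0 * tau - 1.0, 1.0 / np.log10(m * n + 10))
    ess = m * n / tau
    return float(min(ess, m * n))


def effective_sample_size(draws: PosteriorDraws) -> dict[str, float]:
    """Autocorrelation-based ESS per parameter, capped at the draw count."""
    if draws.n_chains < 2:
        raise ValueError("effective_sample_size requires at least 2 chains")
    if draws.n_iterations < 4:
        raise ValueError("effective_sample_size requires at least 4 iterations")
    return {name: _ess_single(draws.get(name)) for name in draws.parameter_names}


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

class _Mass:
    """Diagonal or dense inverse-mass (position-space covariance) metric."""

    def __init__(self, inv_diag: np.ndarray | None = None,
                 inv_dense: np.ndarray | None = None):
        if inv_dense is not None:
            self.dense = True
            self.sigma = inv_dense                      # ~ posterior covariance
            self.chol = np.linalg.cholesky(inv_dense)   # lower
        else:
            self.dense = False
            self.inv_diag = inv_diag

    def sample_momentum(self, rng: np.random.Generator, dim: int) -> np.ndarray:
        z = rng.standard_normal(dim)
        if self.dense:
            from scipy.linalg import solve_triangular

            return solve_triangular(self.chol.T, z, lower=False)
        return z / np.sqrt(self.inv_diag)

    def velocity(self, p: np.ndarray) -> np.ndarray:
        """dK/dp = Sigma p (the position-space step direction)."""
        if self.dense:
            return self.chol @ (self.chol.T @ p)
        return self.inv_diag * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ self.velocity(p))


def _find_initial_step(logp_grad: LogpGrad, q: np.ndarray, mass: _Mass,
                       rng: np.random.Generator) -> float:
    eps = 0.1
    lp, grad = logp_grad(q)
    p = mass.sample_momentum(rng, q.size)
    h0 = lp - mass.kinetic(p)

    def one_step(eps: float) -> float:
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * mass.velocity(p1)
        lp1, g1 = logp_grad(q1)
        p1 = p1 + 0.5 * eps * g1
        h1 = lp1 - mass.kinetic(p1)
        return h1 - h0

    delta = one_step(eps)
    if not np.isfinite(delta):
        delta = -np.inf
    direction = 1 if delta > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        delta = one_step(eps)
        if not np.isfinite(delta):
            delta = -np.inf
        if (direction == 1 and delta <= np.log(0.5)) or (
            direction == -1 and delta >= np.log(0.5)
        ):
            break
    return eps


def _hmc_chain(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int,
    target_accept: float,
    dense_mass: bool = True,
) -> tuple[np.ndarray, dict]:
    dim = q0.size
    q = q0.copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial point")

    mass = _Mass(inv_diag=np.ones(dim))
    eps = _find_initial_step(logp_grad, q, mass, rng)

    # dual averaging state
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0

    # two covariance-estimation windows: a coarse one feeding an interim
    # metric, then a refined one on the better-mixing chain
    stage1_end = max(int(0.15 * n_warmup), 10)
    stage2_end = max(int(0.50 * n_warmup), stage1_end + 10)
    stage3_end = max(int(0.90 * n_warmup), stage2_end + 10)
    samples: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    n_divergent_sampling = 0
    n_accept = 0
    total = n_warmup + n_draws

    def build_mass(window: list[np.ndarray]) -> _Mass:
        arr = np.asarray(window)
        n = arr.shape[0]
        var = arr.var(axis=0, ddof=1)
        shrink = n / (n + 5.0)
        var = shrink * var + 1e-3 * (1 - shrink)
        if dense_mass and n >= 20:
            cov = np.cov(arr.T)
            cov = shrink * cov + np.diag((1 - shrink) * np.maximum(var, 1e-8))
            # ensure PD
            try:
                np.linalg.cholesky(cov)
                return _Mass(inv_dense=cov)
            except np.linalg.LinAlgError:
                pass
        return _Mass(inv_diag=np.maximum(var, 1e-10))

    for it in range(total):
        p = mass.sample_momentum(rng, dim)
        h0 = lp - mass.kinetic(p)
        n_leap = int(rng.integers(1, max_leapfrog + 1))

        q_new, p_new, grad_new = q, p, grad
        lp_new = lp
        diverged = False
        delta = -np.inf
        p_new = p_new + 0.5 * eps * grad_new
        for step in range(n_leap):
            q_new = q_new + eps * mass.velocity(p_new)
            lp_new, grad_new = logp_grad(q_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            if step < n_leap - 1:
                p_new = p_new + eps * grad_new
        if not diverged:
            p_new = p_new + 0.5 * eps * grad_new
            h1 = lp_new - mass.kinetic(p_new)
            delta = h1 - h0
            if not np.isfinite(delta) or delta < -1000.0:
                diverged = True

        if diverged:
            accept_prob = 0.0
            n_divergent += 1
            if it >= n_warmup:
                n_divergent_sampling += 1
        else:
            accept_prob = min(1.0, np.exp(min(delta, 0.0)))
            if np.log(rng.uniform()) < delta:
                q, lp, grad = q_new, lp_new, grad_new
                n_accept += 1

        if it < n_warmup:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_count + t0)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = np.exp(log_eps)

            if it >= stage1_end:
                samples.append(q.copy())
            if it in (stage2_end - 1, stage3_end - 1) and len(samples) >= 10:
                mass = build_mass(samples)
                samples = []
                eps = _find_initial_step(logp_grad, q, mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = q

    meta = {
        "step_size": float(eps),
        "divergences": int(n_divergent_sampling),
        "divergences_warmup": int(n_divergent - n_divergent_sampling),
        "accept_rate": n_accept / total,
    }
    return draws, meta


def sample_posterior(
    logp_grad: LogpGrad,
    init: np.ndarray,
    *,
    parameter_names: list[str] | None = None,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_draws: int = 500,
    seed: int = 0,
    max_leapfrog: int = 24,
    target_accept: float = 0.8,
    init_jitter: float = 0.5,
    dense_mass: bool = True,
) -> PosteriorDraws:
    """Run `n_chains` independent HMC chains on an unconstrained posterior.

    `logp_grad` returns the joint log density (up to a constant) and its
    gradient. Identical seeds and settings give bit-identical output.
    """
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    init = np.asarray(init, dtype=float)
    dim = init.size
    if parameter_names is None:
        parameter_names = [f"theta[{i}]" for i in range(dim)]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_chains)
    all_draws = np.empty((n_chains, n_draws, dim))
    metas = []
    for c in range(n_chains):
        rng = np.random.default_rng(child_seeds[c])
        q0 = init + init_jitter * rng.standard_normal(dim)
        d, meta = _hmc_chain(
            logp_grad, q0, n_warmup, n_draws, rng, max_leapfrog, target_accept,
            dense_mass=dense_mass,
        )
        all_draws[c] = d
        metas.append(meta)

    meta = {
        "seed": seed,
        "n_warmup": n_warmup,
        "n_chains": n_chains,
        "chains": metas,
        "divergences": sum(m["divergences"] for m in metas),
    }
    return PosteriorDraws(all_draws, list(parameter_names), meta)


def check_convergence(
    draws: PosteriorDraws, rhat_max: float = 1.05, ess_min: float = 100.0
) -> bool:
    """Flag non-convergence (stored in sampler_meta, warned, not hidden)."""
    rhat = gelman_rubin(draws)
    ess = effective_sample_size(draws)
    bad = [
        n
        for n in draws.parameter_names
        if (np.isfinite(rhat[n]) and rhat[n] > rhat_max)
        or (np.isfinite(ess[n]) and ess[n] < ess_min)
    ]
    converged = not bad
    draws.sampler_meta["converged"] = converged
    draws.sampler_meta["flagged_parameters"] = bad
    if not converged:
        warnings.warn(
            f"MCMC convergence flagged for {len(bad)} parameter(s): {bad[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return converged
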