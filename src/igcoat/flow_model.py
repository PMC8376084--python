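"""Hierarchical binomial logistic model for Ig-coated cell counts.

positive_i ~ Binomial(total_i, inv-logit(x_i' beta + u_d(i) + v_d(i) * ig_i))

with a correlated per-dog (intercept, Ig-slope) random effect. Fixed
effects carry improper flat priors by default (optionally Normal(0, 10)),
random-effect SDs half-Student-t(3, 0, 2.5), and the 2x2 random-effect
correlation a uniform (LKJ(1)) prior. Sampling uses the package HMC
engine on a non-centred parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from igcoat.design import DesignMatrix, build_design  # noqa: F401  (re-export)
from igcoat.mcmc import PosteriorDraws, check_convergence, sample_posterior

FLOW_FACTORS = ["ig_class", "cohort", "stage"]

_HALF_T_DF = 3.0
_HALF_T_SCALE = 2.5


def validate_flow_counts(counts: pd.DataFrame) -> None:
    for col in ("dog_id", "cohort", "stage", "ig_class", "positive", "total"):
        if col not in counts.columns:
            raise ValueError(f"flow counts missing column {col!r}")
    if (counts["total"] < 1).any():
        raise ValueError("total must be >= 1")
    if ((counts["positive"] < 0) | (counts["positive"] > counts["total"])).any():
        raise ValueError("positive must satisfy 0 <= positive <= total")


def _half_t_logpdf_grad(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nu, s = _HALF_T_DF, _HALF_T_SCALE
    lp = -0.5 * (nu + 1.0) * np.log1p(sigma**2 / (nu * s**2))
    grad = -(nu + 1.0) * sigma / (nu * s**2 + sigma**2)
    return lp, grad


@dataclass
class _FlowPosterior:
    """Unconstrained joint posterior with analytic gradient.

    Centred random-effect parameterization: (u_d, v_d) are sampled
    directly under their MVN(0, Sigma(sigma_u, sigma_v, rho)) prior,
    which is the well-conditioned choice when the per-dog effects are
    tightly identified by the binomial counts.
    """

    X: np.ndarray            # n x P
    pos: np.ndarray
    tot: np.ndarray
    dog_index: np.ndarray
    ig: np.ndarray           # 0/1 slope covariate
    n_dogs: int
    beta_prior_sd: float | None = None   # None = improper flat

    def __post_init__(self) -> None:
        self.P = self.X.shape[1]
        self.dim = self.P + 2 * self.n_dogs + 3

    def unpack(self, theta: np.ndarray):
        P, D = self.P, self.n_dogs
        beta = theta[:P]
        u = theta[P : P + D]
        v = theta[P + D : P + 2 * D]
        log_su, log_sv, zeta = theta[P + 2 * D :]
        return beta, u, v, log_su, log_sv, zeta

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, u, v, log_su, log_sv, zeta = self.unpack(theta)
        if abs(log_su) > 30 or abs(log_sv) > 30 or abs(zeta) > 30:
            return -np.inf, np.zeros_like(theta)
        su, sv = math.exp(log_su), math.exp(log_sv)
        rho = math.tanh(zeta)
        c = 1.0 / max(1.0 - rho * rho, 1e-12)

        eta = self.X @ beta + u[self.dog_index] + v[self.dog_index] * self.ig

        # binomial log-likelihood (constants dropped), numerically stable
        log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        lp = float(np.sum(self.pos * eta - self.tot * log1pexp))
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        g = self.pos - self.tot * mu                      # dlp/deta per row

        grad = np.zeros_like(theta)
        grad[: self.P] = self.X.T @ g
        gu = np.bincount(self.dog_index, weights=g, minlength=self.n_dogs)
        gv = np.bincount(
            self.dog_index, weights=g * self.ig, minlength=self.n_dogs
        )

        P, D = self.P, self.n_dogs
        # MVN(0, Sigma) prior on the per-dog pairs, standardized scales
        a = u / su
        b = v / sv
        s_aa, s_ab, s_bb = float(a @ a), float(a @ b), float(b @ b)
        quad = s_aa - 2.0 * rho * s_ab + s_bb
        lp += (
            -D * (log_su + log_sv)
            - 0.5 * D * math.log(max(1.0 - rho * rho, 1e-300))
            - 0.5 * c * quad
        )
        grad[P : P + D] = gu - c * (a - rho * b) / su
        grad[P + D : P + 2 * D] = gv - c * (b - rho * a) / sv

        # half-t priors on sigmas (+log sigma from the log-scale jacobian)
        lp_su, gp_su = _half_t_logpdf_grad(np.array([su]))
        lp_sv, gp_sv = _half_t_logpdf_grad(np.array([sv]))
        lp += float(lp_su[0]) + log_su + float(lp_sv[0]) + log_sv
        grad[P + 2 * D] = (
            -D + c * (s_aa - rho * s_ab) + su * float(gp_su[0]) + 1.0
        )
        grad[P + 2 * D + 1] = (
            -D + c * (s_bb - rho * s_ab) + sv * float(gp_sv[0]) + 1.0
        )

        # correlation: rho = tanh(zeta), uniform (LKJ(1)) prior on rho
        lp += math.log(max(1.0 - rho * rho, 1e-300))
        grad[P + 2 * D + 2] = D * rho + s_ab - rho * c * quad - 2.0 * rho

        if self.beta_prior_sd is not None:
            sd2 = self.beta_prior_sd**2
            lp += -0.5 * float(beta @ beta) / sd2
            grad[: self.P] -= beta / sd2
        return lp, grad

    def constrain(self, theta: np.ndarray) -> np.ndarray:
        """Map an unconstrained draw to (beta, u, v, sigma_u, sigma_v, rho)."""
        beta, u, v, log_su, log_sv, zeta = self.unpack(theta)
        return np.concatenate(
            [beta, u, v, [math.exp(log_su), math.exp(log_sv), math.tanh(zeta)]]
        )


def fit_flow_model(
    counts: pd.DataFrame,
    design: DesignMatrix,
    *,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
    beta_prior_sd: float | None = None,
    max_leapfrog: int = 24,
    check: bool = True,
) -> PosteriorDraws:
    """Sample the posterior of the hierarchical binomial coating model.

    Returned draws are on the constrained scale with names
    ``beta[<term>]``, ``u[<dog>]``, ``v[<dog>]``, ``sigma_u``, ``sigma_v``
    and ``rho``. Non-convergence (split R-hat/ESS gate) is flagged in
    ``sampler_meta`` and warned, never silently accepted.
    """
    validate_flow_counts(counts)
    if len(counts) != design.n_rows:
        raise ValueError("counts rows do not match the design matrix")
    if design.n_dogs < 2:
        raise ValueError("at least 2 dogs are required")
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")

    post = _FlowPosterior(
        X=design.fixed,
        pos=counts["positive"].to_numpy(dtype=float),
        tot=counts["total"].to_numpy(dtype=float),
        dog_index=design.dog_index,
        ig=design.ig_indicator,
        n_dogs=design.n_dogs,
        beta_prior_sd=beta_prior_sd,
    )

    # moment-based start: empirical logit of the pooled proportion
    pbar = float(
        np.clip(counts["positive"].sum() / counts["total"].sum(), 1e-4, 1 - 1e-4)
    )
    init = np.zeros(post.dim)
    init[0] = math.log(pbar / (1 - pbar))
    init[post.P + 2 * post.n_dogs :] = [math.log(0.3), math.log(0.3), 0.0]

    raw = sample_posterior(
        post.logp_grad,
        init,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
        max_leapfrog=max_leapfrog,
        init_jitter=0.1,
    )

    names = (
        [f"beta[{t}]" for t in design.term_names]
        + [f"u[{d}]" for d in design.dog_ids]
        + [f"v[{d}]" for d in design.dog_ids]
        + ["sigma_u", "sigma_v", "rho"]
    )
    con = np.empty_like(raw.draws)
    for c in range(raw.n_chains):
        for i in range(raw.n_iterations):
            con[c, i] = post.constrain(raw.draws[c, i])
    draws = PosteriorDraws(con, names, dict(raw.sampler_meta))
    draws.sampler_meta["model"] = "flow_binomial"
    draws.sampler_meta["term_names"] = list(design.term_names)
    if check:
        check_convergence(draws)
    return draws


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def _beta_matrix(draws: PosteriorDraws, design: DesignMatrix) -> np.ndarray:
    return draws.stacked_matrix([f"beta[{t}]" for t in design.term_names])


def predict_proportions(
    draws: PosteriorDraws,
    design: DesignMatrix,
    grid: list[dict[str, str]],
    interval_mass: float = 0.90,
    *,
    marginalize: bool = False,
    n_marginal: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior predicted coating proportion for each factor combination.

    Population mode (default) sets random effects to zero; with
    `marginalize=True` the proportion is integrated over new-dog random
    effects by Monte Carlo over Normal(0, Sigma) using each draw's
    (sigma_u, sigma_v, rho).
    """
    beta = _beta_matrix(draws, design)
    alpha = (1.0 - interval_mass) / 2.0
    lo_name = f"lo{int(round(interval_mass * 100))}"
    hi_name = f"hi{int(round(interval_mass * 100))}"
    rng = np.random.default_rng(seed)

    rows = []
    for cell in grid:
        x = design.encode(cell)
        eta = beta @ x
        if marginalize:
            su = draws.stacked("sigma_u")
            sv = draws.stacked("sigma_v")
            rho = draws.stacked("rho")
            z = rng.standard_normal((n_marginal, 2))
            ig = 1.0 if cell.get("ig_class") == _slope_level(design) else 0.0
            re = (
                su[:, None] * z[None, :, 0]
                + ig
                * sv[:, None]
                * (
                    rho[:, None] * z[None, :, 0]
                    + np.sqrt(np.maximum(1 - rho[:, None] ** 2, 0.0)) * z[None, :, 1]
                )
            )
            p = (1.0 / (1.0 + np.exp(-(eta[:, None] + re)))).mean(axis=1)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
        rows.append(
            {
                **cell,
                "median": float(np.median(p)),
                lo_name: float(np.quantile(p, alpha)),
                hi_name: float(np.quantile(p, 1 - alpha)),
            }
        )
    return pd.DataFrame(rows)


def _slope_level(design: DesignMatrix) -> str | None:
    levels = design.levels.get("ig_class")
    return levels[0] if levels else None


def glmm_r2(draws: PosteriorDraws, design: DesignMatrix) -> tuple[float, float]:
    """Nakagawa marginal/conditional coefficients of determination for the
    binomial-logit GLMM, computed per draw and summarized by the median.

    The distribution-specific variance is the logistic pi^2/3; the
    random-effect variance averages var(u + v*ig) over the design rows,
    including the covariance term for rows with the Ig slope active.
    """
    beta = _beta_matrix(draws, design)
    eta = beta @ design.fixed.T                       # draws x rows
    var_fixed = eta.var(axis=1)
    su = draws.stacked("sigma_u")
    sv = draws.stacked("sigma_v")
    rho = draws.stacked("rho")
    ig_mean = float(design.ig_indicator.mean())       # ig is 0/1 so ig^2 = ig
    var_re = su**2 + sv**2 * ig_mean + 2.0 * rho * su * sv * ig_mean
    denom = var_fixed + var_re + math.pi**2 / 3.0
    marginal = float(np.median(var_fixed / denom))
    conditional = float(np.median((var_fixed + var_re) / denom))
    return marginal, conditional


def flow_summary_table(
    draws: PosteriorDraws, design: DesignMatrix, interval: float = 0.90
) -> pd.DataFrame:
    """Per-term posterior summary (median, CI bounds, R-hat, ESS)."""
    summ = draws.summary(interval)
    terms = [f"beta[{t}]" for t in design.term_names] + [
        "sigma_u",
        "sigma_v",
        "rho",
    ]
    out = summ.loc[terms].reset_index(names="term")
    return out
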