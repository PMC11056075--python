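"""Bayesian normal-normal hierarchical meta-analysis by numerical integration.

Model (NNHM): study log effects ``y_i ~ N(theta_i, se_i^2)`` with
``theta_i ~ N(mu, tau^2)``; priors ``mu ~ N(m0, s0^2)`` (default N(0, 2^2))
and ``tau ~`` half-normal or half-Cauchy with scale 0.5.

Everything is deterministic quadrature — no MCMC. Conditional on tau the
model is conjugate: ``mu | tau, y`` is normal and ``p(y | tau)`` has a closed
form through the rank-one structure of ``cov = diag(se_i^2 + tau^2) +
s0^2 * J``. The one remaining integral over tau is done adaptively on a
compactified axis ``u = tau / (tau + scale)``, giving

* the log marginal likelihood ``log p(y)`` (the Bayes-factor ingredient),
* the discretized posterior ``p(tau | y)`` on a stored grid,
* the marginal posterior of mu as a normal mixture over the tau grid,
* shortest (highest-posterior-density, for unimodal posteriors) credible
  intervals.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special, stats

from .data import MetaAnalysisDataset

__all__ = [
    "PriorFamily",
    "HeterogeneityPrior",
    "EffectPrior",
    "MixtureOfNormals",
    "BayesMetaResults",
    "BayesMetaAnalysis",
    "QuadratureError",
    "prior_density",
    "conditional_mu_posterior",
    "likelihood_given_tau",
    "fit_nnhm",
    "shortest_interval",
]

_LOG2PI = math.log(2.0 * math.pi)


class QuadratureError(RuntimeError):
    """Marginal-likelihood quadrature did not meet its error tolerance."""


class PriorFamily(str, enum.Enum):
    HALF_NORMAL = "half-normal"
    HALF_CAUCHY = "half-cauchy"


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior on the between-study SD tau, supported on [0, inf)."""

    family: PriorFamily
    scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("prior scale must be > 0")
        object.__setattr__(self, "family", PriorFamily(self.family))

    @property
    def _dist(self):
        if self.family is PriorFamily.HALF_NORMAL:
            return stats.halfnorm(scale=self.scale)
        return stats.halfcauchy(scale=self.scale)

    def pdf(self, tau):
        return self._dist.pdf(tau)

    def logpdf(self, tau):
        # analytic forms (hot path inside the quadrature integrand)
        tau = np.asarray(tau, dtype=float)
        s = self.scale
        if self.family is PriorFamily.HALF_NORMAL:
            return math.log(2.0) - 0.5 * math.log(2.0 * math.pi * s * s) - tau**2 / (2.0 * s * s)
        return math.log(2.0 / (math.pi * s)) - np.log1p((tau / s) ** 2)

    def cdf(self, tau):
        return self._dist.cdf(tau)

    @classmethod
    def half_normal(cls, scale: float = 0.5) -> "HeterogeneityPrior":
        return cls(PriorFamily.HALF_NORMAL, scale)

    @classmethod
    def half_cauchy(cls, scale: float = 0.5) -> "HeterogeneityPrior":
        return cls(PriorFamily.HALF_CAUCHY, scale)


@dataclass(frozen=True)
class EffectPrior:
    """Normal prior on the pooled log effect mu."""

    mean: float = 0.0
    sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("effect prior sd must be > 0")


def prior_density(prior: HeterogeneityPrior, tau) -> np.ndarray | float:
    """Density of the heterogeneity prior at ``tau`` (>= 0; negative errors)."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    out = prior.pdf(tau_arr)
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def conditional_mu_posterior(
    dataset: MetaAnalysisDataset, effect_prior: EffectPrior, tau: float
) -> tuple[float, float]:
    """Exact normal posterior of mu given tau: returns (mean, sd).

    Conjugate update: precision ``P = sum 1/(se_i^2 + tau^2) + 1/s0^2``,
    mean ``(sum w_i y_i + m0 / s0^2) / P``.
    """
    se2 = dataset.se**2
    w = 1.0 / (se2 + tau**2)
    prec = float(np.sum(w) + 1.0 / effect_prior.sd**2)
    mean = float((np.sum(w * dataset.y) + effect_prior.mean / effect_prior.sd**2) / prec)
    return mean, prec**-0.5


def _log_lik_tau(
    y: np.ndarray, se: np.ndarray, effect_prior: EffectPrior, tau: np.ndarray
) -> np.ndarray:
    """log p(y | tau), vectorized over tau.

    y | tau ~ N(m0 * 1, D + s0^2 * J) with D = diag(se^2 + tau^2). The
    determinant and quadratic form use the matrix-determinant lemma and
    Sherman–Morrison, so no dense matrix is formed:

    |cov| = |D| * (1 + s0^2 * sum 1/d_i)
    r' cov^-1 r = sum r_i^2/d_i - s0^2 (sum r_i/d_i)^2 / (1 + s0^2 sum 1/d_i)
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    d = se[None, :] ** 2 + tau[:, None] ** 2  # (T, k)
    r = y - effect_prior.mean
    s0sq = effect_prior.sd**2
    inv_d = 1.0 / d
    c = 1.0 + s0sq * inv_d.sum(axis=1)
    quad = (r**2 * inv_d).sum(axis=1) - s0sq * (r * inv_d).sum(axis=1) ** 2 / c
    logdet = np.log(d).sum(axis=1) + np.log(c)
    return -0.5 * (len(y) * _LOG2PI + logdet + quad)


def likelihood_given_tau(
    dataset: MetaAnalysisDataset, effect_prior: EffectPrior, tau
) -> np.ndarray | float:
    """Log marginal likelihood of the data given tau (mu integrated out)."""
    out = _log_lik_tau(dataset.y, dataset.se, effect_prior, tau)
    return float(out[0]) if np.isscalar(tau) else out


# ---------------------------------------------------------------------------
# posterior-of-mu mixture


class MixtureOfNormals:
    """Finite normal mixture with pdf/cdf/ppf; the marginal mu posterior."""

    def __init__(self, weights, means, sds):
        self.weights = np.asarray(weights, dtype=float)
        self.means = np.asarray(means, dtype=float)
        self.sds = np.asarray(sds, dtype=float)
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("mixture weights must sum to a positive number")
        self.weights = self.weights / total
        # drop numerically irrelevant components (mass error <= ~1e-10)
        keep = self.weights > 1e-13
        if keep.sum() and not keep.all():
            self.weights = self.weights[keep] / self.weights[keep].sum()
            self.means = self.means[keep]
            self.sds = self.sds[keep]
        lo = float(np.min(self.means - 12 * self.sds))
        hi = float(np.max(self.means + 12 * self.sds))
        self._support = (lo, hi)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        out = np.sum(self.weights * np.exp(-0.5 * z**2) / (self.sds * math.sqrt(2 * math.pi)), axis=-1)
        return out

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        return np.sum(self.weights * special.ndtr(z), axis=-1)

    def _bracket_grid(self):
        # cached cdf grid: brackets quantile root-finding to a narrow cell
        if not hasattr(self, "_grid_x"):
            lo, hi = self._support
            self._grid_x = np.linspace(lo, hi, 1025)
            self._grid_c = self.cdf(self._grid_x)
        return self._grid_x, self._grid_c

    def ppf(self, q: float) -> float:
        if not 0.0 < q < 1.0:
            raise ValueError("quantile level must be in (0, 1)")
        x, c = self._bracket_grid()
        i = int(np.clip(np.searchsorted(c, q), 1, len(x) - 1))
        lo, hi = x[i - 1], x[i]
        if not (self.cdf(lo) - q) * (self.cdf(hi) - q) <= 0:
            lo, hi = self._support
        return float(optimize.brentq(lambda t: self.cdf(t) - q, lo, hi, xtol=1e-12))

    @property
    def mean(self) -> float:
        return float(np.sum(self.weights * self.means))

    @property
    def median(self) -> float:
        return self.ppf(0.5)

    def is_unimodal(self, n_grid: int = 2001) -> bool:
        lo = float(np.min(self.means - 6 * self.sds))
        hi = float(np.max(self.means + 6 * self.sds))
        x = np.linspace(lo, hi, n_grid)
        dens = self.pdf(x)
        d = np.diff(dens)
        # count strict sign changes of the derivative from + to -
        sign = np.sign(d)
        sign = sign[sign != 0]
        flips = np.sum((sign[:-1] > 0) & (sign[1:] < 0))
        return int(flips) <= 1


def shortest_interval(dist, level: float = 0.95, full_output: bool = False):
    """Shortest interval containing ``level`` probability mass.

    ``dist`` must expose ``cdf`` and ``ppf``. For unimodal densities this is
    the highest-posterior-density interval. The lower endpoint's mass
    ``a in [0, 1 - level]`` is found by bounded scalar minimization of
    ``ppf(a + level) - ppf(a)``. For multimodal densities (where the true HPD
    region can be a union) the shortest *single* interval is returned and a
    flag is set.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    slack = 1.0 - level

    def width(a: float) -> float:
        a = min(max(a, 1e-12), slack - 1e-12) if slack > 2e-12 else a
        return dist.ppf(a + level) - dist.ppf(a)

    # coarse scan first: the width need not be unimodal in a when the
    # density is multimodal, so a pure local search could stall
    scan = np.linspace(0.0, slack, 33)
    widths = [width(a) for a in scan]
    i0 = int(np.argmin(widths))
    lo_b = scan[max(i0 - 1, 0)]
    hi_b = scan[min(i0 + 1, len(scan) - 1)]
    res = optimize.minimize_scalar(
        width, bounds=(lo_b, hi_b), method="bounded", options={"xatol": 1e-10}
    )
    a_opt = float(np.clip(res.x, 1e-12, slack - 1e-12)) if slack > 2e-12 else float(res.x)
    # polish against the symmetric candidate to be safe on symmetric densities
    candidates = [a_opt, slack / 2.0]
    a_best = min(candidates, key=width)
    low = dist.ppf(a_best)
    high = dist.ppf(a_best + level)
    if full_output:
        mass = float(dist.cdf(high) - dist.cdf(low))
        multimodal = not dist.is_unimodal() if hasattr(dist, "is_unimodal") else False
        return (low, high), mass, multimodal
    return low, high


# ---------------------------------------------------------------------------
# the model


@dataclass
class BayesMetaResults:
    """Posterior summaries and marginal likelihood of one NNHM fit."""

    log_marginal_likelihood: float
    tau_grid: np.ndarray
    tau_weights: np.ndarray
    mu_posterior: MixtureOfNormals
    mu_median: float
    mu_mean: float
    cri_low: float
    cri_high: float
    tau_median: float
    level: float
    quad_abserr: float
    converged: bool
    multimodal: bool = False
    label: str = ""
    metric: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def cri(self) -> tuple[float, float]:
        return (self.cri_low, self.cri_high)

    @property
    def excludes_null(self) -> bool:
        return not (self.cri_low <= 0.0 <= self.cri_high)

    def exp_summary(self) -> dict[str, float]:
        return {
            "estimate": float(np.exp(self.mu_median)),
            "cri_low": float(np.exp(self.cri_low)),
            "cri_high": float(np.exp(self.cri_high)),
        }

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "metric": self.metric,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "mu_median": self.mu_median,
            "mu_mean": self.mu_mean,
            "cri_low": self.cri_low,
            "cri_high": self.cri_high,
            "tau_median": self.tau_median,
            "level": self.level,
            "quad_abserr": self.quad_abserr,
            "converged": self.converged,
            "excludes_null": self.excludes_null,
        }
        for key, val in self.exp_summary().items():
            d[f"exp_{key}"] = val
        return d

    def summary(self) -> str:
        lines = [
            f"NNHM fit {self.label or ''}".rstrip(),
            f"  log marginal likelihood  {self.log_marginal_likelihood: .6f}",
            f"  mu  median {self.mu_median: .4f}   mean {self.mu_mean: .4f}",
            f"  {100 * self.level:.0f}% shortest CrI  [{self.cri_low: .4f}, {self.cri_high: .4f}]",
            f"  exp(mu) {np.exp(self.mu_median):.4f}  "
            f"[{np.exp(self.cri_low):.4f}, {np.exp(self.cri_high):.4f}]",
            f"  tau median {self.tau_median:.4f}",
            f"  excludes null: {self.excludes_null}   converged: {self.converged}",
        ]
        return "\n".join(lines)


class BayesMetaAnalysis:
    """Normal-normal hierarchical Bayesian meta-analysis model.

    Parameters
    ----------
    dataset : MetaAnalysisDataset
        Log-scale study effects with standard errors (k >= 1; a single study
        is fitted with the prior dominating rather than refused).
    het_prior : HeterogeneityPrior
        Prior on tau; default half-normal with scale 0.5.
    effect_prior : EffectPrior
        Normal prior on mu; default N(0, 2).
    grid_size : int
        Number of stored tau points for the discretized posterior (>= 201).
    level : float
        Credible level for the shortest interval (default 0.95).
    log_tol : float
        Absolute tolerance on the log marginal likelihood; fits whose
        quadrature error estimate exceeds it are flagged unconverged.
    """

    def __init__(
        self,
        dataset: MetaAnalysisDataset,
        het_prior: HeterogeneityPrior | None = None,
        effect_prior: EffectPrior | None = None,
        grid_size: int = 401,
        level: float = 0.95,
        log_tol: float = 1e-8,
    ):
        if dataset.k < 1:
            raise ValueError("empty dataset")
        self.dataset = dataset
        self.het_prior = het_prior or HeterogeneityPrior.half_normal(0.5)
        self.effect_prior = effect_prior or EffectPrior(0.0, 2.0)
        if grid_size < 201:
            raise ValueError("grid_size must be >= 201")
        self.grid_size = int(grid_size)
        self.level = float(level)
        self.log_tol = float(log_tol)

    # u = tau / (tau + s)  <=>  tau = s u / (1 - u); dtau = s / (1-u)^2 du
    def _tau_of_u(self, u: np.ndarray) -> np.ndarray:
        s = self.het_prior.scale
        return s * u / (1.0 - u)

    def _log_integrand_u(self, u: np.ndarray) -> np.ndarray:
        """log of p(y|tau(u)) p(tau(u)) |dtau/du| on the unit interval."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        s = self.het_prior.scale
        tau = self._tau_of_u(u)
        ll = _log_lik_tau(self.dataset.y, self.dataset.se, self.effect_prior, tau)
        lp = self.het_prior.logpdf(tau)
        jac = np.log(s) - 2.0 * np.log1p(-u)
        return ll + lp + jac

    def fit(self, raise_on_failure: bool = False) -> BayesMetaResults:
        n = self.grid_size
        # open midpoint grid avoids the u = 1 singularity of the substitution
        u_grid = (np.arange(n) + 0.5) / n
        log_f = self._log_integrand_u(u_grid)
        shift = float(np.max(log_f))

        def integrand(u: float) -> float:
            return float(np.exp(self._log_integrand_u(u)[0] - shift))

        integral, abserr = integrate.quad(
            integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-10, limit=200
        )
        if integral <= 0:
            if raise_on_failure:
                raise QuadratureError("marginal likelihood quadrature returned <= 0")
            integral = float(np.sum(np.exp(log_f - shift)) / n)
            abserr = np.inf
        log_ml = shift + math.log(integral)
        log_err = abserr / integral  # abs error on the log scale (delta method)
        converged = bool(np.isfinite(log_err) and log_err <= max(self.log_tol, 1e-12))
        if not converged and raise_on_failure:
            raise QuadratureError(
                f"quadrature error {log_err:.3e} exceeds tolerance {self.log_tol:.1e}"
            )

        # discretized tau posterior on the stored grid (equal du cells)
        w = np.exp(log_f - shift)
        w = w / np.sum(w)
        tau_grid = self._tau_of_u(u_grid)

        # mu posterior: mixture over tau of exact conditional normals
        se2 = self.dataset.se**2
        prec_i = 1.0 / (se2[None, :] + tau_grid[:, None] ** 2)
        prec = prec_i.sum(axis=1) + 1.0 / self.effect_prior.sd**2
        means = (
            (prec_i * self.dataset.y[None, :]).sum(axis=1)
            + self.effect_prior.mean / self.effect_prior.sd**2
        ) / prec
        sds = prec**-0.5
        mixture = MixtureOfNormals(w, means, sds)

        (lo, hi), mass, multimodal = shortest_interval(
            mixture, self.level, full_output=True
        )
        cum = np.cumsum(w)
        tau_median = float(np.interp(0.5, cum, tau_grid))

        return BayesMetaResults(
            log_marginal_likelihood=float(log_ml),
            tau_grid=tau_grid,
            tau_weights=w,
            mu_posterior=mixture,
            mu_median=mixture.median,
            mu_mean=mixture.mean,
            cri_low=float(lo),
            cri_high=float(hi),
            tau_median=tau_median,
            level=self.level,
            quad_abserr=float(log_err),
            converged=converged,
            multimodal=bool(multimodal),
            label=self.dataset.label,
            metric=self.dataset.metric.value,
            extra={"cri_mass": mass},
        )


def fit_nnhm(
    dataset: MetaAnalysisDataset,
    het_prior: HeterogeneityPrior | None = None,
    effect_prior: EffectPrior | None = None,
    **config,
) -> BayesMetaResults:
    """Fit the NNHM by quadrature; convenience wrapper over BayesMetaAnalysis."""
    return BayesMetaAnalysis(dataset, het_prior, effect_prior, **config).fit()
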