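"""Frequentist pooled estimators for random-effects meta-analysis.

Three estimators of the pooled log effect mu:

* ``DSL`` — DerSimonian–Laird: moment estimate of the between-study variance
  tau^2, inverse-variance random-effects weights, z-based 95% CI.
* ``HKSJ_DSL`` — Hartung–Knapp–Sidik–Jonkman variance correction applied to
  the DSL point estimate: the pooled variance is replaced by a weighted
  dispersion estimate and the CI uses t_{k-1} quantiles.
* ``IVHET`` — the inverse-variance heterogeneity model of Doi and colleagues:
  fixed-effect weights, variance inflated by tau^2 (DSL moment estimate), so
  the CI widens without re-weighting studies.

All estimation is on the natural-log scale; ``excludes_null`` refers to
OR/RR = 1, i.e. 0 on the log scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import MetaAnalysisDataset

__all__ = [
    "Estimator",
    "FrequentistResults",
    "RandomEffectsMeta",
    "dsl_fit",
    "hksj_fit",
    "ivhet_fit",
]


class Estimator(str, enum.Enum):
    DSL = "DSL"
    HKSJ_DSL = "HKSJ_DSL"
    IVHET = "IVHET"


@dataclass(frozen=True)
class FrequentistResults:
    """Pooled estimate, heterogeneity statistics and 95% CI for one estimator."""

    estimator: Estimator
    mu_hat: float
    se_mu: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    df: float  # inf for z-based intervals
    k: int
    unstable: bool = False  # df = 1 HKSJ intervals are flagged, not refused

    @property
    def excludes_null(self) -> bool:
        """True iff 1 is outside exp([ci_low, ci_high])."""
        return not (self.ci_low <= 0.0 <= self.ci_high)

    @property
    def tau(self) -> float:
        return float(np.sqrt(self.tau2))

    def exp_summary(self) -> dict[str, float]:
        """Estimate and CI exponentiated to the OR/RR scale."""
        return {
            "estimate": float(np.exp(self.mu_hat)),
            "ci_low": float(np.exp(self.ci_low)),
            "ci_high": float(np.exp(self.ci_high)),
        }

    def to_dict(self) -> dict:
        d = {
            "estimator": self.estimator.value,
            "mu_hat": self.mu_hat,
            "se_mu": self.se_mu,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "Q": self.Q,
            "I2": self.I2,
            "df": self.df,
            "k": self.k,
            "excludes_null": self.excludes_null,
        }
        for key, val in self.exp_summary().items():
            d[f"exp_{key}"] = val
        return d

    def summary(self) -> str:
        lines = [
            f"{self.estimator.value} pooled estimate (k={self.k})",
            f"  mu_hat   {self.mu_hat: .4f}  (se {self.se_mu:.4f})",
            f"  95% CI   [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            f"  exp(mu)  {np.exp(self.mu_hat):.4f}  "
            f"[{np.exp(self.ci_low):.4f}, {np.exp(self.ci_high):.4f}]",
            f"  tau2 {self.tau2:.4f}   Q {self.Q:.3f}   I2 {100 * self.I2:.1f}%",
            f"  excludes null: {self.excludes_null}",
        ]
        return "\n".join(lines)


def _dsl_components(y: np.ndarray, se: np.ndarray):
    """Fixed-effect weights, Q and the DSL moment estimate of tau^2."""
    w = 1.0 / se**2
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    if k <= 1:
        return w, Q, 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    return w, Q, float(tau2)


def _i2(Q: float, k: int) -> float:
    if Q <= 0 or k <= 1:
        return 0.0
    return max(0.0, (Q - (k - 1)) / Q)


class RandomEffectsMeta:
    """Frequentist pooling model for one meta-analysis dataset.

    Parameters
    ----------
    dataset : MetaAnalysisDataset
        Study-level log effects with standard errors.

    Examples
    --------
    >>> res = RandomEffectsMeta(dataset).fit(method="dsl")
    >>> res.mu_hat, res.ci_low, res.ci_high
    """

    def __init__(self, dataset: MetaAnalysisDataset):
        if dataset.k < 1:
            raise ValueError("empty dataset")
        self.dataset = dataset
        self.y = dataset.y
        self.se = dataset.se
        if np.any(self.se <= 0):
            raise ValueError("all standard errors must be > 0")

    def fit(self, method: str | Estimator = Estimator.DSL) -> FrequentistResults:
        if not isinstance(method, Estimator):
            method = Estimator(str(method).upper().replace("-", "_"))
        if method is Estimator.DSL:
            return self._fit_dsl()
        if method is Estimator.HKSJ_DSL:
            return self._fit_hksj()
        return self._fit_ivhet()

    def fit_all(self) -> dict[Estimator, FrequentistResults]:
        out = {}
        for est in Estimator:
            if est is Estimator.HKSJ_DSL and self.dataset.k < 2:
                continue
            out[est] = self.fit(est)
        return out

    # -- estimators ---------------------------------------------------------

    def _fit_dsl(self) -> FrequentistResults:
        y, se, k = self.y, self.se, len(self.y)
        _, Q, tau2 = _dsl_components(y, se)
        w_star = 1.0 / (se**2 + tau2)
        mu = float(np.sum(w_star * y) / np.sum(w_star))
        se_mu = float(np.sum(w_star) ** -0.5)
        z = stats.norm.ppf(0.975)
        return FrequentistResults(
            Estimator.DSL, mu, se_mu, mu - z * se_mu, mu + z * se_mu,
            tau2, Q, _i2(Q, k), np.inf, k,
        )

    def _fit_hksj(self) -> FrequentistResults:
        k = len(self.y)
        if k < 2:
            raise ValueError("HKSJ requires at least 2 studies")
        y, se = self.y, self.se
        _, Q, tau2 = _dsl_components(y, se)
        w_star = 1.0 / (se**2 + tau2)
        mu = float(np.sum(w_star * y) / np.sum(w_star))
        v = float(np.sum(w_star * (y - mu) ** 2) / ((k - 1) * np.sum(w_star)))
        se_mu = float(np.sqrt(v))
        t = stats.t.ppf(0.975, df=k - 1)
        return FrequentistResults(
            Estimator.HKSJ_DSL, mu, se_mu, mu - t * se_mu, mu + t * se_mu,
            tau2, Q, _i2(Q, k), k - 1, k, unstable=(k == 2),
        )

    def _fit_ivhet(self) -> FrequentistResults:
        y, se, k = self.y, self.se, len(self.y)
        _, Q, tau2 = _dsl_components(y, se)
        w = 1.0 / se**2
        w_hat = w / np.sum(w)
        mu = float(np.sum(w_hat * y))
        var = float(np.sum(w_hat**2 * (se**2 + tau2)))
        se_mu = float(np.sqrt(var))
        z = stats.norm.ppf(0.975)
        return FrequentistResults(
            Estimator.IVHET, mu, se_mu, mu - z * se_mu, mu + z * se_mu,
            tau2, Q, _i2(Q, k), np.inf, k,
        )


def dsl_fit(dataset: MetaAnalysisDataset) -> FrequentistResults:
    """DerSimonian–Laird random-effects fit (z-based 95% CI)."""
    return RandomEffectsMeta(dataset).fit(Estimator.DSL)


def hksj_fit(dataset: MetaAnalysisDataset) -> FrequentistResults:
    """HKSJ variance-corrected DSL fit (t_{k-1} 95% CI); requires k >= 2."""
    return RandomEffectsMeta(dataset).fit(Estimator.HKSJ_DSL)


def ivhet_fit(dataset: MetaAnalysisDataset) -> FrequentistResults:
    """Inverse-variance heterogeneity (IVhet) fit with DSL tau^2 inflation."""
    return RandomEffectsMeta(dataset).fit(Estimator.IVHET)


def results_frame(fits: dict[Estimator, FrequentistResults]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits.values()])
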