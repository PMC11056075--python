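"""Pooled-vs-separate model comparison for RCT + NRS meta-analyses.

Two data models are compared through their marginal likelihoods:

* *pooled* — all studies (RCT and NRS) share one (mu, tau) NNHM;
* *separate* — the RCT subgroup and the NRS subgroup each get an independent
  NNHM with the same priors, so the separate-model marginal likelihood is the
  product of the two subgroup marginal likelihoods.

The Bayes factor for pooling is ``BF = p(y | pooled) / (p(y_rct | M) *
p(y_nrs | M))``. Decision rule: POOLED if BF > 3, SEPARATE if BF < 1/3, else
INDETERMINATE. Posterior model probability: ``odds = BF * prior_odds``;
``pp = odds / (odds + 1)`` (model prior probabilities default to 0.5/0.5).

The model-averaged posterior of the reported effect is the mixture
``pp * (mu | pooled) + (1 - pp) * (reported effect | separate)``; under the
separate model the reported-effect posterior defaults to the RCT-subgroup mu
posterior (the RCT estimate is the inferential target; NRS act as co-data
whose influence vanishes under conflict). Configurable to the NRS posterior
or an equal RCT/NRS mixture.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .data import Design, MetaAnalysisDataset
from .nnhm import (
    BayesMetaAnalysis,
    BayesMetaResults,
    EffectPrior,
    HeterogeneityPrior,
    MixtureOfNormals,
    PriorFamily,
    shortest_interval,
)

__all__ = [
    "Decision",
    "ModelComparison",
    "BmaEstimate",
    "PoolabilityAnalysis",
    "PoolabilityResults",
    "compare_models",
    "posterior_model_probability",
    "bf_decision",
    "model_average",
    "run_both_priors",
]


class Decision(str, enum.Enum):
    POOLED = "POOLED"
    SEPARATE = "SEPARATE"
    INDETERMINATE = "INDETERMINATE"


def bf_decision(bf_pooled: float, threshold: float = 3.0) -> Decision:
    """BF decision rule; boundary values resolve to INDETERMINATE."""
    if bf_pooled > threshold:
        return Decision.POOLED
    if bf_pooled < 1.0 / threshold:
        return Decision.SEPARATE
    return Decision.INDETERMINATE


def posterior_model_probability(bf: float, prior_prob: float = 0.5) -> float:
    """Posterior probability of the model favoured by ``bf``.

    posterior odds = bf * prior_prob / (1 - prior_prob); returns
    odds / (odds + 1).
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be > 0")
    if not 0.0 < prior_prob < 1.0:
        raise ValueError("prior model probability must be in (0, 1)")
    odds = bf * prior_prob / (1.0 - prior_prob)
    return odds / (odds + 1.0)


@dataclass(frozen=True)
class ModelComparison:
    """Marginal likelihoods, Bayes factors and the pooling decision."""

    log_ml_joint: float
    log_ml_rct: float
    log_ml_nrs: float
    prior_prob_pooled: float = 0.5
    label: str = ""

    @property
    def log_bf_pooled(self) -> float:
        return self.log_ml_joint - (self.log_ml_rct + self.log_ml_nrs)

    @property
    def bf_pooled(self) -> float:
        return math.exp(self.log_bf_pooled)

    @property
    def bf_separate(self) -> float:
        return math.exp(-self.log_bf_pooled)

    @property
    def pp_pooled(self) -> float:
        return posterior_model_probability(self.bf_pooled, self.prior_prob_pooled)

    @property
    def decision(self) -> Decision:
        return bf_decision(self.bf_pooled)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "log_ml_joint": self.log_ml_joint,
            "log_ml_rct": self.log_ml_rct,
            "log_ml_nrs": self.log_ml_nrs,
            "bf_pooled": self.bf_pooled,
            "bf_separate": self.bf_separate,
            "pp_pooled": self.pp_pooled,
            "decision": self.decision.value,
        }


@dataclass
class BmaEstimate:
    """Model-averaged posterior of the reported effect with shortest CrI."""

    weights: tuple[float, float]  # (pooled, separate)
    mixture: MixtureOfNormals
    cri_low: float
    cri_high: float
    point: float  # posterior median
    separate_component: str = "rct"
    multimodal: bool = False

    @property
    def excludes_null(self) -> bool:
        return not (self.cri_low <= 0.0 <= self.cri_high)


def _check_two_designs(dataset: MetaAnalysisDataset) -> None:
    if dataset.n_rct < 1 or dataset.n_nrs < 1:
        raise ValueError(
            f"dataset {dataset.label!r} needs >= 1 RCT and >= 1 NRS for a "
            "pooled-vs-separate comparison "
            f"(has {dataset.n_rct} RCT, {dataset.n_nrs} NRS)"
        )


@dataclass
class PoolabilityResults:
    """Full pooled-vs-separate analysis of one dataset under one tau prior."""

    joint: BayesMetaResults
    rct: BayesMetaResults
    nrs: BayesMetaResults
    comparison: ModelComparison
    bma: BmaEstimate

    def summary(self) -> str:
        c = self.comparison
        lines = [
            f"Poolability analysis {c.label or ''}".rstrip(),
            f"  log ML  joint {c.log_ml_joint: .4f}  rct {c.log_ml_rct: .4f}  "
            f"nrs {c.log_ml_nrs: .4f}",
            f"  BF(pooled) {c.bf_pooled:.3f}   BF(separate) {c.bf_separate:.3f}",
            f"  posterior P(pooled) {c.pp_pooled:.3f}   decision: {c.decision.value}",
            f"  model-averaged median {self.bma.point: .4f}  "
            f"CrI [{self.bma.cri_low: .4f}, {self.bma.cri_high: .4f}]",
        ]
        return "\n".join(lines)


class PoolabilityAnalysis:
    """Should RCT and NRS be pooled? Bayes-factor model comparison + BMA.

    Fits the pooled NNHM and the two single-design NNHMs with identical
    priors, forms the Bayes factor and posterior model probability, applies
    the BF > 3 / < 1/3 rule, and builds the model-averaged posterior.
    """

    def __init__(
        self,
        dataset: MetaAnalysisDataset,
        het_prior: HeterogeneityPrior | None = None,
        effect_prior: EffectPrior | None = None,
        prior_prob_pooled: float = 0.5,
        separate_component: str = "rct",
        **fit_config,
    ):
        _check_two_designs(dataset)
        if separate_component not in ("rct", "nrs", "mixture"):
            raise ValueError("separate_component must be 'rct', 'nrs' or 'mixture'")
        self.dataset = dataset
        self.het_prior = het_prior or HeterogeneityPrior.half_normal(0.5)
        self.effect_prior = effect_prior or EffectPrior(0.0, 2.0)
        self.prior_prob_pooled = float(prior_prob_pooled)
        self.separate_component = separate_component
        self.fit_config = fit_config

    def fit(self) -> PoolabilityResults:
        kw = dict(het_prior=self.het_prior, effect_prior=self.effect_prior)
        joint = BayesMetaAnalysis(self.dataset, **kw, **self.fit_config).fit()
        rct = BayesMetaAnalysis(self.dataset.subset(Design.RCT), **kw, **self.fit_config).fit()
        nrs = BayesMetaAnalysis(self.dataset.subset(Design.NRS), **kw, **self.fit_config).fit()
        comparison = ModelComparison(
            log_ml_joint=joint.log_marginal_likelihood,
            log_ml_rct=rct.log_marginal_likelihood,
            log_ml_nrs=nrs.log_marginal_likelihood,
            prior_prob_pooled=self.prior_prob_pooled,
            label=self.dataset.label,
        )
        bma = self._model_average(comparison, joint, rct, nrs)
        return PoolabilityResults(joint=joint, rct=rct, nrs=nrs, comparison=comparison, bma=bma)

    def _model_average(
        self,
        comparison: ModelComparison,
        joint: BayesMetaResults,
        rct: BayesMetaResults,
        nrs: BayesMetaResults,
    ) -> BmaEstimate:
        pp = comparison.pp_pooled
        if self.separate_component == "rct":
            parts = [(1.0 - pp, rct.mu_posterior)]
        elif self.separate_component == "nrs":
            parts = [(1.0 - pp, nrs.mu_posterior)]
        else:
            parts = [
                ((1.0 - pp) / 2.0, rct.mu_posterior),
                ((1.0 - pp) / 2.0, nrs.mu_posterior),
            ]
        weights = [pp]
        means = [joint.mu_posterior.means]
        sds = [joint.mu_posterior.sds]
        comp_w = [pp * joint.mu_posterior.weights]
        for w, mix in parts:
            comp_w.append(w * mix.weights)
            means.append(mix.means)
            sds.append(mix.sds)
            weights.append(w)
        mixture = MixtureOfNormals(
            np.concatenate(comp_w), np.concatenate(means), np.concatenate(sds)
        )
        (lo, hi), _mass, multimodal = shortest_interval(mixture, joint.level, full_output=True)
        return BmaEstimate(
            weights=(pp, 1.0 - pp),
            mixture=mixture,
            cri_low=float(lo),
            cri_high=float(hi),
            point=mixture.median,
            separate_component=self.separate_component,
            multimodal=bool(multimodal),
        )


def compare_models(
    dataset: MetaAnalysisDataset,
    het_prior: HeterogeneityPrior | None = None,
    effect_prior: EffectPrior | None = None,
    **fit_config,
) -> ModelComparison:
    """Bayes-factor comparison of pooled vs separate RCT/NRS models."""
    return PoolabilityAnalysis(dataset, het_prior, effect_prior, **fit_config).fit().comparison


def model_average(
    dataset: MetaAnalysisDataset,
    het_prior: HeterogeneityPrior | None = None,
    effect_prior: EffectPrior | None = None,
    **kwargs,
) -> BmaEstimate:
    """Model-averaged posterior of the reported effect with shortest CrI."""
    return PoolabilityAnalysis(dataset, het_prior, effect_prior, **kwargs).fit().bma


def run_both_priors(
    dataset: MetaAnalysisDataset,
    scale: float = 0.5,
    effect_prior: EffectPrior | None = None,
    **kwargs,
) -> dict[PriorFamily, PoolabilityResults | Exception]:
    """Complete analysis under half-normal and half-Cauchy tau priors.

    Per-prior failures are captured and returned in place of results, since
    computability can be prior-specific.
    """
    out: dict[PriorFamily, PoolabilityResults | Exception] = {}
    for family in PriorFamily:
        prior = HeterogeneityPrior(family, scale)
        try:
            out[family] = PoolabilityAnalysis(
                dataset, prior, effect_prior, **kwargs
            ).fit()
        except Exception as err:  # noqa: BLE001 - surfaced to the caller per prior
            out[family] = err
    return out
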