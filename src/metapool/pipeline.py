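"""End-to-end cohort runner and in-package reference fixture.

Runs every estimator (frequentist DSL / HKSJ-DSL / IVhet and the Bayesian
NNHM under both heterogeneity priors) on a cohort of meta-analyses,
classifies frequentist-CI vs Bayesian-CrI agreement about the null, and
tabulates Bayes-factor pooling decisions.

The packaged fixture ``fixtures/table2.csv`` transcribes the published
per-meta-analysis Bayes factors, posterior model probabilities and study
counts of the 50-meta-analysis cohort, and serves as in-package test data
for the decision rule, the posterior-probability identity and the BF
reciprocity check.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MetaAnalysisDataset
from .frequentist import Estimator, RandomEffectsMeta
from .model_selection import Decision, PoolabilityAnalysis, bf_decision, run_both_priors
from .nnhm import EffectPrior, HeterogeneityPrior, PriorFamily

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementCategory",
    "AgreementRecord",
    "FixtureIntegrityError",
    "load_table2_fixture",
    "summarize_fixture",
    "run_cohort",
    "CohortReport",
]


class FixtureIntegrityError(ValueError):
    """The packaged fixture violates one of its structural invariants."""


class AgreementCategory(str, enum.Enum):
    BOTH_EXCLUDE = "BOTH_EXCLUDE"
    FREQ_ONLY = "FREQ_ONLY"
    BAYES_ONLY = "BAYES_ONLY"
    NEITHER = "NEITHER"


@dataclass(frozen=True)
class AgreementRecord:
    """Does the frequentist CI / Bayesian CrI exclude the null (OR or RR = 1)?"""

    label: str
    freq_excludes_null: bool
    bayes_excludes_null: bool

    @property
    def category(self) -> AgreementCategory:
        if self.freq_excludes_null and self.bayes_excludes_null:
            return AgreementCategory.BOTH_EXCLUDE
        if self.freq_excludes_null:
            return AgreementCategory.FREQ_ONLY
        if self.bayes_excludes_null:
            return AgreementCategory.BAYES_ONLY
        return AgreementCategory.NEITHER


# ---------------------------------------------------------------------------
# fixture


def load_table2_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate the transcribed published per-meta-analysis table."""
    if path is None:
        ref = resources.files("metapool") / "fixtures" / "table2.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if len(df) != 50:
        raise FixtureIntegrityError(f"fixture must have 50 rows, found {len(df)}")
    bad = df[df.k_total != df.k_rct + df.k_nrs]
    if not bad.empty:
        raise FixtureIntegrityError(
            f"rows where total != RCT + NRS: {bad.author.tolist()}"
        )
    if not df.metric.isin(["OR", "RR"]).all():
        raise FixtureIntegrityError("metric must be OR or RR in every row")
    return df


def _pp_identity_ok(bf: float, pp: float, ndec: int = 3) -> bool:
    """Is printed pp consistent with bf/(bf+1), given both are rounded?

    The printed BF represents an interval bf +/- 0.0005; the identity holds
    if the printed pp is within 0.0005 of pp(b) for some b in that interval.
    """
    half = 0.5 * 10.0**-ndec
    lo, hi = max(bf - half, 1e-12), bf + half
    pp_lo, pp_hi = lo / (lo + 1.0), hi / (hi + 1.0)
    return pp_lo - half <= pp <= pp_hi + half


def _reciprocity_ok(bf_pooled: float, bf_separate: float, ndec: int = 3) -> bool:
    """Is pooled BF x separate BF compatible with 1 at printed precision?"""
    half = 0.5 * 10.0**-ndec
    lo = max(bf_pooled - half, 1e-12) * max(bf_separate - half, 1e-12)
    hi = (bf_pooled + half) * (bf_separate + half)
    return lo <= 1.0 <= hi


def summarize_fixture(df: pd.DataFrame | None = None, threshold: float = 3.0) -> dict:
    """Decision counts and descriptive statistics from the fixture.

    Applies the BF decision rule to each printed pooled Bayes factor, checks
    the row-wise pp = bf/(bf+1) identity and pooled/separate reciprocity at
    3-decimal precision, and computes cohort descriptors (study counts, RCT
    proportion).
    """
    if df is None:
        df = load_table2_fixture()
    out: dict = {"n_rows": int(len(df))}
    for prior, suffix in (("half_normal", "hn"), ("half_cauchy", "hc")):
        bf_col, pp_col, sep_col = (
            f"bf_pooled_{suffix}",
            f"pp_pooled_{suffix}",
            f"bf_separate_{suffix}",
        )
        sub = df.dropna(subset=[bf_col])
        decisions = [bf_decision(bf, threshold) for bf in sub[bf_col]]
        metric = sub.metric.tolist()
        counts = {
            "n_computable": int(len(sub)),
            "pooled": sum(d is Decision.POOLED for d in decisions),
            "separate": sum(d is Decision.SEPARATE for d in decisions),
            "indeterminate": sum(d is Decision.INDETERMINATE for d in decisions),
            "pooled_by_metric": {
                m: sum(
                    d is Decision.POOLED and met == m
                    for d, met in zip(decisions, metric)
                )
                for m in ("OR", "RR")
            },
        }
        pp_bad = [
            str(a)
            for a, bf, pp in zip(sub.author, sub[bf_col], sub[pp_col])
            if not _pp_identity_ok(bf, pp)
        ]
        recip_bad = [
            str(a)
            for a, b1, b2 in zip(sub.author, sub[bf_col], sub[sep_col])
            if not _reciprocity_ok(b1, b2)
        ]
        counts["pp_identity_failures"] = pp_bad
        counts["reciprocity_failures"] = recip_bad
        out[prior] = counts
    k = df.k_total
    prop = df.k_rct / df.k_total
    out["study_counts"] = {
        "median": float(k.median()),
        "min": int(k.min()),
        "max": int(k.max()),
        "q1": float(k.quantile(0.25)),
        "q3": float(k.quantile(0.75)),
    }
    out["rct_proportion"] = {
        "median": float(prop.median()),
        "min": float(prop.min()),
        "max": float(prop.max()),
    }
    out["metric_counts"] = df.metric.value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# cohort runner


@dataclass
class CohortReport:
    """Per-dataset results plus cohort-level tabulations."""

    per_dataset: pd.DataFrame
    model_comparison: pd.DataFrame
    summary: dict
    failures: list[dict] = field(default_factory=list)


def run_cohort(
    datasets: list[MetaAnalysisDataset],
    scale: float = 0.5,
    effect_prior: EffectPrior | None = None,
    estimator: Estimator | str = Estimator.DSL,
    level: float = 0.95,
    **fit_config,
) -> CohortReport:
    """Fit every estimator on every dataset and tabulate agreement/decisions.

    Per-dataset failures are logged and excluded from denominators, with
    explicit failure records kept in the report.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if not isinstance(estimator, Estimator):
        estimator = Estimator(str(estimator).upper().replace("-", "_"))
    rows, comp_rows, failures = [], [], []
    tau_dsl: list[float] = []
    for ds in datasets:
        row: dict = {"label": ds.label, "metric": ds.metric.value, "k": ds.k,
                     "k_rct": ds.n_rct, "k_nrs": ds.n_nrs}
        try:
            freq = RandomEffectsMeta(ds).fit_all()
        except Exception as err:  # noqa: BLE001
            failures.append({"label": ds.label, "stage": "frequentist", "error": str(err)})
            logger.warning("%s: frequentist fit failed: %s", ds.label, err)
            continue
        for est, res in freq.items():
            p = est.value.lower()
            row.update({
                f"{p}_mu": res.mu_hat, f"{p}_ci_low": res.ci_low,
                f"{p}_ci_high": res.ci_high, f"{p}_excludes_null": res.excludes_null,
            })
        row["dsl_tau"] = freq[Estimator.DSL].tau
        tau_dsl.append(freq[Estimator.DSL].tau)

        both = run_both_priors(ds, scale=scale, effect_prior=effect_prior, level=level,
                               **fit_config)
        for family, res in both.items():
            p = "hn" if family is PriorFamily.HALF_NORMAL else "hc"
            if isinstance(res, Exception):
                failures.append({"label": ds.label, "stage": f"bayes_{p}", "error": str(res)})
                logger.warning("%s (%s): Bayesian fit failed: %s", ds.label, p, res)
                row[f"{p}_failed"] = True
                continue
            row.update({
                f"{p}_mu_median": res.joint.mu_median,
                f"{p}_cri_low": res.bma.cri_low,
                f"{p}_cri_high": res.bma.cri_high,
                f"{p}_bayes_excludes_null": res.bma.excludes_null,
                f"{p}_bf_pooled": res.comparison.bf_pooled,
                f"{p}_pp_pooled": res.comparison.pp_pooled,
                f"{p}_decision": res.comparison.decision.value,
                f"{p}_failed": False,
            })
            comp_rows.append({"label": ds.label, "prior": family.value,
                              **{k: v for k, v in res.comparison.to_dict().items()
                                 if k != "label"},
                              "k": ds.k, "k_rct": ds.n_rct, "k_nrs": ds.n_nrs,
                              "metric": ds.metric.value})
            freq_excl = freq[estimator].excludes_null if estimator in freq else None
            if freq_excl is not None:
                rec = AgreementRecord(ds.label, freq_excl, res.bma.excludes_null)
                row[f"{p}_agreement"] = rec.category.value
        rows.append(row)

    per_dataset = pd.DataFrame(rows)
    model_comparison = pd.DataFrame(comp_rows)
    summary: dict = {
        "n_datasets": len(datasets),
        "n_fitted": int(len(per_dataset)),
        "n_failures": len(failures),
        "dsl_tau_median": float(np.median(tau_dsl)) if tau_dsl else float("nan"),
        "dsl_tau_iqr": (
            [float(np.percentile(tau_dsl, 25)), float(np.percentile(tau_dsl, 75))]
            if tau_dsl else [float("nan")] * 2
        ),
    }
    for p in ("hn", "hc"):
        col = f"{p}_agreement"
        if col in per_dataset:
            cats = per_dataset[col].dropna()
            summary[f"{p}_agreement_counts"] = {
                c.value: int((cats == c.value).sum()) for c in AgreementCategory
            }
        dcol = f"{p}_decision"
        if dcol in per_dataset:
            dec = per_dataset[dcol].dropna()
            summary[f"{p}_decision_counts"] = {
                d.value: int((dec == d.value).sum()) for d in Decision
            }
    return CohortReport(per_dataset=per_dataset, model_comparison=model_comparison,
                        summary=summary, failures=failures)
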