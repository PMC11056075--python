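"""Seeded generator of synthetic RCT+NRS meta-analytic cohorts.

Emulates the cohort structure of binary-outcome critical-care meta-analyses
mixing randomized trials and non-randomized studies: about 9 studies per
meta-analysis (range 2-60), roughly a third of them RCTs, between-study
heterogeneity tau around 0.25 on the log scale, with an optional additive
NRS bias term for conflict scenarios.

Reproducibility: a single master seed spawns per-dataset child seeds through
``numpy.random.SeedSequence([seed, index])``, so any one dataset can be
regenerated without generating the whole cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit, logit

from .data import (
    ArmCounts,
    Design,
    IncomputableStudyError,
    Metric,
    MetaAnalysisDataset,
    Study,
    write_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["SimulationMode", "SyntheticConfig", "generate_meta", "generate_cohort", "write_cohort"]


class SimulationMode:
    BINOMIAL = "BINOMIAL"
    NORMAL = "NORMAL"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the cohort being emulated.

    ``k_rct``/``k_nrs`` may be fixed; when None, the per-meta study count is
    drawn from a discrete log-normal (median 9, clipped to [2, 60]) and the
    RCT share from Beta(2, 4) (median near 0.33), always keeping at least one
    study of each design.
    """

    n_meta: int = 50
    k_rct: int | None = None
    k_nrs: int | None = None
    mu_true: float = math.log(0.75)  # moderate protective effect on log scale
    tau_true: float = 0.25
    delta_nrs: float = 0.0
    arm_size_range: tuple[int, int] = (20, 500)
    p_ctrl_range: tuple[float, float] = (0.05, 0.40)
    mode: str = SimulationMode.BINOMIAL
    metric: Metric = Metric.OR
    seed: int = 0
    # NORMAL mode: se_i = se_scale / sqrt(chi2_{se_df})  (inverse-chi draw)
    se_scale: float = 0.55
    se_df: int = 4

    def __post_init__(self) -> None:
        if self.tau_true < 0:
            raise ValueError("tau_true must be >= 0")
        if self.arm_size_range[0] < 2:
            raise ValueError("arm sizes must be >= 2")
        if not (0.0 < self.p_ctrl_range[0] <= self.p_ctrl_range[1] < 1.0):
            raise ValueError("control event probabilities must lie in (0, 1)")
        if self.mode not in (SimulationMode.BINOMIAL, SimulationMode.NORMAL):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "metric", Metric(self.metric))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["metric"] = self.metric.value
        d["arm_size_range"] = list(self.arm_size_range)
        d["p_ctrl_range"] = list(self.p_ctrl_range)
        return d


def _rng_for(config: SyntheticConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(index)]))


def _draw_design_counts(config: SyntheticConfig, rng: np.random.Generator) -> tuple[int, int]:
    if config.k_rct is not None and config.k_nrs is not None:
        return config.k_rct, config.k_nrs
    k = int(np.clip(np.rint(np.exp(rng.normal(math.log(9.0), 0.75))), 2, 60))
    frac = rng.beta(2.0, 4.0)
    k_rct = int(np.clip(np.rint(frac * k), 1, k - 1))
    return k_rct, k - k_rct


class _RejectDraw(Exception):
    """Internal: this (theta, p_ctrl) draw implies an invalid probability or
    an uninformative table; redraw the whole study."""


def _draw_binomial_study(
    config: SyntheticConfig, rng: np.random.Generator, theta: float
) -> ArmCounts:
    """One attempt at a study's 2x2 table with true log effect theta."""
    p_ctrl = rng.uniform(*config.p_ctrl_range)
    if config.metric is Metric.OR:
        p_treat = float(expit(logit(p_ctrl) + theta))
    else:
        p_treat = p_ctrl * math.exp(theta)
        if not 0.0 < p_treat < 1.0:
            raise _RejectDraw
    n1 = int(rng.integers(config.arm_size_range[0], config.arm_size_range[1] + 1))
    n2 = int(rng.integers(config.arm_size_range[0], config.arm_size_range[1] + 1))
    a = int(rng.binomial(n1, p_treat))
    c = int(rng.binomial(n2, p_ctrl))
    if a == 0 and c == 0:  # carries no effect information in either metric
        raise _RejectDraw
    return ArmCounts(a, n1, c, n2)


def generate_meta(config: SyntheticConfig, index: int = 0) -> MetaAnalysisDataset:
    """One synthetic meta-analysis, fully reproducible from (seed, index)."""
    rng = _rng_for(config, index)
    k_rct, k_nrs = _draw_design_counts(config, rng)
    designs = [Design.RCT] * k_rct + [Design.NRS] * k_nrs
    studies: list[Study] = []
    for i, design in enumerate(designs):
        shift = config.delta_nrs if design is Design.NRS else 0.0
        sid = f"{design.value.lower()}{i + 1:02d}"
        if config.mode == SimulationMode.BINOMIAL:
            n_reject = 0
            for _ in range(10000):
                # theta is part of the rejected draw: an extreme latent
                # effect can make every control risk invalid in RR mode
                theta = rng.normal(config.mu_true + shift, config.tau_true)
                try:
                    counts = _draw_binomial_study(config, rng, theta)
                    studies.append(Study.from_counts(sid, design, counts, config.metric))
                    break
                except (_RejectDraw, IncomputableStudyError):
                    n_reject += 1
                    continue
            else:
                raise RuntimeError("rejection sampling failed; check config ranges")
            if n_reject:
                logger.debug("meta %d study %s: %d rejected draws", index, sid, n_reject)
        else:
            theta = rng.normal(config.mu_true + shift, config.tau_true)
            se = config.se_scale / math.sqrt(rng.chisquare(config.se_df))
            y = rng.normal(theta, se)
            studies.append(Study(sid, design, y, se))
    return MetaAnalysisDataset(
        label=f"sim-{config.seed}-{index:03d}", metric=config.metric, studies=studies
    )


def generate_cohort(config: SyntheticConfig) -> list[MetaAnalysisDataset]:
    """``n_meta`` independent synthetic meta-analyses."""
    if config.n_meta < 1:
        raise ValueError("n_meta must be >= 1")
    return [generate_meta(config, i) for i in range(config.n_meta)]


def write_cohort(config: SyntheticConfig, out_dir: str | Path) -> list[Path]:
    """Write a cohort as effect-schema CSVs plus a YAML manifest of the config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, ds in enumerate(generate_cohort(config)):
        path = out_dir / f"{ds.label}.csv"
        write_dataset(ds, path)
        paths.append(path)
    manifest = {"config": config.to_dict(), "datasets": [p.name for p in paths]}
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return paths


def with_overrides(config: SyntheticConfig, **kwargs) -> SyntheticConfig:
    """Functional update helper (frozen dataclass)."""
    return replace(config, **kwargs)
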