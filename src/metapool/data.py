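"""Study-level data model for RCT/NRS meta-analyses.

Effects are kept on the natural-log scale internally (log odds ratio or log
risk ratio); exponentiation to the author metric happens only at reporting
time, because the normal-normal hierarchical model's normality assumption
applies to log effects.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "Metric",
    "ArmCounts",
    "Study",
    "MetaAnalysisDataset",
    "IncomputableStudyError",
    "DatasetParseError",
    "log_odds_ratio",
    "log_risk_ratio",
    "read_dataset",
    "write_dataset",
]


class Design(str, enum.Enum):
    """Study design stratum: randomized trial or non-randomized study."""

    RCT = "RCT"
    NRS = "NRS"


class Metric(str, enum.Enum):
    """Effect metric of the meta-analysis (log scale internally)."""

    OR = "OR"
    RR = "RR"


class IncomputableStudyError(ValueError):
    """A 2x2 table carries no usable effect information (degenerate)."""


class DatasetParseError(ValueError):
    """A CSV row or column violates the dataset schema."""


@dataclass(frozen=True)
class ArmCounts:
    """2x2 binary-outcome table: events / totals for treatment and control."""

    events_treat: int
    total_treat: int
    events_ctrl: int
    total_ctrl: int

    def __post_init__(self) -> None:
        for ev, tot, arm in (
            (self.events_treat, self.total_treat, "treatment"),
            (self.events_ctrl, self.total_ctrl, "control"),
        ):
            if tot < 1:
                raise ValueError(f"{arm} arm total must be >= 1, got {tot}")
            if ev < 0 or ev > tot:
                raise ValueError(f"{arm} arm events must be in [0, total], got {ev}/{tot}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d): events/non-events treatment, events/non-events control."""
        return (
            self.events_treat,
            self.total_treat - self.events_treat,
            self.events_ctrl,
            self.total_ctrl - self.events_ctrl,
        )


def log_odds_ratio(counts: ArmCounts, correction: float = 0.5) -> tuple[float, float]:
    """Log odds ratio and its standard error from a 2x2 table.

    The continuity ``correction`` is added to ALL four cells if and only if
    any cell is zero (never selectively), following the convention of the
    RevMan/metan programs.

    Returns
    -------
    (y, se) : log OR and its large-sample standard error
        ``y = ln(a*d / (b*c))``, ``se = sqrt(1/a + 1/b + 1/c + 1/d)`` on the
        (possibly corrected) cells.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    a, b, c, d = (float(x) for x in counts.cells)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    if min(a, b, c, d) == 0.0 or (a == 0.0 and c == 0.0) or (b == 0.0 and d == 0.0):
        raise IncomputableStudyError(f"degenerate 2x2 table {counts.cells}")
    y = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return y, se


def log_risk_ratio(counts: ArmCounts, correction: float = 0.5) -> tuple[float, float]:
    """Log risk ratio and its standard error from a 2x2 table.

    If an event count is zero, ``correction`` is added to the events and
    totals of both arms (all-or-none, never selectively).
    ``y = ln((a/n1)/(c/n2))``, ``se = sqrt(1/a - 1/n1 + 1/c - 1/n2)``.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    a = float(counts.events_treat)
    n1 = float(counts.total_treat)
    c = float(counts.events_ctrl)
    n2 = float(counts.total_ctrl)
    if a == 0.0 and c == 0.0:
        raise IncomputableStudyError(f"no events in either arm: {counts}")
    if a == 0.0 or c == 0.0:
        a, n1, c, n2 = a + correction, n1 + correction, c + correction, n2 + correction
    if a == 0.0 or c == 0.0:
        raise IncomputableStudyError(f"degenerate table after correction: {counts}")
    y = math.log((a / n1) / (c / n2))
    var = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        raise IncomputableStudyError(f"zero-variance table (all events both arms): {counts}")
    return y, se


_EFFECT_FUN = {Metric.OR: log_odds_ratio, Metric.RR: log_risk_ratio}


@dataclass(frozen=True)
class Study:
    """One study's design label and log-scale effect with standard error."""

    study_id: str
    design: Design
    y: float
    se: float
    counts: ArmCounts | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"study {self.study_id}: effect must be finite, got {self.y}")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"study {self.study_id}: se must be > 0, got {self.se}")

    @classmethod
    def from_counts(
        cls,
        study_id: str,
        design: Design | str,
        counts: ArmCounts,
        metric: Metric | str = Metric.OR,
        correction: float = 0.5,
    ) -> "Study":
        y, se = _EFFECT_FUN[Metric(metric)](counts, correction)
        return cls(study_id=study_id, design=Design(design), y=y, se=se, counts=counts)


@dataclass
class MetaAnalysisDataset:
    """A labelled, ordered collection of studies sharing one effect metric."""

    label: str
    metric: Metric
    studies: list[Study] = field(default_factory=list)
    n_dropped: int = 0  # studies dropped for degenerate 2x2 tables

    def __post_init__(self) -> None:
        self.metric = Metric(self.metric)
        if len(self.studies) < 1:
            raise ValueError(f"dataset {self.label!r} must contain at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.label!r}: duplicate study_ids")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def n_rct(self) -> int:
        return sum(1 for s in self.studies if s.design is Design.RCT)

    @property
    def n_nrs(self) -> int:
        return sum(1 for s in self.studies if s.design is Design.NRS)

    def subset(self, design: Design | str) -> "MetaAnalysisDataset":
        """Single-design subgroup, preserving study order."""
        design = Design(design)
        kept = [s for s in self.studies if s.design is design]
        if not kept:
            raise ValueError(f"dataset {self.label!r} has no {design.value} studies")
        return MetaAnalysisDataset(
            label=f"{self.label}:{design.value}", metric=self.metric, studies=kept
        )

    @property
    def y(self):
        import numpy as np

        return np.array([s.y for s in self.studies], dtype=float)

    @property
    def se(self):
        import numpy as np

        return np.array([s.se for s in self.studies], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.studies:
            row = {
                "study_id": s.study_id,
                "design": s.design.value,
                "y": s.y,
                "se": s.se,
                "events_treat": s.counts.events_treat if s.counts else None,
                "total_treat": s.counts.total_treat if s.counts else None,
                "events_ctrl": s.counts.events_ctrl if s.counts else None,
                "total_ctrl": s.counts.total_ctrl if s.counts else None,
            }
            rows.append(row)
        return pd.DataFrame(rows)


_COUNT_COLS = ("events_treat", "total_treat", "events_ctrl", "total_ctrl")


def _has_value(v) -> bool:
    return v is not None and not (isinstance(v, float) and math.isnan(v)) and v != ""


def read_dataset(
    path: str | Path,
    metric: Metric | str | None = None,
    label: str | None = None,
    correction: float = 0.5,
    config: str | Path | None = None,
    drop_degenerate: bool = True,
) -> MetaAnalysisDataset:
    """Read a study-level CSV into a validated :class:`MetaAnalysisDataset`.

    The CSV must have a header with ``study_id``, ``design`` and either
    ``(y, se)`` or the four 2x2 count columns; mixed rows are allowed. The
    metric comes from ``metric``, or from a sidecar YAML ``config`` with a
    ``metric:`` key. Studies with degenerate tables are dropped with a logged
    warning (count kept in ``n_dropped``) rather than failing the dataset.
    """
    path = Path(path)
    if config is not None:
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
        metric = metric or cfg.get("metric")
        label = label or cfg.get("label")
    if metric is None:
        raise DatasetParseError(f"{path}: no metric given (pass metric= or a sidecar config)")
    metric = Metric(metric)
    label = label or path.stem

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("study_id", "design"):
        if col not in df.columns:
            raise DatasetParseError(f"{path}: missing required column {col!r}")
    has_ys = "y" in df.columns and "se" in df.columns
    has_counts = all(c in df.columns for c in _COUNT_COLS)
    if not (has_ys or has_counts):
        raise DatasetParseError(
            f"{path}: need either columns (y, se) or columns {_COUNT_COLS}"
        )

    studies: list[Study] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        sid = str(row["study_id"])
        try:
            design = Design(str(row["design"]).strip())
        except ValueError:
            raise DatasetParseError(
                f"{path}, row {rowno}, column 'design': unknown design label "
                f"{row['design']!r} (expected RCT or NRS)"
            ) from None
        row_counts = has_counts and all(_has_value(row[c]) for c in _COUNT_COLS)
        row_ys = has_ys and _has_value(row.get("y")) and _has_value(row.get("se"))
        if row_counts:
            counts = ArmCounts(*(int(row[c]) for c in _COUNT_COLS))
            try:
                studies.append(Study.from_counts(sid, design, counts, metric, correction))
            except IncomputableStudyError as err:
                if not drop_degenerate:
                    raise
                n_dropped += 1
                logger.warning("%s row %d (%s): dropped degenerate study: %s", path, rowno, sid, err)
        elif row_ys:
            y, se = float(row["y"]), float(row["se"])
            if not se > 0:
                raise DatasetParseError(f"{path}, row {rowno}, column 'se': must be > 0, got {se}")
            if not math.isfinite(y):
                raise DatasetParseError(f"{path}, row {rowno}, column 'y': must be finite")
            studies.append(Study(sid, design, y, se))
        else:
            raise DatasetParseError(
                f"{path}, row {rowno}: neither (y, se) nor a complete 2x2 table present"
            )

    ds = MetaAnalysisDataset(label=label, metric=metric, studies=studies)
    ds.n_dropped = n_dropped
    return ds


def write_dataset(dataset: MetaAnalysisDataset, path: str | Path, config: str | Path | None = None) -> None:
    """Write a dataset to CSV (and optionally its sidecar YAML config).

    Round-trips with :func:`read_dataset` to full float precision.
    """
    df = dataset.to_frame()
    # shortest round-trip float repr so read(write(ds)) is the identity on y, se
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    if config is not None:
        with open(config, "w") as fh:
            yaml.safe_dump({"metric": dataset.metric.value, "label": dataset.label}, fh)
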