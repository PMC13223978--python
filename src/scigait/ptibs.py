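"""Porcine Thoracic Injury Behaviour Scale (PTIBS) scoring.

A 10-stage ordinal locomotor scale for pigs: 1 = no active hindlimb
movement, 10 = normal ambulation; stages 1-3 are "dragging", 4-6
"stepping", 7-10 "walking".  Sessions are scored from video by several
independent observers blinded to group and session; observer scores are
aggregated (mean by default, median selectable), and group values are
reported descriptively as mean ± SEM, with per-animal changes from
Baseline aggregated the same way.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import mean_sem
from .exceptions import ParameterError, RubricLookupError

CATEGORIES = ("dragging", "stepping", "walking")
CATEGORY_BANDS = {"dragging": range(1, 4), "stepping": range(4, 7),
                  "walking": range(7, 11)}


def category_of(level: int) -> str:
    """Category band of an integer PTIBS level (1-10)."""
    for cat, band in CATEGORY_BANDS.items():
        if level in band:
            return cat
    raise ParameterError(f"PTIBS level must be 1..10, got {level}")


@dataclass(frozen=True)
class RubricLevel:
    level: int
    category: str
    key: str
    descriptor: str
    provisional: bool


@dataclass(frozen=True)
class PtibsRubric:
    """The 10 ordered levels with canonical descriptor keys."""

    levels: tuple[RubricLevel, ...]

    def __post_init__(self):
        if [lv.level for lv in self.levels] != list(range(1, 11)):
            raise ParameterError("rubric must hold exactly levels 1..10 in order")
        for lv in self.levels:
            if lv.category != category_of(lv.level):
                raise ParameterError(
                    f"level {lv.level} must be in category {category_of(lv.level)!r}")

    @classmethod
    def default(cls) -> "PtibsRubric":
        """The rubric shipped with the package (editable JSON)."""
        text = resources.files("scigait.data").joinpath("ptibs_rubric.json").read_text()
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "PtibsRubric":
        data = json.loads(text)
        return cls(tuple(RubricLevel(level=d["level"], category=d["category"],
                                     key=d["key"], descriptor=d["descriptor"],
                                     provisional=bool(d.get("provisional", False)))
                         for d in data["levels"]))

    def score_level(self, descriptor_key: str) -> RubricLevel:
        """Look up a level by its canonical behaviour descriptor key."""
        wanted = " ".join(descriptor_key.lower().split())
        for lv in self.levels:
            if lv.key == wanted:
                return lv
        raise RubricLookupError(descriptor_key, [lv.key for lv in self.levels])


def score_level(descriptor_key: str,
                rubric: Optional[PtibsRubric] = None) -> RubricLevel:
    """Module-level rubric lookup against the shipped default rubric."""
    return (rubric or PtibsRubric.default()).score_level(descriptor_key)


def aggregate_observers(scores: Sequence[int],
                        method: Literal["mean", "median"] = "mean") -> float:
    """Aggregate blinded observer scores (default arithmetic mean)."""
    if len(scores) == 0:
        raise ParameterError("aggregate_observers requires at least one score")
    for s in scores:
        if int(s) != s or not (1 <= s <= 10):
            raise ParameterError(f"observer scores must be integers in 1..10, got {s!r}")
    arr = np.asarray(scores, dtype=float)
    if method == "mean":
        return float(arr.mean())
    if method == "median":
        return float(np.median(arr))
    raise ParameterError(f"unknown aggregation method {method!r}")


@dataclass(frozen=True)
class PtibsAssessment:
    """Observer scores for one animal x session, with their aggregate."""

    animal_id: str
    session: str
    observer_scores: tuple[int, ...]
    aggregation: str = "mean"
    aggregated: float = field(init=False)
    category: str = field(init=False)

    def __post_init__(self):
        agg = aggregate_observers(self.observer_scores, self.aggregation)
        object.__setattr__(self, "aggregated", agg)
        cats = {category_of(int(s)) for s in self.observer_scores}
        object.__setattr__(self, "category",
                           cats.pop() if len(cats) == 1 else "mixed")


def group_summary(assessments: Sequence[PtibsAssessment]) -> tuple[float, float, int]:
    """(mean, SEM, n) of aggregated scores over animals in one group+session."""
    if not assessments:
        raise ParameterError("group_summary requires at least one assessment")
    vals = [a.aggregated for a in assessments]
    m, s = mean_sem(vals)
    return m, s, len(vals)


def change_from_baseline(session_assessments: Sequence[PtibsAssessment],
                         baseline_assessments: Sequence[PtibsAssessment]
                         ) -> tuple[float, float, int]:
    """Group change: per-animal (session - Baseline), then mean ± SEM.

    Every animal in the session set must have a Baseline assessment.
    """
    base = {a.animal_id: a.aggregated for a in baseline_assessments}
    deltas = []
    for a in session_assessments:
        if a.animal_id not in base:
            raise ParameterError(f"animal {a.animal_id!r} has no Baseline assessment")
        deltas.append(a.aggregated - base[a.animal_id])
    if not deltas:
        raise ParameterError("change_from_baseline requires at least one animal")
    m, s = mean_sem(deltas)
    return m, s, len(deltas)


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------

class PtibsModel:
    """PTIBS analysis over an observer-score table.

    Expects a tidy table with columns ``animal``, ``group``, ``session``,
    ``observer``, ``score`` (one row per observer rating); ``fit()``
    aggregates observers per assessment, then animals per group, returning
    a :class:`PtibsResults`.
    """

    REQUIRED = ("animal", "group", "session", "score")

    def __init__(self, table: pd.DataFrame, *,
                 aggregation: Literal["mean", "median"] = "mean"):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ParameterError(f"observer table lacks columns {missing}")
        self.table = table.copy()
        self.aggregation = aggregation

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PtibsModel":
        return cls(pd.read_csv(path, sep=None, engine="python"), **kwargs)

    def fit(self) -> "PtibsResults":
        assessments: list[tuple[str, PtibsAssessment]] = []
        for (animal, group, session), sub in self.table.groupby(
                ["animal", "group", "session"], sort=True):
            a = PtibsAssessment(animal_id=str(animal), session=str(session),
                                observer_scores=tuple(int(s) for s in sub["score"]),
                                aggregation=self.aggregation)
            assessments.append((str(group), a))
        return PtibsResults(self, assessments)


class PtibsResults:
    """Aggregated assessments plus group mean ± SEM and baseline changes."""

    def __init__(self, model: PtibsModel,
                 assessments: list[tuple[str, PtibsAssessment]]):
        self.model = model
        self.assessments = assessments

    def assessment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"animal": a.animal_id, "group": g, "session": a.session,
              "n_observers": len(a.observer_scores), "score": a.aggregated,
              "category": a.category}
             for g, a in self.assessments])

    def group_table(self) -> pd.DataFrame:
        df = self.assessment_table()
        rows = []
        for (group, session), sub in df.groupby(["group", "session"], sort=True):
            m, s = mean_sem(sub["score"].to_numpy())
            row = {"group": group, "session": session, "n": len(sub),
                   "score_mean": m, "score_sem": s,
                   "sem_flagged_n1": len(sub) == 1}
            base = df[(df["group"] == group) & (df["session"] == "Baseline")]
            if session != "Baseline" and not base.empty:
                merged = sub.merge(base[["animal", "score"]], on="animal",
                                   suffixes=("", "_base"))
                if len(merged) == len(sub):
                    dm, ds = mean_sem((merged["score"] - merged["score_base"]).to_numpy())
                    row["change_mean"], row["change_sem"] = dm, ds
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        gt = self.group_table()
        lines = ["PTIBS group summary (mean +/- SEM)", "=" * 36]
        for _, r in gt.iterrows():
            line = (f"{r['group']:>8s} {r['session']:<8s} n={r['n']}  "
                    f"score {r['score_mean']:4.1f} +/- {r['score_sem']:.1f}")
            if "change_mean" in gt.columns and not pd.isna(r.get("change_mean", float("nan"))):
                line += f"  change vs Baseline {r['change_mean']:+.1f} +/- {r['change_sem']:.1f}"
            lines.append(line)
        return "\n".join(lines)
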