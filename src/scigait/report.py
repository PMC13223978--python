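"""Study-level orchestration: run every analysis over a study directory.

A *study directory* is the layout :func:`scigait.simulate.generate_study`
writes (and that instrumented recordings can be exported to): one
sub-directory per animal, one per session, with delimited activity/gait
files, plus an observer-score table ``ptibs_scores.csv`` at the root.

:class:`StudyModel` composes the three analyses — activity binning, gait
kinematics gated by walking detection and PTIBS eligibility, and PTIBS
group summaries — isolating per-session failures so one corrupt file never
aborts the rest.  The resulting report body is deterministic for a fixed
config (no timestamps), so re-runs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import ActivityModel, ActivityThresholds
from .exceptions import ParameterError, SciGaitError
from .gait import GaitDetectionConfig, GaitSessionModel, GaitSessionResults
from .ptibs import PtibsModel, PtibsResults
from .signals import SESSIONS, SessionSchema, load_session

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Everything a study run needs; round-trips losslessly through YAML."""

    study_dir: str
    out_dir: str = "results"
    rest_upper: float = 5.0
    low_upper: float = 50.0
    activity_mode: str = "yaw"
    block_seconds: float = 5.0
    walk_band: tuple[float, float] = (2.5, 4.0)
    min_peak_prominence: float = 5.0
    cycle_duration_bounds: tuple[float, float] = (0.4, 2.0)
    cycles_per_session: int = 10
    ptibs_aggregation: str = "mean"
    seed: int = 0

    def thresholds(self) -> ActivityThresholds:
        return ActivityThresholds(self.rest_upper, self.low_upper)

    def gait_config(self) -> GaitDetectionConfig:
        return GaitDetectionConfig(
            block_seconds=self.block_seconds, walk_band=tuple(self.walk_band),
            min_peak_prominence=self.min_peak_prominence,
            cycle_duration_bounds=tuple(self.cycle_duration_bounds),
            cycles_per_session=self.cycles_per_session)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["walk_band"] = list(d["walk_band"])
        d["cycle_duration_bounds"] = list(d["cycle_duration_bounds"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text) or {}
        for k in ("walk_band", "cycle_duration_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        return cls.from_yaml(Path(path).read_text())

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _discover_sessions(study_dir: Path) -> list[tuple[str, str, Path]]:
    """(animal, session, session_dir) triples found under the study root."""
    out = []
    for animal_dir in sorted(p for p in study_dir.iterdir() if p.is_dir()):
        for session in SESSIONS:
            sdir = animal_dir / session
            if sdir.is_dir():
                out.append((animal_dir.name, session, sdir))
    return out


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else round(f, 9)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _json_safe(obj.to_dict(orient="records"))
    return obj


class StudyModel:
    """Full-pipeline analysis of one study directory."""

    def __init__(self, config: StudyConfig, schema: SessionSchema | None = None):
        self.config = config
        self.schema = schema or SessionSchema()
        self.study_dir = Path(config.study_dir)
        if not self.study_dir.is_dir():
            raise ParameterError(f"study directory {self.study_dir} does not exist")

    # -- helpers -----------------------------------------------------------
    def _groups(self) -> dict[str, str]:
        ptibs_csv = self.study_dir / "ptibs_scores.csv"
        if ptibs_csv.is_file():
            df = pd.read_csv(ptibs_csv)
            if {"animal", "group"} <= set(df.columns):
                return dict(zip(df["animal"].astype(str), df["group"]))
        manifest = self.study_dir / "manifest.json"
        if manifest.is_file():
            data = json.loads(manifest.read_text())
            return {a: d["group"] for a, d in data.get("animals", {}).items()}
        logger.warning("no group metadata found; defaulting every animal to DAMAGED")
        return {}

    def fit(self) -> "StudyResults":
        cfg = self.config
        discovered = _discover_sessions(self.study_dir)
        if not discovered:
            raise ParameterError(
                f"no <animal>/<session> directories found under {self.study_dir}")
        groups = self._groups()
        errors: list[dict] = []

        # PTIBS ------------------------------------------------------------
        ptibs_results: Optional[PtibsResults] = None
        scores: dict[tuple[str, str], float] = {}
        ptibs_csv = self.study_dir / "ptibs_scores.csv"
        if ptibs_csv.is_file():
            try:
                ptibs_results = PtibsModel.from_csv(
                    ptibs_csv, aggregation=cfg.ptibs_aggregation).fit()
                for _, r in ptibs_results.assessment_table().iterrows():
                    scores[(r["animal"], r["session"])] = r["score"]
            except SciGaitError as exc:
                errors.append({"stage": "ptibs", "error": str(exc)})
        else:
            logger.warning("no ptibs_scores.csv in %s; PTIBS section absent",
                           self.study_dir)

        # per-session activity + gait --------------------------------------
        activity_sessions = []
        gait_results: dict[tuple[str, str], GaitSessionResults] = {}
        for animal, session, sdir in discovered:
            group = groups.get(animal, "DAMAGED")
            act_paths = {}
            if (sdir / "activity_imu_thoracic.csv").is_file():
                act_paths["thoracic"] = sdir / "activity_imu_thoracic.csv"
            if (sdir / "activity_imu_lumbar.csv").is_file():
                act_paths["lumbar"] = sdir / "activity_imu_lumbar.csv"
            if act_paths:
                try:
                    activity_sessions.append(load_session(
                        act_paths, self.schema, animal_id=animal, group=group,
                        session=session))
                except SciGaitError as exc:
                    errors.append({"stage": "activity", "animal": animal,
                                   "session": session, "error": str(exc)})

            gait_paths = {}
            for key, name in (("thoracic", "gait_imu_thoracic.csv"),
                              ("hip_left", "gait_hip_left.csv"),
                              ("hip_right", "gait_hip_right.csv")):
                if (sdir / name).is_file():
                    gait_paths[key] = sdir / name
            if "hip_left" not in gait_paths and "hip_right" not in gait_paths:
                if gait_paths:
                    errors.append({"stage": "gait", "animal": animal,
                                   "session": session,
                                   "error": "goniometer files missing; gait section absent"})
                continue
            try:
                rec = load_session(gait_paths, self.schema, animal_id=animal,
                                   group=group, session=session)
                res = GaitSessionModel(rec, cfg.gait_config(),
                                       ptibs_score=scores.get((animal, session))).fit()
                gait_results[(animal, session)] = res
            except SciGaitError as exc:
                errors.append({"stage": "gait", "animal": animal,
                               "session": session, "error": str(exc)})

        activity_results = None
        if activity_sessions:
            try:
                activity_results = ActivityModel(
                    activity_sessions, cfg.thresholds(),
                    mode=cfg.activity_mode).fit()
            except SciGaitError as exc:
                errors.append({"stage": "activity", "error": str(exc)})

        return StudyResults(self, activity_results, gait_results,
                            ptibs_results, errors)


class StudyResults:
    """Report bundle: tidy tables per analysis plus provenance and errors."""

    def __init__(self, model: StudyModel, activity, gait_results,
                 ptibs_results, errors):
        self.model = model
        self.config = model.config
        self.activity = activity
        self.gait_results = gait_results
        self.ptibs = ptibs_results
        self.errors = errors

    # -- gait aggregation --------------------------------------------------
    def gait_delta_table(self) -> pd.DataFrame:
        """Baseline-relative gait deltas for analysable animal x session x side."""
        rows = []
        by_animal: dict[str, dict[str, GaitSessionResults]] = {}
        for (animal, session), res in self.gait_results.items():
            by_animal.setdefault(animal, {})[session] = res
        for animal, sessions in sorted(by_animal.items()):
            base = sessions.get("Baseline")
            if base is None:
                continue
            for session, res in sorted(sessions.items()):
                if session == "Baseline":
                    continue
                for side in ("left", "right"):
                    if not (res.analysable(side) and base.analysable(side)):
                        continue
                    d = res.delta_vs(base, side)
                    if d is None:
                        continue
                    rows.append({"animal": animal, "session": session, "side": side,
                                 "d_max_pct": d.d_max_pct, "d_min_pct": d.d_min_pct,
                                 "d_rom_pct": d.d_rom_pct,
                                 "d_pct_at_max": d.d_pct_at_max,
                                 "d_pct_at_min": d.d_pct_at_min})
        return pd.DataFrame(rows)

    def gait_session_table(self) -> pd.DataFrame:
        rows = []
        for (animal, session), res in sorted(self.gait_results.items()):
            for side in ("left", "right"):
                m = res.metrics(side)
                row = {"animal": animal, "session": session, "side": side,
                       "n_walking_intervals": len(res.intervals),
                       "n_cycles": res.n_cycles(side),
                       "analysable": res.analysable(side)}
                if m is not None:
                    row.update({"max_angle": m.max_angle, "min_angle": m.min_angle,
                                "rom": m.rom, "pct_at_max": m.pct_at_max,
                                "pct_at_min": m.pct_at_min})
                rows.append(row)
        return pd.DataFrame(rows)

    # -- report body -------------------------------------------------------
    def report(self) -> dict:
        body: dict = {
            "provenance": {"package": "scigait", "version": __version__,
                           "config": self.config.to_dict(),
                           "config_hash": self.config.content_hash(),
                           "seed": self.config.seed},
            "errors": self.errors,
        }
        if self.activity is not None:
            body["activity"] = {
                "sessions": _json_safe(self.activity.table),
                "groups": _json_safe(self.activity.group_table())}
        if self.gait_results:
            curves = pd.concat([res.representative_table()
                                for res in self.gait_results.values()
                                if not res.representative_table().empty],
                               ignore_index=True) if self.gait_results else pd.DataFrame()
            body["gait"] = {
                "sessions": _json_safe(self.gait_session_table()),
                "deltas": _json_safe(self.gait_delta_table()),
                "representative_curves": _json_safe(curves)}
        if self.ptibs is not None:
            body["ptibs"] = {
                "assessments": _json_safe(self.ptibs.assessment_table()),
                "groups": _json_safe(self.ptibs.group_table())}
        return body

    def to_json(self) -> str:
        return json.dumps(self.report(), indent=2, sort_keys=True)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "report.json"
        path.write_text(self.to_json())
        return path

    def summary(self) -> str:
        parts = [f"scigait study report  (config {self.config.content_hash()})"]
        if self.activity is not None:
            parts.append(self.activity.summary())
        if self.ptibs is not None:
            parts.append(self.ptibs.summary())
        if self.gait_results:
            parts.append("Gait sessions")
            parts.append("=" * 13)
            for (_, _), res in sorted(self.gait_results.items()):
                parts.append(res.summary())
        if self.errors:
            parts.append(f"{len(self.errors)} session-level error(s); see report body")
        return "\n\n".join(parts)


def run_study(config: StudyConfig,
              schema: SessionSchema | None = None) -> StudyResults:
    """Convenience wrapper: ``StudyModel(config, schema).fit()``."""
    return StudyModel(config, schema).fit()


# ---------------------------------------------------------------------------
# Figure-ready exports
# ---------------------------------------------------------------------------

def export_figures_data(results: StudyResults, out_dir) -> list[Path]:
    """Write one tidy table per figure family.

    * ``activity_stacked_bar.csv`` — rest/low/high fractions per bar
      (each row sums to 100).
    * ``activity_recovery.csv`` — recovery-vs-baseline lines.
    * ``ptibs_trajectories.csv`` — per-animal traces plus group means.
    * ``gait_cycle_curves.csv`` — 101-point mean ± SEM curves.
    * ``gait_deltas.json`` — baseline-relative gait changes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if results.activity is not None:
        tab = results.activity.table
        bar = tab[["animal", "group", "session", "placement", "fraction_rest",
                   "fraction_low", "fraction_high"]]
        p = out / "activity_stacked_bar.csv"
        bar.to_csv(p, index=False)
        written.append(p)
        rec = tab.dropna(subset=["recovery_pct"])[
            ["animal", "group", "session", "placement", "recovery_pct"]]
        p = out / "activity_recovery.csv"
        rec.to_csv(p, index=False)
        written.append(p)

    if results.ptibs is not None:
        traces = results.ptibs.assessment_table()[
            ["animal", "group", "session", "score"]].assign(kind="animal")
        gm = results.ptibs.group_table()[
            ["group", "session", "score_mean", "score_sem"]]
        gm = gm.rename(columns={"score_mean": "score"}).assign(
            animal="group_mean", kind="group_mean")
        both = pd.concat([traces, gm[["animal", "group", "session", "score",
                                      "score_sem", "kind"]]], ignore_index=True)
        p = out / "ptibs_trajectories.csv"
        both.to_csv(p, index=False)
        written.append(p)

    if results.gait_results:
        curves = [res.representative_table() for res in results.gait_results.values()]
        curves = [c for c in curves if not c.empty]
        if curves:
            p = out / "gait_cycle_curves.csv"
            pd.concat(curves, ignore_index=True).to_csv(p, index=False)
            written.append(p)
        p = out / "gait_deltas.json"
        p.write_text(json.dumps(_json_safe(results.gait_delta_table()),
                                indent=2, sort_keys=True))
        written.append(p)
    return written
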