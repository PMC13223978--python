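"""Unsupervised 30-min activity quantification.

The dorsal-plane angular-acceleration magnitude (rotation parallel to the
horizontal plane of the animal, i.e. turning left or right) is smoothed with
a Savitzky-Golay filter, rectified, and binned into three intensity levels:

* Rest  — [0, 5) deg/s^2 (recumbency)
* Low   — [5, 50) deg/s^2 (low-impact activity such as walking)
* High  — [50, inf) deg/s^2 (high-impact activity such as playing)

Non-rest activity (magnitude >= 5 deg/s^2, as % of time) is the general
physical-activity marker; recovery is a session's non-rest percentage
normalised to the animal's mean Baseline value.  A value of exactly
5 deg/s^2 is Low (non-rest); exactly 50 is High — a half-open partition so
the three bins never overlap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import mean_sem
from .exceptions import ConfigError, ParameterError, SciGaitError
from .signals import ImuTriad, SessionRecording, SignalChannel, savgol_filter

logger = logging.getLogger(__name__)

INTENSITY_LABELS = ("rest", "low", "high")


@dataclass(frozen=True)
class ActivityThresholds:
    """Bin edges (deg/s^2) between Rest/Low and Low/High intensity."""

    rest_upper: float = 5.0
    low_upper: float = 50.0

    def __post_init__(self):
        if not (0 < self.rest_upper < self.low_upper):
            raise ParameterError(
                f"need 0 < rest_upper < low_upper, got {self.rest_upper}, {self.low_upper}")


@dataclass(frozen=True)
class ActivitySummary:
    """Per-session, per-IMU-placement activity fractions (% of time)."""

    placement: str
    fraction_rest: float
    fraction_low: float
    fraction_high: float
    non_rest_pct: float
    recovery_pct: Optional[float] = None  # absent for Baseline sessions


def dorsal_plane_magnitude(imu: ImuTriad, *, yaw_axis: str = "dorso_ventral",
                           mode: str = "yaw", poly_order: int = 3,
                           frame_seconds: float = 0.051) -> SignalChannel:
    """Smoothed |angular acceleration| parallel to the dorsal plane.

    ``mode="yaw"`` (default) takes the single component about the
    dorso-ventral axis; ``mode="in_plane_norm"`` takes the Euclidean norm of
    the two remaining (in-plane) axis components instead — both readings of
    "parallel to the dorsal plane" are exposed since raw traces cannot
    arbitrate between them.
    """
    if mode not in ("yaw", "in_plane_norm"):
        raise ConfigError(f"mode must be 'yaw' or 'in_plane_norm', got {mode!r}")
    try:
        yaw = imu.channel(yaw_axis)
    except ConfigError:
        raise ConfigError(
            f"axis map lacks a yaw assignment {yaw_axis!r} for triad at "
            f"{imu.placement}; axes present: {imu.axes}")
    if mode == "yaw":
        smoothed = savgol_filter(yaw, poly_order, frame_seconds)
        mag = np.abs(smoothed.samples)
    else:
        others = [savgol_filter(c, poly_order, frame_seconds).samples
                  for c in imu.channels if c.axis != yaw_axis]
        mag = np.hypot(*others)
    return yaw.with_samples(mag)


def classify_intensity(mag: SignalChannel | np.ndarray,
                       thr: ActivityThresholds = ActivityThresholds()) -> np.ndarray:
    """Per-sample intensity codes: 0=Rest, 1=Low, 2=High.

    Boundary convention: [0, rest_upper) Rest, [rest_upper, low_upper) Low,
    [low_upper, inf) High.
    """
    x = mag.samples if isinstance(mag, SignalChannel) else np.asarray(mag, dtype=float)
    if np.any(x < 0):
        raise SciGaitError("negative magnitude sample: upstream must rectify first")
    return np.digitize(x, [thr.rest_upper, thr.low_upper]).astype(np.int8)


def intensity_fractions(labels: np.ndarray) -> tuple[float, float, float]:
    """Percent of samples in each of (rest, low, high); sums to 100."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("empty label sequence")
    counts = np.bincount(labels, minlength=3)
    return tuple(100.0 * counts[:3] / labels.size)


def non_rest_percentage(labels: np.ndarray) -> float:
    """% of samples labelled Low or High (magnitude >= rest threshold)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ParameterError("empty label sequence")
    return 100.0 * float(np.count_nonzero(labels > 0)) / labels.size


def recovery_percentage(session_non_rest: float,
                        baseline_non_rest_values: Sequence[float]) -> float:
    """Session non-rest as % of the mean Baseline non-rest.

    100 means unchanged from Baseline; recovery - 100 is the change
    (e.g. 40.2 -> a -59.8% change).  A zero/empty baseline is undefined and
    returns NaN with a warning.
    """
    base = np.asarray(baseline_non_rest_values, dtype=float)
    if base.size == 0 or base.mean() <= 0:
        logger.warning("recovery undefined: baseline mean non-rest is zero/empty")
        return float("nan")
    return 100.0 * session_non_rest / float(base.mean())


BaselineLookup = Callable[[str, str], Sequence[float]]


def summarize_activity(session: SessionRecording,
                       thr: ActivityThresholds = ActivityThresholds(),
                       baseline_lookup: Optional[BaselineLookup] = None, *,
                       mode: str = "yaw",
                       yaw_axis: str = "dorso_ventral") -> list[ActivitySummary]:
    """Full per-placement activity summary for one session.

    ``baseline_lookup(animal_id, placement)`` returns the animal's Baseline
    non-rest percentages for that placement (recovery is skipped for
    Baseline sessions or when no lookup is given).  A missing IMU placement
    yields a partial result with a warning.
    """
    out: list[ActivitySummary] = []
    for placement, triad in (("thoracic", session.thoracic), ("lumbar", session.lumbar)):
        if triad is None:
            logger.warning("session %s/%s: missing %s IMU, partial activity summary",
                           session.animal_id, session.session, placement)
            continue
        mag = dorsal_plane_magnitude(triad, yaw_axis=yaw_axis, mode=mode)
        labels = classify_intensity(mag, thr)
        f_rest, f_low, f_high = intensity_fractions(labels)
        nr = non_rest_percentage(labels)
        recovery = None
        if session.session != "Baseline" and baseline_lookup is not None:
            base = baseline_lookup(session.animal_id, placement)
            recovery = recovery_percentage(nr, base)
        out.append(ActivitySummary(placement=placement, fraction_rest=f_rest,
                                   fraction_low=f_low, fraction_high=f_high,
                                   non_rest_pct=nr, recovery_pct=recovery))
    return out


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------

class ActivityModel:
    """Activity analysis over a collection of session recordings.

    Statsmodels-style entry point: build from data, ``fit()`` computes the
    per-session summaries, baseline-relative recovery and group mean ± SEM
    tables, returning an :class:`ActivityResults`.
    """

    def __init__(self, sessions: Iterable[SessionRecording],
                 thresholds: ActivityThresholds = ActivityThresholds(), *,
                 mode: str = "yaw", yaw_axis: str = "dorso_ventral"):
        self.sessions = list(sessions)
        self.thresholds = thresholds
        self.mode = mode
        self.yaw_axis = yaw_axis
        if not self.sessions:
            raise ParameterError("ActivityModel requires at least one session")

    def fit(self) -> "ActivityResults":
        baseline_nr: dict[tuple[str, str], list[float]] = {}
        for s in self.sessions:
            if s.session != "Baseline":
                continue
            for summ in summarize_activity(s, self.thresholds, None,
                                           mode=self.mode, yaw_axis=self.yaw_axis):
                baseline_nr.setdefault((s.animal_id, summ.placement), []).append(
                    summ.non_rest_pct)

        def lookup(animal_id: str, placement: str) -> Sequence[float]:
            return baseline_nr.get((animal_id, placement), [])

        rows = []
        for s in self.sessions:
            for summ in summarize_activity(s, self.thresholds, lookup,
                                           mode=self.mode, yaw_axis=self.yaw_axis):
                rows.append({"animal": s.animal_id, "group": s.group,
                             "session": s.session, "placement": summ.placement,
                             "fraction_rest": summ.fraction_rest,
                             "fraction_low": summ.fraction_low,
                             "fraction_high": summ.fraction_high,
                             "non_rest_pct": summ.non_rest_pct,
                             "recovery_pct": summ.recovery_pct})
        table = pd.DataFrame(rows)
        return ActivityResults(self, table)


class ActivityResults:
    """Per-session activity table plus group mean ± SEM aggregation."""

    def __init__(self, model: ActivityModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def group_table(self) -> pd.DataFrame:
        """Group x session x placement mean ± SEM of fractions and recovery.

        Change-vs-baseline is the mean over animals of per-animal
        (recovery - 100), per the study's descriptive convention.
        """
        rows = []
        for (group, session, placement), sub in self.table.groupby(
                ["group", "session", "placement"], sort=True):
            row = {"group": group, "session": session, "placement": placement,
                   "n": len(sub)}
            for coln in ("fraction_rest", "fraction_low", "fraction_high",
                         "non_rest_pct"):
                m, s = mean_sem(sub[coln].to_numpy())
                row[coln + "_mean"], row[coln + "_sem"] = m, s
            rec = sub["recovery_pct"].dropna().to_numpy()
            if rec.size:
                m, s = mean_sem(rec)
                row["recovery_mean"], row["recovery_sem"] = m, s
                m2, s2 = mean_sem(rec - 100.0)
                row["change_vs_baseline_mean"], row["change_vs_baseline_sem"] = m2, s2
            else:
                row["recovery_mean"] = row["recovery_sem"] = float("nan")
                row["change_vs_baseline_mean"] = row["change_vs_baseline_sem"] = float("nan")
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        gt = self.group_table()
        lines = ["Activity summary (group mean +/- SEM, % of time)",
                 "=" * 48]
        for _, r in gt.iterrows():
            lines.append(
                f"{r['group']:>8s} {r['session']:<8s} {r['placement']:<8s} "
                f"rest {r['fraction_rest_mean']:5.1f}+/-{r['fraction_rest_sem']:.1f}  "
                f"low {r['fraction_low_mean']:5.1f}+/-{r['fraction_low_sem']:.1f}  "
                f"high {r['fraction_high_mean']:5.1f}+/-{r['fraction_high_sem']:.1f}  "
                f"non-rest {r['non_rest_pct_mean']:5.1f}"
                + ("" if np.isnan(r["change_vs_baseline_mean"]) else
                   f"  change vs baseline {r['change_vs_baseline_mean']:+.1f}%"))
        return "\n".join(lines)
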