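"""Walking detection and hip gait-cycle kinematics.

Walking periods are found on the thoracic IMU's medio-lateral component
(forelimb rhythm survives hindlimb paralysis): the signal is cut into
consecutive non-overlapping 5-s blocks and a block counts as walking when
the frequency of its peak FFT magnitude (ignoring bins below 0.4 Hz) falls
in the 2.5-4.0 Hz band, a range drawn from porcine walking speed and step
time.  Hip electro-goniometer traces inside those periods are segmented
into gait cycles delimited by successive peak-flexion events, each cycle is
linearly interpolated onto 101 points (0..100 % of the cycle), and scalar
metrics are extracted: peak flexion (max angle), peak extension (min
angle), range of motion, and the cycle percentages at which the extrema
occur.  Metrics are computed per cycle and then averaged — the pointwise
mean ± SEM curve is for visualisation only, since averaging asynchronous
curves first would bias the extrema.

Session eligibility mirrors the behavioural gate: an animal must manage at
least three reciprocating hindlimb gait cycles (PTIBS score > 3) for its
session to enter the quantitative analysis; ten cycles per session are then
selected (first ten valid ones, chronological).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ParameterError
from .signals import (SessionRecording, SignalChannel, butterworth_lowpass,
                      resample)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitDetectionConfig:
    """Tunables of the walking detector and cycle segmenter."""

    block_seconds: float = 5.0
    walk_band: tuple[float, float] = (2.5, 4.0)
    min_search_hz: float = 0.4          # FFT bins below this are never the peak
    min_peak_prominence: float = 5.0    # deg, flexion-peak prominence
    cycle_duration_bounds: tuple[float, float] = (0.4, 2.0)
    cycles_per_session: int = 10
    min_cycles_required: int = 3
    resample_rate: float = 1000.0
    lowpass_order: int = 4
    lowpass_cutoff_hz: float = 10.0

    def __post_init__(self):
        if not (self.block_seconds > 0):
            raise ParameterError("block_seconds must be > 0")
        if not (self.walk_band[0] < self.walk_band[1]):
            raise ParameterError("walk_band lower bound must be below upper")
        lo, hi = self.cycle_duration_bounds
        if not (0 < lo < hi):
            raise ParameterError("cycle_duration_bounds must be positive and ordered")


@dataclass(frozen=True)
class WalkingInterval:
    """A run of adjacent walking blocks."""

    start: float
    end: float
    dominant_frequency: float


@dataclass(frozen=True)
class RawCycle:
    """One peak-flexion-to-peak-flexion hip-angle segment (endpoints included)."""

    angles: np.ndarray
    rate: float
    start_time: float

    @property
    def duration(self) -> float:
        return (self.angles.size - 1) / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.angles.size) / self.rate


@dataclass(frozen=True)
class NormalizedGaitCycle:
    """Hip angle at 0,1,...,100 % of the gait cycle."""

    angles: np.ndarray
    side: str = ""

    def __post_init__(self):
        arr = np.asarray(self.angles, dtype=float)
        if arr.shape != (101,):
            raise ParameterError(f"a normalized cycle has exactly 101 points, got {arr.shape}")
        object.__setattr__(self, "angles", arr)


@dataclass(frozen=True)
class GaitMetrics:
    """Scalar kinematic variables of one (or an averaged) gait cycle."""

    max_angle: float   # peak hip flexion, deg
    min_angle: float   # peak hip extension, deg
    rom: float         # range of motion, deg
    pct_at_max: float  # % of cycle at first occurrence of the maximum
    pct_at_min: float


@dataclass(frozen=True)
class GaitDelta:
    """Baseline-relative change: angles in relative %, timing in points."""

    d_max_pct: float
    d_min_pct: float
    d_rom_pct: float
    d_pct_at_max: float  # percentage points; negative = earlier in the cycle
    d_pct_at_min: float


def detect_walking(thoracic_ml: SignalChannel,
                   cfg: GaitDetectionConfig = GaitDetectionConfig()) -> list[WalkingInterval]:
    """Block-FFT walking detection on the thoracic medio-lateral channel.

    The channel is expected already resampled to 1 kHz and low-pass filtered
    at 10 Hz (see :func:`prepare_gait_channels`).  Adjacent walking blocks
    are merged; the merged interval's dominant frequency is taken from the
    block with the strongest spectral peak.
    """
    n_block = int(round(cfg.block_seconds * thoracic_ml.rate))
    if thoracic_ml.n < n_block:
        logger.warning("channel shorter than one %.3g-s block: no walking intervals",
                       cfg.block_seconds)
        return []
    n_blocks = thoracic_ml.n // n_block
    freqs = np.fft.rfftfreq(n_block, d=1.0 / thoracic_ml.rate)
    searchable = freqs >= cfg.min_search_hz
    lo, hi = cfg.walk_band

    block_hits: list[tuple[int, float, float]] = []  # (block index, f_peak, magnitude)
    for b in range(n_blocks):
        seg = thoracic_ml.samples[b * n_block:(b + 1) * n_block]
        mag = np.abs(np.fft.rfft(seg))
        mag[~searchable] = 0.0
        k = int(np.argmax(mag))
        f_peak = float(freqs[k])
        if lo <= f_peak <= hi:  # closed band membership
            block_hits.append((b, f_peak, float(mag[k])))

    intervals: list[WalkingInterval] = []
    run: list[tuple[int, float, float]] = []
    t0 = thoracic_ml.start_time

    def flush(run):
        if not run:
            return
        best = max(run, key=lambda t: t[2])
        intervals.append(WalkingInterval(
            start=t0 + run[0][0] * cfg.block_seconds,
            end=t0 + (run[-1][0] + 1) * cfg.block_seconds,
            dominant_frequency=best[1]))

    for hit in block_hits:
        if run and hit[0] != run[-1][0] + 1:
            flush(run)
            run = []
        run.append(hit)
    flush(run)
    return intervals


def eligibility(ptibs_score: float, n_cycles_available: int) -> bool:
    """Quantitative-gait gate: PTIBS > 3 and at least three gait cycles."""
    return ptibs_score > 3 and n_cycles_available >= 3


def prepare_gait_channels(session: SessionRecording,
                          cfg: GaitDetectionConfig = GaitDetectionConfig(), *,
                          detection_axis: str = "medio_lateral"
                          ) -> tuple[Optional[SignalChannel], dict[str, SignalChannel]]:
    """Resample IMU to the goniometer rate and low-pass everything at 10 Hz.

    Returns the filtered thoracic detection channel (None if the thoracic
    triad is absent) and a dict of filtered hip channels by side.
    """
    det = None
    if session.thoracic is not None:
        ml = session.thoracic.channel(detection_axis)
        ml = resample(ml, cfg.resample_rate)
        det = butterworth_lowpass(ml, cfg.lowpass_order, cfg.lowpass_cutoff_hz)
    hips: dict[str, SignalChannel] = {}
    for side in ("left", "right"):
        ch = session.hip(side)
        if ch is not None:
            if ch.rate != cfg.resample_rate:
                ch = resample(ch, cfg.resample_rate)
            hips[side] = butterworth_lowpass(ch, cfg.lowpass_order, cfg.lowpass_cutoff_hz)
    return det, hips


def segment_cycles(hip_angle: SignalChannel,
                   intervals: Sequence[WalkingInterval],
                   cfg: GaitDetectionConfig = GaitDetectionConfig()) -> list[RawCycle]:
    """Peak-flexion-to-peak-flexion cycles inside walking intervals.

    Local maxima with prominence >= ``min_peak_prominence`` delimit cycles;
    cycles outside ``cycle_duration_bounds`` are discarded and the first
    ``cycles_per_session`` valid cycles (chronological) are retained.
    Callers mark the session non-analysable when fewer than
    ``min_cycles_required`` cycles come back.
    """
    peaks, _ = sps.find_peaks(hip_angle.samples, prominence=cfg.min_peak_prominence)
    peak_times = hip_angle.start_time + peaks / hip_angle.rate
    lo, hi = cfg.cycle_duration_bounds
    cycles: list[RawCycle] = []
    for iv in intervals:
        inside = peaks[(peak_times >= iv.start) & (peak_times <= iv.end)]
        for a, b in zip(inside[:-1], inside[1:]):
            duration = (b - a) / hip_angle.rate
            if lo <= duration <= hi:
                cycles.append(RawCycle(angles=hip_angle.samples[a:b + 1].copy(),
                                       rate=hip_angle.rate,
                                       start_time=hip_angle.start_time + a / hip_angle.rate))
            if len(cycles) >= cfg.cycles_per_session:
                return cycles
    return cycles


def normalize_cycle(cycle: RawCycle, side: str = "") -> NormalizedGaitCycle:
    """Linear interpolation of a raw cycle onto 0,1,...,100 % of its duration."""
    if cycle.angles.size < 4:
        raise ParameterError(f"cycle too short to normalise ({cycle.angles.size} samples)")
    t = np.arange(cycle.angles.size) / cycle.rate
    grid = np.linspace(0.0, t[-1], 101)
    return NormalizedGaitCycle(np.interp(grid, t, cycle.angles), side=side)


def cycle_metrics(nc: NormalizedGaitCycle) -> GaitMetrics:
    """Extrema, ROM and extremum timing of a normalized cycle.

    Ties resolve to the first index (a constant cycle reports both extrema
    at 0 % with zero ROM).
    """
    a = nc.angles
    i_max = int(np.argmax(a))
    i_min = int(np.argmin(a))
    return GaitMetrics(max_angle=float(a[i_max]), min_angle=float(a[i_min]),
                       rom=float(a[i_max] - a[i_min]),
                       pct_at_max=float(i_max), pct_at_min=float(i_min))


def circular_mean_pct(pcts: Sequence[float]) -> float:
    """Mean of cycle percentages on the circle (0 % and 100 % coincide).

    Cycle delimitation puts the flexion peak at the 0 %/100 % wrap point, so
    per-cycle timing values cluster around the wrap; an arithmetic mean of
    {0, 100, 0, ...} would land mid-cycle.  Result in [0, 100).
    """
    ang = 2 * np.pi * np.asarray(pcts, dtype=float) / 100.0
    mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean / (2 * np.pi) * 100.0) % 100.0)


def circular_diff_pct(a: float, b: float) -> float:
    """Signed shortest difference a-b on the 0-100 cycle circle, in (-50, 50]."""
    d = (a - b) % 100.0
    return d - 100.0 if d > 50.0 else d


@dataclass(frozen=True)
class RepresentativeCycle:
    """Pointwise mean ± SEM curve plus cycle-averaged metrics for one side."""

    mean: np.ndarray
    sem: np.ndarray
    metrics: GaitMetrics
    n_cycles: int
    side: str = ""


def representative_cycle(cycles: Sequence[NormalizedGaitCycle]) -> RepresentativeCycle:
    """Average a set of normalized cycles.

    The metrics are the mean of the per-cycle metrics — the authoritative
    values — not re-extracted from the mean curve, whose extrema are damped
    whenever individual peaks are asynchronous.  Timing percentages are
    averaged circularly (see :func:`circular_mean_pct`): with peak-flexion
    delimitation the flexion extremum of each cycle sits at the 0 %/100 %
    wrap point.
    """
    if not cycles:
        raise ParameterError("representative_cycle requires at least one cycle")
    stack = np.stack([c.angles for c in cycles])
    mean = stack.mean(axis=0)
    if len(cycles) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(cycles))
    else:
        sem = np.zeros_like(mean)
    per = [cycle_metrics(c) for c in cycles]
    metrics = GaitMetrics(
        max_angle=float(np.mean([m.max_angle for m in per])),
        min_angle=float(np.mean([m.min_angle for m in per])),
        rom=float(np.mean([m.rom for m in per])),
        pct_at_max=circular_mean_pct([m.pct_at_max for m in per]),
        pct_at_min=circular_mean_pct([m.pct_at_min for m in per]))
    return RepresentativeCycle(mean=mean, sem=sem, metrics=metrics,
                               n_cycles=len(cycles), side=cycles[0].side)


def gait_delta(post: GaitMetrics, base: GaitMetrics) -> GaitDelta:
    """Baseline-relative change of the gait variables.

    Angle terms are 100*(post-base)/base (relative %, signed denominator, so
    a shallower extension — a negative baseline angle moving toward zero —
    reads as a negative change in extension); timing terms are
    percentage-point shifts along the cycle circle, signed with the shortest
    arc (negative = extremum reached earlier in the cycle; a 99 % vs 1 %
    comparison is a 2-point shift, not 98).  A zero baseline denominator
    yields NaN with a warning.
    """

    def rel(p: float, b: float) -> float:
        if b == 0:
            logger.warning("gait delta undefined: zero baseline value")
            return float("nan")
        return 100.0 * (p - b) / b

    return GaitDelta(d_max_pct=rel(post.max_angle, base.max_angle),
                     d_min_pct=rel(post.min_angle, base.min_angle),
                     d_rom_pct=rel(post.rom, base.rom),
                     d_pct_at_max=circular_diff_pct(post.pct_at_max, base.pct_at_max),
                     d_pct_at_min=circular_diff_pct(post.pct_at_min, base.pct_at_min))


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------

class GaitSessionModel:
    """Gait analysis of one session recording.

    ``fit()`` runs the full quantitative pipeline — resample to 1 kHz,
    zero-phase low-pass at 10 Hz, block-FFT walking detection, per-side
    cycle segmentation, 101-point normalization and metric extraction —
    and returns a :class:`GaitSessionResults`.
    """

    def __init__(self, session: SessionRecording,
                 cfg: GaitDetectionConfig = GaitDetectionConfig(), *,
                 ptibs_score: Optional[float] = None,
                 detection_axis: str = "medio_lateral"):
        self.session = session
        self.cfg = cfg
        self.ptibs_score = ptibs_score
        self.detection_axis = detection_axis

    def fit(self) -> "GaitSessionResults":
        det, hips = prepare_gait_channels(self.session, self.cfg,
                                          detection_axis=self.detection_axis)
        intervals: list[WalkingInterval] = []
        if det is not None:
            intervals = detect_walking(det, self.cfg)
        else:
            logger.warning("session %s/%s: no thoracic IMU, walking detection skipped",
                           self.session.animal_id, self.session.session)
        sides: dict[str, dict] = {}
        for side, hip in hips.items():
            raw = segment_cycles(hip, intervals, self.cfg)
            normalized = [normalize_cycle(c, side=side) for c in raw]
            sides[side] = {"raw": raw, "normalized": normalized,
                           "representative": (representative_cycle(normalized)
                                              if normalized else None)}
        return GaitSessionResults(self, intervals, sides)


class GaitSessionResults:
    """Walking intervals, per-side cycles and their metrics for one session."""

    def __init__(self, model: GaitSessionModel,
                 intervals: list[WalkingInterval], sides: dict[str, dict]):
        self.model = model
        self.session = model.session
        self.intervals = intervals
        self.sides = sides

    def n_cycles(self, side: str) -> int:
        return len(self.sides.get(side, {}).get("normalized", []))

    def analysable(self, side: str) -> bool:
        """Eligibility gate; the PTIBS score defaults permissive if unknown."""
        score = self.model.ptibs_score
        n = self.n_cycles(side)
        if score is None:
            return n >= self.model.cfg.min_cycles_required
        return eligibility(score, n)

    def metrics(self, side: str) -> Optional[GaitMetrics]:
        rep = self.sides.get(side, {}).get("representative")
        return rep.metrics if rep is not None else None

    def cycle_table(self) -> pd.DataFrame:
        rows = []
        for side, d in sorted(self.sides.items()):
            for i, (raw, nc) in enumerate(zip(d["raw"], d["normalized"])):
                m = cycle_metrics(nc)
                rows.append({"animal": self.session.animal_id,
                             "session": self.session.session, "side": side,
                             "cycle": i, "start_s": raw.start_time,
                             "duration_s": raw.duration,
                             "max_angle": m.max_angle, "min_angle": m.min_angle,
                             "rom": m.rom, "pct_at_max": m.pct_at_max,
                             "pct_at_min": m.pct_at_min})
        return pd.DataFrame(rows)

    def representative_table(self) -> pd.DataFrame:
        """101 rows per side: pct, mean_angle, sem_angle (Fig-style export)."""
        rows = []
        for side, d in sorted(self.sides.items()):
            rep = d["representative"]
            if rep is None:
                continue
            for pct in range(101):
                rows.append({"animal": self.session.animal_id,
                             "session": self.session.session, "side": side,
                             "pct": pct, "mean_angle": float(rep.mean[pct]),
                             "sem_angle": float(rep.sem[pct])})
        return pd.DataFrame(rows)

    def delta_vs(self, baseline: "GaitSessionResults", side: str) -> Optional[GaitDelta]:
        post, base = self.metrics(side), baseline.metrics(side)
        if post is None or base is None:
            return None
        return gait_delta(post, base)

    def summary(self) -> str:
        lines = [f"Gait session {self.session.animal_id}/{self.session.session}: "
                 f"{len(self.intervals)} walking interval(s)"]
        for iv in self.intervals:
            lines.append(f"  walking {iv.start:6.1f}-{iv.end:6.1f} s  "
                         f"dominant {iv.dominant_frequency:.2f} Hz")
        for side in sorted(self.sides):
            m = self.metrics(side)
            if m is None:
                lines.append(f"  {side} hip: no analysable cycles")
            else:
                lines.append(
                    f"  {side} hip: n={self.n_cycles(side)} cycles  "
                    f"flexion {m.max_angle:+.1f} deg @ {m.pct_at_max:.0f}%  "
                    f"extension {m.min_angle:+.1f} deg @ {m.pct_at_min:.0f}%  "
                    f"ROM {m.rom:.1f} deg")
        return "\n".join(lines)
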