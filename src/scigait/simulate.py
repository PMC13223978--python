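"""Seeded generators of piglet-like recording sessions with ground truth.

The study's raw animal recordings have no public accession, so every
pipeline stage is exercised against phenomenological synthetic sessions
that reproduce the statistical structure the analyses assume:

* **Activity sessions** — alternating rest/low/high epochs whose
  dorsal-plane (yaw) angular-acceleration magnitudes are drawn uniformly
  inside the corresponding intensity bin (0-5 / 5-50 / >50 deg/s^2, with a
  margin so additive sensor noise cannot move a sample across a bin edge),
  varied smoothly via linear interpolation between per-second knots.
* **Gait sessions** — walking bouts during which the thoracic medio-lateral
  component oscillates at a configurable rhythm (in or out of the
  2.5-4.0 Hz walking band) over a noise background, while both hip
  channels trace a smooth periodic flexion/extension waveform built from
  piecewise cubic smoothstep segments passing exactly through the
  prescribed (timing %, peak angle) extrema — asymmetric cycles
  (pct_at_max != 25 %) are therefore first-class.  Waveforms start and end
  on zero crossings so bout edges are continuous.
* **Studies** — a full 2-group (DAMAGED n=3, CONTROL n=1) x 3-session
  (Baseline, 2-d Post, 14-d Post) dataset written as delimited text plus a
  JSON truth manifest: paralysis at 2-d Post (no hip cycles, forelimb
  rhythm preserved), partial recovery at 14-d Post, PTIBS trajectories to
  match.

All generators are deterministic for a fixed seed.  Sensor rates default
to 2 kHz (IMU) and 1 kHz (goniometer) so the resampling path is always on.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .signals import (DEFAULT_IMU_AXES, ImuTriad, SessionRecording,
                      SignalChannel, write_channels)

logger = logging.getLogger(__name__)

STATES = ("rest", "low", "high")

#: Default uniform magnitude ranges per state (deg/s^2).  Kept clear of the
#: 5 and 50 deg/s^2 bin edges so smoothing and sensor noise cannot push a
#: sample into the neighbouring bin.
DEFAULT_STATE_RANGES: Mapping[str, tuple[float, float]] = {
    "rest": (0.2, 3.5), "low": (7.0, 45.0), "high": (55.0, 150.0)}

_BIN_EDGES = {"rest": (0.0, 5.0), "low": (5.0, 50.0), "high": (50.0, float("inf"))}


# ---------------------------------------------------------------------------
# Activity sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityScenario:
    """Epoch schedule and magnitude model for one activity session."""

    epochs: tuple[tuple[float, str], ...]   # (duration s, state)
    seed: int
    state_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_RANGES))
    noise_sd: float = 0.5
    imu_rate: float = 2000.0
    knot_interval_s: float = 1.0

    def __post_init__(self):
        if not self.epochs:
            raise ParameterError("activity schedule must contain at least one epoch")
        for dur, state in self.epochs:
            if dur <= 0:
                raise ParameterError(f"epoch durations must be positive, got {dur}")
            if state not in STATES:
                raise ParameterError(f"unknown state {state!r}; use one of {STATES}")
        for state, (lo, hi) in self.state_ranges.items():
            blo, bhi = _BIN_EDGES[state]
            if not (blo <= lo < hi <= bhi) and not (state == "high" and blo <= lo < hi):
                raise ParameterError(
                    f"{state} magnitude range ({lo}, {hi}) leaves its bin {_BIN_EDGES[state]}")

    @property
    def total_seconds(self) -> float:
        return sum(d for d, _ in self.epochs)

    def true_fractions(self) -> tuple[float, float, float]:
        """Scheduled (rest, low, high) time fractions in % (the ground truth)."""
        total = self.total_seconds
        sums = {s: 0.0 for s in STATES}
        for dur, state in self.epochs:
            sums[state] += dur
        return tuple(100.0 * sums[s] / total for s in STATES)

    @classmethod
    def from_fractions(cls, fractions: Sequence[float], seed: int, *,
                       total_seconds: float = 1800.0, epoch_seconds: float = 30.0,
                       **kwargs) -> "ActivityScenario":
        """Build a shuffled epoch schedule hitting the given state fractions.

        ``fractions`` are (rest, low, high) shares summing to 1; the default
        emulates the study's 30-min unsupervised recording as 30-s epochs.
        """
        frac = np.asarray(fractions, dtype=float)
        if frac.size != 3 or abs(frac.sum() - 1.0) > 1e-9 or np.any(frac < 0):
            raise ParameterError("fractions must be three non-negative shares summing to 1")
        n_epochs = int(round(total_seconds / epoch_seconds))
        counts = np.floor(frac * n_epochs).astype(int)
        # distribute the remainder to the largest fractional parts
        rem = n_epochs - counts.sum()
        order = np.argsort(-(frac * n_epochs - counts))
        for i in range(rem):
            counts[order[i % 3]] += 1
        states = [s for s, c in zip(STATES, counts) for _ in range(c)]
        rng = np.random.default_rng(seed)
        rng.shuffle(states)
        epochs = tuple((epoch_seconds, s) for s in states)
        return cls(epochs=epochs, seed=seed, **kwargs)


def _epoch_yaw_signal(scenario: ActivityScenario, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Signed yaw angular acceleration plus per-sample true state codes."""
    rate = scenario.imu_rate
    pieces, labels = [], []
    for dur, state in scenario.epochs:
        n = int(round(dur * rate))
        lo, hi = scenario.state_ranges[state]
        n_knots = max(2, int(round(dur / scenario.knot_interval_s)) + 1)
        knots_t = np.linspace(0, dur, n_knots)
        knots_v = rng.uniform(lo, hi, size=n_knots)
        t = np.arange(n) / rate
        mag = np.interp(t, knots_t, knots_v)
        sign = rng.choice([-1.0, 1.0])
        pieces.append(sign * mag)
        labels.append(np.full(n, STATES.index(state), dtype=np.int8))
    yaw = np.concatenate(pieces)
    yaw = yaw + rng.normal(0.0, scenario.noise_sd, size=yaw.size)
    return yaw, np.concatenate(labels)


def _noise_channel(n: int, rate: float, axis: str, sd: float,
                   rng: np.random.Generator) -> SignalChannel:
    return SignalChannel(rng.normal(0.0, sd, size=n), rate=rate,
                         units="deg/s^2", axis=axis)


def generate_activity_session(scenario: ActivityScenario, *,
                              animal_id: str = "synthetic", group: str = "DAMAGED",
                              session: str = "Baseline"
                              ) -> tuple[SessionRecording, np.ndarray]:
    """One activity session (both IMU placements) plus the true label track.

    The two placements share the epoch schedule (the animal has one
    behaviour) but draw independent in-bin magnitudes and noise.
    """
    rng = np.random.default_rng(scenario.seed)
    triads = {}
    labels = None
    for placement in ("thoracic_T4", "lumbar_L3"):
        yaw, lab = _epoch_yaw_signal(scenario, rng)
        if labels is None:
            labels = lab
        n = yaw.size
        ml = _noise_channel(n, scenario.imu_rate, "medio_lateral", scenario.noise_sd, rng)
        cc = _noise_channel(n, scenario.imu_rate, "cranio_caudal", scenario.noise_sd, rng)
        dv = SignalChannel(yaw, rate=scenario.imu_rate, units="deg/s^2",
                           axis="dorso_ventral")
        triads[placement] = ImuTriad(channels=(ml, cc, dv), placement=placement)
    rec = SessionRecording(animal_id=animal_id, group=group, session=session,
                           thoracic=triads["thoracic_T4"], lumbar=triads["lumbar_L3"])
    return rec, labels


# ---------------------------------------------------------------------------
# Gait sessions
# ---------------------------------------------------------------------------

def _smoothstep(s: np.ndarray) -> np.ndarray:
    return s * s * (3.0 - 2.0 * s)


def _inv_smoothstep(y: float) -> float:
    """Inverse of 3s^2-2s^3 on [0, 1] by bisection (monotone there)."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _smoothstep(np.asarray(mid)) < y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class HipWaveform:
    """Periodic hip-angle template through prescribed extrema.

    Two cubic smoothstep segments join (pct_at_max, peak flexion) to
    (pct_at_min, peak extension) and back; both segment endpoints have zero
    slope, so the template attains exactly the prescribed extrema at the
    prescribed cycle percentages and is monotone in between (no overshoot).
    """

    def __init__(self, flexion: float, extension: float,
                 pct_at_max: float, pct_at_min: float):
        if not (flexion > 0 > extension):
            raise ParameterError("need flexion > 0 > extension")
        if not (0 <= pct_at_max <= 100 and 0 <= pct_at_min <= 100):
            raise ParameterError("extrema percentages must lie in [0, 100]")
        if pct_at_max == pct_at_min:
            raise ParameterError("pct_at_max and pct_at_min must differ")
        self.flexion, self.extension = float(flexion), float(extension)
        self.pct_at_max, self.pct_at_min = float(pct_at_max), float(pct_at_min)
        self.p_max = pct_at_max / 100.0
        self.p_min = pct_at_min / 100.0
        # flexion -> extension arc, computed in percent space so prescribed
        # integer percentages stay exact
        self.d_fall = ((self.pct_at_min - self.pct_at_max) % 100.0) / 100.0

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        r = np.mod(np.asarray(phase, dtype=float) - self.p_max, 1.0)
        out = np.empty_like(r)
        falling = r < self.d_fall
        s1 = r[falling] / self.d_fall
        out[falling] = self.flexion + (self.extension - self.flexion) * _smoothstep(s1)
        s2 = (r[~falling] - self.d_fall) / (1.0 - self.d_fall)
        out[~falling] = self.extension + (self.flexion - self.extension) * _smoothstep(s2)
        return out

    @property
    def rising_zero_phase(self) -> float:
        """Phase of the upward zero crossing (extension -> flexion arc)."""
        s = _inv_smoothstep((0.0 - self.extension) / (self.flexion - self.extension))
        return (self.p_min + s * (1.0 - self.d_fall)) % 1.0

    @property
    def falling_zero_phase(self) -> float:
        s = _inv_smoothstep(self.flexion / (self.flexion - self.extension))
        return (self.p_max + s * self.d_fall) % 1.0


@dataclass(frozen=True)
class GaitScenario:
    """Walking bouts, hip waveform and noise model for one gait session."""

    seed: int
    duration_s: float = 60.0
    bouts: tuple[tuple[float, float], ...] = ((5.0, 20.0), (30.0, 50.0))
    stride_freq_hz: float = 3.0          # thoracic (forelimb) rhythm
    peak_flexion_deg: float = 25.0
    peak_extension_deg: float = -15.0
    pct_at_max: float = 40.0
    pct_at_min: float = 85.0
    cycle_duration_s: float = 0.65       # hip (hindlimb stride) period
    coupling_amplitude: float = 8.0      # thoracic ML oscillation, deg/s^2
    noise_sd: float = 1.6                # IMU noise; default SNR = 5
    # resting postural sway: a low-frequency background component below the
    # walking band, so idle periods have a realistic (sub-band) dominant
    # frequency instead of a spectrally flat floor
    sway_amplitude: float = 3.0          # deg/s^2
    sway_freq_hz: float = 0.8
    hip_noise_sd: float = 0.3            # goniometer noise, deg
    hip_active: bool = True              # False emulates hindlimb paralysis
    right_half_cycle_offset: bool = True
    imu_rate: float = 2000.0
    gonio_rate: float = 1000.0

    def __post_init__(self):
        if self.hip_active:
            HipWaveform(self.peak_flexion_deg, self.peak_extension_deg,
                        self.pct_at_max, self.pct_at_min)  # validates
        for (a, b) in self.bouts:
            if not (0 <= a < b):
                raise ParameterError(f"bout ({a}, {b}) must be ordered and non-negative")

    @property
    def snr(self) -> float:
        return self.coupling_amplitude / self.noise_sd

    def clipped_bouts(self) -> tuple[tuple[float, float], ...]:
        out = []
        for a, b in self.bouts:
            if a >= self.duration_s:
                logger.warning("bout (%g, %g) lies beyond the %g-s recording; dropped",
                               a, b, self.duration_s)
                continue
            if b > self.duration_s:
                logger.warning("bout (%g, %g) truncated at recording end %g s",
                               a, b, self.duration_s)
                b = self.duration_s
            out.append((a, b))
        return tuple(out)

    def true_block_labels(self, block_seconds: float = 5.0) -> np.ndarray:
        """Per-block walking truth: majority (>=50 %) overlap with a bout."""
        n_blocks = int(self.duration_s // block_seconds)
        labels = np.zeros(n_blocks, dtype=bool)
        for b in range(n_blocks):
            t0, t1 = b * block_seconds, (b + 1) * block_seconds
            ov = sum(max(0.0, min(t1, e) - max(t0, s)) for s, e in self.clipped_bouts())
            labels[b] = ov >= 0.5 * block_seconds
        return labels


@dataclass(frozen=True)
class GaitTruth:
    """Ground truth accompanying a generated gait session."""

    bouts: tuple[tuple[float, float], ...]
    cycles: pd.DataFrame        # side, start_s, end_s, duration_s, metrics...
    stride_freq_hz: float


def _hip_side_waveform(scenario: GaitScenario, wave: HipWaveform,
                       t: np.ndarray, start_offset: float
                       ) -> tuple[np.ndarray, list[dict]]:
    """Noise-free hip angles for one side plus its per-cycle truth rows."""
    angle = np.zeros_like(t)
    rows: list[dict] = []
    T = scenario.cycle_duration_s
    phase_r = wave.rising_zero_phase
    d_fall_zero = (wave.falling_zero_phase - phase_r) % 1.0
    for bs, be in scenario.clipped_bouts():
        s0 = bs + start_offset
        if be - s0 < T:          # no room for a single full cycle
            continue
        # last zero-crossing time within the bout (waveform ends continuous)
        k_r = int(np.floor((be - s0) / T))
        k_f = int(np.floor((be - s0 - d_fall_zero * T) / T))
        t_end = max(s0 + k_r * T, s0 + (d_fall_zero + k_f) * T)
        mask = (t >= s0) & (t <= t_end)
        angle[mask] = wave(phase_r + (t[mask] - s0) / T)
        # flexion-peak times inside the active window
        off = ((wave.p_max - phase_r) % 1.0) * T
        peaks = []
        k = 0
        while s0 + off + k * T <= t_end + 1e-12:
            peaks.append(s0 + off + k * T)
            k += 1
        for a, b in zip(peaks[:-1], peaks[1:]):
            rows.append({"start_s": a, "end_s": b, "duration_s": b - a,
                         "max_angle": wave.flexion, "min_angle": wave.extension,
                         "rom": wave.flexion - wave.extension,
                         "pct_at_max": 0.0,
                         "pct_at_min": wave.d_fall * 100.0})
    return angle, rows


def generate_gait_session(scenario: GaitScenario, *,
                          animal_id: str = "synthetic", group: str = "DAMAGED",
                          session: str = "Baseline"
                          ) -> tuple[SessionRecording, GaitTruth]:
    """One corridor-walking session plus its truth table.

    The truth cycle table is expressed in the analysis convention (cycles
    delimited peak-flexion to peak-flexion, so the flexion extremum sits at
    0 % ≡ 100 % of the cycle and the extension extremum at the prescribed
    arc fraction between flexion peaks).
    """
    rng = np.random.default_rng(scenario.seed)
    t_imu = np.arange(int(round(scenario.duration_s * scenario.imu_rate))) / scenario.imu_rate
    t_g = np.arange(int(round(scenario.duration_s * scenario.gonio_rate))) / scenario.gonio_rate

    # thoracic medio-lateral rhythm during bouts over a noise + sway background
    ml = rng.normal(0.0, scenario.noise_sd, size=t_imu.size)
    if scenario.sway_amplitude > 0:
        phi0 = rng.uniform(0, 2 * np.pi)
        ml += scenario.sway_amplitude * np.sin(
            2 * np.pi * scenario.sway_freq_hz * t_imu + phi0)
    for bs, be in scenario.clipped_bouts():
        phi = rng.uniform(0, 2 * np.pi)
        m = (t_imu >= bs) & (t_imu < be)
        ml[m] += scenario.coupling_amplitude * np.sin(
            2 * np.pi * scenario.stride_freq_hz * (t_imu[m] - bs) + phi)

    def triad(placement: str, ml_samples: np.ndarray | None) -> ImuTriad:
        chans = []
        for axis in DEFAULT_IMU_AXES:
            if axis == "medio_lateral" and ml_samples is not None:
                samples = ml_samples
            else:
                samples = rng.normal(0.0, scenario.noise_sd, size=t_imu.size)
            chans.append(SignalChannel(samples, rate=scenario.imu_rate,
                                       units="deg/s^2", axis=axis))
        return ImuTriad(channels=tuple(chans), placement=placement)

    thoracic = triad("thoracic_T4", ml)
    lumbar = triad("lumbar_L3", None)

    cycle_rows: list[dict] = []
    hips = {}
    for side in ("left", "right"):
        offset = (scenario.cycle_duration_s / 2.0
                  if (side == "right" and scenario.right_half_cycle_offset) else 0.0)
        if scenario.hip_active:
            wave = HipWaveform(scenario.peak_flexion_deg, scenario.peak_extension_deg,
                               scenario.pct_at_max, scenario.pct_at_min)
            angle, rows = _hip_side_waveform(scenario, wave, t_g, offset)
        else:
            angle, rows = np.zeros_like(t_g), []
        for r in rows:
            r["side"] = side
        cycle_rows.extend(rows)
        angle = angle + rng.normal(0.0, scenario.hip_noise_sd, size=t_g.size)
        hips[side] = SignalChannel(angle, rate=scenario.gonio_rate, units="deg",
                                   axis="flexion")

    columns = ["side", "start_s", "end_s", "duration_s", "max_angle",
               "min_angle", "rom", "pct_at_max", "pct_at_min"]
    cycles = pd.DataFrame(cycle_rows, columns=columns)
    rec = SessionRecording(animal_id=animal_id, group=group, session=session,
                           thoracic=thoracic, lumbar=lumbar,
                           hip_left=hips["left"], hip_right=hips["right"])
    return rec, GaitTruth(bouts=scenario.clipped_bouts(), cycles=cycles,
                          stride_freq_hz=scenario.stride_freq_hz)


# ---------------------------------------------------------------------------
# Full study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionEffects:
    """Per-session generator parameters for one study group."""

    activity_fractions: tuple[float, float, float]   # rest/low/high shares
    hip_active: bool
    peak_flexion_deg: float = 25.0
    peak_extension_deg: float = -15.0
    pct_at_max: float = 40.0
    pct_at_min: float = 85.0
    ptibs_observer_scores: tuple[tuple[int, ...], ...] = ((10, 10, 10),)


def _default_effects() -> dict[tuple[str, str], SessionEffects]:
    """Study-shaped defaults: paralysis at 2-d Post, partial recovery at 14-d.

    DAMAGED tuples carry one observer triple per animal (n=3); CONTROL one.
    """
    return {
        ("DAMAGED", "Baseline"): SessionEffects(
            (0.45, 0.40, 0.15), hip_active=True,
            ptibs_observer_scores=((10, 10, 10),) * 3),
        ("DAMAGED", "Post2d"): SessionEffects(
            (0.78, 0.19, 0.03), hip_active=False,
            ptibs_observer_scores=((1, 1, 1),) * 3),
        ("DAMAGED", "Post14d"): SessionEffects(
            (0.50, 0.38, 0.12), hip_active=True, peak_flexion_deg=24.3,
            peak_extension_deg=-9.6, pct_at_max=35.0, pct_at_min=83.0,
            ptibs_observer_scores=((4, 4, 3), (3, 3, 4), (4, 3, 3))),
        ("CONTROL", "Baseline"): SessionEffects(
            (0.45, 0.40, 0.15), hip_active=True,
            ptibs_observer_scores=((10, 10, 10),)),
        ("CONTROL", "Post2d"): SessionEffects(
            (0.82, 0.15, 0.03), hip_active=False,
            ptibs_observer_scores=((2, 2, 2),)),
        ("CONTROL", "Post14d"): SessionEffects(
            (0.48, 0.38, 0.14), hip_active=True, peak_flexion_deg=27.0,
            peak_extension_deg=-20.0, pct_at_max=41.0, pct_at_min=80.0,
            ptibs_observer_scores=((8, 8, 8),)),
    }


@dataclass(frozen=True)
class StudyDesign:
    """Design of a full synthetic study (Fig-3-style session layout)."""

    seed: int
    n_damaged: int = 3
    n_control: int = 1
    activity_total_s: float = 60.0
    activity_epoch_s: float = 5.0
    gait_duration_s: float = 40.0
    gait_bouts: tuple[tuple[float, float], ...] = ((5.0, 15.0), (20.0, 35.0))
    effects: Mapping[tuple[str, str], SessionEffects] = field(
        default_factory=_default_effects)

    # DAMAGED animals beyond this index stay non-ambulatory at 14-d Post
    # (only one of two analysable DAMAGED piglets at 14 d in the design).
    n_damaged_recovering: int = 1

    def animals(self) -> list[tuple[str, str]]:
        out = [(f"D{i + 1}", "DAMAGED") for i in range(self.n_damaged)]
        out += [(f"C{i + 1}", "CONTROL") for i in range(self.n_control)]
        return out


def generate_study(design: StudyDesign, out_dir) -> dict:
    """Write a full synthetic study directory and return its truth manifest.

    Layout::

        out_dir/
          manifest.json
          ptibs_scores.csv
          <animal>/<session>/activity_imu_{thoracic,lumbar}.csv
          <animal>/<session>/gait_imu_{thoracic,lumbar}.csv
          <animal>/<session>/gait_hip_{left,right}.csv
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(design.seed)
    manifest: dict = {"seed": design.seed, "animals": {}, "sessions": list(
        ("Baseline", "Post2d", "Post14d"))}
    ptibs_rows = []

    for a_idx, (animal, group) in enumerate(design.animals()):
        manifest["animals"][animal] = {"group": group, "sessions": {}}
        for session in ("Baseline", "Post2d", "Post14d"):
            eff = design.effects[(group, session)]
            sdir = out / animal / session
            sdir.mkdir(parents=True, exist_ok=True)
            seed_a = int(master.integers(2**31 - 1))
            seed_g = int(master.integers(2**31 - 1))

            act = ActivityScenario.from_fractions(
                eff.activity_fractions, seed=seed_a,
                total_seconds=design.activity_total_s,
                epoch_seconds=design.activity_epoch_s)
            rec_a, _labels = generate_activity_session(
                act, animal_id=animal, group=group, session=session)
            for placement, name in (("thoracic_T4", "activity_imu_thoracic.csv"),
                                    ("lumbar_L3", "activity_imu_lumbar.csv")):
                tri = rec_a.thoracic if placement == "thoracic_T4" else rec_a.lumbar
                write_channels(sdir / name,
                               {"ml": tri.channels[0], "cc": tri.channels[1],
                                "dv": tri.channels[2]})

            hip_active = eff.hip_active
            if (group == "DAMAGED" and session == "Post14d"
                    and a_idx >= design.n_damaged_recovering):
                hip_active = False
            gait = GaitScenario(seed=seed_g, duration_s=design.gait_duration_s,
                                bouts=design.gait_bouts,
                                hip_active=hip_active,
                                peak_flexion_deg=eff.peak_flexion_deg,
                                peak_extension_deg=eff.peak_extension_deg,
                                pct_at_max=eff.pct_at_max,
                                pct_at_min=eff.pct_at_min)
            rec_g, truth = generate_gait_session(
                gait, animal_id=animal, group=group, session=session)
            write_channels(sdir / "gait_imu_thoracic.csv",
                           {"ml": rec_g.thoracic.channels[0],
                            "cc": rec_g.thoracic.channels[1],
                            "dv": rec_g.thoracic.channels[2]})
            write_channels(sdir / "gait_imu_lumbar.csv",
                           {"ml": rec_g.lumbar.channels[0],
                            "cc": rec_g.lumbar.channels[1],
                            "dv": rec_g.lumbar.channels[2]})
            write_channels(sdir / "gait_hip_left.csv", {"angle_deg": rec_g.hip_left})
            write_channels(sdir / "gait_hip_right.csv", {"angle_deg": rec_g.hip_right})

            scores = eff.ptibs_observer_scores[
                a_idx if group == "DAMAGED" else a_idx - design.n_damaged]
            for obs, s in enumerate(scores, start=1):
                ptibs_rows.append({"animal": animal, "group": group,
                                   "session": session, "observer": obs, "score": s})

            manifest["animals"][animal]["sessions"][session] = {
                "activity": {"seed": seed_a,
                             "true_fractions": list(act.true_fractions()),
                             "files": ["activity_imu_thoracic.csv",
                                       "activity_imu_lumbar.csv"]},
                "gait": {"seed": seed_g, "hip_active": hip_active,
                         "bouts": [list(b) for b in truth.bouts],
                         "stride_freq_hz": truth.stride_freq_hz,
                         "true_cycles": truth.cycles.to_dict(orient="records"),
                         "files": ["gait_imu_thoracic.csv", "gait_imu_lumbar.csv",
                                   "gait_hip_left.csv", "gait_hip_right.csv"]},
                "ptibs": {"observer_scores": list(scores)},
            }

    pd.DataFrame(ptibs_rows).to_csv(out / "ptibs_scores.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
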