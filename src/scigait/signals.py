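"""Core signal containers, delimited-text I/O and filtering primitives.

All downstream stages (activity binning, walking detection, gait-cycle
kinematics) consume :class:`SignalChannel`, a uniformly sampled scalar
series with an explicit rate, physical units and axis label.  Session data
are grouped into :class:`SessionRecording`: two tri-axial IMU triads
(thoracic T4 and lumbar L3 placement, angular acceleration in deg/s^2) plus
a left/right pair of hip electro-goniometer channels (degrees; 0 deg is the
upright anatomical reference, flexion positive, extension negative).

Filtering conventions
---------------------
* Savitzky-Golay smoothing is parameterised by a frame *duration* in
  seconds; the window length in samples is ``round(frame_seconds * rate)``
  forced to the next odd integer (the algorithm requires odd windows).
* The Butterworth low-pass is applied forward-backward (zero phase) so that
  event timing — gait-cycle extrema percentages — is not biased by filter
  lag; ``order`` is the per-pass design order.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigError, DataError, ParameterError, SchemaError

logger = logging.getLogger(__name__)

#: Units accepted by SignalChannel (ASCII spellings of deg/s^2, deg, m/s^2,
#: plus deg/s for devices that log angular velocity before differentiation).
VALID_UNITS = ("deg/s^2", "deg", "m/s^2", "deg/s")

PLACEMENTS = ("thoracic_T4", "lumbar_L3")
SESSIONS = ("Baseline", "Post2d", "Post14d")
GROUPS = ("DAMAGED", "CONTROL")

#: Default anatomical axis labels for an IMU triad.  ``dorso_ventral`` is the
#: yaw axis (rotation parallel to the dorsal plane, i.e. turning left/right)
#: used for activity binning; ``medio_lateral`` is the component used for
#: walking-rhythm detection on the thoracic sensor.
DEFAULT_IMU_AXES = ("medio_lateral", "cranio_caudal", "dorso_ventral")


@dataclass(frozen=True, eq=False)
class SignalChannel:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    samples : array-like of float
        At least one sample.
    rate : float
        Sampling rate in Hz, strictly positive.
    units : str
        One of :data:`VALID_UNITS`.
    axis : str
        Free-form axis label (e.g. ``"medio_lateral"``, ``"flexion"``).
    start_time : float
        Time of the first sample in seconds (0-based at recording start).
    """

    samples: np.ndarray
    rate: float
    units: str = "deg/s^2"
    axis: str = ""
    start_time: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ParameterError("SignalChannel requires a 1-D array with >= 1 sample")
        if not (self.rate > 0):
            raise ParameterError(f"rate must be strictly positive, got {self.rate}")
        if self.units not in VALID_UNITS:
            raise ParameterError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration (n-1)/rate in seconds."""
        return (self.n - 1) / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    def with_samples(self, samples, rate: float | None = None) -> "SignalChannel":
        """Copy with new samples (and optionally rate); units/axis preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       rate=self.rate if rate is None else float(rate))


@dataclass(frozen=True)
class ImuTriad:
    """Three angular-acceleration channels about orthogonal device axes."""

    channels: tuple[SignalChannel, SignalChannel, SignalChannel]
    placement: str

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ParameterError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        if len(self.channels) != 3:
            raise ParameterError("an IMU triad holds exactly three channels")
        rates = {c.rate for c in self.channels}
        lengths = {c.n for c in self.channels}
        if len(rates) != 1 or len(lengths) != 1:
            raise DataError("triad channels must share rate and length")

    @property
    def rate(self) -> float:
        return self.channels[0].rate

    @property
    def axes(self) -> tuple[str, str, str]:
        return tuple(c.axis for c in self.channels)

    def channel(self, axis: str) -> SignalChannel:
        for c in self.channels:
            if c.axis == axis:
                return c
        raise ConfigError(f"triad at {self.placement} has no axis {axis!r}; axes: {self.axes}")


@dataclass(frozen=True)
class SessionRecording:
    """One animal x one session (Baseline / 2-d Post / 14-d Post)."""

    animal_id: str
    group: str
    session: str
    thoracic: Optional[ImuTriad] = None
    lumbar: Optional[ImuTriad] = None
    hip_left: Optional[SignalChannel] = None
    hip_right: Optional[SignalChannel] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session not in SESSIONS:
            raise ParameterError(f"session must be one of {SESSIONS}, got {self.session!r}")

    def triad(self, placement: str) -> Optional[ImuTriad]:
        if placement in ("thoracic", "thoracic_T4"):
            return self.thoracic
        if placement in ("lumbar", "lumbar_L3"):
            return self.lumbar
        raise ParameterError(f"unknown placement {placement!r}")

    def hip(self, side: str) -> Optional[SignalChannel]:
        if side == "left":
            return self.hip_left
        if side == "right":
            return self.hip_right
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSchema:
    """Column/axis map for the delimited session files.

    ``imu_axis_columns`` maps anatomical axis label -> column name in the IMU
    files; ``differentiate_gyro`` enables central-difference differentiation
    for devices exporting angular velocity (deg/s) instead of angular
    acceleration.
    """

    time_column: str = "time_s"
    imu_axis_columns: Mapping[str, str] = field(
        default_factory=lambda: {"medio_lateral": "ml", "cranio_caudal": "cc",
                                 "dorso_ventral": "dv"})
    hip_angle_column: str = "angle_deg"
    imu_nominal_rate: float = 2000.0
    gonio_nominal_rate: float = 1000.0
    rate_tolerance: float = 0.01
    differentiate_gyro: bool = False


def _infer_rate(time: np.ndarray, tolerance: float,
                nominal: float | None, path) -> float:
    if time.size < 2:
        raise DataError(f"{path}: cannot infer a sampling rate from a single row")
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise DataError(f"{path}: time column not strictly increasing at row {bad + 1}")
    med = float(np.median(dt))
    if float(np.max(np.abs(dt - med))) / med > tolerance:
        raise DataError(
            f"{path}: non-uniform sampling beyond {tolerance:.1%} of the median "
            f"step ({med:.6g} s); gaps are not imputed")
    rate = 1.0 / med
    if nominal is not None and abs(rate - nominal) / nominal > tolerance:
        logger.warning("%s: inferred rate %.6g Hz deviates >%.0f%% from nominal %g Hz",
                       path, rate, tolerance * 100, nominal)
    return rate


def read_channels(path, columns: Mapping[str, str], *, time_column: str = "time_s",
                  units: str = "deg/s^2", nominal_rate: float | None = None,
                  rate_tolerance: float = 0.01) -> dict[str, SignalChannel]:
    """Read named channels from a comma- or tab-delimited text file.

    ``columns`` maps the output axis label to the column name in the file.
    The time column must be in seconds, strictly increasing and near-uniform
    (within ``rate_tolerance`` of the median step).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in [time_column, *columns.values()] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; "
                          f"found {list(df.columns)}")
    time = df[time_column].to_numpy(dtype=float)
    rate = _infer_rate(time, rate_tolerance, nominal_rate, path)
    start = float(time[0])
    return {axis: SignalChannel(df[col].to_numpy(dtype=float), rate=rate,
                                units=units, axis=axis, start_time=start)
            for axis, col in columns.items()}


def write_channels(path, channels: Mapping[str, SignalChannel], *,
                   time_column: str = "time_s", float_format: str = "%.6f",
                   delimiter: str = ",") -> None:
    """Write channels back to delimited text (round-trips with read_channels)."""
    chans = list(channels.values())
    if not chans:
        raise ParameterError("write_channels requires at least one channel")
    if len({c.rate for c in chans}) != 1 or len({c.n for c in chans}) != 1:
        raise ParameterError("all channels in one file must share rate and length")
    df = pd.DataFrame({time_column: chans[0].times()})
    for name, ch in channels.items():
        df[name] = ch.samples
    df.to_csv(path, index=False, float_format=float_format, sep=delimiter)


def _load_triad(path, schema: SessionSchema, placement: str) -> ImuTriad:
    units = "deg/s" if schema.differentiate_gyro else "deg/s^2"
    chans = read_channels(path, schema.imu_axis_columns,
                          time_column=schema.time_column, units=units,
                          nominal_rate=schema.imu_nominal_rate,
                          rate_tolerance=schema.rate_tolerance)
    ordered = [chans[a] for a in schema.imu_axis_columns]
    if schema.differentiate_gyro:
        ordered = [differentiate(c) for c in ordered]
    return ImuTriad(channels=tuple(ordered), placement=placement)


def load_session(paths: Mapping[str, object], schema: SessionSchema | None = None, *,
                 animal_id: str, group: str, session: str) -> SessionRecording:
    """Assemble a SessionRecording from delimited files.

    ``paths`` may provide any of the keys ``thoracic``, ``lumbar``,
    ``hip_left``, ``hip_right``; absent keys yield None fields (downstream
    stages degrade gracefully and warn).
    """
    schema = schema or SessionSchema()
    kwargs: dict[str, object] = {}
    if "thoracic" in paths:
        kwargs["thoracic"] = _load_triad(paths["thoracic"], schema, "thoracic_T4")
    if "lumbar" in paths:
        kwargs["lumbar"] = _load_triad(paths["lumbar"], schema, "lumbar_L3")
    for side in ("hip_left", "hip_right"):
        if side in paths:
            chans = read_channels(paths[side], {"flexion": schema.hip_angle_column},
                                  time_column=schema.time_column, units="deg",
                                  nominal_rate=schema.gonio_nominal_rate,
                                  rate_tolerance=schema.rate_tolerance)
            kwargs[side] = chans["flexion"]
    return SessionRecording(animal_id=animal_id, group=group, session=session, **kwargs)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def resample(channel: SignalChannel, target_rate: float) -> SignalChannel:
    """Polyphase resampling to ``target_rate`` (anti-alias filtered).

    Identity when the target equals the input rate.  Duration is preserved
    within one sample period of the coarser grid.
    """
    if not (target_rate > 0):
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if math.isclose(target_rate, channel.rate, rel_tol=1e-12):
        return channel
    frac = Fraction(target_rate / channel.rate).limit_denominator(10_000)
    out = sps.resample_poly(channel.samples, frac.numerator, frac.denominator,
                            padtype="line")
    return channel.with_samples(out, rate=target_rate)


def savgol_filter(channel: SignalChannel, poly_order: int = 3,
                  frame_seconds: float = 0.051) -> SignalChannel:
    """Savitzky-Golay least-squares smoothing.

    The window is ``round(frame_seconds * rate)`` samples, forced odd by
    rounding up (102 samples at 2 kHz becomes 103; at 1 kHz the 0.051 s frame
    is exactly 51).
    """
    window = int(round(frame_seconds * channel.rate))
    if window % 2 == 0:
        window += 1
    if window <= poly_order:
        raise ParameterError(
            f"SG window ({window} samples from {frame_seconds} s at "
            f"{channel.rate} Hz) must exceed poly_order={poly_order}")
    if window > channel.n:
        raise ParameterError(f"SG window {window} exceeds signal length {channel.n}")
    out = sps.savgol_filter(channel.samples, window_length=window, polyorder=poly_order)
    return channel.with_samples(out)


def butterworth_lowpass(channel: SignalChannel, order: int = 4,
                        cutoff_hz: float = 10.0) -> SignalChannel:
    """Zero-phase (forward-backward) Butterworth low-pass; DC gain 1.

    ``order`` is the per-pass design order; the effective magnitude response
    is squared by the two passes.
    """
    nyq = channel.rate / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ParameterError(f"cutoff_hz must lie in (0, {nyq}) Hz, got {cutoff_hz}")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=channel.rate, output="sos")
    out = sps.sosfiltfilt(sos, channel.samples)
    return channel.with_samples(out)


def differentiate(channel: SignalChannel) -> SignalChannel:
    """Central-difference time derivative (deg/s -> deg/s^2)."""
    deriv = np.gradient(channel.samples, 1.0 / channel.rate)
    units = {"deg/s": "deg/s^2", "deg": "deg/s"}.get(channel.units, channel.units)
    return replace(channel, samples=deriv, units=units)
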