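"""Reading, writing, resampling and slicing lumbar IMU recordings.

A recording is a uniformly sampled six-axis signal from a sensor worn on
the lower back: triaxial accelerometer in m/s^2 (x = vertical including
gravity, y = medial-lateral, z = anterior-posterior) and, optionally, a
triaxial gyroscope in rad/s.  On-disk format is plain delimited text with
a header row ``t,ax,ay,az,gx,gy,gz``; the gyroscope columns may be absent
(accelerometer-only devices), in which case downstream feature extraction
is restricted to the accelerometer set.

Time convention: seconds; sample ``i`` nominally at ``time[0] + i/fs``;
event intervals are half-open ``[start, end)`` so that windows tiled over
adjacent events never share a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "ImuRecording",
    "EventAnnotation",
    "FormatError",
    "SamplingError",
    "STANDARD_GRAVITY",
    "ACTIVITY_LABELS",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "resample_recording",
    "slice_by_annotation",
]

STANDARD_GRAVITY = 9.81  # m/s^2

ACTIVITY_LABELS = frozenset({"ascent", "descent", "gait"})

# Relative tolerance on sample spacing: |dt - 1/fs| < _DT_RTOL / fs.
_DT_RTOL = 1e-6


class FormatError(ValueError):
    """A signal or annotation file does not match the expected layout."""


class SamplingError(ValueError):
    """A time column is not uniformly sampled at the declared rate."""


@dataclass
class ImuRecording:
    """Uniformly sampled six-axis (or accelerometer-only) lumbar signal.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing, uniform at ``1/fs``.
    accel : ndarray, shape (n, 3)
        Acceleration in m/s^2, columns (x=vertical incl. gravity,
        y=medial-lateral, z=anterior-posterior).
    gyro : ndarray of shape (n, 3), or None
        Angular velocity in rad/s, same column convention; ``None`` for
        accelerometer-only recordings.
    fs : float
        Sampling rate in Hz.
    subject_id, visit_id : str
        Opaque provenance labels.
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray | None
    fs: float
    subject_id: str = ""
    visit_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = self.time.shape[0]
        if n < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.accel.shape != (n, 3):
            raise ValueError(f"accel shape {self.accel.shape} != ({n}, 3)")
        if self.gyro is not None and self.gyro.shape != (n, 3):
            raise ValueError(f"gyro shape {self.gyro.shape} != ({n}, 3)")
        _check_uniform(self.time, self.fs)

    # convenience channel views -------------------------------------------------
    @property
    def accel_x(self) -> np.ndarray:
        return self.accel[:, 0]

    @property
    def accel_y(self) -> np.ndarray:
        return self.accel[:, 1]

    @property
    def accel_z(self) -> np.ndarray:
        return self.accel[:, 2]

    @property
    def has_gyro(self) -> bool:
        return self.gyro is not None

    @property
    def n_samples(self) -> int:
        return int(self.time.shape[0])

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, ``(n-1)/fs``."""
        return float(self.time[-1] - self.time[0])

    @property
    def span(self) -> tuple[float, float]:
        """Half-open time span covered by the recording, ``[t0, t_last + 1/fs)``."""
        return float(self.time[0]), float(self.time[-1] + 1.0 / self.fs)


def _check_uniform(time: np.ndarray, fs: float) -> None:
    dt = np.diff(time)
    step = 1.0 / fs
    bad = np.flatnonzero(np.abs(dt - step) >= _DT_RTOL * step)
    if bad.size:
        i = int(bad[0])
        raise SamplingError(
            f"non-uniform sampling at index {i}: dt={dt[i]:.9g} s, expected {step:.9g} s"
        )


@dataclass(frozen=True)
class EventAnnotation:
    """A labeled half-open time interval ``[start, end)`` in a recording."""

    start: float
    end: float
    label: str
    task_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(
                f"label {self.label!r} not in {sorted(ACTIVITY_LABELS)}"
            )


_ACCEL_COLS = ("ax", "ay", "az")
_GYRO_COLS = ("gx", "gy", "gz")


def read_recording(
    path: str | Path,
    fs: float,
    *,
    units: str = "ms2",
    subject_id: str = "",
    visit_id: str = "",
) -> ImuRecording:
    """Read a delimited-text IMU recording.

    Expects a header row with columns ``t, ax, ay, az`` and optionally
    ``gx, gy, gz``.  ``units`` is ``"ms2"`` (native) or ``"g"``; g-unit
    accelerometer data is converted by 9.81.
    """
    if units not in ("ms2", "g"):
        raise ValueError(f"units must be 'ms2' or 'g', got {units!r}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed text
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ("t", *_ACCEL_COLS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_gyro = all(c in df.columns for c in _GYRO_COLS)
    accel = df.loc[:, list(_ACCEL_COLS)].to_numpy(dtype=float)
    if units == "g":
        accel = accel * STANDARD_GRAVITY
    gyro = df.loc[:, list(_GYRO_COLS)].to_numpy(dtype=float) if has_gyro else None
    return ImuRecording(
        time=df["t"].to_numpy(dtype=float),
        accel=accel,
        gyro=gyro,
        fs=float(fs),
        subject_id=subject_id,
        visit_id=visit_id,
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV (columns t,ax,ay,az[,gx,gy,gz]), full precision."""
    cols = {"t": rec.time}
    for i, c in enumerate(_ACCEL_COLS):
        cols[c] = rec.accel[:, i]
    if rec.gyro is not None:
        for i, c in enumerate(_GYRO_COLS):
            cols[c] = rec.gyro[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation CSV with columns ``start,end,label,task_id``."""
    try:
        df = pd.read_csv(path, dtype={"task_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ("start", "end", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "task_id" not in df.columns:
        df["task_id"] = ""
    return [
        EventAnnotation(float(r.start), float(r.end), str(r.label), str(r.task_id))
        for r in df.itertuples()
    ]


def write_annotations(anns: Sequence[EventAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start": [a.start for a in anns],
            "end": [a.end for a in anns],
            "label": [a.label for a in anns],
            "task_id": [a.task_id for a in anns],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def resample_recording(rec: ImuRecording, target_fs: float) -> ImuRecording:
    """Downsample a recording with polyphase anti-aliased (zero-phase) filtering.

    Only downsampling is supported (``target_fs <= rec.fs``); upsampling a
    recording adds no information and is rejected.  Duration is preserved
    to within one output sample.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling not supported (target {target_fs} Hz > source {rec.fs} Hz)"
        )
    if math.isclose(target_fs, rec.fs):
        return replace(rec)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator

    def _poly(arr: np.ndarray) -> np.ndarray:
        # demean per channel so the anti-alias FIR's slightly non-unity DC
        # gain cannot bias constant offsets (gravity); restore after
        mean = arr.mean(axis=0, keepdims=True)
        # high-beta Kaiser: passband flat to ~1e-7 so repeated resampling
        # composes consistently
        return (
            resample_poly(
                arr - mean, up, down, axis=0, padtype="line", window=("kaiser", 14.0)
            )
            + mean
        )

    accel = _poly(rec.accel)
    gyro = _poly(rec.gyro) if rec.gyro is not None else None
    n_out = accel.shape[0]
    time = rec.time[0] + np.arange(n_out) / target_fs
    return ImuRecording(
        time=time,
        accel=accel,
        gyro=gyro,
        fs=float(target_fs),
        subject_id=rec.subject_id,
        visit_id=rec.visit_id,
    )


def slice_by_annotation(rec: ImuRecording, ann: EventAnnotation) -> ImuRecording:
    """Extract the samples with ``ann.start <= t < ann.end`` as a new recording."""
    lo, hi = rec.span
    eps = _DT_RTOL / rec.fs
    if ann.start < lo - eps or ann.end > hi + eps:
        raise IndexError(
            f"annotation [{ann.start}, {ann.end}) outside recording span [{lo}, {hi})"
        )
    mask = (rec.time >= ann.start - eps) & (rec.time < ann.end - eps)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise IndexError(
            f"annotation [{ann.start}, {ann.end}) selects fewer than 2 samples"
        )
    sl = slice(int(idx[0]), int(idx[-1]) + 1)
    return ImuRecording(
        time=rec.time[sl],
        accel=rec.accel[sl],
        gyro=rec.gyro[sl] if rec.gyro is not None else None,
        fs=rec.fs,
        subject_id=rec.subject_id,
        visit_id=rec.visit_id,
    )
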