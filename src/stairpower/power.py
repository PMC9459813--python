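"""Stair climb power (SCP): stopwatch formula and sensor-interval formula.

The clinical Stair Climb Power Test reports the mechanical power of
lifting body mass through the staircase height:

    P = m * g * h / t          (stopwatch method)

with m the participant mass (kg), g = 9.81 m/s^2, h the total height
climbed (m, ~0.6 m for a four-step staircase) and t the stopwatch time
from "go" until both feet reach the top.

The sensor method works from detected initial contacts t_1..t_4 on a
staircase of per-step height h4.  The stopwatch interval includes the
un-instrumented time from "go" to the first contact, which the sensor
cannot observe; it is imputed as t0 = mean of the detected step
intervals.  The four-step form

    P = m * g * h4 * 4 / (t0 + (t_2-t_1) + (t_3-t_2) + (t_4-t_3))

reduces algebraically to m*g*h4 / mean(intervals), and that reduced form
extends naturally to partial detections: intervals flagged as
misdetections (> 1.2 s) are simply dropped from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import STANDARD_GRAVITY
from .step_detection import StepDetectionResult

__all__ = [
    "ScpResult",
    "UnresolvableTrialError",
    "DEFAULT_STEP_HEIGHT_M",
    "standard_scp",
    "stairpy_scp",
    "scp_from_contacts_literal",
    "scp_from_detection",
    "apply_calibration",
]

#: Per-step riser height of a typical four-step test staircase, meters.
DEFAULT_STEP_HEIGHT_M = 0.154


class UnresolvableTrialError(ValueError):
    """No valid step interval remains, so no power can be estimated."""


@dataclass(frozen=True)
class ScpResult:
    """A stair climb power estimate plus the components that produced it."""

    power: float  # watts (after calibration offset, if any)
    method: str  # {"standard", "stairpy"}
    components: dict = field(default_factory=dict)
    calibration_offset: float = 0.0


def standard_scp(
    m: float, h: float, t: float, *, g: float = STANDARD_GRAVITY
) -> float:
    """Stopwatch stair climb power m*g*h/t in watts."""
    if m <= 0 or h <= 0 or t <= 0:
        raise ValueError(f"m, h, t must all be positive (got {m}, {h}, {t})")
    return m * g * h / t


def stairpy_scp(
    m: float,
    h4: float,
    intervals: Sequence[float],
    valid_mask: Sequence[bool] | None = None,
    *,
    g: float = STANDARD_GRAVITY,
) -> ScpResult:
    """Sensor stair climb power from detected step intervals.

    Computes ``m * g * h4 / mean(valid intervals)``.  With a complete
    four-contact detection this is identical to the explicit four-step
    formula with the imputed t0 term (see :func:`scp_from_contacts_literal`);
    with partial detections the invalid intervals are dropped.

    Raises :class:`UnresolvableTrialError` when no valid interval remains.
    """
    if m <= 0 or h4 <= 0:
        raise ValueError(f"m and h4 must be positive (got {m}, {h4})")
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0:
        raise UnresolvableTrialError("no step intervals provided")
    if np.any(iv <= 0):
        raise ValueError("intervals must all be positive")
    mask = (
        np.ones(iv.size, dtype=bool)
        if valid_mask is None
        else np.asarray(valid_mask, dtype=bool)
    )
    if mask.size != iv.size:
        raise ValueError("valid_mask length must match intervals")
    valid = iv[mask]
    if valid.size == 0:
        raise UnresolvableTrialError(
            "no valid step interval (all exceeded the misdetection threshold)"
        )
    mean_iv = float(valid.mean())
    power = m * g * h4 / mean_iv
    return ScpResult(
        power=power,
        method="stairpy",
        components={
            "mass_kg": m,
            "g": g,
            "step_height_m": h4,
            "intervals_s": iv.tolist(),
            "valid_mask": mask.tolist(),
            "t0_s": mean_iv,
            "mean_valid_interval_s": mean_iv,
        },
    )


def scp_from_contacts_literal(
    m: float,
    h4: float,
    contact_times: Sequence[float],
    *,
    g: float = STANDARD_GRAVITY,
) -> float:
    """Literal four-step sensor formula, written out term by term.

    ``m*g*h4*k / (t0 + (t_2-t_1) + ... + (t_k - t_{k-1}))`` with
    ``k = len(contacts)`` detected steps and ``t0 = mean(intervals)``.
    Exists as an independent cross-check of the reduced mean-interval
    form used by :func:`stairpy_scp`.
    """
    t = np.asarray(contact_times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 contacts")
    intervals = np.diff(t)
    t0 = float(intervals.mean())
    denom = t0 + float(intervals.sum())
    return m * g * h4 * t.size / denom


def scp_from_detection(
    m: float,
    res: StepDetectionResult,
    h4: float = DEFAULT_STEP_HEIGHT_M,
    *,
    g: float = STANDARD_GRAVITY,
) -> ScpResult:
    """Power from a :class:`StepDetectionResult`, honoring its validity mask."""
    return stairpy_scp(m, h4, res.intervals, res.valid_mask, g=g)


def apply_calibration(res: ScpResult, offset: float) -> ScpResult:
    """Add an optional additive calibration offset (watts) to an estimate.

    Default workflow leaves the estimate uncorrected (offset 0): the raw
    sensor value is arguably the better estimate of true power, and a
    constant offset is irrelevant for within-subject change over time.
    Offsets compose additively.
    """
    return replace(
        res,
        power=res.power + offset,
        calibration_offset=res.calibration_offset + offset,
    )
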