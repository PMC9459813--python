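"""Fixed-length sliding-window segmentation of labeled recordings.

Activity classification operates on short windows rather than whole
events: each annotated event (stair ascent, stair descent, level gait)
is cut into 1.5 s windows with 50% overlap.  Windowing is applied per
sliced event, never across annotation boundaries, so a window can never
mix activity labels.

At 50 Hz a 1.5 s window is 75 samples, whose exact half is 37.5 samples;
the hop is floored to 37 samples so the realized overlap is >= the
requested fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ACTIVITY_LABELS, ImuRecording

__all__ = ["SegmentWindow", "make_windows"]


@dataclass
class SegmentWindow:
    """One fixed-length window of a labeled recording, with provenance."""

    accel: np.ndarray  # (W, 3) m/s^2
    gyro: np.ndarray | None  # (W, 3) rad/s or None
    fs: float
    label: str
    subject_id: str = ""
    visit_id: str = ""
    task_id: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"label {self.label!r} not in {sorted(ACTIVITY_LABELS)}")
        if self.gyro is not None and self.gyro.shape != self.accel.shape:
            raise ValueError("gyro and accel windows must have equal shape")

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    @property
    def has_gyro(self) -> bool:
        return self.gyro is not None


def make_windows(
    rec: ImuRecording,
    label: str,
    *,
    window_s: float = 1.5,
    overlap: float = 0.5,
    task_id: str = "",
) -> list[SegmentWindow]:
    """Cut a (single-activity) recording into overlapping fixed windows.

    Window length is ``W = round(window_s * fs)`` samples and the hop is
    ``H = floor(W * (1 - overlap))``; windows start at samples 0, H, 2H, ...
    and a trailing partial window is discarded, giving
    ``floor((N - W) / H) + 1`` windows.  A recording shorter than one
    window yields an empty list with a warning rather than an error, so
    that batch processing of short events degrades gracefully.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if window_s <= 0:
        raise ValueError(f"window_s must be positive, got {window_s}")
    w = int(round(window_s * rec.fs))
    h = int(math.floor(w * (1.0 - overlap)))
    if h < 1:
        raise ValueError("hop is zero; decrease overlap or enlarge window")
    n = rec.n_samples
    if n < w:
        warnings.warn(
            f"recording of {n} samples shorter than one {w}-sample window; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    starts = range(0, n - w + 1, h)
    out = []
    for s in starts:
        out.append(
            SegmentWindow(
                accel=rec.accel[s : s + w],
                gyro=rec.gyro[s : s + w] if rec.gyro is not None else None,
                fs=rec.fs,
                label=label,
                subject_id=rec.subject_id,
                visit_id=rec.visit_id,
                task_id=task_id,
                start_time=float(rec.time[s]),
            )
        )
    return out
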