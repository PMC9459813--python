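"""Structured run configuration: one inspectable home for every constant.

Every numeric choice the pipeline makes (detector constants, window
geometry, classifier grids, calibration offset, seed) lives here, can be
loaded from a YAML file, and is echoed -- together with a content hash --
into every JSON artifact the command-line tools write, so any output can
be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .classify import DEFAULT_GRIDS
from .step_detection import DetectorConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    window_s: float = 1.5
    overlap: float = 0.5
    target_fs: float = 50.0
    units: str = "ms2"
    step_height_m: float = 0.154
    calibration_offset_w: float = 0.0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    grids: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        """Block embedded in every JSON artifact."""
        import stairpower

        return {
            "config_hash": self.config_hash(),
            "config": self.to_dict(),
            "version": stairpower.__version__,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        det = d.pop("detector", None)
        cfg = cls(**d)
        if det is not None:
            try:
                cfg.detector = DetectorConfig(**det)
            except TypeError as exc:
                raise ValueError(f"invalid detector config: {exc}") from exc
        return cfg


def load_config(path: str | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)
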