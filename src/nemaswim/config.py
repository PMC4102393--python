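"""YAML configuration: one file holding the analysis and tracking defaults.

Example
-------
::

    trial:
      mode_energy_eps: 0.005
      curvature_window_fraction: 0.0833
    tracking:
      std_kernel: 5
      keyframe_every: 20

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Tuple

import yaml

from .tracking import TrackingParams
from .trial import TrialConfig

__all__ = ["load_config"]


def _build(cls, section: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> Tuple[TrialConfig, TrackingParams]:
    """Read a YAML config file; missing sections fall back to defaults."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    trial = _build(TrialConfig, dict(raw.get("trial", {})))
    tracking = _build(TrackingParams, dict(raw.get("tracking", {})))
    return trial, tracking
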