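"""Run configuration: defaults, YAML loading, and overrides.

Every analysis parameter defaults to the study-protocol value where one is
defined (20-ms PETH bins, the -10 s to -2 s baseline, the 4-consecutive-bin
modulation rule over -2 s to +3 s, 250-ms epoch bins, 200-ms/100-ms decoder
windows with 10 CV splits, 500 runs and 5 shuffled nulls, the 10-success
session filter, and the 1000-spike unit filter). Simulation sizes and the
decoder's run counts can be scaled in the config; the effective
(fully-resolved) configuration is persisted with every run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class SimulateConfig:
    n_mice_per_group: int = 9
    units_per_mouse: int = 5
    criterion_ms: int = 1600
    log_duration_median_ms: float = 1100.0
    log_duration_sigma: float = 0.55
    mean_ipi_ms: float = 9000.0
    max_rewards: int = 60
    max_session_min: float = 90.0
    cie_press_gain_multiplier: float = 1.5
    cie_outcome_gain_multiplier: float = 0.5


@dataclass
class PethConfig:
    bin_width_ms: float = 20.0
    window_ms: tuple[float, float] = (-10_000.0, 10_000.0)
    baseline_window_ms: tuple[float, float] = (-10_000.0, -2_000.0)
    detection_window_ms: tuple[float, float] = (-2_000.0, 3_000.0)
    min_consecutive_bins: int = 4
    smooth_sigma_bins: float = 0.4
    interval_method: str = "percentile"  # or "parametric" (mean +/- 1.96 SD)


@dataclass
class DecodingConfig:
    min_successes: int = 10
    n_runs: int = 500
    n_nulls: int = 5
    n_splits: int = 10
    step_ms: float = 100.0
    width_ms: float = 200.0
    svm_c: float = 1.0
    n_per_class_cap: Optional[int] = None
    alignments: tuple[str, ...] = ("press_onset", "press_offset")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    session_table: Optional[str] = None  # load instead of simulate when set
    spike_table: Optional[str] = None
    min_spikes_per_unit: int = 1000
    analysis_criterion_ms: int = 1600
    n_last_sessions: int = 2
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    peth: PethConfig = field(default_factory=PethConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _apply(obj: Any, overrides: dict[str, Any], context: str = "config") -> None:
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown {context} key: {key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, context=f"{context}.{key}")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def load_config(path=None, overrides: Optional[dict[str, Any]] = None) -> RunConfig:
    """Defaults, optionally updated from a YAML file, then from overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _apply(cfg, data)
    if overrides:
        _apply(cfg, overrides)
    return cfg
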