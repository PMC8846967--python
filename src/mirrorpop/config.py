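"""Pipeline configuration.

All numeric analysis parameters live here so that every downstream result is a
pure function of (Dataset, PipelineConfig).  Defaults are the study's analysis
settings: 20-ms bins, 60-ms Gaussian smoothing (interpreted as the kernel's
standard deviation), soft-normalization floor of +5 spk/s, a −600/+800 ms
analysis window around the alignment event, a 500-ms movement epoch, a 500-ms
pre-object baseline, a 200-ms / 20-ms sliding t-test with a five-consecutive-bin
rule at α = 0.05 uncorrected, and a 2,000-iteration unit-resampling bootstrap
with a 97.5% sign-consistency criterion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    bin_width: float = 0.020          # s
    smooth_sd: float = 0.060          # s (Gaussian kernel s.d.)
    soft_norm_floor: float = 5.0      # spk/s added to each unit's max |rate|
    epoch_window: tuple[float, float] = (-0.600, 0.800)   # s rel. align event
    movement_epoch: tuple[float, float] = (0.0, 0.500)    # s rel. align event
    baseline_window: tuple[float, float] = (-0.500, 0.0)  # s rel. object presentation
    sign_epoch: tuple[float, float] = (-0.600, 0.600)     # s rel. align event
    heatmap_window: tuple[float, float] = (-0.600, 0.600) # s rel. align event
    ttest_interval: tuple[float, float] = (-0.600, 0.600) # s rel. align event
    ttest_window: float = 0.200       # s
    ttest_step: float = 0.020         # s
    consec_bins: int = 5
    alpha: float = 0.05
    n_boot: int = 2000
    boot_criterion: float = 0.975
    min_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epoch_window", "movement_epoch", "baseline_window",
                     "sign_epoch", "heatmap_window", "ttest_interval"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must have positive length, got ({lo}, {hi})")
        if self.bin_width <= 0 or self.smooth_sd <= 0 or self.ttest_window <= 0 \
                or self.ttest_step <= 0:
            raise ValueError("bin_width, smooth_sd, ttest_window, ttest_step must be > 0")
        if self.consec_bins < 1:
            raise ValueError("consec_bins must be >= 1")
        if not 0.0 < self.boot_criterion < 1.0:
            raise ValueError("boot_criterion must lie in (0, 1)")
        if self.soft_norm_floor < 0:
            raise ValueError("soft_norm_floor must be >= 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @property
    def n_bins(self) -> int:
        """Number of analysis bins T (70 at defaults)."""
        t0, t1 = self.epoch_window
        n = (t1 - t0) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_window length must be divisible by bin_width")
        return int(round(n))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
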