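"""Run configuration shared across pipeline stages.

A single structured (YAML) file holds the bin sizes, window half-widths,
spike-in locus and thresholds used throughout; every run logs the resolved
configuration and seed so results are reproducible from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # profile construction
    profile_bin: int = 1            # bp, native endpoint resolution
    profile_halfwidth: int = 5000   # bp around each hotspot center
    # resection estimation
    resection_bin_mean: int = 10    # bp bins for mean/min resection
    resection_bin_max: int = 20     # bp bins for maximum resection
    resection_halfwidth: int = 4000  # bp window for E(x)
    max_halfwidth: int = 6000       # bp, dynamic background needs 5-6 kb
    window_bins: int = 5            # sliding-window width for min/max scans
    alpha: float = 0.05             # one-sided t-test level for min resection
    # central-peak decomposition
    central_halfwidth: int = 200    # bp, central peak width ~400 bp
    flank_range: tuple[int, int] = (800, 3000)  # |offset| range for height matching
    # spike-in normalization
    spike_chrom: str = "chrS"
    spike_pos: int = 100_000
    spike_ratio: float = 0.02       # spike cells : bulk cells = 1:50
    spike_window: int = 5000        # bp around centers for intensity sums
    # peak calling / QC thresholds
    min_fold: float = 2.5
    frip_min: float = 0.01
    nsc_min: float = 1.05
    rsc_min: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.flank_range = tuple(self.flank_range)
        for name in ("profile_bin", "profile_halfwidth", "resection_bin_mean",
                     "resection_bin_max", "resection_halfwidth",
                     "max_halfwidth", "window_bins", "central_halfwidth",
                     "spike_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.spike_ratio <= 1):
            raise ValueError("spike_ratio must be in (0, 1]")
        if self.flank_range[0] >= self.flank_range[1]:
            raise ValueError("flank_range must be increasing")

    @property
    def spike_divisor(self) -> float:
        """Mixing divisor implied by the spike ratio (1:50 for 2%)."""
        return 1.0 / self.spike_ratio

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides take precedence."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.log()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)

    def resolved(self) -> dict:
        d = asdict(self)
        d["flank_range"] = list(self.flank_range)
        return d

    def log(self) -> None:
        logger.info("resolved config: %s", self.resolved())
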