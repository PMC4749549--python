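"""Configuration objects for simulation, event detection, and the pipeline.

All randomness in the package flows from a single root seed through named
substreams (see :func:`substream`), so each stage is independently
reproducible when other stages are toggled or re-run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

ENVIRONMENTS = ("A", "B")
DEFAULT_DAYS = (1, 3, 5, 7, 9, 11, 13, 15)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a reproducible RNG for a named substream of a root seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic two-environment longitudinal experiment.

    The defaults emulate the study design the analysis assumes: 8 recording
    days spaced every other calendar day over 15 days, two linear-track
    environments per day, five 3-minute trials per session sampled at 20 Hz
    on a 96 cm track divided into 24 bins of 4 cm.
    """

    n_cells: int = 200
    day_values: Sequence[int] = DEFAULT_DAYS
    trials_per_session: int = 5
    trial_duration: float = 180.0          # s
    frame_rate: float = 20.0               # Hz
    track_length: float = 96.0             # cm
    n_bins: int = 24
    run_speed: float = 20.0                # cm/s, constant lap speed
    pause_mean: float = 2.0                # s, mean exponential dwell at track ends
    place_cell_fraction: float = 0.5
    field_width: float = 10.0              # cm, full width at half maximum
    base_rate: float = 0.05                # events/s, median cell rate while active
    rate_spread: float = 0.4               # log-std of per-cell base rates
    active_fraction: float = 0.6           # stationary fraction of active cells
    recruitment_persistence: float = 0.8   # P(active at d+1 step | active at d)
    shared_drift_sigma: float = 0.25       # per-calendar-day std, shared log-rate walk
    env_drift_sigma: float = 0.12          # per-calendar-day std, env-specific walk
    env_gain_sigma: float = 0.4            # log-std of static per-env rate gains
    remap_mode: bool = True                # independent field positions per environment
    amp_median: float = 0.3                # dF/F, median event amplitude
    amp_sigma: float = 0.35                # log-std of event amplitudes
    kernel_rise: float = 0.2               # s
    kernel_decay: float = 0.75             # s
    noise_sigma: float = 0.02              # dF/F
    footprint_radius: float = 8.0          # µm, 50%-of-max radius
    footprint_jitter: float = 2.0          # µm per session
    fov_size: float = 400.0                # µm, square field of view
    min_separation: float = 20.0           # µm, minimum centroid spacing
    um_per_px: float = 1.0
    seed: int = 0

    @property
    def n_days(self) -> int:
        return len(self.day_values)

    @property
    def bin_width(self) -> float:
        return self.track_length / self.n_bins

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    def validate(self) -> "SimConfig":
        if self.trial_duration <= 0 or self.frame_rate <= 0:
            raise InvalidConfigError("trial_duration and frame_rate must be positive")
        if self.n_cells < 1 or self.trials_per_session < 1 or self.n_days < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.track_length <= 0 or self.n_bins < 1:
            raise InvalidConfigError("track geometry invalid")
        for name in ("place_cell_fraction", "active_fraction",
                     "recruitment_persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        for name in ("base_rate", "shared_drift_sigma", "env_drift_sigma",
                     "env_gain_sigma",
                     "noise_sigma", "footprint_jitter", "pause_mean"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.run_speed <= 0:
            raise InvalidConfigError("run_speed must be positive")
        if self.kernel_decay <= self.kernel_rise or self.kernel_rise <= 0:
            raise InvalidConfigError("require kernel_decay > kernel_rise > 0")
        if self.footprint_radius <= 0 or self.fov_size <= 0 or self.um_per_px <= 0:
            raise InvalidConfigError("footprint geometry must be positive")
        if len(set(self.day_values)) != len(self.day_values):
            raise InvalidConfigError("day_values must be distinct")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["day_values"] = list(self.day_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "day_values" in d:
            d["day_values"] = tuple(d["day_values"])
        return cls(**d)


@dataclass
class DetectionParams:
    """Thresholds for Ca2+ event detection from dF/F traces.

    ``mad_threshold``/``peak_over_prev``/``peak_over_next`` default to the
    slow-indicator setting (4 / 4 / 2 MAD); a fast indicator uses 5 / 5 / 2.5.
    MAD is the raw median absolute deviation without the 1.4826
    normal-consistency factor: the integer multipliers absorb the constant.
    """

    mad_threshold: float = 4.0
    peak_over_prev: float = 4.0
    peak_over_next: float = 2.0
    lowpass_cutoff: float = 2.0       # Hz
    baseline_window: float = 20.0     # s, sliding-median window
    neighbor_radius: float = 18.0     # µm
    crosstalk_window: float = 0.2     # s, closed interval on |dt|
    dedup_correlation: float = 0.9
    dedup_bin: float = 0.1            # s, bin for event-train correlation
    decay_rise_ratio_min: float = 2.0
    indicator_decay: float = 0.75     # s, nominal indicator decay constant
    decay_bounds: tuple = (0.2, 5.0)  # acceptable decay, × indicator_decay

    def validate(self) -> "DetectionParams":
        for name in ("mad_threshold", "peak_over_prev", "peak_over_next",
                     "lowpass_cutoff", "baseline_window", "crosstalk_window",
                     "neighbor_radius", "indicator_decay"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decay_bounds"] = list(self.decay_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        d = dict(d)
        if "decay_bounds" in d:
            d["decay_bounds"] = tuple(d["decay_bounds"])
        return cls(**d)


def session_keys(config: SimConfig) -> list[tuple[str, int]]:
    """All (environment, day) session identifiers in chronological order."""
    return [(env, day) for day in config.day_values for env in ENVIRONMENTS]
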