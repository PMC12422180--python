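"""Configuration objects shared across the simulation and analysis pipeline.

Every parameter that the task paradigm, the real-time controller or the
offline analysis depends on lives in one of the frozen dataclasses below, so
that a run is fully described by a :class:`RunConfig` (plus a seed) and can be
serialized to a flat YAML file.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = [
    "TaskGeometry",
    "KinematicsModel",
    "StimProtocol",
    "SpeedThresholds",
    "EpochSpec",
    "RunConfig",
    "config_hash",
]


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry of the tablet reaching task.

    Targets alternate between a left and a right x position; each side offers
    four vertical positions, giving 32 distinct start-y x end-y x direction
    trajectory classes.
    """

    screen_w: int = 1920
    screen_h: int = 1080
    target_x_left: int = 100
    target_x_right: int = 1820
    target_ys: tuple[int, ...] = (390, 465, 615, 690)
    rect_size: int = 175
    inter_movement_interval: float = 0.350  # s of dwell between movements

    def __post_init__(self) -> None:
        if not self.target_x_left < self.target_x_right:
            raise ValueError("target_x_left must be < target_x_right")
        if any(not (0 <= y <= self.screen_h) for y in self.target_ys):
            raise ValueError("all target_ys must lie within [0, screen_h]")
        if self.rect_size <= 0:
            raise ValueError("rect_size must be positive")
        if self.inter_movement_interval < 0:
            raise ValueError("inter_movement_interval must be >= 0")


@dataclass(frozen=True)
class KinematicsModel:
    """Generative model of reach kinematics.

    Peak speed of movement i (before noise and reinforcement) follows a
    geometric bradykinetic decrement ``peak_speed_start * (1-decrement_rate)**i``.
    ``reinforcement_delta`` is the fractional change applied to the target
    peak speed of the next same-direction movement after a stimulated
    movement (positive after fast-classified, negative after slow-classified
    stimulated movements).
    """

    sample_rate: float = 62.0  # Hz
    duration_mean: float = 0.812  # s
    duration_sd: float = 0.115  # s
    peak_speed_start: float = 1800.0  # px/s
    decrement_rate: float = 0.002  # fraction per movement
    noise_cv: float = 0.10  # multiplicative peak-speed noise CV
    reinforcement_delta: float = 0.0
    position_noise_sd: float = 2.0  # px, additive per sample
    timing_jitter: float = 0.0  # fraction of 1/sample_rate, uniform jitter

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")
        if self.duration_sd < 0 or self.noise_cv < 0 or self.position_noise_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not abs(self.reinforcement_delta) < 1:
            raise ValueError("|reinforcement_delta| must be < 1")
        if not 0 <= self.decrement_rate < 1:
            raise ValueError("decrement_rate must lie in [0, 1)")


@dataclass(frozen=True)
class StimProtocol:
    """Block structure and stimulation-burst bookkeeping.

    Stimulation parameters beyond the burst duration (frequency, pulse width,
    amplitude) are metadata only; no electrical model is attached to them.
    """

    condition_order: tuple[str, ...] = ("fast", "slow")  # conditions of stim blocks
    burst_duration: float = 0.300  # s
    stim_frequency: float = 130.0  # Hz, metadata
    pulse_width_us: float = 60.0  # metadata
    amplitude_ma: float = 2.0  # metadata
    block_length: int = 96  # movements per block
    n_blocks: int = 4
    stim_blocks: tuple[int, ...] = (1, 3)  # 1-indexed

    def __post_init__(self) -> None:
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if self.block_length < 3:
            raise ValueError("block_length must be >= 3")
        if any(b < 1 or b > self.n_blocks for b in self.stim_blocks):
            raise ValueError("stim_blocks must be a subset of the blocks")
        if len(self.condition_order) != len(self.stim_blocks):
            raise ValueError("need one condition per stimulation block")
        if any(c not in ("fast", "slow") for c in self.condition_order):
            raise ValueError("conditions must be 'fast' or 'slow'")

    def block_condition(self, block: int) -> str | None:
        """Target condition of a (1-indexed) block, None for recovery blocks."""
        if block in self.stim_blocks:
            return self.condition_order[self.stim_blocks.index(block)]
        return None


@dataclass(frozen=True)
class SpeedThresholds:
    """Offline behavioral thresholds.

    Defaults are the published constants: the movement threshold is 3 SD
    above pooled rest-period speed, the outlier threshold 3 SD above the
    pooled average movement speed.
    """

    movement_threshold: float = 800.77  # px/s
    outlier_threshold: float = 2413.35  # px/s
    rest_window: float = 0.300  # s
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.movement_threshold < self.outlier_threshold:
            raise ValueError(
                "need 0 < movement_threshold < outlier_threshold"
            )
        if self.rest_window <= 0:
            raise ValueError("rest_window must be positive")


@dataclass(frozen=True)
class EpochSpec:
    """Parameters of the event-related spectral analysis.

    Epochs are 2 s windows centred on the time of peak speed; power is
    z-scored against the -400..-100 ms pre-peak baseline; beta is 20-35 Hz;
    the two analysis windows bracket the stimulation artifact, each DBS
    on/offset is masked with a +/-65 ms window, and time points where at
    least 15% of epochs are masked are excluded from cluster statistics.
    """

    sample_rate: float = 1000.0  # Hz
    window: tuple[float, float] = (-1.0, 1.0)  # s around peak speed
    baseline: tuple[float, float] = (-0.400, -0.100)  # s
    beta_band: tuple[float, float] = (20.0, 35.0)  # Hz
    stim_window: tuple[float, float] = (0.13, 0.30)  # s
    post_window: tuple[float, float] = (0.41, 1.00)  # s
    artifact_halfwidth: float = 0.065  # s
    nan_epoch_fraction: float = 0.15
    n_cycles: float = 4.0
    freq_lo: float = 5.0  # Hz, TFR grid
    freq_hi: float = 45.0
    freq_step: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.baseline[1] <= 0:
            raise ValueError("baseline must precede the peak-speed time")
        if not self.stim_window[1] <= self.post_window[0]:
            raise ValueError("stim_window must precede post_window")
        if not 0 < self.nan_epoch_fraction < 1:
            raise ValueError("nan_epoch_fraction must lie in (0, 1)")
        if self.n_cycles <= 0 or self.artifact_halfwidth < 0:
            raise ValueError("n_cycles must be > 0, artifact_halfwidth >= 0")

    @property
    def frequencies(self) -> tuple[float, ...]:
        out = []
        f = self.freq_lo
        while f <= self.freq_hi + 1e-9:
            out.append(round(f, 6))
            f += self.freq_step
        return tuple(out)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    n_subjects: int = 1
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    kinematics: KinematicsModel = field(default_factory=KinematicsModel)
    protocol: StimProtocol = field(default_factory=StimProtocol)
    thresholds: SpeedThresholds = field(default_factory=SpeedThresholds)
    epoch_spec: EpochSpec = field(default_factory=EpochSpec)

    def subject_protocol(self, subject: int) -> StimProtocol:
        """Protocol for one subject; condition order alternates across subjects."""
        if subject % 2 == 0:
            return self.protocol
        return dataclasses.replace(
            self.protocol, condition_order=tuple(reversed(self.protocol.condition_order))
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, key):
            sub = raw.get(key, {})
            if sub is None:
                sub = {}
            sub = {k: _tuplify(v) for k, v in sub.items()}
            return klass(**sub)

        return cls(
            seed=int(raw.get("seed", 0)),
            n_subjects=int(raw.get("n_subjects", 1)),
            geometry=build(TaskGeometry, "geometry"),
            kinematics=build(KinematicsModel, "kinematics"),
            protocol=build(StimProtocol, "protocol"),
            thresholds=build(SpeedThresholds, "thresholds"),
            epoch_spec=build(EpochSpec, "epoch_spec"),
        )


def _tuplify(v):
    if isinstance(v, list):
        return tuple(v)
    return v


def _plainify(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj


def config_hash(config: RunConfig | dict | Sequence | str) -> str:
    """Short stable hash identifying a configuration in output files."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    payload = yaml.safe_dump(_plainify(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
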