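"""Acquisition and pipeline configuration.

Every threshold used by the analysis stages lives here with its default, so a
single config file reproduces a full run. Defaults mirror the published
pipeline constants: 3-min frame interval, 100-px debris filter, perinuclear
ring 1 px away and 5 px thick, trace pruning at 10 h / 3 contiguous gap
frames / 5% total gaps, 6-point healing kernel, 10,000 bootstrap resamples
at a 95% confidence level, and 24/12-h mitotic-entry windows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

CHANNEL_ROLES = ("nuclear", "donor", "acceptor")


@dataclass
class NoiseModel:
    """Additive Gaussian read noise plus optional Poisson shot noise.

    ``poisson_scale`` is the photon count per intensity unit; 0 disables shot
    noise. ``gaussian_sd`` is in intensity units; 0 disables read noise.
    """

    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0

    @property
    def noise_free(self) -> bool:
        return self.gaussian_sd == 0 and self.poisson_scale == 0


@dataclass
class AcquisitionConfig:
    """Imaging parameters of a (real or simulated) time-lapse movie."""

    frame_interval_min: float = 3.0
    n_frames: int = 2
    image_size: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.55
    channel_roles: Tuple[str, ...] = CHANNEL_ROLES
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        roles = tuple(self.channel_roles)
        if sorted(roles) != sorted(CHANNEL_ROLES):
            raise ValueError(
                f"channel_roles must be a permutation of {CHANNEL_ROLES}, got {roles}"
            )
        self.channel_roles = roles
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        self.image_size = tuple(self.image_size)

    def channel_index(self, role: str) -> int:
        return self.channel_roles.index(role)

    @property
    def duration_hours(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min / 60.0

    def times_min(self):
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass
class SegmentationConfig:
    threshold_method: str = "otsu"  # or "fixed"
    threshold_value: float | None = None
    seed_min_distance: int = 5
    min_area_px: int = 100  # debris filter: objects < 100 px are discarded


@dataclass
class TrackingConfig:
    max_gap_frames: int = 3  # re-link across gaps of up to 3 frames
    ambiguity_margin: float = 0.10  # top-two overlaps within 10% -> ambiguous


@dataclass
class RingConfig:
    inner_gap_px: float = 1.0  # ring starts 1 px away from the nucleus
    thickness_px: float = 5.0  # and is 5 px thick
    metric: str = "euclidean"  # or "chebyshev"


@dataclass
class QCConfig:
    min_hours: float = 10.0
    max_contig_gap_frames: int = 3
    max_gap_fraction: float = 0.05
    heal_kernel: int = 6


@dataclass
class BootstrapConfig:
    n_resamples: int = 10_000
    ci_level: float = 95.0
    resample_unit: str = "cell"  # or "value"
    t0_index: int = 0


@dataclass
class FateConfig:
    area_drop_fraction: float = 0.60
    trailing_median_frames: int = 10
    split_horizon_frames: int = 20
    window_hours: float = 24.0  # 24 h default; 12 h for mitogen conditions
    allowed_windows: Tuple[float, float] = (24.0, 12.0)


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    ring: RingConfig = field(default_factory=RingConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    fate: FateConfig = field(default_factory=FateConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                sub = d[f.name]
                kwargs[f.name] = f.default_factory().__class__(**sub)  # type: ignore[misc]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config from YAML/JSON, or return defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        return PipelineConfig.from_yaml(path)
    return PipelineConfig.from_dict(json.loads(path.read_text()))
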