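"""Render ground-truth cohorts into three-channel time-lapse stacks.

Channels follow the biosensor-imaging roles: a bright nuclear marker
(H2B-mCherry role) for segmentation/tracking, and a FRET donor (ECFP role)
and acceptor (YPet role) pair whose ring-mean ratio reports ERK activity.

The activity-to-ratio map is linear, ``r(a) = r0 + k*a`` with r0 = 1.0 and
k = 0.25, giving a ~25% ratio swing over the default pulse amplitude — the
dynamic range of a typical ERK FRET reporter. In a noise-free render the
acceptor/donor ratio is uniform over each cell's cytoplasm and equals
``r(a)`` exactly, so an ideal ring measurement recovers the programmed
activity without bias.

During mitosis the nucleus condenses (area shrinks to 40%) and brightens
(2x); after division two daughter nuclei appear. Cells overlapping the image
border are rendered clipped and carry ``border_flag`` in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .config import AcquisitionConfig
from .cohort import GroundTruthTable

RATIO_INTERCEPT = 1.0  # r0: ring ratio at zero activity
RATIO_GAIN = 0.25  # k: ratio change per activity unit
NUCLEAR_INTENSITY = 1000.0
DONOR_INTENSITY = 500.0
BACKGROUND = 10.0


def activity_to_ratio(activity, r0: float = RATIO_INTERCEPT, k: float = RATIO_GAIN):
    """Monotone map from true ERK activity to acceptor/donor ring ratio."""
    return r0 + k * np.asarray(activity, dtype=float)


@dataclass
class ImageStack:
    """T x C x H x W intensity stack with channel-role metadata."""

    data: np.ndarray
    channel_roles: tuple[str, ...]
    frame_interval_min: float
    pixel_size_um: float = 0.55

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be T x C x H x W")
        if self.data.shape[1] != len(self.channel_roles):
            raise ValueError("channel count does not match channel_roles")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, role: str) -> np.ndarray:
        return self.data[:, self.channel_roles.index(role)]

    def frame(self, t: int, role: str) -> np.ndarray:
        return self.data[t, self.channel_roles.index(role)]

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            metadata={
                "axes": "TCYX",
                "channel_roles": list(self.channel_roles),
                "frame_interval_min": self.frame_interval_min,
            },
        )


def _set_disk(img: np.ndarray, y: float, x: float, r: float, value: float) -> None:
    """Paint a hard disk of the given value; clips at image borders.

    Painting replaces rather than adds, so each pixel belongs to exactly one
    emitting cell and the in-cell acceptor/donor ratio is exact per pixel.
    """
    H, W = img.shape
    y0, y1 = max(0, int(np.floor(y - r))), min(H, int(np.ceil(y + r)) + 1)
    x0, x1 = max(0, int(np.floor(x - r))), min(W, int(np.ceil(x + r)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = value


def render_frame(
    truth: GroundTruthTable,
    frame: int,
    acq: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one (C, H, W) frame; noise applied if ``rng`` is given."""
    H, W = acq.image_size
    out = np.zeros((3, H, W), dtype=np.float64)
    nuc = out[0]
    donor = out[1]
    acceptor = out[2]
    donor += BACKGROUND
    acceptor += BACKGROUND

    rows = truth.frame_rows(frame)
    # deterministic paint order: higher cell_id paints last in overlaps
    for row in rows.sort_values("cell_id").itertuples(index=False):
        ratio = activity_to_ratio(row.activity)
        _set_disk(donor, row.y, row.x, row.cyto_radius_px, DONOR_INTENSITY)
        _set_disk(acceptor, row.y, row.x, row.cyto_radius_px, DONOR_INTENSITY * ratio)
        _set_disk(
            nuc, row.y, row.x, row.radius_px, NUCLEAR_INTENSITY * row.intensity_scale
        )

    if rng is not None and not acq.noise.noise_free:
        if acq.noise.poisson_scale > 0:
            s = acq.noise.poisson_scale
            out = rng.poisson(out * s).astype(np.float64) / s
        if acq.noise.gaussian_sd > 0:
            out = out + rng.normal(0.0, acq.noise.gaussian_sd, size=out.shape)
    # reorder channels to the acquisition's role order
    order = {"nuclear": 0, "donor": 1, "acceptor": 2}
    idx = [order[role] for role in acq.channel_roles]
    return out[idx]


def iter_frames(
    truth: GroundTruthTable, acq: AcquisitionConfig, seed: int | None
) -> Iterator[np.ndarray]:
    """Yield rendered (C, H, W) frames one at a time (memory-light path)."""
    rng = None if seed is None else np.random.default_rng(seed)
    for t in range(acq.n_frames):
        yield render_frame(truth, t, acq, rng)


def render_frames(
    truth: GroundTruthTable, acq: AcquisitionConfig, seed: int | None = None
) -> ImageStack:
    """Render the full movie into an :class:`ImageStack`.

    ``seed=None`` renders noise-free regardless of the acquisition's noise
    model (useful for oracle tests); otherwise noise follows ``acq.noise``.
    """
    frames = [f for f in iter_frames(truth, acq, seed)]
    return ImageStack(
        data=np.stack(frames),
        channel_roles=tuple(acq.channel_roles),
        frame_interval_min=acq.frame_interval_min,
        pixel_size_um=acq.pixel_size_um,
    )
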