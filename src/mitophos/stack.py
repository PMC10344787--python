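"""Calibrated time-lapse image container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabeledStack:
    """A time-lapse stack with spatial/temporal calibration.

    Parameters
    ----------
    frames
        Intensity frames, shape ``(T, H, W)``.
    pixel_size
        Pixel edge length in micrometres per pixel.
    frame_interval
        Time between consecutive frames in seconds.
    labels
        Optional per-frame integer label masks aligned with ``frames``
        (0 = background). Synthetic stacks carry their noiseless
        ground-truth masks here.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.frames.shape:
                raise ValueError("labels must be aligned with frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Total observation time in seconds (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval
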