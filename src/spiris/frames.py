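"""Image-stack container shared by the simulator and the detection stages.

Coordinate convention used throughout the package: images are row-major 2-D
arrays, pixel (0, 0) sits at the top-left, coordinates are 0-based and refer
to pixel centers, ``x`` is the column index and ``y`` the row index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameStack"]


@dataclass
class FrameStack:
    """Ordered grayscale frames along a focus (z) or time axis.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensity frames, floating point.
    axis_kind : {"z", "time"}
        Whether frames step through focus positions (endpoint assay) or
        acquisition times (kinetic assay).
    axis_values : ndarray, shape (n_frames,)
        Focus position in micrometres, or time in seconds, per frame.
        Strictly monotone.
    pixel_pitch : float
        Physical pixel size at the sample plane, micrometres per pixel.
    """

    frames: np.ndarray
    axis_kind: str
    axis_values: np.ndarray
    pixel_pitch: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (n_frames, h, w)")
        if self.axis_kind not in ("z", "time"):
            raise ValueError(f"axis_kind must be 'z' or 'time', got {self.axis_kind!r}")
        if len(self.axis_values) != len(self.frames):
            raise ValueError("axis_values length must match frame count")
        if len(self.axis_values) > 1:
            steps = np.diff(self.axis_values)
            if not (np.all(steps > 0) or np.all(steps < 0)):
                raise ValueError("axis_values must be strictly monotone")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    def copy(self) -> "FrameStack":
        return FrameStack(
            self.frames.copy(), self.axis_kind, self.axis_values.copy(),
            self.pixel_pitch, dict(self.meta),
        )
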