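"""Time-lapse image stack container and TIFF I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_stack", "read_stack"]


@dataclass
class ImageStack:
    """Ordered grayscale frames of one field of view.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Grayscale intensities.
    times : ndarray, shape (n_frames,)
        Acquisition times in hours, strictly increasing.
    pixel_size : float
        Physical pixel size, µm/pixel.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, y, x), got shape {self.frames.shape}")
        if self.frames.shape[0] != self.times.size:
            raise ValueError("number of frames does not match number of times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def write_stack(path: str | Path, stack: ImageStack, metadata: dict | None = None) -> None:
    """Write a multi-frame grayscale TIFF plus a JSON sidecar.

    The sidecar (same stem, ``.json``) records acquisition times, pixel size
    and any extra metadata (e.g. ground-truth simulation parameters, seed).
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = {
        "times_h": stack.times.tolist(),
        "pixel_size_um": stack.pixel_size,
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-frame TIFF written by :func:`write_stack` (with sidecar)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        times = np.asarray(meta["times_h"], dtype=float)
        pixel_size = float(meta["pixel_size_um"])
    else:
        times = np.arange(frames.shape[0], dtype=float)
        pixel_size = 1.0
    return ImageStack(frames=frames, times=times, pixel_size=pixel_size)
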