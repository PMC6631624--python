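"""Texture-based segmentation of the cell-free wound region.

In phase contrast, cell-covered regions carry high local intensity variance
while bare plastic is smooth, so the wound is found as the connected
low-texture region crossing the scratch axis:

1. local standard-deviation filter (texture map);
2. Otsu threshold on the texture map; wound candidate = low texture;
3. morphological closing then opening to regularize the mask;
4. keep the largest low-texture component touching the initial wound axis
   (the vertical mid-line for a centered scratch).

When the texture histogram is unimodal (fully confluent or fully bare
frame), Otsu cannot separate wound from monolayer; the frame is then
classified by comparing the overall texture level against a wavelet-based
estimate of the sensor noise floor: texture at the noise floor means bare
plastic everywhere (full wound), texture well above it means confluent
cells (no wound).

Intensity offsets leave the mask unchanged — the method looks at local
variance, never absolute brightness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, opening
from skimage.restoration import estimate_sigma

from .stack import ImageStack

__all__ = [
    "SegmentationConfig",
    "WoundMaskSeries",
    "WoundTimeSeries",
    "segment_wound",
    "segment_stack",
    "measure_area_series",
    "initial_wound_width",
    "local_texture",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the texture segmentation.

    texture_window : side (px) of the local standard-deviation window.
    morph_radius : disk radius (px) for closing/opening cleanup.
    contrast_min : minimum ratio of cell-region to wound-region texture for
        the Otsu split to be trusted; below it the frame is treated as
        homogeneous.
    homogeneous_factor : a homogeneous frame counts as all-wound when its
        median texture is below this multiple of the estimated noise floor.
    axis_column : pixel column of the initial wound axis (None = frame
        center); only low-texture components touching it are kept.
    """

    texture_window: int = 15
    morph_radius: int = 4
    contrast_min: float = 2.0
    homogeneous_factor: float = 2.0
    axis_column: int | None = None


@dataclass
class WoundMaskSeries:
    """Per-frame binary wound masks (True = wound) and physical areas (µm²)."""

    masks: np.ndarray
    areas: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        expected = self.masks.sum(axis=(1, 2)) * self.pixel_size**2
        if not np.allclose(self.areas, expected):
            raise ValueError("areas inconsistent with mask pixel counts")


@dataclass
class WoundTimeSeries:
    """Normalized wound area A/A0 against time for one field of view."""

    times: np.ndarray
    a_over_a0: np.ndarray
    areas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a_over_a0 = np.asarray(self.a_over_a0, dtype=float)
        if self.times.shape != self.a_over_a0.shape:
            raise ValueError("times and a_over_a0 must have the same length")
        if self.a_over_a0.size and self.a_over_a0[0] != 1.0:
            raise ValueError("a_over_a0 must start at exactly 1")
        if np.any(self.a_over_a0 < 0):
            raise ValueError("normalized areas must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_h": self.times, "a_over_a0": self.a_over_a0})
        if self.areas is not None:
            df.insert(1, "area_um2", self.areas)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WoundTimeSeries":
        df = pd.read_csv(path)
        areas = df["area_um2"].to_numpy() if "area_um2" in df else None
        return cls(
            times=df["time_h"].to_numpy(),
            a_over_a0=df["a_over_a0"].to_numpy(),
            areas=areas,
        )


def local_texture(frame: np.ndarray, window: int = 15) -> np.ndarray:
    """Local standard deviation of intensities in a ``window`` × ``window`` box."""
    f = np.asarray(frame, dtype=float)
    m1 = uniform_filter(f, size=window, mode="reflect")
    m2 = uniform_filter(f * f, size=window, mode="reflect")
    return np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))


def segment_wound(frame: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Segment the cell-free wound region of one frame (True = wound).

    A constant-intensity frame (no texture anywhere) returns a full-frame
    mask and emits a warning.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")

    tex = local_texture(frame, config.texture_window)
    if tex.max() == 0:
        warnings.warn(
            "constant-intensity frame: no texture anywhere, returning full-frame wound mask",
            stacklevel=2,
        )
        return np.ones(frame.shape, dtype=bool)

    thr = threshold_otsu(tex)
    cand = tex < thr
    if not cand.any() or cand.all():
        return _classify_homogeneous(frame, tex, config)
    contrast = tex[~cand].mean() / max(tex[cand].mean(), np.finfo(float).tiny)
    if contrast < config.contrast_min:
        return _classify_homogeneous(frame, tex, config)

    selem = disk(config.morph_radius)
    mask = opening(closing(cand, selem), selem).astype(bool)
    if not mask.any():
        return mask

    axis = config.axis_column if config.axis_column is not None else frame.shape[1] // 2
    labels = label(mask)
    on_axis = np.unique(labels[:, axis])
    on_axis = on_axis[on_axis > 0]
    if on_axis.size == 0:
        return np.zeros(frame.shape, dtype=bool)
    sizes = [(labels == lab).sum() for lab in on_axis]
    keep = on_axis[int(np.argmax(sizes))]
    return labels == keep


def _classify_homogeneous(
    frame: np.ndarray, tex: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Decide whether a texture-homogeneous frame is all wound or all cells."""
    noise_floor = float(estimate_sigma(frame))
    med = float(np.median(tex))
    if noise_floor == 0 or med <= config.homogeneous_factor * noise_floor:
        return np.ones(frame.shape, dtype=bool)
    return np.zeros(frame.shape, dtype=bool)


def segment_stack(stack: ImageStack, config: SegmentationConfig | None = None) -> WoundMaskSeries:
    """Segment every frame of a stack; area = pixel count × pixel_size²."""
    masks = np.stack([segment_wound(f, config) for f in stack.frames])
    areas = masks.sum(axis=(1, 2)).astype(float) * stack.pixel_size**2
    return WoundMaskSeries(masks=masks, areas=areas, pixel_size=stack.pixel_size)


def measure_area_series(
    stack: ImageStack, config: SegmentationConfig | None = None
) -> WoundTimeSeries:
    """Wound area per frame, normalized to the area at time 0 (A/A0).

    Raises ``ValueError`` when the first frame has no wound (A0 = 0), since
    the series cannot be normalized.
    """
    if len(stack) < 3:
        raise ValueError(f"need at least 3 frames, got {len(stack)}")
    mask_series = segment_stack(stack, config)
    a0 = mask_series.areas[0]
    if a0 == 0:
        raise ValueError("no wound detected at time 0 (A0 = 0); cannot normalize")
    a_over_a0 = mask_series.areas / a0
    a_over_a0[0] = 1.0
    return WoundTimeSeries(times=stack.times.copy(), a_over_a0=a_over_a0, areas=mask_series.areas)


def initial_wound_width(mask0: np.ndarray, pixel_size: float) -> float:
    """Initial wound width b: mean horizontal extent across rows × pixel size.

    For a vertical scratch, each row's wound pixel count is the local
    edge-to-edge distance; b is their mean in µm.  Raises on an empty mask.
    """
    mask0 = np.asarray(mask0, dtype=bool)
    if not mask0.any():
        raise ValueError("empty wound mask: no initial wound to measure")
    return float(mask0.sum(axis=1).mean() * pixel_size)
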