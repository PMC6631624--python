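"""Render simulated density fields into phase-contrast-like time-lapse stacks.

Phase-contrast images of a monolayer carry high local texture where cells
sit and are smooth over cell-free plastic.  The renderer reproduces that
contrast mechanism: a band-limited speckle texture on a flat background,
plus per-pixel sensor noise.  The speckle amplitude follows an occupancy
ramp: below a density threshold the area is effectively cell-free (sparse,
spread cells produce little phase contrast) and carries no texture; over a
narrow density band around that threshold the texture switches on and then
saturates for packed cells.  The 1D density profile is extruded vertically
(the scratch is a vertical stripe; closure is horizontal), matching the 1D
wound model.

The ground-truth wound mask marks the same contour the optics draw — the
cell-free area, density below the occupancy threshold — so it is the true
wound boundary of the rendered image and segmentation can be validated
pixel-for-pixel against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulate import DensityField, Grid1D
from .stack import ImageStack

__all__ = ["RenderConfig", "render_timelapse"]


def _smoothstep(s: np.ndarray) -> np.ndarray:
    """Cubic smoothstep: 0 for s <= -1, 1 for s >= 1, C1-smooth between."""
    s = np.clip((s + 1.0) / 2.0, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


@dataclass(frozen=True)
class RenderConfig:
    """Rendering settings (intensities are arbitrary grayscale units).

    ``speckle_sigma`` (px) sets the correlation length of the cell texture;
    it is kept above the sensor-noise scale so that texture and noise are
    separable.  ``mask_threshold`` is the density fraction of u_hat below
    which a pixel counts as cell-free and belongs to the ground-truth wound
    mask; the texture amplitude ramps from 0 to full over a density band of
    half-width ``occupancy_width`` centered on that same threshold, so the
    optical wound edge and the ground-truth edge coincide.  Identical seed
    and config give a bit-identical stack.
    """

    pixel_size: float = 5.0
    frame_shape: tuple[int, int] = (200, 600)
    cell_texture_amplitude: float = 0.3
    background_level: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0
    speckle_sigma: float = 1.5
    mask_threshold: float = 0.2
    occupancy_width: float = 0.08

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.mask_threshold < 1):
            raise ValueError("mask_threshold must lie in (0, 1)")

    @classmethod
    def for_grid(cls, grid: Grid1D, pixel_size: float = 5.0, rows: int = 200, **kw) -> "RenderConfig":
        """Config whose frame width tiles the simulation domain exactly."""
        cols = int(round(grid.length / pixel_size))
        return cls(pixel_size=pixel_size, frame_shape=(rows, cols), **kw)


def render_timelapse(
    field: DensityField,
    cfg: RenderConfig,
    u_hat: float | None = None,
) -> tuple[ImageStack, np.ndarray]:
    """Render a density field into a grayscale stack plus ground-truth masks.

    Parameters
    ----------
    field : DensityField
        Simulated u(x, t); one rendered frame per saved time.
    cfg : RenderConfig
        Optics / noise settings.
    u_hat : float, optional
        Confluent density used to normalize the field to [0, 1]; defaults
        to the field's maximum value.

    Returns
    -------
    (ImageStack, ndarray of bool with shape (n_frames, rows, cols))
        The rendered stack and the per-frame ground-truth wound masks
        (density fraction below ``cfg.mask_threshold``).

    Raises
    ------
    ValueError
        If the frame does not tile the simulated domain to within one
        pixel at the given pixel size.
    """
    rows, cols = cfg.frame_shape
    span = cols * cfg.pixel_size
    if abs(span - field.grid.length) > cfg.pixel_size:
        raise ValueError(
            f"frame of {cols} px at {cfg.pixel_size} µm/px spans {span} µm but the "
            f"simulated domain is {field.grid.length} µm; frame must tile the domain "
            "to within one pixel"
        )

    if u_hat is None:
        u_hat = float(field.values.max())
    if u_hat > 0:
        norm = np.clip(field.values / u_hat, 0.0, 1.0)
    else:
        norm = np.zeros_like(field.values)

    # sample density at pixel-column centers
    x_cols = field.grid.x_min + (np.arange(cols) + 0.5) * cfg.pixel_size
    rng = np.random.default_rng(cfg.seed)
    n_frames = field.times.size
    frames = np.empty((n_frames, rows, cols), dtype=np.float32)
    masks = np.empty((n_frames, rows, cols), dtype=bool)

    for i in range(n_frames):
        u_cols = np.interp(x_cols, field.x, norm[i])
        occupancy = _smoothstep((u_cols - cfg.mask_threshold) / cfg.occupancy_width)
        speckle = gaussian_filter(rng.standard_normal((rows, cols)), cfg.speckle_sigma)
        sd = speckle.std()
        if sd > 0:
            speckle /= sd
        frame = (
            cfg.background_level
            + cfg.cell_texture_amplitude * occupancy[None, :] * speckle
            + cfg.noise_sd * rng.standard_normal((rows, cols))
        )
        frames[i] = frame.astype(np.float32)
        masks[i] = np.broadcast_to(u_cols < cfg.mask_threshold, (rows, cols))

    stack = ImageStack(frames=frames, times=field.times.copy(), pixel_size=cfg.pixel_size)
    return stack, masks
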