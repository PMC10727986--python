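"""Preprocessing of two-band optoacoustic skin volumes.

Reconstructed raster-scan optoacoustic mesoscopy (RSOM) volumes carry a
high-frequency (HF, 40-120 MHz) and a low-frequency (10-40 MHz, LF) band.
Before segmentation the volumes are reduced to 2D maximum-intensity
projections (MIP) along the scan-width (Y) axis and normalized per channel
against the maximum intensity.  Arrays are indexed ``[z, y, x]`` with z the
depth axis; all physical coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

CHANNELS = ("HF", "LF")

#: fixed raster (depth x lateral) used by the 2D segmentation stage
DEFAULT_RASTER = (768, 256)


@dataclass
class Volume3D:
    """Two-channel 3D intensity volume with anisotropic voxel spacing.

    ``channels`` maps band name ("HF", "LF") to a float array of identical
    shape ``(nz, ny, nx)``; ``spacing`` is the (z, y, x) voxel pitch in um.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"expected channels {CHANNELS}, got {tuple(self.channels)}")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if len(self.shape) != 3:
            raise ValueError("Volume3D requires 3D channel arrays")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class Mip2D:
    """Per-channel 2D maximum intensity projection (depth x lateral)."""

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float]
    projection_axis: str = "y"
    provenance: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


def mip_along_y(vol: Volume3D) -> Mip2D:
    """Project ``max`` over the y axis, per channel: out[z, x] = max_y vol[z, y, x]."""
    if any(s == 0 for s in vol.shape):
        raise ValueError("cannot project an empty volume")
    channels = {ch: arr.max(axis=1) for ch, arr in vol.channels.items()}
    dz, _, dx = vol.spacing
    return Mip2D(channels=channels, spacing=(dz, dx), projection_axis="y",
                 provenance=vol.provenance)


def normalize_max(obj, per_channel: bool = True):
    """Divide each channel by its maximum so the output peaks at 1.

    Value ordering is preserved; an all-zero (or non-positive) channel is an
    error because its normalization is undefined.
    """
    if isinstance(obj, (Volume3D, Mip2D)):
        out = {}
        for ch, arr in obj.channels.items():
            m = float(arr.max()) if per_channel else max(
                float(a.max()) for a in obj.channels.values())
            if m <= 0:
                raise ValueError(f"channel {ch!r} has no positive intensity to normalize")
            out[ch] = arr / m
        return replace(obj, channels=out)
    arr = np.asarray(obj, dtype=float)
    m = float(arr.max())
    if m <= 0:
        raise ValueError("array has no positive intensity to normalize")
    return arr / m


def compose_rgb(mip: Mip2D) -> np.ndarray:
    """Stack HF into red, LF into green, leave blue empty: shape (H, W, 3)."""
    hf = np.asarray(mip.channels["HF"], dtype=float)
    lf = np.asarray(mip.channels["LF"], dtype=float)
    return np.stack([hf, lf, np.zeros_like(hf)], axis=-1)


def decompose_rgb(rgb: np.ndarray, spacing: tuple[float, float]) -> Mip2D:
    """Inverse of :func:`compose_rgb` (blue plane is discarded)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) array")
    return Mip2D(channels={"HF": rgb[..., 0], "LF": rgb[..., 1]}, spacing=spacing)


def to_grayscale(mip: Mip2D) -> np.ndarray:
    """Channel-mean grayscale of the (normalized) two-band image."""
    return (np.asarray(mip.channels["HF"], float)
            + np.asarray(mip.channels["LF"], float)) / 2.0


def resample_raster(image: np.ndarray, target: tuple[int, int] = DEFAULT_RASTER) -> np.ndarray:
    """Bilinear resample of a 2D image (or 2D mask) to the segmentation raster."""
    image = np.asarray(image)
    if image.dtype == bool:
        out = resize(image.astype(float), target, order=1, anti_aliasing=False)
        return out >= 0.5
    return resize(image.astype(float), target, order=1, anti_aliasing=False)
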