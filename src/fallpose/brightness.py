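"""Percentile-clipped min-max brightness normalization.

Dim scenes cost pose estimators their face keypoints, which in turn breaks
head-based forward-fall detection. This module implements the standard
rescue: per RGB channel, find the ``p_low`` and ``p_high`` percentile
pixel values, clip the channel to that range (discarding outlier pixels),
then map it affinely onto a configured output range. The output range
deliberately stays inside ``[0, 255]`` (default ``[10, 245]``) to avoid
saturating at the 8-bit rails.

Numeric conventions, stated so two implementations agree bit-for-bit:
percentiles use linear interpolation between order statistics; rounding is
half-up; a constant channel (``hi == lo``) maps every pixel to
``out_min``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

__all__ = [
    "NormalizationParams",
    "normalize_brightness",
    "load_image",
    "save_image",
    "normalize_image_file",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile clip bounds and 8-bit output range."""

    p_low: float = 1.0
    p_high: float = 99.0
    out_min: int = 10
    out_max: int = 245

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_low < self.p_high <= 100.0:
            raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({self.p_low}, {self.p_high})")
        if not 0 <= self.out_min < self.out_max <= 255:
            raise ValueError(
                f"need 0 <= out_min < out_max <= 255, got ({self.out_min}, {self.out_max})"
            )


def _normalize_channel(channel: np.ndarray, params: NormalizationParams) -> np.ndarray:
    values = channel.astype(np.float64)
    lo, hi = np.percentile(values, [params.p_low, params.p_high])
    if hi <= lo:
        return np.full(channel.shape, params.out_min, dtype=np.uint8)
    clipped = np.clip(values, lo, hi)
    scaled = (clipped - lo) * (params.out_max - params.out_min) / (hi - lo) + params.out_min
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def normalize_brightness(
    image: np.ndarray,
    params: NormalizationParams = NormalizationParams(),
) -> np.ndarray:
    """Normalize an 8-bit grayscale ``(H, W)`` or color ``(H, W, C)`` image.

    Channels are normalized independently. Shape and channel count are
    preserved; the output dtype is ``uint8`` with every value inside
    ``[out_min, out_max]``.

    Raises
    ------
    ValueError
        On an empty image or an unsupported number of dimensions.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty image")
    if arr.ndim == 2:
        return _normalize_channel(arr, params)
    if arr.ndim == 3:
        channels = [_normalize_channel(arr[..., c], params) for c in range(arr.shape[2])]
        return np.stack(channels, axis=-1)
    raise ValueError(f"expected a 2D or 3D image array, got ndim={arr.ndim}")


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Read a PNG/JPEG file into a uint8 array (grayscale or RGB)."""
    with Image.open(path) as img:
        if img.mode not in ("L", "RGB"):
            img = img.convert("RGB")
        return np.asarray(img, dtype=np.uint8)


def save_image(image: np.ndarray, path: Union[str, Path]) -> None:
    """Write a uint8 array to PNG or JPEG (format inferred from suffix)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def normalize_image_file(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    params: NormalizationParams = NormalizationParams(),
) -> None:
    """File-to-file convenience wrapper used by the CLI."""
    save_image(normalize_brightness(load_image(in_path), params), out_path)
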