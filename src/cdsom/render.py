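"""Portrait rendering: grid values -> PNG mosaic images.

Centralized metagene values are mapped over a symmetric blue - neutral -
maroon scale (high expression maroon, low blue); node (0, 0) renders at the
top-left. Rendering is deterministic: identical portraits give
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image

from .som import Portrait


@dataclass
class ColorScale:
    low: tuple = (0.10, 0.15, 0.60)  # blue
    mid: tuple = (0.96, 0.96, 0.94)  # neutral
    high: tuple = (0.50, 0.00, 0.13)  # maroon
    vmax: Optional[float] = None  # symmetric range [-vmax, vmax]; None = data max


def _interpolate(t: np.ndarray, scale: ColorScale) -> np.ndarray:
    """t in [-1, 1] -> RGB float array via the two-segment linear ramp."""
    low, mid, high = (np.array(c, dtype=float) for c in (scale.low, scale.mid, scale.high))
    rgb = np.empty(t.shape + (3,))
    neg = t < 0
    tt = np.abs(t)[..., None]
    rgb[neg] = (mid + (low - mid) * tt[neg]).clip(0, 1)
    rgb[~neg] = (mid + (high - mid) * tt[~neg]).clip(0, 1)
    return rgb


def render_portrait(
    portrait: Portrait,
    path,
    scale: Optional[ColorScale] = None,
    pixel_size: int = 8,
) -> None:
    """Write a portrait as a PNG of (rows * pixel_size) x (cols * pixel_size)."""
    values = portrait.values
    if not np.all(np.isfinite(values)):
        raise ValueError("portrait contains non-finite values")
    scale = scale or ColorScale()
    vmax = scale.vmax if scale.vmax is not None else float(np.abs(values).max())
    if vmax == 0:
        vmax = 1.0  # all-zero portrait -> uniform mid color
    t = np.clip(values / vmax, -1.0, 1.0)
    rgb = (_interpolate(t, scale) * 255).round().astype(np.uint8)
    big = np.kron(rgb, np.ones((pixel_size, pixel_size, 1), dtype=np.uint8))
    Image.fromarray(big, mode="RGB").save(path, format="PNG")
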