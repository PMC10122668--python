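"""Deterministic rasterization of geometry plans to PNG images.

Rendering draws at an integer supersampling factor with PIL's exact
(non-anti-aliased) primitives, then box-downsamples, which smooths
oblique edges while leaving the interior of uniform patches at exactly
the requested gray level (a 2x2 block of identical subpixels averages
to itself). Gray level g in [0, 1] maps to round-half-up(g * 255).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .geometry import Circle, GeometryPlan, Rect, Segment

__all__ = ["RasterImage", "render", "write_png", "read_png", "image_checksum"]

DEFAULT_WIDTH = 800
DEFAULT_HEIGHT = 600
STIMULUS_FRACTION = 0.8  # stimuli occupy the central 80% of the short side


@dataclass(frozen=True)
class RasterImage:
    width: int
    height: int
    pixels: np.ndarray  # (height, width, 3) uint8

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="RGB")


def _level(channel: float) -> int:
    """Map a [0, 1] color channel to 8-bit, rounding half up."""
    return min(255, int(channel * 255 + 0.5))


def _rgb(color) -> tuple:
    return tuple(_level(c) for c in color)


def render(
    plan: GeometryPlan,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    background_gray: float = 0.5,
    supersample: int = 2,
) -> RasterImage:
    """Rasterize a plan. Identical inputs give bit-identical pixels."""
    if width < 64 or height < 64:
        raise ValueError("width and height must be at least 64 pixels")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    ss = supersample
    W, H = width * ss, height * ss
    scale = STIMULUS_FRACTION * min(width, height) / 2 * ss
    cx, cy = W / 2, H / 2

    def to_px(x, y):
        return (cx + x * scale, cy - y * scale)

    bg = _rgb((background_gray,) * 3)
    img = Image.new("RGB", (W, H), bg)
    draw = ImageDraw.Draw(img)
    for p in plan.primitives:
        color = _rgb(p.color)
        if isinstance(p, Segment):
            w = max(1, round(p.width * scale))
            draw.line([to_px(p.x1, p.y1), to_px(p.x2, p.y2)], fill=color, width=w)
        elif isinstance(p, Circle):
            r = p.r * scale
            if round(r) < 1:
                raise ValueError(f"degenerate circle (radius ~0 px): {p}")
            x0, y0 = to_px(p.cx - p.r, p.cy + p.r)
            x1, y1 = to_px(p.cx + p.r, p.cy - p.r)
            if p.fill:
                draw.ellipse([x0, y0, x1, y1], fill=color)
            else:
                w = max(1, round(p.width * scale))
                draw.ellipse([x0, y0, x1, y1], outline=color, width=w)
        elif isinstance(p, Rect):
            if p.x2 <= p.x1 or p.y2 <= p.y1:
                continue  # zero-area patch draws nothing
            x0, y0 = to_px(p.x1, p.y2)
            x1, y1 = to_px(p.x2, p.y1)
            draw.rectangle([x0, y0, x1, y1], fill=color)
        else:  # pragma: no cover - closed primitive set
            raise TypeError(f"unknown primitive: {p!r}")
    if ss > 1:
        img = img.resize((width, height), Image.BOX)
    return RasterImage(width=width, height=height,
                       pixels=np.asarray(img, dtype=np.uint8).copy())


def write_png(image: RasterImage, path) -> None:
    """Write a lossless PNG; fixed encoder settings keep bytes reproducible."""
    image.to_pil().save(path, format="PNG", optimize=False, compress_level=6)


def read_png(path) -> RasterImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8).copy()
    return RasterImage(width=arr.shape[1], height=arr.shape[0], pixels=arr)


def image_checksum(image: RasterImage) -> str:
    """Stable hex digest of the raw pixel bytes (plus dimensions)."""
    h = hashlib.sha256()
    h.update(f"{image.width}x{image.height}".encode())
    h.update(image.pixels.tobytes())
    return h.hexdigest()
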