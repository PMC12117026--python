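"""Color-coded direction maps and vector-field overlays.

Fiber directions are axial (180-degree periodic), so the color wheel maps
hue = 2*phi (plus a configurable rotation), making phi and phi + 180 render
identically. Pixels with multiple directions are shown as subpixel mosaics:
with the default subpixel factor 2 each image pixel becomes a 2x2 block whose
subpixels cycle through the pixel's directions (1 direction: all four share
its hue; 2 directions: a 2+2 split; 3 directions: a 2+1+1 split). Pixels
without any direction are black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = ["RenderSpec", "direction_to_rgb", "render_direction_map",
           "vector_segments", "render_vector_map"]


@dataclass
class RenderSpec:
    """Rendering parameters: hue rotation of the color wheel (degrees added
    to 2*phi; 0 maps phi = 0 to red), subpixel factor for mosaic rendering,
    and the kernel size n for vector overlays (one overlaid vector set per
    n x n block)."""

    hue_rotation_deg: float = 0.0
    subpixel_factor: int = 2
    vector_kernel: int = 20

    def __post_init__(self) -> None:
        if self.subpixel_factor < 1 or self.vector_kernel < 1:
            raise ValueError("subpixel_factor and vector_kernel must be >= 1")


def direction_to_rgb(directions_deg, spec: RenderSpec | None = None,
                     value=None) -> np.ndarray:
    """Map axial directions (degrees) to RGB via the orientation color wheel
    (hue = 2*phi); NaN maps to black. ``value`` optionally scales brightness."""
    spec = spec or RenderSpec()
    d = np.asarray(directions_deg, dtype=float)
    hue = ((2.0 * d + spec.hue_rotation_deg) % 360.0) / 360.0
    nan = np.isnan(d)
    hsv = np.stack([np.where(nan, 0.0, hue),
                    np.ones_like(hue),
                    np.where(nan, 0.0, 1.0 if value is None else value)], axis=-1)
    return hsv_to_rgb(hsv)


def render_direction_map(directions_deg: np.ndarray,
                         spec: RenderSpec | None = None) -> np.ndarray:
    """Render an (H, W) or (H, W, k) direction map (k <= 3) as an RGB uint8
    image of shape (f*H, f*W, 3) with f = subpixel_factor.

    Within each f x f block the subpixels cycle through the pixel's non-NaN
    directions in channel order (row-major subpixel order), so one direction
    fills the whole block, two give a 2+2 split and three a 2+1+1 split at
    f = 2. Pixels without directions render black.
    """
    spec = spec or RenderSpec()
    d = np.asarray(directions_deg, dtype=float)
    if d.ndim == 2:
        d = d[..., None]
    if d.ndim != 3 or d.shape[2] > 3:
        raise ValueError("directions must be (H, W) or (H, W, k<=3)")
    h, w, k = d.shape
    f = spec.subpixel_factor

    # left-compact the valid directions per pixel, then cycle them over the
    # f*f subpixels
    order = np.argsort(np.isnan(d), axis=2, kind="stable")
    compact = np.take_along_axis(d, order, axis=2)
    ndir = (~np.isnan(d)).sum(axis=2)
    sub = np.arange(f * f)
    chan = sub[None, None, :] % np.maximum(ndir, 1)[..., None]
    picked = np.take_along_axis(compact, chan, axis=2)          # (H, W, f*f)
    picked = np.where((ndir == 0)[..., None], np.nan, picked)

    rgb = direction_to_rgb(picked, spec)                        # (H, W, f*f, 3)
    rgb = rgb.reshape(h, w, f, f, 3).transpose(0, 2, 1, 3, 4).reshape(h * f, w * f, 3)
    return (rgb * 255).round().astype(np.uint8)


def vector_segments(directions_deg: np.ndarray, spec: RenderSpec | None = None,
                    weight_map: np.ndarray | None = None):
    """Overlaid unit-direction segments, one set per n x n block.

    For each block, the distinct (direction, weight) combinations of its
    pixels and channels yield one line segment each, centered on the block
    center, with half-length 0.45*n scaled by the weight (normalized by the
    global maximum weight; unweighted maps use length 1). Returns an array of
    rows (x0, y0, x1, y1, direction_deg).
    """
    spec = spec or RenderSpec()
    d = np.asarray(directions_deg, dtype=float)
    if d.ndim == 2:
        d = d[..., None]
    h, w, k = d.shape
    n = spec.vector_kernel
    if weight_map is not None:
        weight_map = np.asarray(weight_map, dtype=float)
        if weight_map.shape != (h, w):
            raise ValueError("weight_map shape must match the direction map")
        wmax = float(np.nanmax(weight_map)) or 1.0
    segments = []
    for r0 in range(0, h - n + 1, n):
        for c0 in range(0, w - n + 1, n):
            block = d[r0:r0 + n, c0:c0 + n]
            wts = (np.ones((n, n)) if weight_map is None
                   else weight_map[r0:r0 + n, c0:c0 + n] / wmax)
            combos = set()
            for ch in range(k):
                vals = block[..., ch]
                ok = ~np.isnan(vals)
                combos.update(zip(np.round(vals[ok], 9), np.round(wts[ok], 9)))
            cy, cx = r0 + n / 2.0, c0 + n / 2.0
            for direction, weight in sorted(combos):
                half = 0.45 * n * weight
                # image rows grow downward; flip y so angles read math-style
                dx = half * np.cos(np.deg2rad(direction))
                dy = -half * np.sin(np.deg2rad(direction))
                segments.append((cx - dx, cy - dy, cx + dx, cy + dy, direction))
    return np.asarray(segments).reshape(-1, 5)


def render_vector_map(directions_deg: np.ndarray, spec: RenderSpec | None = None,
                      weight_map: np.ndarray | None = None, out_path=None,
                      background: np.ndarray | None = None):
    """Draw the vector overlay with matplotlib; returns the figure (and
    writes PNG/SVG when ``out_path`` is given)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    spec = spec or RenderSpec()
    d = np.asarray(directions_deg, dtype=float)
    h, w = d.shape[:2]
    segs = vector_segments(d, spec, weight_map)
    fig, ax = plt.subplots(figsize=(max(3, w / 25), max(3, h / 25)))
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper")
    else:
        ax.set_facecolor("black")
    if len(segs):
        lines = [[(x0, y0), (x1, y1)] for x0, y0, x1, y1, _ in segs]
        colors = direction_to_rgb(segs[:, 4], spec)
        ax.add_collection(LineCollection(lines, colors=colors, linewidths=1.2))
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    if out_path is not None:
        fig.savefig(out_path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
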