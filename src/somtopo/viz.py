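"""Hexagonal map rendering (SVG).

Each node is drawn as a pointy-top hexagon at its offset-lattice
position.  Continuous layers (means, protein counts) map through a
matplotlib colormap over a shared value range; mask layers use two fixed
fills; missing node values are grey.  Output is deterministic for a
fixed topography and style, so rendered maps can be diffed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .som import hex_coordinates
from .topography import Topography

__all__ = ["RenderStyle", "render_topography", "shared_range"]

_SQ3 = np.sqrt(3.0)


@dataclass
class RenderStyle:
    scale: float = 36.0  # pixels per lattice unit
    cmap: str = "viridis"
    vmin: float | None = None
    vmax: float | None = None
    show_labels: bool = False
    missing_fill: str = "#bdbdbd"
    mask_true_fill: str = "#d62728"
    mask_false_fill: str = "#f0f0f0"
    stroke: str = "#ffffff"


def _hex_points(cx: float, cy: float, radius: float) -> str:
    pts = []
    for i in range(6):
        ang = np.pi / 180.0 * (60.0 * i + 30.0)
        pts.append(f"{cx + radius * np.cos(ang):.3f},{cy + radius * np.sin(ang):.3f}")
    return " ".join(pts)


def _color(value: float, vmin: float, vmax: float, cmap: str) -> str:
    from matplotlib import colormaps
    from matplotlib.colors import to_hex

    if vmax <= vmin:
        frac = 0.5
    else:
        frac = float(np.clip((value - vmin) / (vmax - vmin), 0.0, 1.0))
    return to_hex(colormaps[cmap](frac))


def shared_range(topos: list[Topography]) -> tuple[float, float]:
    """Common (vmin, vmax) so small multiples share one color scale."""
    vals = np.concatenate(
        [np.asarray(t.values, dtype=float) for t in topos]
    )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return 0.0, 1.0
    return float(vals.min()), float(vals.max())


def render_topography(
    topo: Topography,
    path=None,
    style: RenderStyle | None = None,
) -> str:
    """Render one topography layer as an SVG string; optionally save it."""
    style = style or RenderStyle()
    rows, cols = topo.grid_shape
    coords = hex_coordinates(rows, cols)
    s = style.scale
    radius = s / _SQ3
    pad = radius + 2
    width = (cols + 0.5) * s + 2 * pad
    height = (rows - 1) * (_SQ3 / 2) * s + 2 * pad

    is_mask = topo.layer_kind == "high_mask"
    values = np.asarray(topo.values, dtype=bool if is_mask else float)
    if not is_mask:
        finite = values[np.isfinite(values)]
        vmin = style.vmin if style.vmin is not None else (
            float(finite.min()) if finite.size else 0.0)
        vmax = style.vmax if style.vmax is not None else (
            float(finite.max()) if finite.size else 1.0)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        f"<!-- layer={topo.layer_kind} condition={topo.condition or ''} -->",
    ]
    for i in range(rows * cols):
        cx = coords[i, 0] * s + pad
        cy = coords[i, 1] * s + pad
        v = values[i]
        if is_mask:
            fill = style.mask_true_fill if v else style.mask_false_fill
        elif not np.isfinite(v):
            fill = style.missing_fill
        else:
            fill = _color(float(v), vmin, vmax, style.cmap)
        parts.append(
            f'<polygon points="{_hex_points(cx, cy, radius)}" fill="{fill}" '
            f'stroke="{style.stroke}" stroke-width="1"/>'
        )
        if style.show_labels:
            parts.append(
                f'<text x="{cx:.3f}" y="{cy + 3:.3f}" font-size="{s / 4:.1f}" '
                f'text-anchor="middle" fill="#333333">{i + 1}</text>'
            )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg
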