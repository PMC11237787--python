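"""Pseudocolor stroke-order rendering of a session.

Strokes are drawn as polylines on a blank canvas, each in a color taken
from a fixed sequential colormap (viridis: multi-hue, monotone
lightness, so stroke order reads naturally) sampled uniformly by stroke
index.  Later strokes overdraw earlier ones.  Rendering is pure: same
session + canvas -> byte-identical PNG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
from PIL import Image, ImageDraw

from .ink import DrawingSession
from .simulate import CANVAS_W, CANVAS_H

_CMAP = matplotlib.colormaps["viridis"]


@dataclass
class CanvasSpec:
    """Raster geometry; default mirrors the 2160x1620 tablet at 1/4 scale."""

    width: int = 540
    height: int = 405
    background: tuple[int, int, int] = (255, 255, 255)
    line_width: int = 3
    source_width: int = CANVAS_W
    source_height: int = CANVAS_H


@dataclass
class PseudocolorImage:
    image: Image.Image
    legend: list[tuple[int, tuple[int, int, int]]] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        self.image.save(Path(path), format="PNG")


def stroke_order_colors(n_strokes: int) -> list[tuple[int, int, int]]:
    """n 8-bit RGB colors, uniform along the colormap; deterministic.

    n=1 gives the colormap start; n=2 the two endpoints; colors are
    pairwise distinct for n <= 256.
    """
    if n_strokes <= 0:
        return []
    if n_strokes == 1:
        positions = [0.0]
    else:
        positions = [i / (n_strokes - 1) for i in range(n_strokes)]
    out: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    for pos in positions:
        r, g, b, _ = _CMAP(pos)
        color = _dedupe((round(r * 255), round(g * 255), round(b * 255)), seen)
        seen.add(color)
        out.append(color)
    return out


def _dedupe(
    color: tuple[int, int, int], seen: set[tuple[int, int, int]]
) -> tuple[int, int, int]:
    """Resolve 8-bit quantization collisions between neighbouring
    colormap entries by the smallest blue (then green) nudge."""
    if color not in seen:
        return color
    r, g, b = color
    for channel, base in ((2, b), (1, g)):
        for d in range(1, 256):
            for v in (base + d, base - d):
                if 0 <= v <= 255:
                    cand = list(color)
                    cand[channel] = v
                    if tuple(cand) not in seen:
                        return tuple(cand)  # type: ignore[return-value]
    raise ValueError("color space exhausted")


def render_pseudocolor(
    session: DrawingSession, canvas: CanvasSpec | None = None
) -> PseudocolorImage:
    """Draw the session's strokes in index order on a fresh canvas."""
    canvas = canvas or CanvasSpec()
    img = Image.new("RGB", (canvas.width, canvas.height), canvas.background)
    if not session.strokes:
        warnings.warn(
            f"session {session.subject_id}/{session.task_id} has no strokes; "
            "rendering a blank canvas",
            stacklevel=2,
        )
        return PseudocolorImage(image=img, legend=[])
    draw = ImageDraw.Draw(img)
    sx = canvas.width / canvas.source_width
    sy = canvas.height / canvas.source_height
    colors = stroke_order_colors(len(session.strokes))
    for stroke, color in zip(session.strokes, colors):
        pts = [(e.x * sx, e.y * sy) for e in stroke.events]
        if len(pts) == 1:
            pts = pts * 2
        draw.line(pts, fill=color, width=canvas.line_width, joint="curve")
    legend = list(enumerate(colors))
    return PseudocolorImage(image=img, legend=legend)
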