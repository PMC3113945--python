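"""Per-zoom-level layout specialization and rasterization (steps 2-3).

The pyramid has six semantic zoom levels by default, index 0 (lowest
magnification, whole cell on screen) to 5 (highest).  The scale halves at
each increment: level ``k`` uses ``2**(L-1-k)`` master units per pixel, so
level 5 renders at one pixel per master unit.

Zooming is *semantic*: higher levels reveal new object and label classes,
not just bigger pixels.  The default feature policy is cumulative, so the
drawn set is monotone non-decreasing with zoom:

====== =============================================================
level  adds
====== =============================================================
0      compound/transporter/RNA glyphs, reaction lines, cluster shading
1      pathway names
2      enzyme glyphs
3      compound names
4      enzyme and gene names
5      EC numbers
====== =============================================================

Enzymes are deliberately absent from the lowest zoom level.  A label that
would collide with an already-placed glyph or label at a level's font size
is dropped (never truncated), with deterministic greedy placement in
frame_id order.

Rasterization uses Pillow with its built-in bitmap font, so identical
inputs yield identical pixel buffers.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from PIL import Image, ImageDraw, ImageFont
from pydantic import BaseModel, Field

from .layout_engine import Glyph, LabelSpec, MasterLayout, Rect, ReactionLine

N_LEVELS = 6

#: label classes switched on at each level (cumulative)
DEFAULT_LABEL_POLICY: dict[int, list[str]] = {
    0: [],
    1: ["pathway_name"],
    2: [],
    3: ["compound_name"],
    4: ["enzyme_name", "gene_name"],
    5: ["ec_number"],
}

#: glyph shapes switched on at each level (cumulative)
DEFAULT_GLYPH_POLICY: dict[int, list[str]] = {
    0: ["circle", "box", "tee"],
    1: [],
    2: ["triangle"],
    3: [],
    4: [],
    5: [],
}

_FONT_SIZES = {
    "pathway_name": 12,
    "compound_name": 9,
    "enzyme_name": 9,
    "gene_name": 9,
    "ec_number": 8,
}


class StyleConfig(BaseModel):
    """Colors, sizes and the semantic-zoom feature policy."""

    background: tuple[int, int, int] = (255, 255, 255)
    reaction_line: tuple[int, int, int] = (0, 0, 204)  # bioreactions are blue
    cluster_fill: tuple[int, int, int] = (232, 232, 240)
    cluster_edge: tuple[int, int, int] = (200, 200, 214)
    membrane_fill: tuple[int, int, int] = (189, 183, 107)
    periplasm_fill: tuple[int, int, int] = (245, 245, 225)
    compound_fill: tuple[int, int, int] = (60, 60, 60)
    enzyme_fill: tuple[int, int, int] = (0, 128, 0)
    transporter_fill: tuple[int, int, int] = (139, 69, 19)
    rna_fill: tuple[int, int, int] = (128, 0, 128)
    text_color: tuple[int, int, int] = (30, 30, 30)
    font: Optional[str] = None  # path to a TTF; default = PIL bitmap font
    n_levels: int = N_LEVELS
    label_policy: dict[int, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LABEL_POLICY.items()}
    )
    glyph_policy: dict[int, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GLYPH_POLICY.items()}
    )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "StyleConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def glyph_shapes_at(self, level: int) -> set[str]:
        out: set[str] = set()
        for k in range(level + 1):
            out.update(self.glyph_policy.get(k, []))
        return out

    def label_classes_at(self, level: int) -> set[str]:
        out: set[str] = set()
        for k in range(level + 1):
            out.update(self.label_policy.get(k, []))
        return out


class ZoomLevel(BaseModel):
    index: int
    scale: int  # master units per pixel

    @classmethod
    def of(cls, index: int, n_levels: int = N_LEVELS) -> "ZoomLevel":
        if not 0 <= index < n_levels:
            raise ValueError(f"zoom index {index} out of range 0..{n_levels - 1}")
        return cls(index=index, scale=2 ** (n_levels - 1 - index))


def round_half_up(v: float) -> int:
    return math.floor(v + 0.5)


class PlacedLabel(BaseModel):
    owner: str
    cls: str
    text: str
    x: int  # left edge, px
    y: int  # vertical center, px
    font_size: int
    bbox: Rect


class ZoomGlyph(BaseModel):
    frame_id: str
    shape: str
    x: int
    y: int
    w: int
    h: int


class ZoomLine(BaseModel):
    frame_id: str
    points: list[tuple[int, int]]


class ZoomLayout(BaseModel):
    """Concrete pixel geometry at one zoom level."""

    level: int
    scale: int
    width: int
    height: int
    regions: dict[str, Rect] = Field(default_factory=dict)
    cluster_rects: list[Rect] = Field(default_factory=list)
    lines: list[ZoomLine] = Field(default_factory=list)
    glyphs: list[ZoomGlyph] = Field(default_factory=list)
    labels: list[PlacedLabel] = Field(default_factory=list)

    def drawn_frame_ids(self) -> set[str]:
        return {g.frame_id for g in self.glyphs} | {l.frame_id for l in self.lines}


def _load_font(style: StyleConfig, size: int) -> ImageFont.ImageFont:
    if style.font is not None:
        try:
            return ImageFont.truetype(style.font, size)
        except OSError as exc:
            raise FileNotFoundError(f"font not resolvable: {style.font!r}") from exc
    return ImageFont.load_default(size=size)


def _text_extent(style: StyleConfig, text: str, size: int) -> tuple[int, int]:
    font = _load_font(style, size)
    x0, y0, x1, y1 = font.getbbox(text)
    return x1 - x0, y1 - y0


def specialize_layout(
    master: MasterLayout, level: Union[int, ZoomLevel], style: Optional[StyleConfig] = None
) -> ZoomLayout:
    """Apply the feature policy and fix pixel geometry for one level.

    Scaling divides master coordinates by the level scale with half-up
    rounding, applied exactly once here.  Labels whose rendered box would
    collide with a glyph or an earlier label are dropped.
    """
    style = style or StyleConfig()
    zl = level if isinstance(level, ZoomLevel) else ZoomLevel.of(level, style.n_levels)
    s = zl.scale

    def px(v: float) -> int:
        return round_half_up(v / s)

    out = ZoomLayout(
        level=zl.index,
        scale=s,
        width=math.ceil(master.canvas_w / s),
        height=math.ceil(master.canvas_h / s),
    )
    out.regions = {
        name: Rect(x0=px(r.x0), y0=px(r.y0), x1=px(r.x1), y1=px(r.y1))
        for name, r in master.regions.items()
    }
    out.cluster_rects = [
        Rect(x0=px(cb.rect.x0), y0=px(cb.rect.y0), x1=px(cb.rect.x1), y1=px(cb.rect.y1))
        for cb in master.cluster_boxes
    ]
    shapes = style.glyph_shapes_at(zl.index)
    for g in sorted(master.glyphs, key=lambda g: (g.frame_id, g.x, g.y)):
        if g.shape not in shapes:
            continue
        out.glyphs.append(
            ZoomGlyph(
                frame_id=g.frame_id,
                shape=g.shape,
                x=px(g.x),
                y=px(g.y),
                w=max(px(g.w), 2),
                h=max(px(g.h), 2),
            )
        )
    for line in sorted(master.lines, key=lambda l: (l.frame_id, l.points[0])):
        out.lines.append(
            ZoomLine(frame_id=line.frame_id, points=[(px(x), px(y)) for x, y in line.points])
        )
    _place_labels(master.labels, out, style)
    return out


def _glyph_px_bbox(g: ZoomGlyph) -> Rect:
    return Rect(
        x0=g.x - g.w // 2, y0=g.y - g.h // 2, x1=g.x + (g.w + 1) // 2, y1=g.y + (g.h + 1) // 2
    )


def _place_labels(labels: list[LabelSpec], out: ZoomLayout, style: StyleConfig) -> None:
    classes = style.label_classes_at(out.level)
    obstacles: list[Rect] = [_glyph_px_bbox(g) for g in out.glyphs]
    s = out.scale
    candidates = [l for l in labels if l.cls in classes]
    candidates.sort(key=lambda l: (l.cls, l.owner, l.x, l.y))
    for lab in candidates:
        size = _FONT_SIZES.get(lab.cls, 9)
        tw, th = _text_extent(style, lab.text, size)
        x = round_half_up(lab.x / s)
        y = round_half_up(lab.y / s)
        box = Rect(x0=x, y0=y - th // 2, x1=x + tw, y1=y + (th + 1) // 2)
        if box.x1 > out.width or box.x0 < 0 or box.y0 < 0 or box.y1 > out.height:
            continue
        if any(box.intersects(ob) for ob in obstacles):
            continue
        obstacles.append(box)
        out.labels.append(
            PlacedLabel(owner=lab.owner, cls=lab.cls, text=lab.text, x=x, y=y, font_size=size, bbox=box)
        )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

class RenderStats:
    """Counts raster renders; the cache-purity tests key on this."""

    def __init__(self) -> None:
        self.renders = 0


def render_image(
    zl: ZoomLayout, style: Optional[StyleConfig] = None, stats: Optional[RenderStats] = None
) -> Image.Image:
    """Draw one large RGB image for a level; deterministic."""
    style = style or StyleConfig()
    if stats is not None:
        stats.renders += 1
    img = Image.new("RGB", (zl.width, zl.height), style.background)
    draw = ImageDraw.Draw(img)

    for name in ("periplasm", "outer_membrane", "inner_membrane"):
        r = zl.regions.get(name)
        if r is None or r.h == 0:
            continue
        fill = style.periplasm_fill if name == "periplasm" else style.membrane_fill
        draw.rectangle([r.x0, r.y0, r.x1 - 1, r.y1 - 1], fill=fill)
    for r in zl.cluster_rects:
        draw.rectangle([r.x0, r.y0, r.x1 - 1, r.y1 - 1], fill=style.cluster_fill, outline=style.cluster_edge)
    for line in zl.lines:
        draw.line(line.points, fill=style.reaction_line, width=max(1, 2 if zl.scale <= 2 else 1))
    for g in zl.glyphs:
        b = _glyph_px_bbox(g)
        if g.shape == "circle":
            draw.ellipse([b.x0, b.y0, b.x1, b.y1], fill=style.compound_fill)
        elif g.shape == "triangle":
            draw.polygon([(g.x, b.y0), (b.x1, b.y1), (b.x0, b.y1)], fill=style.enzyme_fill)
        elif g.shape == "box":
            draw.rectangle([b.x0, b.y0, b.x1, b.y1], fill=style.transporter_fill)
        elif g.shape == "tee":
            draw.line([(b.x0, b.y0), (b.x1, b.y0)], fill=style.rna_fill, width=2)
            draw.line([(g.x, b.y0), (g.x, b.y1)], fill=style.rna_fill, width=2)
    for lab in zl.labels:
        font = _load_font(style, lab.font_size)
        draw.text((lab.x, lab.bbox.y0), lab.text, fill=style.text_color, font=font)
    return img


def raster_to_array(img: Image.Image) -> np.ndarray:
    return np.asarray(img)
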