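"""Omics Viewer: paint experimental values onto the map as overlays.

A datafile is a two-dimensional tab-delimited table whose rows are
labeled with gene, reaction, compound, or protein identifiers and whose
columns are experiments.  Gene and protein labels are mapped to the
reaction steps they catalyze; reaction labels map to their own lines;
compound labels map to every duplicate compound glyph.  The global range
of values across the selected columns is mapped to a color spectrum
(yellow -> orange -> red by default, gray for missing), shared by all
columns so that animation frames are directly comparable.  Each selected
column yields one overlay — the frames of the animation; the base tiles
are never regenerated.

Datafile dialect: "#" comment lines are skipped; LF and CRLF both
accepted; a header row is auto-detected (first row whose value cells are
non-numeric) and supplies experiment names; non-numeric cells such as
"NA" are recorded as missing, not dropped.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

from PIL import Image, ImageDraw
from pydantic import BaseModel, Field

from .layout_engine import MasterLayout
from .search_highlight import Overlay, OverlayPrimitive, SearchIndex
from .network_model import PGDB, Kind
from .zoom_renderer import StyleConfig, ZoomLevel, round_half_up

DEFAULT_RAMP = [(255, 255, 160), (255, 165, 0), (200, 0, 0)]  # yellow-orange-red
MISSING_COLOR = (150, 150, 150)


class OmicsFormatError(ValueError):
    pass


class OmicsRow(BaseModel):
    label: str
    values: list[Optional[float]]


class OmicsDataset(BaseModel):
    rows: list[OmicsRow]
    experiment_names: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.experiment_names)


def _try_float(cell: str) -> Optional[float]:
    try:
        v = float(cell)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def parse_datafile(
    path: Union[str, Path],
    columns: Optional[Sequence[int]] = None,
    transform: str = "identity",
) -> OmicsDataset:
    """Parse a tab-delimited omics datafile.

    ``columns`` selects value columns by 0-based index (after the label
    column); ``transform`` ("identity" | "log10") is applied later by
    :func:`fit_colormap` and is recorded here only through the caller.
    Duplicate labels keep the last occurrence, with a warning.
    """
    lines = Path(path).read_text().replace("\r\n", "\n").split("\n")
    records: list[list[str]] = []
    for line in lines:
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        records.append(line.split("\t"))
    if not records:
        raise OmicsFormatError("datafile contains no data rows")
    n_value_cols = max(len(r) - 1 for r in records)
    if n_value_cols < 1:
        raise OmicsFormatError("datafile has zero value columns")

    # header auto-detection: first row counts as a header when none of its
    # value cells parse as numbers
    first_vals = records[0][1:]
    has_header = bool(first_vals) and all(_try_float(c) is None for c in first_vals if c.strip())
    names: list[str]
    if has_header:
        names = [c.strip() or f"exp{i + 1}" for i, c in enumerate(records[0][1:])]
        names += [f"exp{i + 1}" for i in range(len(names), n_value_cols)]
        body = records[1:]
    else:
        names = [f"exp{i + 1}" for i in range(n_value_cols)]
        body = records
    if not body:
        raise OmicsFormatError("datafile has a header but no data rows")

    sel = list(columns) if columns is not None else list(range(n_value_cols))
    for c in sel:
        if not 0 <= c < n_value_cols:
            raise OmicsFormatError(f"selected column {c} out of range 0..{n_value_cols - 1}")

    seen: dict[str, int] = {}
    rows: list[OmicsRow] = []
    for rec in body:
        label = rec[0].strip()
        cells = rec[1:] + [""] * (n_value_cols - len(rec) + 1)
        vals = [_try_float(cells[c].strip()) for c in sel]
        if label in seen:
            warnings.warn(f"duplicate label {label!r}: keeping last occurrence")
            rows[seen[label]] = OmicsRow(label=label, values=vals)
        else:
            seen[label] = len(rows)
            rows.append(OmicsRow(label=label, values=vals))
    return OmicsDataset(rows=rows, experiment_names=[names[c] for c in sel])


# ---------------------------------------------------------------------------
# Row resolution
# ---------------------------------------------------------------------------

class RowResolution(BaseModel):
    #: row label -> frame_ids of the map elements it paints
    mapping: dict[str, list[str]]
    unresolved: list[str]


def resolve_rows(ds: OmicsDataset, index: SearchIndex) -> RowResolution:
    """Resolve row labels (by frame_id or name, case-insensitive on name)
    to the map elements they color.

    Genes and proteins are mapped to their reaction steps; reactions map
    to themselves; compounds map to their glyph occurrences (represented
    by the compound frame_id).  Unresolved labels are reported, never
    fatal.
    """
    mapping: dict[str, list[str]] = {}
    unresolved: list[str] = []
    for row in ds.rows:
        elements = _resolve_label(row.label, index)
        if elements:
            mapping[row.label] = elements
        else:
            unresolved.append(row.label)
    return RowResolution(mapping=mapping, unresolved=unresolved)


def _resolve_label(label: str, index: SearchIndex) -> list[str]:
    ll = label.lower()
    for kind in (Kind.reaction, Kind.compound, Kind.gene, Kind.protein):
        hits = [
            e
            for e in index.entries[kind]
            if e.frame_id == label or e.name.lower() == ll or any(s.lower() == ll for s in e.synonyms)
        ]
        if not hits:
            continue
        reaction_ids = {e.frame_id for e in index.entries[Kind.reaction]}
        out: list[str] = []
        for ent in hits:
            if kind in (Kind.reaction, Kind.compound):
                out.append(ent.frame_id)
            elif kind == Kind.protein:
                out.extend(index.enzyme_reactions.get(ent.frame_id, []))
            elif kind == Kind.gene:
                # gene labels paint the reaction steps their products catalyze
                out.extend(
                    fid
                    for fid in index.gene_expansion.get(ent.frame_id, [])
                    if fid in reaction_ids
                )
        return sorted(set(out))
    return []


# ---------------------------------------------------------------------------
# Color mapping
# ---------------------------------------------------------------------------

class ColorMap(BaseModel):
    """Monotone value -> color ramp over a fixed domain."""

    ramp: list[tuple[int, int, int]] = Field(default_factory=lambda: list(DEFAULT_RAMP))
    v_min: float
    v_max: float
    transform: str = "identity"  # identity | log10
    missing_color: tuple[int, int, int] = MISSING_COLOR

    def _fraction(self, value: float) -> float:
        v = math.log10(value) if self.transform == "log10" else value
        lo = math.log10(self.v_min) if self.transform == "log10" else self.v_min
        hi = math.log10(self.v_max) if self.transform == "log10" else self.v_max
        if hi <= lo:
            return 0.5  # degenerate (constant) domain: ramp midpoint
        return min(1.0, max(0.0, (v - lo) / (hi - lo)))  # clamp out-of-range

    def color(self, value: Optional[float]) -> tuple[int, int, int]:
        """Exact piecewise-linear interpolation between the ramp stops
        (no lookup-table quantization, so ramp stops are hit exactly)."""
        if value is None:
            return tuple(self.missing_color)
        pos = self._fraction(value) * (len(self.ramp) - 1)
        i = min(int(pos), len(self.ramp) - 2)
        t = pos - i
        lo, hi = self.ramp[i], self.ramp[i + 1]
        return tuple(round(a + (b - a) * t) for a, b in zip(lo, hi))


def fit_colormap(
    ds: OmicsDataset,
    ramp: Optional[list[tuple[int, int, int]]] = None,
    transform: str = "identity",
) -> ColorMap:
    """Fit a single shared color map over the global min/max of all
    selected columns (one key for the whole animation)."""
    values = [v for row in ds.rows for v in row.values if v is not None]
    if not values:
        raise OmicsFormatError("dataset has no numeric values")
    if transform == "log10":
        bad = next((row.label for row in ds.rows if any(v is not None and v <= 0 for v in row.values)), None)
        if bad is not None:
            raise OmicsFormatError(f"log10 transform requires positive values; row {bad!r} violates this")
    elif transform != "identity":
        raise OmicsFormatError(f"unknown transform {transform!r}")
    return ColorMap(
        ramp=ramp or list(DEFAULT_RAMP),
        v_min=min(values),
        v_max=max(values),
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

class OmicsFrameSet(BaseModel):
    frames: list[Overlay]
    colormap: ColorMap
    experiment_names: list[str]


def build_frames(
    ds: OmicsDataset,
    resolution: RowResolution,
    cmap: ColorMap,
    master: Optional[MasterLayout] = None,
) -> OmicsFrameSet:
    """One overlay per experiment column, in column order.

    An element's color is ``cmap(value)`` for that column; a resolved row
    with a missing value in some column gets the missing color there.  An
    element receiving values from several rows takes their mean, with a
    warning.  Base tiles are untouched — frames are pure overlays.
    """
    frames: list[Overlay] = []
    for col, exp in enumerate(ds.experiment_names):
        values: dict[str, list[Optional[float]]] = {}
        for row in ds.rows:
            if row.label not in resolution.mapping:
                continue
            for fid in resolution.mapping[row.label]:
                values.setdefault(fid, []).append(row.values[col])
        ov = Overlay(name=exp, color=cmap.ramp[-1])
        for fid in sorted(values):
            vs = [v for v in values[fid] if v is not None]
            if len(vs) > 1:
                warnings.warn(f"element {fid!r} receives {len(vs)} values in column {exp!r}; using mean")
            value = sum(vs) / len(vs) if vs else None
            color = cmap.color(value)
            ov.found.append(_found(fid, master))
            ov.primitives.extend(_paint_element(fid, color, master))
        frames.append(ov)
    return OmicsFrameSet(frames=frames, colormap=cmap, experiment_names=list(ds.experiment_names))


def _found(fid: str, master: Optional[MasterLayout]):
    from .search_highlight import FoundObject

    anchor = (0, 0)
    if master is not None:
        glyphs = master.glyphs_of(fid)
        lines = master.lines_of(fid)
        if glyphs:
            anchor = (glyphs[0].x, glyphs[0].y)
        elif lines:
            x0, y0 = lines[0].points[0]
            x1, y1 = lines[0].points[-1]
            anchor = ((x0 + x1) // 2, (y0 + y1) // 2)
    return FoundObject(frame_id=fid, name=fid, anchor=anchor)


def _paint_element(fid: str, color: tuple[int, int, int], master: Optional[MasterLayout]) -> list[OverlayPrimitive]:
    prims: list[OverlayPrimitive] = []
    if master is None:
        prims.append(OverlayPrimitive(shape="circle", color=color, points=[(0, 0)], size=1))
        return prims
    for g in master.glyphs_of(fid):
        if g.shape == "circle":
            prims.append(OverlayPrimitive(shape="circle", color=color, points=[(g.x, g.y)], size=g.w // 2 + 2))
        else:
            b = g.bbox
            prims.append(OverlayPrimitive(shape="rect", color=color, points=[(b.x0, b.y0), (b.x1, b.y1)]))
    for line in master.lines_of(fid):
        prims.append(OverlayPrimitive(shape="polyline", color=color, points=line.points, size=4))
    return prims


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def composite_frame(base: Image.Image, frame: Overlay, scale: int) -> Image.Image:
    """Paint a frame's primitives over a copy of the base level raster."""
    out = base.copy()
    draw = ImageDraw.Draw(out)
    for prim in frame.primitives:
        color = tuple(prim.color)
        pts = [(round_half_up(x / scale), round_half_up(y / scale)) for x, y in prim.points]
        if prim.shape == "circle":
            (cx, cy) = pts[0]
            r = max(1, round_half_up(prim.size / scale))
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color)
        elif prim.shape == "rect":
            (x0, y0), (x1, y1) = pts
            draw.rectangle([x0, y0, x1, y1], fill=color)
        else:
            draw.line(pts, fill=color, width=max(1, round_half_up(prim.size / max(scale // 2, 1))))
    return out


def render_legend(cmap: ColorMap, width: int = 256, height: int = 40) -> Image.Image:
    """The color key: the ramp spanning [v_min, v_max] with end labels."""
    img = Image.new("RGB", (width, height), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    bar_h = height - 16
    span = cmap.v_max - cmap.v_min
    for x in range(width):
        frac = x / max(width - 1, 1)
        value = cmap.v_min + frac * span
        draw.line([(x, 0), (x, bar_h)], fill=cmap.color(value if span > 0 else cmap.v_min))
    draw.text((2, bar_h + 2), f"{cmap.v_min:g}", fill=(0, 0, 0))
    hi = f"{cmap.v_max:g}"
    draw.text((width - 6 * len(hi) - 2, bar_h + 2), hi, fill=(0, 0, 0))
    return img


def export_frames(
    fs: OmicsFrameSet,
    base: Image.Image,
    zoom: Union[int, ZoomLevel],
    outdir: Union[str, Path],
    n_levels: int = 6,
) -> list[Path]:
    """Write one overlay JSON + one composited raster per frame, plus the
    color-key legend.  Deterministic: re-export is byte-identical."""
    zl = zoom if isinstance(zoom, ZoomLevel) else ZoomLevel.of(zoom, n_levels)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, frame in enumerate(fs.frames):
        doc = outdir / f"frame_{i:03d}.json"
        doc.write_text(json.dumps(frame.model_dump(mode="json"), sort_keys=True, indent=0))
        png = outdir / f"frame_{i:03d}.png"
        composite_frame(base, frame, zl.scale).save(png, "PNG")
        written += [doc, png]
    legend = outdir / "legend.png"
    render_legend(fs.colormap).save(legend, "PNG")
    written.append(legend)
    return written
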