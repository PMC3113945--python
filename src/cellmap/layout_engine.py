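"""Master layout: zoom-independent placement of every drawable object.

This is step 1 of the base-image pipeline.  It runs once per organism and
its result is persisted next to the network file (conceptually part of the
organism's database).  The layout is a deterministic slot-packing scheme
that honors the spatial conventions of whole-cell metabolic map diagrams:

* horizontal bands, top to bottom: extracellular space, outer membrane,
  periplasm, inner membrane, cytoplasm (a Gram-negative two-membrane
  template; a single-membrane organism degenerates the periplasm to zero
  height);
* inside the cytoplasm, pathways of central metabolism (glycolysis, TCA)
  occupy the middle column, separating catabolic pathways on the right
  from anabolic/intermediary pathways on the left; signal-transduction
  pathways run along the bottom left; reactions assigned to no pathway
  form a rectangular grid at the far right;
* pathways are grouped into shaded cluster boxes by their cluster label;
* transporters and other membrane proteins are embedded in their
  membrane band; periplasmic reactions sit between the two membranes on
  the right side;
* pathways flow predominantly downward; each reaction draws its own
  substrate/product glyphs locally (metabolites are duplicated across
  pathways rather than connected by long edges), except that consecutive
  steps of a within-pathway chain share the connecting metabolite glyph.

Coordinates are integers in "master units" with a top-left origin and y
increasing downward; one master unit equals one pixel at the highest zoom
level.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field

from .network_model import (
    PGDB,
    Compartment,
    Pathway,
    PathwayCategory,
    Reaction,
    validate,
)

REGION_NAMES = (
    "extracellular",
    "outer_membrane",
    "periplasm",
    "inner_membrane",
    "cytoplasm",
    "unassigned_grid",
    "signal_strip",
)

#: left-to-right order of pathway-category columns inside the cytoplasm
CATEGORY_ORDER = (
    PathwayCategory.anabolic_intermediary,
    PathwayCategory.central,
    PathwayCategory.catabolic,
    PathwayCategory.other,
)


class CanvasOverflowError(ValueError):
    def __init__(self, required: tuple[int, int], configured: tuple[int, int]):
        self.required = required
        self.configured = configured
        super().__init__(
            f"layout requires a {required[0]}x{required[1]} canvas; "
            f"configured maximum is {configured[0]}x{configured[1]}"
        )


class LayoutConfig(BaseModel):
    """Geometry knobs, all in master units."""

    margin: int = 40
    extracellular_h: int = 50
    outer_membrane_h: int = 36
    periplasm_h: int = 140
    inner_membrane_h: int = 36
    single_membrane: bool = False  # degenerate periplasm of zero height
    cytoplasm_top_pad: int = 44

    glyph_r: int = 5          # compound circle radius
    enzyme_size: int = 6      # enzyme triangle half-extent
    rna_size: int = 6         # tee half-extent
    transporter_w: int = 14
    glyph_spacing: int = 26
    step_h: int = 56          # substrate row -> product row distance
    line_gap: int = 8         # line stops short of glyph rows
    enzyme_dx: int = 18       # enzyme triangle offset right of the line
    enzyme_spacing: int = 15
    chain_column_cap: int = 8  # reactions per vertical chain column

    pathway_pad: int = 16
    pathway_label_h: int = 18
    cluster_pad: int = 22
    cluster_label_h: int = 20
    area_gap: int = 56        # gap between category columns
    block_gap: int = 26       # gap between packed blocks

    grid_cell_w: int = 96
    grid_cell_h: int = 78
    grid_columns: Optional[int] = None  # default: ceil(sqrt(n))

    max_canvas_w: int = 24000
    max_canvas_h: int = 24000


class Rect(BaseModel):
    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def w(self) -> int:
        return self.x1 - self.x0

    @property
    def h(self) -> int:
        return self.y1 - self.y0

    @property
    def cx(self) -> int:
        return (self.x0 + self.x1) // 2

    @property
    def cy(self) -> int:
        return (self.y0 + self.y1) // 2

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )

    def intersects(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def translated(self, dx: int, dy: int) -> "Rect":
        return Rect(x0=self.x0 + dx, y0=self.y0 + dy, x1=self.x1 + dx, y1=self.y1 + dy)


class Glyph(BaseModel):
    """One placed occurrence of a drawable object.

    ``roles`` records the (reaction, side) occurrences collapsed into this
    glyph (chain sharing merges consecutive product/substrate occurrences).
    """

    frame_id: str
    shape: str  # circle | triangle | tee | box
    x: int
    y: int
    w: int
    h: int
    roles: list[str] = Field(default_factory=list)  # e.g. "RXN-1:substrate"

    @property
    def bbox(self) -> Rect:
        return Rect(
            x0=self.x - self.w // 2,
            y0=self.y - self.h // 2,
            x1=self.x + (self.w + 1) // 2,
            y1=self.y + (self.h + 1) // 2,
        )

    def translated(self, dx: int, dy: int) -> "Glyph":
        return self.model_copy(update={"x": self.x + dx, "y": self.y + dy})


class ReactionLine(BaseModel):
    frame_id: str
    points: list[tuple[int, int]]
    pathway: Optional[str] = None
    region: str = "cytoplasm"

    def translated(self, dx: int, dy: int) -> "ReactionLine":
        return self.model_copy(
            update={"points": [(x + dx, y + dy) for x, y in self.points]}
        )


class LabelSpec(BaseModel):
    """A candidate label; the zoom specializer decides if it fits."""

    owner: str
    cls: str  # pathway_name | compound_name | enzyme_name | gene_name | ec_number
    text: str
    x: int  # anchor: text starts here (left edge), vertically centered on y
    y: int

    def translated(self, dx: int, dy: int) -> "LabelSpec":
        return self.model_copy(update={"x": self.x + dx, "y": self.y + dy})


class ClusterBox(BaseModel):
    label: str
    category: PathwayCategory
    rect: Rect
    pathway_ids: list[str]


class PathwayBox(BaseModel):
    frame_id: str
    rect: Rect


class MasterLayout(BaseModel):
    organism_id: str
    version_stamp: str
    canvas_w: int
    canvas_h: int
    regions: dict[str, Rect]
    cluster_boxes: list[ClusterBox] = Field(default_factory=list)
    pathway_boxes: list[PathwayBox] = Field(default_factory=list)
    lines: list[ReactionLine] = Field(default_factory=list)
    glyphs: list[Glyph] = Field(default_factory=list)
    labels: list[LabelSpec] = Field(default_factory=list)

    def glyphs_of(self, frame_id: str) -> list[Glyph]:
        return [g for g in self.glyphs if g.frame_id == frame_id]

    def lines_of(self, frame_id: str) -> list[ReactionLine]:
        return [l for l in self.lines if l.frame_id == frame_id]

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "MasterLayout":
        return cls.model_validate(json.loads(text))

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "MasterLayout":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

_CATEGORY_REGION = {
    PathwayCategory.central: "cytoplasm",
    PathwayCategory.catabolic: "cytoplasm",
    PathwayCategory.anabolic_intermediary: "cytoplasm",
    PathwayCategory.other: "cytoplasm",
    PathwayCategory.signal: "signal_strip",
}

_COMPARTMENT_REGION = {
    Compartment.periplasm: "periplasm",
    Compartment.inner_membrane: "inner_membrane",
    Compartment.outer_membrane: "outer_membrane",
}


def primary_pathway(pgdb: PGDB, rxn: Reaction) -> Optional[str]:
    """The pathway a multiply-assigned reaction is drawn in: first by frame_id."""
    resolved = [p for p in rxn.pathways if p in pgdb.pathways]
    return min(resolved) if resolved else None


def assign_regions(pgdb: PGDB) -> dict[str, str]:
    """Map every pathway, reaction, and transporter protein to its region.

    Compartment takes precedence over pathway category: a periplasmic or
    membrane reaction is drawn in its band no matter which pathway claims
    it.  Pathway-less cytosolic reactions go to the unassigned grid.
    """
    regions: dict[str, str] = {}
    for pwy in pgdb.pathways.values():
        regions[pwy.frame_id] = _CATEGORY_REGION[pwy.category]
    for rxn in pgdb.reactions.values():
        if rxn.compartment in _COMPARTMENT_REGION:
            regions[rxn.frame_id] = _COMPARTMENT_REGION[rxn.compartment]
            continue
        pwy_id = primary_pathway(pgdb, rxn)
        if pwy_id is None:
            regions[rxn.frame_id] = "unassigned_grid"
        else:
            regions[rxn.frame_id] = regions[pwy_id]
    for prot in pgdb.proteins.values():
        if prot.is_transporter:
            regions[prot.frame_id] = _transporter_band(pgdb, prot.frame_id)
    return regions


def _transporter_band(pgdb: PGDB, prot_id: str) -> str:
    for rxn in pgdb.reactions.values():
        if prot_id in rxn.enzymes and rxn.compartment == Compartment.outer_membrane:
            return "outer_membrane"
    return "inner_membrane"


# ---------------------------------------------------------------------------
# Internal block model (relative-coordinate fragments)
# ---------------------------------------------------------------------------

class _Block:
    def __init__(self, w: int = 0, h: int = 0):
        self.w = w
        self.h = h
        self.glyphs: list[Glyph] = []
        self.lines: list[ReactionLine] = []
        self.labels: list[LabelSpec] = []
        self.cluster_boxes: list[ClusterBox] = []
        self.pathway_boxes: list[PathwayBox] = []

    def merge(self, other: "_Block", dx: int, dy: int) -> None:
        self.glyphs += [g.translated(dx, dy) for g in other.glyphs]
        self.lines += [l.translated(dx, dy) for l in other.lines]
        self.labels += [l.translated(dx, dy) for l in other.labels]
        self.cluster_boxes += [
            cb.model_copy(update={"rect": cb.rect.translated(dx, dy)})
            for cb in other.cluster_boxes
        ]
        self.pathway_boxes += [
            pb.model_copy(update={"rect": pb.rect.translated(dx, dy)})
            for pb in other.pathway_boxes
        ]


def _pack_shelves(blocks: Sequence[_Block], target_w: int, gap: int) -> _Block:
    """Deterministic shelf packing, preserving the given block order."""
    out = _Block()
    x = y = 0
    shelf_h = 0
    for blk in blocks:
        if x > 0 and x + blk.w > target_w:
            x = 0
            y += shelf_h + gap
            shelf_h = 0
        out.merge(blk, x, y)
        x += blk.w + gap
        shelf_h = max(shelf_h, blk.h)
        out.w = max(out.w, x - gap)
    out.h = y + shelf_h
    return out


# ---------------------------------------------------------------------------
# Pathway internals
# ---------------------------------------------------------------------------

def _chain_rows(
    reactions: list[Reaction],
) -> list[list[tuple[str, list[str]]]]:
    """Rows of (compound, roles) for a chain column.

    Row 0 holds the substrates of the first reaction; row i holds the
    products of reaction i merged with the not-yet-placed substrates of
    reaction i+1 (chain sharing).
    """
    rows: list[list[tuple[str, list[str]]]] = []
    if not reactions:
        return rows
    first = reactions[0]
    rows.append(
        [(p.compound, [f"{first.frame_id}:substrate"]) for p in first.substrates]
    )
    for i, rxn in enumerate(reactions):
        row: dict[str, list[str]] = {}
        for p in rxn.products:
            row.setdefault(p.compound, []).append(f"{rxn.frame_id}:product")
        if i + 1 < len(reactions):
            nxt = reactions[i + 1]
            for p in nxt.substrates:
                if p.compound in row:
                    row[p.compound].append(f"{nxt.frame_id}:substrate")
                else:
                    row.setdefault(p.compound, []).append(f"{nxt.frame_id}:substrate")
        rows.append(sorted(row.items()))
    return rows


def _layout_pathway(pgdb: PGDB, pwy: Pathway, cfg: LayoutConfig) -> _Block:
    """Lay out one pathway as vertical chain columns, flowing downward."""
    drawn = [
        pgdb.reactions[rid]
        for rid in pwy.reactions
        if rid in pgdb.reactions
        and pgdb.reactions[rid].compartment == Compartment.cytosol
        and primary_pathway(pgdb, pgdb.reactions[rid]) == pwy.frame_id
    ]
    pad = cfg.pathway_pad
    top = pad + cfg.pathway_label_h
    blk = _Block()
    col_x = pad
    max_bottom = top
    for start in range(0, len(drawn), cfg.chain_column_cap):
        chunk = drawn[start : start + cfg.chain_column_cap]
        rows = _chain_rows(chunk)
        n_enz_max = max((len(r.enzymes) for r in chunk), default=0)
        max_row_n = max((len(r) for r in rows), default=0)
        half_w = max(
            (max_row_n * cfg.glyph_spacing) // 2 + cfg.glyph_r,
            cfg.enzyme_dx + max(n_enz_max, 1) * cfg.enzyme_spacing,
            24,
        )
        xc = col_x + half_w
        row_ys = [top + cfg.glyph_r + j * cfg.step_h for j in range(len(rows))]
        for j, row in enumerate(rows):
            n = len(row)
            for k, (cpd, roles) in enumerate(row):
                gx = xc + (2 * k - (n - 1)) * cfg.glyph_spacing // 2
                blk.glyphs.append(
                    Glyph(
                        frame_id=cpd,
                        shape="circle",
                        x=gx,
                        y=row_ys[j],
                        w=2 * cfg.glyph_r,
                        h=2 * cfg.glyph_r,
                        roles=roles,
                    )
                )
                blk.labels.append(
                    LabelSpec(
                        owner=cpd,
                        cls="compound_name",
                        text=pgdb.compounds[cpd].name if cpd in pgdb.compounds else cpd,
                        x=gx + cfg.glyph_r + 3,
                        y=row_ys[j],
                    )
                )
        for j, rxn in enumerate(chunk):
            y_top = row_ys[j] + cfg.line_gap
            y_bot = row_ys[j + 1] - cfg.line_gap
            blk.lines.append(
                ReactionLine(
                    frame_id=rxn.frame_id,
                    points=[(xc, y_top), (xc, y_bot)],
                    pathway=pwy.frame_id,
                    region="signal_strip" if pwy.category == PathwayCategory.signal else "cytoplasm",
                )
            )
            y_mid = (y_top + y_bot) // 2
            if rxn.ec_numbers:
                blk.labels.append(
                    LabelSpec(
                        owner=rxn.frame_id,
                        cls="ec_number",
                        text=rxn.ec_numbers[0],
                        x=xc + 4,
                        y=y_mid + cfg.step_h // 4,
                    )
                )
            for e_i, enz_id in enumerate(rxn.enzymes):
                ex = xc + cfg.enzyme_dx + e_i * cfg.enzyme_spacing
                blk.glyphs.append(
                    Glyph(
                        frame_id=enz_id,
                        shape="triangle",
                        x=ex,
                        y=y_mid,
                        w=2 * cfg.enzyme_size,
                        h=2 * cfg.enzyme_size,
                        roles=[f"{rxn.frame_id}:enzyme"],
                    )
                )
                blk.labels.append(
                    LabelSpec(
                        owner=enz_id,
                        cls="enzyme_name",
                        text=pgdb.proteins[enz_id].name if enz_id in pgdb.proteins else enz_id,
                        x=ex + cfg.enzyme_size + 3,
                        y=y_mid - 5,
                    )
                )
                gene_names = [
                    pgdb.genes[g].name
                    for g in (pgdb.proteins[enz_id].genes if enz_id in pgdb.proteins else [])
                    if g in pgdb.genes
                ]
                if gene_names:
                    blk.labels.append(
                        LabelSpec(
                            owner=enz_id,
                            cls="gene_name",
                            text="/".join(gene_names),
                            x=ex + cfg.enzyme_size + 3,
                            y=y_mid + 6,
                        )
                    )
        col_w = 2 * half_w
        col_x += col_w + cfg.glyph_spacing
        if row_ys:
            max_bottom = max(max_bottom, row_ys[-1] + cfg.glyph_r)
    blk.w = max(col_x - cfg.glyph_spacing + pad, 2 * pad + 40)
    blk.h = max_bottom + pad
    blk.labels.insert(
        0,
        LabelSpec(owner=pwy.frame_id, cls="pathway_name", text=pwy.name, x=pad, y=pad + cfg.pathway_label_h // 2),
    )
    blk.pathway_boxes.append(
        PathwayBox(frame_id=pwy.frame_id, rect=Rect(x0=0, y0=0, x1=blk.w, y1=blk.h))
    )
    return blk


def _layout_category(
    pgdb: PGDB, pathways: list[Pathway], cfg: LayoutConfig
) -> _Block:
    """Shelf-pack this category's cluster boxes into a roughly square area."""
    clusters: dict[str, list[Pathway]] = {}
    for pwy in pathways:
        clusters.setdefault(pwy.cluster or "other pathways", []).append(pwy)
    cluster_blocks: list[_Block] = []
    for label in sorted(clusters):
        # descending reaction count, ties by frame_id
        pws = sorted(clusters[label], key=lambda p: (-len(p.reactions), p.frame_id))
        blocks = [_layout_pathway(pgdb, p, cfg) for p in pws]
        area = sum((b.w + cfg.block_gap) * (b.h + cfg.block_gap) for b in blocks)
        target = max(
            int(math.sqrt(area * 1.4)) if area else 0,
            max((b.w for b in blocks), default=0),
        )
        inner = _pack_shelves(blocks, target, cfg.block_gap)
        boxed = _Block(
            w=inner.w + 2 * cfg.cluster_pad,
            h=inner.h + 2 * cfg.cluster_pad + cfg.cluster_label_h,
        )
        boxed.merge(inner, cfg.cluster_pad, cfg.cluster_pad + cfg.cluster_label_h)
        boxed.cluster_boxes.insert(
            0,
            ClusterBox(
                label=label,
                category=pws[0].category,
                rect=Rect(x0=0, y0=0, x1=boxed.w, y1=boxed.h),
                pathway_ids=[p.frame_id for p in pws],
            ),
        )
        cluster_blocks.append(boxed)
    area = sum((b.w + cfg.block_gap) * (b.h + cfg.block_gap) for b in cluster_blocks)
    target = max(
        int(math.sqrt(area * 1.3)) if area else 0,
        max((b.w for b in cluster_blocks), default=0),
    )
    return _pack_shelves(cluster_blocks, target, cfg.block_gap)


def _layout_grid(
    pgdb: PGDB, reactions: list[Reaction], cfg: LayoutConfig
) -> _Block:
    """Rectangular grid of pathway-less reactions, row-major by frame_id."""
    n = len(reactions)
    blk = _Block()
    if n == 0:
        return blk
    cols = cfg.grid_columns or max(1, math.ceil(math.sqrt(n)))
    rows = math.ceil(n / cols)
    max_side = max(
        max((len(r.substrates) for r in reactions), default=1),
        max((len(r.products) for r in reactions), default=1),
        1,
    )
    cell_w = max(cfg.grid_cell_w, max_side * (2 * cfg.glyph_r + 8) + 2 * cfg.glyph_r + 20)
    cell_h = cfg.grid_cell_h
    for i, rxn in enumerate(reactions):
        r, c = divmod(i, cols)
        x0, y0 = c * cell_w, r * cell_h
        xc = x0 + cell_w // 2
        y_s = y0 + cfg.glyph_r + 6
        y_p = y0 + cell_h - cfg.glyph_r - 10
        spacing = 2 * cfg.glyph_r + 8
        for side, y, parts in (
            ("substrate", y_s, rxn.substrates),
            ("product", y_p, rxn.products),
        ):
            m = len(parts)
            for k, part in enumerate(parts):
                gx = xc + (2 * k - (m - 1)) * spacing // 2
                blk.glyphs.append(
                    Glyph(
                        frame_id=part.compound,
                        shape="circle",
                        x=gx,
                        y=y,
                        w=2 * cfg.glyph_r,
                        h=2 * cfg.glyph_r,
                        roles=[f"{rxn.frame_id}:{side}"],
                    )
                )
        blk.lines.append(
            ReactionLine(
                frame_id=rxn.frame_id,
                points=[(xc, y_s + cfg.line_gap), (xc, y_p - cfg.line_gap)],
                pathway=None,
                region="unassigned_grid",
            )
        )
        for e_i, enz_id in enumerate(rxn.enzymes):
            blk.glyphs.append(
                Glyph(
                    frame_id=enz_id,
                    shape="triangle",
                    x=xc + cfg.enzyme_dx + e_i * cfg.enzyme_spacing,
                    y=(y_s + y_p) // 2,
                    w=2 * cfg.enzyme_size,
                    h=2 * cfg.enzyme_size,
                    roles=[f"{rxn.frame_id}:enzyme"],
                )
            )
        if rxn.ec_numbers:
            blk.labels.append(
                LabelSpec(
                    owner=rxn.frame_id,
                    cls="ec_number",
                    text=rxn.ec_numbers[0],
                    x=xc + 4,
                    y=(y_s + y_p) // 2,
                )
            )
    blk.w = cols * cell_w
    blk.h = rows * cell_h
    return blk


def _layout_periplasm_row(
    pgdb: PGDB, reactions: list[Reaction], cfg: LayoutConfig
) -> _Block:
    """Periplasmic reactions in a single horizontal row (right-aligned later)."""
    blk = _Block()
    if not reactions:
        return blk
    cell_w = cfg.grid_cell_w
    h = cfg.periplasm_h
    for i, rxn in enumerate(reactions):
        xc = i * cell_w + cell_w // 2
        y_s = cfg.glyph_r + 8
        y_p = h - cfg.glyph_r - 12
        for side, y, parts in (
            ("substrate", y_s, rxn.substrates[:1]),
            ("product", y_p, rxn.products[:1]),
        ):
            for part in parts:
                blk.glyphs.append(
                    Glyph(
                        frame_id=part.compound,
                        shape="circle",
                        x=xc,
                        y=y,
                        w=2 * cfg.glyph_r,
                        h=2 * cfg.glyph_r,
                        roles=[f"{rxn.frame_id}:{side}"],
                    )
                )
        blk.lines.append(
            ReactionLine(
                frame_id=rxn.frame_id,
                points=[(xc, y_s + cfg.line_gap), (xc, y_p - cfg.line_gap)],
                region="periplasm",
            )
        )
        for e_i, enz_id in enumerate(rxn.enzymes):
            blk.glyphs.append(
                Glyph(
                    frame_id=enz_id,
                    shape="triangle",
                    x=xc + cfg.enzyme_dx + e_i * cfg.enzyme_spacing,
                    y=(y_s + y_p) // 2,
                    w=2 * cfg.enzyme_size,
                    h=2 * cfg.enzyme_size,
                    roles=[f"{rxn.frame_id}:enzyme"],
                )
            )
    blk.w = len(reactions) * cell_w
    blk.h = h
    return blk


# ---------------------------------------------------------------------------
# Master layout assembly
# ---------------------------------------------------------------------------

def layout_master(pgdb: PGDB, cfg: Optional[LayoutConfig] = None) -> MasterLayout:
    """Place every drawable object; deterministic for a given PGDB."""
    cfg = cfg or LayoutConfig()
    report = validate(pgdb)
    if report.errors:
        first = report.errors[0]
        raise ValueError(f"PGDB fails validation: [{first.code}] {first.message}")
    region_of = assign_regions(pgdb)
    periplasm_h = 0 if cfg.single_membrane else cfg.periplasm_h

    # --- category areas ---------------------------------------------------
    by_category: dict[PathwayCategory, list[Pathway]] = {}
    for pwy_id in sorted(pgdb.pathways):
        pwy = pgdb.pathways[pwy_id]
        by_category.setdefault(pwy.category, []).append(pwy)
    areas = {
        cat: _layout_category(pgdb, by_category[cat], cfg)
        for cat in CATEGORY_ORDER
        if cat in by_category
    }
    signal_blk = (
        _layout_category(pgdb, by_category[PathwayCategory.signal], cfg)
        if PathwayCategory.signal in by_category
        else _Block()
    )

    grid_rxns = [
        pgdb.reactions[rid]
        for rid in sorted(pgdb.reactions)
        if region_of[rid] == "unassigned_grid"
    ]
    grid_blk = _layout_grid(pgdb, grid_rxns, cfg)

    peri_rxns = [
        pgdb.reactions[rid]
        for rid in sorted(pgdb.reactions)
        if region_of[rid] == "periplasm"
    ]
    peri_blk = _layout_periplasm_row(pgdb, peri_rxns, cfg) if periplasm_h else _Block()

    # --- horizontal assembly of the cytoplasm ------------------------------
    margin = cfg.margin
    x = margin
    area_x: dict[PathwayCategory, int] = {}
    for cat in CATEGORY_ORDER:
        if cat in areas:
            area_x[cat] = x
            x += areas[cat].w + cfg.area_gap
    grid_x = x
    x += grid_blk.w
    content_w = x + margin
    canvas_w = max(
        content_w,
        peri_blk.w + 2 * margin,
        signal_blk.w + 2 * margin,
        400,
    )

    # --- vertical bands -----------------------------------------------------
    y = 0
    regions: dict[str, Rect] = {}
    for name, h in (
        ("extracellular", cfg.extracellular_h),
        ("outer_membrane", 0 if cfg.single_membrane else cfg.outer_membrane_h),
        ("periplasm", periplasm_h),
        ("inner_membrane", cfg.inner_membrane_h),
    ):
        regions[name] = Rect(x0=0, y0=y, x1=canvas_w, y1=y + h)
        y += h
    cyto_y = y
    cat_y = cyto_y + cfg.cytoplasm_top_pad
    max_area_h = max((b.h for b in areas.values()), default=0)
    max_area_h = max(max_area_h, grid_blk.h)
    signal_y = cat_y + max_area_h + (cfg.block_gap if signal_blk.h else 0)
    bottom = signal_y + signal_blk.h + margin
    canvas_h = bottom
    regions["cytoplasm"] = Rect(x0=0, y0=cyto_y, x1=canvas_w, y1=canvas_h)
    regions["unassigned_grid"] = Rect(
        x0=grid_x, y0=cat_y, x1=grid_x + max(grid_blk.w, 1), y1=cat_y + max(grid_blk.h, 1)
    )
    regions["signal_strip"] = Rect(
        x0=margin,
        y0=signal_y,
        x1=margin + max(signal_blk.w, 1),
        y1=signal_y + max(signal_blk.h, 1),
    )

    if canvas_w > cfg.max_canvas_w or canvas_h > cfg.max_canvas_h:
        raise CanvasOverflowError(
            (canvas_w, canvas_h), (cfg.max_canvas_w, cfg.max_canvas_h)
        )

    master = MasterLayout(
        organism_id=pgdb.organism_id,
        version_stamp=pgdb.version_stamp,
        canvas_w=canvas_w,
        canvas_h=canvas_h,
        regions=regions,
    )
    out = _Block()
    for cat, blk in areas.items():
        out.merge(blk, area_x[cat], cat_y)
    out.merge(grid_blk, grid_x, cat_y)
    out.merge(signal_blk, margin, signal_y)
    if peri_blk.w:
        peri = regions["periplasm"]
        out.merge(peri_blk, canvas_w - margin - peri_blk.w, peri.y0)

    # --- membrane-embedded transporters and membrane reactions -------------
    _place_membranes(pgdb, region_of, regions, out, cfg, canvas_w, peri_blk.w)
    # --- RNA strip along the very bottom of the cytoplasm -------------------
    _place_rnas(pgdb, out, cfg, margin, canvas_h - margin + cfg.rna_size)

    master.glyphs = out.glyphs
    master.lines = out.lines
    master.labels = out.labels
    master.cluster_boxes = out.cluster_boxes
    master.pathway_boxes = out.pathway_boxes
    return duplicate_metabolites(master)


def _place_membranes(
    pgdb: PGDB,
    region_of: dict[str, str],
    regions: dict[str, Rect],
    out: _Block,
    cfg: LayoutConfig,
    canvas_w: int,
    periplasm_row_w: int = 0,
) -> None:
    # keep membrane slots clear of the right-aligned periplasm row
    usable_w = canvas_w - 2 * cfg.margin - (periplasm_row_w + 40 if periplasm_row_w else 0)
    for band in ("inner_membrane", "outer_membrane"):
        rect = regions[band]
        if rect.h == 0:
            continue
        transporters = sorted(
            p for p, reg in region_of.items() if reg == band and p in pgdb.proteins
        )
        rxns = sorted(
            r for r, reg in region_of.items() if reg == band and r in pgdb.reactions
        )
        slots = len(transporters) + len(rxns)
        if slots == 0:
            continue
        spacing = max(usable_w // max(slots, 1), 40)
        xi = cfg.margin + spacing // 2
        tx: dict[str, int] = {}
        for prot_id in transporters:
            out.glyphs.append(
                Glyph(
                    frame_id=prot_id,
                    shape="box",
                    x=xi,
                    y=rect.cy,
                    w=cfg.transporter_w,
                    h=max(rect.h - 6, 4),
                    roles=["transporter"],
                )
            )
            out.labels.append(
                LabelSpec(
                    owner=prot_id,
                    cls="enzyme_name",
                    text=pgdb.proteins[prot_id].name,
                    x=xi + cfg.transporter_w,
                    y=rect.cy,
                )
            )
            tx[prot_id] = xi
            xi += spacing
        for rxn_id in rxns:
            rxn = pgdb.reactions[rxn_id]
            # draw through the transporter that catalyzes it, if placed
            x_line = next((tx[e] for e in rxn.enzymes if e in tx), None)
            if x_line is None:
                x_line = xi
                xi += spacing
            out.lines.append(
                ReactionLine(
                    frame_id=rxn_id,
                    points=[(x_line, rect.y0 + 2), (x_line, rect.y1 - 2)],
                    region=band,
                )
            )
            # first substrate drawn on the import side, first product on the
            # export side of the band (transport across the membrane)
            for parts, gy in (
                (rxn.substrates[:1], rect.y0 - 2 - cfg.glyph_r),
                (rxn.products[:1], rect.y1 + 2 + cfg.glyph_r),
            ):
                for part in parts:
                    out.glyphs.append(
                        Glyph(
                            frame_id=part.compound,
                            shape="circle",
                            x=x_line,
                            y=gy,
                            w=2 * cfg.glyph_r,
                            h=2 * cfg.glyph_r,
                            roles=[f"{rxn_id}:substrate" if gy < rect.y0 else f"{rxn_id}:product"],
                        )
                    )


def _place_rnas(
    pgdb: PGDB, out: _Block, cfg: LayoutConfig, x0: int, y: int
) -> None:
    for i, rna_id in enumerate(sorted(pgdb.rnas)):
        x = x0 + cfg.rna_size + i * (4 * cfg.rna_size + cfg.glyph_spacing)
        out.glyphs.append(
            Glyph(
                frame_id=rna_id,
                shape="tee",
                x=x,
                y=y,
                w=2 * cfg.rna_size,
                h=2 * cfg.rna_size,
                roles=["rna"],
            )
        )


def duplicate_metabolites(master: MasterLayout) -> MasterLayout:
    """Finalize local metabolite duplication (idempotent).

    Layout construction already gives each reaction its own local
    substrate/product glyphs, collapsing only consecutive within-pathway
    chain occurrences.  This pass asserts that no connecting edges exist
    between duplicate glyphs of the same compound (such edges would make
    an organism-scale diagram unreadable) and returns the layout.
    """
    compound_lines = {l.frame_id for l in master.lines}
    for g in master.glyphs:
        if g.frame_id in compound_lines:  # a glyph owner must never also be an edge
            raise ValueError(
                f"object {g.frame_id!r} owns both a glyph and a connecting line"
            )
    return master
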