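"""Object location ("node data") and tooltip text ("frame data").

The base tiles alone say nothing about *where* each object sits in the
image.  Node data fills that gap: per zoom level, a mapping from frame_id
to the clickable geometric primitives (circles, rectangles, polylines) of
every drawn occurrence, in that level's pixel coordinates.  Frame data is
the per-object textual description (title, object class, descriptive
lines, links to related objects) shown in tooltips.

Both are exported as JSON documents — one node-data file per zoom level
plus one frame-data file — which together with the tile tree form the
complete published-map bundle for any client.

Polyline hit-testing uses a 3-pixel half-width corridor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

from .layout_engine import MasterLayout
from .network_model import PGDB, Kind
from .zoom_renderer import ZoomLayout, _glyph_px_bbox

HIT_HALF_WIDTH = 3.0


# A primitive is a dict: {"type": "circle", "cx", "cy", "r"} |
# {"type": "rect", "x0", "y0", "x1", "y1"} |
# {"type": "polyline", "points": [[x, y], ...]}
Primitive = dict
NodeData = dict[str, list[Primitive]]  # frame_id -> primitives, one level


def build_node_data(zl: ZoomLayout) -> NodeData:
    """One primitive per drawn element at this level, in pixel coordinates."""
    nd: NodeData = {}
    for g in zl.glyphs:
        if g.shape == "circle":
            prim = {"type": "circle", "cx": g.x, "cy": g.y, "r": max(g.w, g.h) // 2}
        else:
            b = _glyph_px_bbox(g)
            prim = {"type": "rect", "x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1}
        nd.setdefault(g.frame_id, []).append(prim)
    for line in zl.lines:
        nd.setdefault(line.frame_id, []).append(
            {"type": "polyline", "points": [list(p) for p in line.points]}
        )
    return nd


def hit_test(nd: NodeData, x: float, y: float) -> list[str]:
    """frame_ids whose primitives contain the point (sorted)."""
    hits: set[str] = set()
    for fid, prims in nd.items():
        for prim in prims:
            if _prim_contains(prim, x, y):
                hits.add(fid)
                break
    return sorted(hits)


def _prim_contains(prim: Primitive, x: float, y: float) -> bool:
    if prim["type"] == "circle":
        return (x - prim["cx"]) ** 2 + (y - prim["cy"]) ** 2 <= prim["r"] ** 2
    if prim["type"] == "rect":
        return prim["x0"] <= x <= prim["x1"] and prim["y0"] <= y <= prim["y1"]
    pts = prim["points"]
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if _segment_distance(x, y, x0, y0, x1, y1) <= HIT_HALF_WIDTH:
            return True
    return False


def _segment_distance(px: float, py: float, x0: float, y0: float, x1: float, y1: float) -> float:
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return ((px - x0) ** 2 + (py - y0) ** 2) ** 0.5
    t = max(0.0, min(1.0, ((px - x0) * dx + (py - y0) * dy) / L2))
    cx, cy = x0 + t * dx, y0 + t * dy
    return ((px - cx) ** 2 + (py - cy) ** 2) ** 0.5


# ---------------------------------------------------------------------------
# Frame data
# ---------------------------------------------------------------------------

FrameData = dict[str, dict]


_CLASS_TITLES = {
    Kind.compound: "Compound",
    Kind.reaction: "Reaction",
    Kind.pathway: "Pathway",
    Kind.protein: "Protein",
    Kind.rna: "RNA",
    Kind.gene: "Gene",
}


def build_frame_data(pgdb: PGDB) -> FrameData:
    """Deterministic tooltip content for every entity.

    The template assembles: display name, object class, synonyms, and
    class-specific lines (formula, EC numbers, compartment, pathway
    memberships, catalyzing enzymes, gene products), plus link targets to
    the related objects named in those lines.
    """
    fd: FrameData = {}
    enzyme_rxns: dict[str, list[str]] = {}
    for rxn in pgdb.reactions.values():
        for enz in rxn.enzymes:
            enzyme_rxns.setdefault(enz, []).append(rxn.frame_id)
    for ent in pgdb.entities():
        lines: list[str] = []
        links: list[str] = []
        if ent.synonyms:
            lines.append("Synonyms: " + ", ".join(ent.synonyms))
        kind = ent.kind
        if kind == Kind.compound and ent.formula:
            lines.append(f"Formula: {ent.formula}")
        elif kind == Kind.reaction:
            if ent.ec_numbers:
                lines.append("EC: " + ", ".join(ent.ec_numbers))
            lines.append(f"Compartment: {ent.compartment.value}")
            pwy_names = [
                pgdb.pathways[p].name for p in ent.pathways if p in pgdb.pathways
            ]
            if pwy_names:
                lines.append("Pathways: " + ", ".join(sorted(pwy_names)))
            links += sorted(ent.pathways) + sorted(ent.enzymes)
            links += sorted({p.compound for p in ent.substrates + ent.products})
        elif kind == Kind.pathway:
            lines.append(f"Reactions: {len(ent.reactions)}")
            lines.append(f"Category: {ent.category.value}")
            links += list(ent.reactions)
        elif kind == Kind.protein:
            roles = [r for r, flag in (("enzyme", ent.is_enzyme), ("transporter", ent.is_transporter)) if flag]
            if roles:
                lines.append("Roles: " + ", ".join(roles))
            rxns = sorted(enzyme_rxns.get(ent.frame_id, []))
            if rxns:
                lines.append("Catalyzes: " + ", ".join(rxns))
            links += sorted(ent.genes) + rxns
        elif kind == Kind.rna:
            links += sorted(ent.genes)
        elif kind == Kind.gene:
            prod_names = [
                pgdb.get(p).name for p in ent.products if pgdb.get(p) is not None
            ]
            if prod_names:
                lines.append("Products: " + ", ".join(sorted(prod_names)))
            links += sorted(ent.products)
        fd[ent.frame_id] = {
            "title": ent.name,
            "class": _CLASS_TITLES[kind],
            "lines": lines,
            "links": sorted(set(links)),
        }
    return fd


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_client_data(
    node_data_by_level: dict[int, NodeData],
    frame_data: FrameData,
    outdir: Union[str, Path],
) -> list[Path]:
    """Write the published-map data bundle: one node-data JSON per level
    plus a single frame-data JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for level in sorted(node_data_by_level):
        p = outdir / f"nodedata_{level}.json"
        doc = {"level": level, "objects": node_data_by_level[level]}
        p.write_text(json.dumps(doc, sort_keys=True, indent=0))
        written.append(p)
    p = outdir / "framedata.json"
    p.write_text(json.dumps({"objects": frame_data}, sort_keys=True, indent=0))
    written.append(p)
    return written


def load_client_data(outdir: Union[str, Path]) -> tuple[dict[int, NodeData], FrameData]:
    outdir = Path(outdir)
    nd: dict[int, NodeData] = {}
    for p in sorted(outdir.glob("nodedata_*.json")):
        doc = json.loads(p.read_text())
        nd[int(doc["level"])] = doc["objects"]
    fd = json.loads((outdir / "framedata.json").read_text())["objects"]
    return nd, fd
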