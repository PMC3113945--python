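"""Search / highlight: the five command families and their overlays.

Searching and highlighting are the same act: a query produces a named
*overlay*, a separate graphical plane of colored primitives drawn above
the base tiles, plus the ordered list of objects found (the "List"
dialog), each with a marker anchor.

Command families and what gets highlighted:

* pathways  — by name/frame_id (exact) or substring over name, synonyms
  and frame_id; highlighting covers the reactions of the pathways found.
* reactions — exact, substring, EC number (full or dot-prefix, so
  "1.1.1" covers "1.1.1.1"), or enzyme name; the enzyme-name search is
  the enzyme substring search restricted to the enzymes' reactions.
* genes     — exact, substring, or a file of identifiers (one per line;
  unresolvable identifiers are reported, not fatal); matches expand to
  the genes' products as drawn: reactions, RNAs, transporters, enzymes.
* enzymes   — exact or substring; highlights both the protein glyphs and
  the reactions they catalyze.
* compounds — exact or substring; highlights every duplicate glyph
  occurrence of the compounds found.

Matching conventions: substring matching is case-insensitive over name,
synonyms and frame_id; exact matching is case-sensitive on frame_id
(a database key) and case-insensitive on name (human text), ignoring
synonyms.  Overlay primitives live in master coordinates and are
projected onto a zoom level at export time, so one search serves every
level.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

from pydantic import BaseModel, Field

from .layout_engine import MasterLayout
from .network_model import PGDB, Entity, Kind
from .zoom_renderer import ZoomLevel, round_half_up

DEFAULT_COLORS = {
    "pathways": (255, 0, 0),
    "reactions": (255, 140, 0),
    "genes": (0, 160, 0),
    "enzymes": (160, 0, 200),
    "compounds": (0, 120, 255),
}

_EC_RE = re.compile(r"^\d+(\.(\d+|-)){0,3}$")


class EmptyQueryError(ValueError):
    pass


class ECFormatError(ValueError):
    pass


class FoundObject(BaseModel):
    frame_id: str
    name: str
    anchor: tuple[int, int]  # master coordinates of the List marker


class OverlayPrimitive(BaseModel):
    shape: str  # circle | rect | polyline
    color: tuple[int, int, int]
    points: list[tuple[int, int]]  # master coords; circle: [center], r in size
    size: int = 0


class Overlay(BaseModel):
    """One executed search: the keyword names the overlay."""

    name: str
    color: tuple[int, int, int] = (255, 0, 0)
    primitives: list[OverlayPrimitive] = Field(default_factory=list)
    found: list[FoundObject] = Field(default_factory=list)
    unresolved: list[str] = Field(default_factory=list)
    active: bool = True


class SearchIndex:
    """Lowercased string index over names, synonyms and frame_ids,
    plus EC and gene/enzyme expansion maps.  Rebuilt when the stamp
    changes."""

    def __init__(self, pgdb: PGDB):
        self.stamp = pgdb.version_stamp
        self.entries: dict[Kind, list[Entity]] = {k: [] for k in Kind}
        for ent in pgdb.entities():
            self.entries[ent.kind].append(ent)
        for lst in self.entries.values():
            lst.sort(key=lambda e: e.frame_id)
        self.enzyme_reactions: dict[str, list[str]] = {}
        for rxn in pgdb.reactions.values():
            for enz in rxn.enzymes:
                self.enzyme_reactions.setdefault(enz, []).append(rxn.frame_id)
        # gene -> drawn display elements of its products
        self.gene_expansion: dict[str, list[str]] = {}
        for gene in pgdb.genes.values():
            out: list[str] = []
            for prod in gene.products:
                if prod in pgdb.rnas:
                    out.append(prod)
                elif prod in pgdb.proteins:
                    prot = pgdb.proteins[prod]
                    if prot.is_transporter:
                        out.append(prod)
                    if prot.is_enzyme and not prot.is_transporter:
                        out.append(prod)
                    out.extend(self.enzyme_reactions.get(prod, []))
            self.gene_expansion[gene.frame_id] = sorted(set(out))

    # -- string predicates ----------------------------------------------------

    @staticmethod
    def matches_exact(ent: Entity, q: str) -> bool:
        return ent.frame_id == q or ent.name.lower() == q.lower()

    @staticmethod
    def matches_substring(ent: Entity, q: str) -> bool:
        ql = q.lower()
        return (
            ql in ent.name.lower()
            or ql in ent.frame_id.lower()
            or any(ql in s.lower() for s in ent.synonyms)
        )

    def find(self, kind: Kind, q: str, mode: str) -> list[Entity]:
        if not q:
            raise EmptyQueryError("query string is empty")
        pred = self.matches_exact if mode == "exact" else self.matches_substring
        return [e for e in self.entries[kind] if pred(e, q)]

    def autocomplete(self, kind: Kind, prefix: str, limit: int = 20) -> list[str]:
        """Top-`limit` names starting with the prefix, in name order."""
        pl = prefix.lower()
        names = sorted(
            {
                e.name
                for e in self.entries[kind]
                if e.name.lower().startswith(pl)
                or any(s.lower().startswith(pl) for s in e.synonyms)
            }
        )
        return names[:limit]


class Searcher:
    """Executes highlight commands against one organism's index + layout.

    ``master`` may be omitted when only found-sets matter (no overlay
    geometry), e.g. for bulk oracle comparisons.
    """

    def __init__(self, pgdb: PGDB, master: Optional[MasterLayout] = None):
        self.pgdb = pgdb
        self.master = master
        self.index = SearchIndex(pgdb)

    # -- geometry helpers -----------------------------------------------------

    def _anchor(self, frame_id: str) -> tuple[int, int]:
        if self.master is None:
            return (0, 0)
        glyphs = self.master.glyphs_of(frame_id)
        if glyphs:
            return (glyphs[0].x, glyphs[0].y)
        lines = self.master.lines_of(frame_id)
        if lines:
            pts = lines[0].points
            mid = pts[len(pts) // 2 - 1] if len(pts) > 1 else pts[0]
            x0, y0 = pts[0]
            x1, y1 = pts[-1]
            return ((x0 + x1) // 2, (y0 + y1) // 2)
        for pb in self.master.pathway_boxes:
            if pb.frame_id == frame_id:
                return (pb.rect.cx, pb.rect.cy)
        return (0, 0)

    def _element_primitives(self, frame_id: str, color: tuple[int, int, int]) -> list[OverlayPrimitive]:
        prims: list[OverlayPrimitive] = []
        if self.master is None:
            return prims
        for g in self.master.glyphs_of(frame_id):
            if g.shape == "circle":
                prims.append(
                    OverlayPrimitive(shape="circle", color=color, points=[(g.x, g.y)], size=g.w // 2 + 3)
                )
            else:
                b = g.bbox
                prims.append(
                    OverlayPrimitive(
                        shape="rect", color=color, points=[(b.x0 - 2, b.y0 - 2), (b.x1 + 2, b.y1 + 2)]
                    )
                )
        for line in self.master.lines_of(frame_id):
            prims.append(OverlayPrimitive(shape="polyline", color=color, points=line.points, size=3))
        return prims

    def _make_overlay(
        self,
        name: str,
        color: tuple[int, int, int],
        found_ids: Iterable[str],
        highlight_ids: Iterable[str],
        unresolved: Optional[list[str]] = None,
    ) -> Overlay:
        ov = Overlay(name=name, color=color, unresolved=unresolved or [])
        for fid in sorted(set(found_ids)):
            ent = self.pgdb.get(fid)
            ov.found.append(
                FoundObject(frame_id=fid, name=ent.name if ent else fid, anchor=self._anchor(fid))
            )
        for fid in sorted(set(highlight_ids)):
            ov.primitives.extend(self._element_primitives(fid, color))
        return ov

    # -- command families -------------------------------------------------------

    def search_pathways(self, q: str, mode: str = "substring") -> Overlay:
        """Highlight Pathway(s): highlighting covers the pathways' reactions."""
        pwys = self.index.find(Kind.pathway, q, mode)
        rxn_ids = [rid for p in pwys for rid in p.reactions]
        return self._make_overlay(q, DEFAULT_COLORS["pathways"], [p.frame_id for p in pwys], rxn_ids)

    def search_reactions(self, q: str, mode: str = "substring") -> Overlay:
        """Highlight Reaction(s): exact | substring | ec | enzyme_name."""
        if mode == "ec":
            if not _EC_RE.match(q):
                raise ECFormatError(f"malformed EC number {q!r}")
            prefix_parts = q.rstrip(".-").split(".")
            rxns = [
                r
                for r in self.index.entries[Kind.reaction]
                if any(_ec_prefix_match(prefix_parts, ec) for ec in r.ec_numbers)
            ]
        elif mode == "enzyme_name":
            enzymes = self.index.find(Kind.protein, q, "substring")
            rxn_ids = {
                rid for e in enzymes for rid in self.index.enzyme_reactions.get(e.frame_id, [])
            }
            rxns = [r for r in self.index.entries[Kind.reaction] if r.frame_id in rxn_ids]
        else:
            rxns = self.index.find(Kind.reaction, q, mode)
        ids = [r.frame_id for r in rxns]
        return self._make_overlay(q, DEFAULT_COLORS["reactions"], ids, ids)

    def search_genes(self, q: Union[str, Path], mode: str = "substring") -> Overlay:
        """Highlight Gene(s): exact | substring | file.

        Matches expand to the genes' drawn products: reactions, RNAs,
        transporters and enzymes.  File mode reads one identifier per
        line and reports unresolvable ones without failing.
        """
        unresolved: list[str] = []
        if mode == "file":
            genes = []
            for raw in Path(q).read_text().splitlines():
                ident = raw.strip()
                if not ident or ident.startswith("#"):
                    continue
                hits = [
                    g
                    for g in self.index.entries[Kind.gene]
                    if g.frame_id == ident or g.name.lower() == ident.lower()
                ]
                if hits:
                    genes.extend(hits)
                else:
                    unresolved.append(ident)
        else:
            genes = self.index.find(Kind.gene, q, mode)
        expansion = [
            fid for g in genes for fid in self.index.gene_expansion.get(g.frame_id, [])
        ]
        name = q if isinstance(q, str) else Path(q).name
        return self._make_overlay(
            name, DEFAULT_COLORS["genes"], expansion, expansion, unresolved=sorted(set(unresolved))
        )

    def search_enzymes(self, q: str, mode: str = "substring") -> Overlay:
        """Highlight Enzyme(s): both the proteins and their reactions."""
        enzymes = [
            e for e in self.index.find(Kind.protein, q, mode) if e.is_enzyme or e.is_transporter
        ]
        ids = [e.frame_id for e in enzymes]
        rxn_ids = [rid for e in ids for rid in self.index.enzyme_reactions.get(e, [])]
        return self._make_overlay(q, DEFAULT_COLORS["enzymes"], ids + rxn_ids, ids + rxn_ids)

    def search_compounds(self, q: str, mode: str = "substring") -> Overlay:
        """Highlight Compound(s): every duplicate glyph occurrence."""
        cpds = self.index.find(Kind.compound, q, mode)
        ids = [c.frame_id for c in cpds]
        return self._make_overlay(q, DEFAULT_COLORS["compounds"], ids, ids)


def _ec_prefix_match(prefix_parts: list[str], ec: str) -> bool:
    parts = ec.split(".")
    if len(prefix_parts) > len(parts):
        return False
    return all(a == b for a, b in zip(prefix_parts, parts))


def list_overlay(ov: Overlay) -> list[FoundObject]:
    """The 'List' dialog: found objects ordered by display name then
    frame_id, each carrying its red-marker anchor."""
    return sorted(ov.found, key=lambda f: (f.name.lower(), f.frame_id))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def overlay_to_dict(ov: Overlay) -> dict:
    return ov.model_dump(mode="json")


def export_overlay_svg(ov: Overlay, level: Union[int, ZoomLevel], master: MasterLayout, n_levels: int = 6) -> str:
    """Project an overlay onto a zoom level as a standalone SVG document."""
    zl = level if isinstance(level, ZoomLevel) else ZoomLevel.of(level, n_levels)
    s = zl.scale
    w = -(-master.canvas_w // s)
    h = -(-master.canvas_h // s)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" viewBox="0 0 {w} {h}">'
    ]
    for prim in ov.primitives:
        rgb = "rgb(%d,%d,%d)" % tuple(prim.color)
        pts = [(round_half_up(x / s), round_half_up(y / s)) for x, y in prim.points]
        if prim.shape == "circle":
            (cx, cy) = pts[0]
            r = max(1, round_half_up(prim.size / s))
            parts.append(f'<circle cx="{cx}" cy="{cy}" r="{r}" fill="none" stroke="{rgb}" stroke-width="2"/>')
        elif prim.shape == "rect":
            (x0, y0), (x1, y1) = pts
            parts.append(
                f'<rect x="{x0}" y="{y0}" width="{x1 - x0}" height="{y1 - y0}" fill="none" stroke="{rgb}" stroke-width="2"/>'
            )
        else:
            d = " ".join(f"{x},{y}" for x, y in pts)
            parts.append(f'<polyline points="{d}" fill="none" stroke="{rgb}" stroke-width="3"/>')
    parts.append("</svg>")
    return "\n".join(parts)
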