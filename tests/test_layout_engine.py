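"""Master layout: regions, packing conventions, duplication, determinism."""

import itertools

import pytest

from cellmap.fixtures import FixtureSpec, make_organism
from cellmap.layout_engine import (
    CanvasOverflowError,
    LayoutConfig,
    assign_regions,
    layout_master,
    primary_pathway,
)
from cellmap.network_model import (
    PGDB,
    Compartment,
    Compound,
    Participant,
    Pathway,
    PathwayCategory,
    Reaction,
)


def _one_reaction_pgdb(compartment=Compartment.cytosol, category=None):
    pgdb = PGDB(organism_id="T")
    pgdb.compounds["C1"] = Compound(frame_id="C1", name="a")
    pgdb.compounds["C2"] = Compound(frame_id="C2", name="b")
    rxn = Reaction(
        frame_id="R1",
        name="a=>b",
        substrates=[Participant(compound="C1")],
        products=[Participant(compound="C2")],
        compartment=compartment,
    )
    pgdb.reactions["R1"] = rxn
    if category is not None:
        pgdb.pathways["P1"] = Pathway(
            frame_id="P1", name="p", reactions=["R1"], category=category
        )
        rxn.pathways = ["P1"]
    return pgdb


@pytest.mark.parametrize(
    "category, compartment, expected",
    [
        (cat, comp, "periplasm" if comp == Compartment.periplasm else None)
        for cat, comp in itertools.product(
            list(PathwayCategory), [Compartment.cytosol, Compartment.periplasm]
        )
    ],
)
def test_compartment_takes_precedence_over_category(category, compartment, expected):
    pgdb = _one_reaction_pgdb(compartment=compartment, category=category)
    regions = assign_regions(pgdb)
    if expected is not None:
        assert regions["R1"] == expected
    elif category == PathwayCategory.signal:
        assert regions["R1"] == "signal_strip"
    else:
        assert regions["R1"] == "cytoplasm"


def test_pathwayless_cytosolic_reactions_go_to_grid():
    pgdb = _one_reaction_pgdb()
    assert assign_regions(pgdb)["R1"] == "unassigned_grid"


def test_one_pathway_per_category_gives_ordered_columns(demo_pgdb, demo_master):
    """Central cluster boxes sit strictly between anabolic (left) and
    catabolic (right) groups."""
    def xs(cat):
        return [
            cb.rect for cb in demo_master.cluster_boxes if cb.category == cat
        ]

    left = xs(PathwayCategory.anabolic_intermediary)
    mid = xs(PathwayCategory.central)
    right = xs(PathwayCategory.catabolic)
    assert left and mid and right
    assert max(r.x1 for r in left) < min(r.x0 for r in mid)
    assert max(r.x1 for r in mid) < min(r.x0 for r in right)


def test_empty_pgdb_layout_has_regions_and_no_glyphs():
    master = layout_master(PGDB(organism_id="EMPTY"))
    assert set(master.regions) == {
        "extracellular", "outer_membrane", "periplasm", "inner_membrane",
        "cytoplasm", "unassigned_grid", "signal_strip",
    }
    assert master.glyphs == [] and master.lines == []


def test_unassigned_grid_ceiling_rows_row_major():
    pgdb = PGDB(organism_id="G")
    for i in range(10):
        c1, c2 = f"C{i}a", f"C{i}b"
        pgdb.compounds[c1] = Compound(frame_id=c1, name=f"s{i}")
        pgdb.compounds[c2] = Compound(frame_id=c2, name=f"p{i}")
        pgdb.reactions[f"R{i:02d}"] = Reaction(
            frame_id=f"R{i:02d}",
            name=f"r{i}",
            substrates=[Participant(compound=c1)],
            products=[Participant(compound=c2)],
        )
    master = layout_master(pgdb, LayoutConfig(grid_columns=4))
    lines = sorted(master.lines, key=lambda l: l.frame_id)
    assert len(lines) == 10
    xs = [l.points[0][0] for l in lines]
    ys = [l.points[0][1] for l in lines]
    assert len(set(ys)) == 3  # ceil(10/4) rows
    # row-major: first four share the first row, in increasing x
    assert ys[0] == ys[1] == ys[2] == ys[3] < ys[4]
    assert xs[0] < xs[1] < xs[2] < xs[3]


def test_pathway_reaction_lines_inside_cluster_boxes(demo_pgdb, demo_master):
    box_of = {}
    for cb in demo_master.cluster_boxes:
        for pid in cb.pathway_ids:
            box_of[pid] = cb.rect
    checked = 0
    for line in demo_master.lines:
        if line.pathway is None:
            continue
        rect = box_of[line.pathway]
        for x, y in line.points:
            assert rect.contains_point(x, y)
        checked += 1
    assert checked > 0


def test_glyph_bounding_boxes_never_overlap(demo_master):
    boxes = [g.bbox for g in demo_master.glyphs]
    for a, b in itertools.combinations(boxes, 2):
        assert not a.intersects(b)


def test_only_membrane_proteins_cross_membrane_bands(demo_pgdb, demo_master):
    bands = [demo_master.regions[n] for n in ("inner_membrane", "outer_membrane")]
    transporters = {
        p.frame_id for p in demo_pgdb.proteins.values() if p.is_transporter
    }
    crossers = set()
    for g in demo_master.glyphs:
        if any(band.intersects(g.bbox) for band in bands):
            crossers.add(g.frame_id)
    assert crossers and crossers <= transporters


def test_transporters_intersect_their_membrane_band(demo_pgdb, demo_master):
    bands = [demo_master.regions[n] for n in ("inner_membrane", "outer_membrane")]
    for prot in demo_pgdb.proteins.values():
        if not prot.is_transporter:
            continue
        glyphs = demo_master.glyphs_of(prot.frame_id)
        assert glyphs, prot.frame_id
        assert any(band.intersects(g.bbox) for g in glyphs for band in bands)


def test_pathways_flow_downward(demo_pgdb, demo_master):
    """Mean substrate y <= mean product y for >= 90% of drawn steps."""
    role_pos = {}
    for g in demo_master.glyphs:
        for role in g.roles:
            role_pos.setdefault(role, []).append(g.y)
    ok = total = 0
    for pwy in demo_pgdb.pathways.values():
        for rid in pwy.reactions:
            subs = role_pos.get(f"{rid}:substrate")
            prods = role_pos.get(f"{rid}:product")
            if not subs or not prods:
                continue
            total += 1
            if sum(subs) / len(subs) <= sum(prods) / len(prods):
                ok += 1
    assert total > 0
    assert ok / total >= 0.9


def test_every_reaction_drawn_exactly_once(demo_pgdb, demo_master):
    drawn = [l.frame_id for l in demo_master.lines]
    assert sorted(drawn) == sorted(demo_pgdb.reactions)


def test_layout_is_deterministic_byte_identical(demo_pgdb):
    a = layout_master(demo_pgdb).to_json()
    b = layout_master(demo_pgdb).to_json()
    assert a == b


def test_serialization_round_trip(tmp_path, demo_master):
    p = tmp_path / "layout.json"
    demo_master.save(p)
    from cellmap.layout_engine import MasterLayout

    assert MasterLayout.load(p).to_json() == demo_master.to_json()


def test_metabolite_duplication_matches_occurrence_census(demo_pgdb, demo_master):
    """Per-compound glyph count equals the brute-force count of
    (reaction, side) occurrences collapsed along within-pathway chains."""
    # independent census over drawn cytosolic pathway reactions
    expected: dict[str, int] = {}
    for pwy in demo_pgdb.pathways.values():
        chain = [
            demo_pgdb.reactions[rid]
            for rid in pwy.reactions
            if demo_pgdb.reactions[rid].compartment == Compartment.cytosol
            and primary_pathway(demo_pgdb, demo_pgdb.reactions[rid]) == pwy.frame_id
        ]
        for i, rxn in enumerate(chain):
            for part in rxn.substrates:
                # collapsed when the same compound was the previous product
                if i > 0 and any(
                    p.compound == part.compound for p in chain[i - 1].products
                ):
                    continue
                expected[part.compound] = expected.get(part.compound, 0) + 1
            for part in rxn.products:
                expected[part.compound] = expected.get(part.compound, 0) + 1
    pathway_rxns = {
        rid
        for pwy in demo_pgdb.pathways.values()
        for rid in pwy.reactions
    }
    for cpd, n_expected in expected.items():
        n_glyphs = sum(
            1
            for g in demo_master.glyphs
            if g.frame_id == cpd
            and all(r.split(":")[0] in pathway_rxns for r in g.roles)
        )
        assert n_glyphs == n_expected, cpd


def test_shared_cofactor_is_duplicated_without_connecting_edges(demo_pgdb, demo_master):
    # cofactors are reused across pathways by construction
    multi = [
        cpd
        for cpd in demo_pgdb.compounds
        if len(demo_master.glyphs_of(cpd)) >= 2
    ]
    assert multi
    # no line is owned by a compound (edges belong to reactions only)
    assert all(l.frame_id in demo_pgdb.reactions for l in demo_master.lines)


def test_canvas_overflow_reports_required_vs_configured(demo_pgdb):
    cfg = LayoutConfig(max_canvas_w=100, max_canvas_h=100)
    with pytest.raises(CanvasOverflowError) as err:
        layout_master(demo_pgdb, cfg)
    assert err.value.configured == (100, 100)
    assert err.value.required[0] > 100


def test_signal_pathway_lines_in_signal_strip(demo_pgdb, demo_master):
    strip = demo_master.regions["signal_strip"]
    signal_rxns = {
        rid
        for p in demo_pgdb.pathways.values()
        if p.category == PathwayCategory.signal
        for rid in p.reactions
    }
    assert signal_rxns
    for line in demo_master.lines:
        if line.frame_id in signal_rxns:
            for x, y in line.points:
                assert strip.contains_point(x, y)
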