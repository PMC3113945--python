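"""The five highlight families against an exhaustive linear-scan oracle."""

import pytest

from cellmap.fixtures import FixtureSpec, make_organism
from cellmap.network_model import Kind, PathwayCategory
from cellmap.search_highlight import (
    ECFormatError,
    EmptyQueryError,
    Searcher,
    export_overlay_svg,
    list_overlay,
)


@pytest.fixture(scope="module")
def searcher(demo_pgdb, demo_master):
    return Searcher(demo_pgdb, demo_master)


@pytest.fixture(scope="module")
def big_pgdb():
    """An organism-scale network (~5,000 entities) for oracle sweeps."""
    spec = FixtureSpec(
        seed=7,
        pathways_per_category={
            PathwayCategory.central: 2,
            PathwayCategory.catabolic: 100,
            PathwayCategory.anabolic_intermediary: 100,
            PathwayCategory.signal: 4,
        },
        unassigned_reactions=80,
        transporters=20,
        periplasmic_reactions=10,
        rnas=10,
    )
    return make_organism(spec)


@pytest.fixture(scope="module")
def big_searcher(big_pgdb):
    return Searcher(big_pgdb)  # found-sets only; no overlay geometry needed


# ---------------------------------------------------------------------------
# Oracle: exhaustive linear scan, written independently of the index
# ---------------------------------------------------------------------------

def _oracle_scan(pgdb, kind, q, mode):
    coll = {
        Kind.pathway: pgdb.pathways,
        Kind.reaction: pgdb.reactions,
        Kind.protein: pgdb.proteins,
        Kind.gene: pgdb.genes,
        Kind.compound: pgdb.compounds,
    }[kind]
    out = set()
    for ent in coll.values():
        if mode == "exact":
            if ent.frame_id == q or ent.name.lower() == q.lower():
                out.add(ent.frame_id)
        else:
            hay = [ent.name, ent.frame_id] + list(ent.synonyms)
            if any(q.lower() in h.lower() for h in hay):
                out.add(ent.frame_id)
    return out


def _sample_queries(pgdb, kind):
    coll = {
        Kind.pathway: pgdb.pathways,
        Kind.reaction: pgdb.reactions,
        Kind.protein: pgdb.proteins,
        Kind.gene: pgdb.genes,
        Kind.compound: pgdb.compounds,
    }[kind]
    ents = sorted(coll.values(), key=lambda e: e.frame_id)
    qs = []
    for ent in ents[:: max(1, len(ents) // 10)]:
        qs.append(ent.frame_id)          # exact frame id
        qs.append(ent.name)              # exact / substring name
        qs.append(ent.name[:4])          # short substring
        if ent.synonyms:
            qs.append(ent.synonyms[0][:5])
    qs += ["biosyn", "degradation", "arg", "ose", "zzz-no-match"]
    return qs


@pytest.mark.parametrize(
    "family, kind",
    [
        ("pathways", Kind.pathway),
        ("reactions", Kind.reaction),
        ("enzymes", Kind.protein),
        ("genes", Kind.gene),
        ("compounds", Kind.compound),
    ],
)
@pytest.mark.parametrize("mode", ["exact", "substring"])
def test_found_sets_equal_linear_scan_oracle(big_pgdb, big_searcher, family, kind, mode):
    for q in _sample_queries(big_pgdb, kind):
        expected = _oracle_scan(big_pgdb, kind, q, mode)
        if family == "pathways":
            got = {f.frame_id for f in big_searcher.search_pathways(q, mode).found}
        elif family == "reactions":
            got = {f.frame_id for f in big_searcher.search_reactions(q, mode).found}
        elif family == "compounds":
            got = {f.frame_id for f in big_searcher.search_compounds(q, mode).found}
        elif family == "enzymes":
            enzymes = {
                e for e in expected
                if big_pgdb.proteins[e].is_enzyme or big_pgdb.proteins[e].is_transporter
            }
            rxns = {
                r.frame_id
                for r in big_pgdb.reactions.values()
                if any(e in enzymes for e in r.enzymes)
            }
            expected = enzymes | rxns
            got = {f.frame_id for f in big_searcher.search_enzymes(q, mode).found}
        else:  # genes expand to their products' display elements
            expanded = set()
            for g in expected:
                for prod in big_pgdb.genes[g].products:
                    if prod in big_pgdb.rnas:
                        expanded.add(prod)
                    elif prod in big_pgdb.proteins:
                        expanded.add(prod)
                        for r in big_pgdb.reactions.values():
                            if prod in r.enzymes:
                                expanded.add(r.frame_id)
            expected = expanded
            got = {f.frame_id for f in big_searcher.search_genes(q, mode).found}
        assert got == expected, (family, mode, q)


def test_substring_results_superset_of_exact(big_pgdb, big_searcher):
    for q in _sample_queries(big_pgdb, Kind.compound)[:20]:
        exact = {f.frame_id for f in big_searcher.search_compounds(q, "exact").found}
        sub = {f.frame_id for f in big_searcher.search_compounds(q, "substring").found}
        assert exact <= sub


# ---------------------------------------------------------------------------
# Family-specific contracts (demo organism, with geometry)
# ---------------------------------------------------------------------------

def test_pathway_highlight_covers_member_reaction_polylines(demo_pgdb, demo_master, searcher):
    ov = searcher.search_pathways("biosyn")
    assert ov.found
    member_rxns = set()
    for f in ov.found:
        member_rxns.update(demo_pgdb.pathways[f.frame_id].reactions)
    polylines = [p for p in ov.primitives if p.shape == "polyline"]
    expected_lines = [
        l for l in demo_master.lines if l.frame_id in member_rxns
    ]
    assert len(polylines) == len(expected_lines)


def test_no_match_gives_empty_overlay(searcher):
    ov = searcher.search_pathways("no-such-pathway-anywhere")
    assert ov.found == [] and ov.primitives == []


def test_ec_prefix_search_matches_prefix_scan(demo_pgdb, searcher):
    ov = searcher.search_reactions("2.7.1", mode="ec")
    expected = {
        r.frame_id
        for r in demo_pgdb.reactions.values()
        if any(ec == "2.7.1" or ec.startswith("2.7.1.") for ec in r.ec_numbers)
    }
    assert {f.frame_id for f in ov.found} == expected and expected


def test_ec_mode_rejects_malformed_strings(searcher):
    with pytest.raises(ECFormatError):
        searcher.search_reactions("kinase", mode="ec")


def test_enzyme_name_mode_is_enzyme_search_restricted_to_reactions(demo_pgdb, searcher):
    q = "enzyme"
    via_rxn = {f.frame_id for f in searcher.search_reactions(q, mode="enzyme_name").found}
    via_enz = {
        f.frame_id
        for f in searcher.search_enzymes(q, mode="substring").found
        if f.frame_id in demo_pgdb.reactions
    }
    assert via_rxn == via_enz and via_rxn


def test_gene_search_finds_all_four_product_classes(demo_pgdb, searcher):
    ov = searcher.search_genes("arg")
    kinds = set()
    for f in ov.found:
        ent = demo_pgdb.get(f.frame_id)
        if ent.kind == Kind.reaction:
            kinds.add("reaction")
        elif ent.kind == Kind.rna:
            kinds.add("rna")
        elif ent.kind == Kind.protein:
            kinds.add("transporter" if ent.is_transporter else "enzyme")
    assert kinds == {"reaction", "rna", "transporter", "enzyme"}


def test_gene_file_mode_reports_unresolved_without_failing(tmp_path, demo_pgdb, searcher):
    genes = sorted(demo_pgdb.genes)[:2]
    listing = tmp_path / "genes.txt"
    listing.write_text("\n".join(genes + ["NOT-A-GENE"]) + "\n")
    ov = searcher.search_genes(listing, mode="file")
    assert ov.unresolved == ["NOT-A-GENE"]
    expected = set()
    for g in genes:
        expected.update(searcher.index.gene_expansion[g])
    assert {f.frame_id for f in ov.found} == expected


def test_enzyme_overlay_includes_protein_glyphs_and_reaction_lines(demo_pgdb, searcher):
    enz = next(
        p for p in demo_pgdb.proteins.values() if p.is_enzyme and not p.is_transporter
    )
    ov = searcher.search_enzymes(enz.frame_id, mode="exact")
    shapes = {p.shape for p in ov.primitives}
    assert "rect" in shapes or "circle" in shapes  # the protein glyph
    assert "polyline" in shapes                    # its reactions


def test_compound_overlay_marks_every_duplicate_glyph(demo_pgdb, demo_master, searcher):
    cpd = next(
        c for c in demo_pgdb.compounds if len(demo_master.glyphs_of(c)) >= 3
    )
    ov = searcher.search_compounds(cpd, mode="exact")
    assert len(ov.found) == 1
    assert len(ov.primitives) == len(demo_master.glyphs_of(cpd))


def test_exact_mode_ignores_synonyms(demo_pgdb, searcher):
    ent = next(c for c in demo_pgdb.compounds.values() if c.synonyms)
    syn = ent.synonyms[0]
    if any(
        c.name.lower() == syn.lower() or c.frame_id == syn
        for c in demo_pgdb.compounds.values()
    ):
        pytest.skip("synonym collides with a name")
    assert searcher.search_compounds(syn, mode="exact").found == []
    assert any(
        f.frame_id == ent.frame_id
        for f in searcher.search_compounds(syn, mode="substring").found
    )


def test_empty_query_raises(searcher):
    with pytest.raises(EmptyQueryError):
        searcher.search_compounds("")


def test_overlays_are_independent(searcher):
    ov1 = searcher.search_pathways("biosyn")
    before = [p.model_copy() for p in ov1.primitives]
    searcher.search_genes("arg")
    ov1.active = False  # toggling one overlay
    ov2 = searcher.search_pathways("biosyn")
    assert [p.model_dump() for p in ov1.primitives] == [p.model_dump() for p in before]
    assert [p.model_dump() for p in ov2.primitives] == [p.model_dump() for p in before]


def test_list_overlay_ordering_and_anchor_containment(demo_master, searcher):
    ov = searcher.search_compounds("ose")
    listed = list_overlay(ov)
    assert len(listed) == len(ov.found)
    keys = [(f.name.lower(), f.frame_id) for f in listed]
    assert keys == sorted(keys)
    for f in listed:
        glyphs = demo_master.glyphs_of(f.frame_id)
        assert any(g.bbox.contains_point(*f.anchor) for g in glyphs)


def test_autocomplete_prefix_name_order(big_searcher):
    names = big_searcher.index.autocomplete(Kind.pathway, "b", limit=20)
    assert names == sorted(names)
    assert len(names) <= 20
    assert all(n.lower().startswith("b") for n in names) or names


def test_overlay_svg_projection(searcher, demo_master):
    ov = searcher.search_pathways("biosyn")
    svg = export_overlay_svg(ov, 3, demo_master)
    assert svg.startswith("<svg") and "<polyline" in svg
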