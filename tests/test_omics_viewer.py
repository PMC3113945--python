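"""Omics painting: parsing, resolution, color mapping, frames, export."""

import warnings

import numpy as np
import pytest

from cellmap.fixtures import make_omics_file
from cellmap.omics_viewer import (
    ColorMap,
    OmicsFormatError,
    build_frames,
    composite_frame,
    export_frames,
    fit_colormap,
    parse_datafile,
    render_legend,
    resolve_rows,
)
from cellmap.search_highlight import Searcher


@pytest.fixture(scope="module")
def searcher(demo_pgdb, demo_master):
    return Searcher(demo_pgdb, demo_master)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_parse_basic_table(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("g1\t1.0\t2.0\t3.0\ng2\t4\t5\t6\n")
    ds = parse_datafile(f)
    assert len(ds.rows) == 2 and ds.n_columns == 3
    assert ds.experiment_names == ["exp1", "exp2", "exp3"]  # no header row
    assert ds.rows[0].values == [1.0, 2.0, 3.0]


def test_header_row_detected_and_used(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("gene\texpA\texpB\ng1\t1\t2\n")
    ds = parse_datafile(f)
    assert ds.experiment_names == ["expA", "expB"]
    assert [r.label for r in ds.rows] == ["g1"]


def test_na_cells_recorded_as_missing_not_dropped(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("g1\tNA\t2\ng2\t3\t\n")
    ds = parse_datafile(f)
    assert ds.rows[0].values == [None, 2.0]
    assert ds.rows[1].values == [3.0, None]


def test_comments_and_crlf_accepted(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_bytes(b"# comment\r\nlabel\te1\r\ng1\t5\r\n")
    ds = parse_datafile(f)
    assert ds.experiment_names == ["e1"]
    assert ds.rows[0].values == [5.0]


def test_zero_value_columns_is_format_error(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("justlabels\nmore\n")
    with pytest.raises(OmicsFormatError):
        parse_datafile(f)


def test_duplicate_labels_warn_and_keep_last(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("g1\t1\ng1\t9\n")
    with pytest.warns(UserWarning, match="duplicate label"):
        ds = parse_datafile(f)
    assert len(ds.rows) == 1 and ds.rows[0].values == [9.0]


def test_column_selection_subset(tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("lab\ta\tb\tc\ng1\t1\t2\t3\n")
    ds = parse_datafile(f, columns=[2, 0])
    assert ds.experiment_names == ["c", "a"]
    assert ds.rows[0].values == [3.0, 1.0]


# ---------------------------------------------------------------------------
# Row resolution
# ---------------------------------------------------------------------------

def test_resolution_conserves_row_count(tmp_path, demo_pgdb, searcher):
    f = tmp_path / "d.tsv"
    make_omics_file(demo_pgdb, f, n_rows=40, n_cols=2, seed=3, bad_label_rate=0.2)
    ds = parse_datafile(f)
    rr = resolve_rows(ds, searcher.index)
    assert len(rr.mapping) + len(rr.unresolved) == len(ds.rows)


def test_gene_label_maps_to_its_enzymes_reactions(demo_pgdb, searcher, tmp_path):
    gene = next(
        g for g in demo_pgdb.genes.values()
        if any(p in demo_pgdb.proteins and demo_pgdb.proteins[p].is_enzyme for p in g.products)
    )
    f = tmp_path / "d.tsv"
    f.write_text(f"{gene.frame_id}\t1.5\n")
    rr = resolve_rows(parse_datafile(f), searcher.index)
    # independent traversal: gene -> protein products -> catalyzed reactions
    expected = sorted(
        {
            r.frame_id
            for r in demo_pgdb.reactions.values()
            if any(e in gene.products for e in r.enzymes)
        }
    )
    assert rr.mapping[gene.frame_id] == expected and expected


def test_unresolvable_label_reported_not_fatal(searcher, tmp_path):
    f = tmp_path / "d.tsv"
    f.write_text("xyzzy\t1\n")
    rr = resolve_rows(parse_datafile(f), searcher.index)
    assert rr.unresolved == ["xyzzy"] and rr.mapping == {}


# ---------------------------------------------------------------------------
# Color mapping
# ---------------------------------------------------------------------------

def _ds(text, tmp_path):
    f = tmp_path / "cm.tsv"
    f.write_text(text)
    return parse_datafile(f)


def test_domain_boundaries_hit_ramp_ends(tmp_path):
    ds = _ds("a\t0\nb\t10\n", tmp_path)
    cm = fit_colormap(ds)
    assert cm.color(0) == tuple(cm.ramp[0])
    assert cm.color(10) == tuple(cm.ramp[-1])
    assert cm.color(-5) == tuple(cm.ramp[0])   # clamped
    assert cm.color(99) == tuple(cm.ramp[-1])  # clamped


def test_constant_dataset_maps_to_ramp_midpoint(tmp_path):
    ds = _ds("a\t4\nb\t4\n", tmp_path)
    cm = fit_colormap(ds)
    # midpoint of yellow->orange->red three-point ramp = the middle color
    assert cm.color(4) == tuple(cm.ramp[1])


def test_midrange_value_interpolates_linearly(tmp_path):
    ds = _ds("a\t0\nb\t10\n", tmp_path)
    cm = fit_colormap(ds)
    # independent linear interpolation: fraction 0.5 on a 3-stop ramp is
    # exactly the middle stop
    assert cm.color(5) == tuple(cm.ramp[1])
    # fraction 0.25 is halfway between stop 0 and stop 1
    expected = tuple(
        round((a + b) / 2) for a, b in zip(cm.ramp[0], cm.ramp[1])
    )
    assert cm.color(2.5) == expected


def test_color_monotone_in_value(tmp_path):
    """Larger values never map to an earlier position on the ramp."""
    ds = _ds("a\t0\nb\t100\n", tmp_path)
    cm = fit_colormap(ds)
    # reference polyline through color space, finely sampled
    ts = np.linspace(0, 1, 1001)
    n = len(cm.ramp) - 1
    ramp_pts = []
    for t in ts:
        pos = t * n
        i = min(int(pos), n - 1)
        f = pos - i
        lo, hi = cm.ramp[i], cm.ramp[i + 1]
        ramp_pts.append([a + (b - a) * f for a, b in zip(lo, hi)])
    ramp_pts = np.array(ramp_pts)
    positions = []
    for v in np.linspace(0, 100, 41):
        c = np.array(cm.color(v))
        positions.append(np.argmin(((ramp_pts - c) ** 2).sum(axis=1)))
    assert all(b >= a for a, b in zip(positions, positions[1:]))


def test_log10_transform_requires_positive_values(tmp_path):
    ds = _ds("a\t0\nb\t10\n", tmp_path)
    with pytest.raises(OmicsFormatError, match="'a'"):
        fit_colormap(ds, transform="log10")
    ds2 = _ds("a\t1\nb\t100\n", tmp_path)
    cm = fit_colormap(ds2, transform="log10")
    assert cm.color(10) == tuple(cm.ramp[1])  # geometric midpoint


def test_all_missing_dataset_rejected(tmp_path):
    ds = _ds("label\te1\na\tNA\nb\tNA\n", tmp_path)
    with pytest.raises(OmicsFormatError):
        fit_colormap(ds)


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def demo_frames(demo_pgdb, demo_master, searcher, tmp_path_factory):
    d = tmp_path_factory.mktemp("omics")
    f = d / "omics.tsv"
    bookkeeping = make_omics_file(
        demo_pgdb, f, n_rows=40, n_cols=3, seed=11, miss_rate=0.15, bad_label_rate=0.1
    )
    ds = parse_datafile(f)
    rr = resolve_rows(ds, searcher.index)
    cm = fit_colormap(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = build_frames(ds, rr, cm, demo_master)
    return bookkeeping, ds, rr, cm, fs


def test_one_frame_per_selected_column_in_order(demo_frames):
    _, ds, _, _, fs = demo_frames
    assert len(fs.frames) == ds.n_columns == 3
    assert [f.name for f in fs.frames] == ds.experiment_names


def test_injected_bad_labels_exactly_account_for_unresolved(demo_frames):
    bookkeeping, ds, rr, _, _ = demo_frames
    assert sorted(rr.unresolved) == bookkeeping["bad_labels"]
    assert len(rr.mapping) == len(ds.rows) - len(bookkeeping["bad_labels"])


def test_per_frame_colored_elements_match_independent_census(demo_frames):
    _, ds, rr, _, fs = demo_frames
    for col, frame in enumerate(fs.frames):
        # bookkeeping: union of elements of resolved rows; value presence
        # decides ramp color vs missing color, not membership
        expected_elements = set()
        for row in ds.rows:
            if row.label in rr.mapping:
                expected_elements.update(rr.mapping[row.label])
        assert {f.frame_id for f in frame.found} == expected_elements


def test_rows_missing_in_a_column_use_missing_color(demo_pgdb, demo_master, searcher, tmp_path):
    rxn = sorted(demo_pgdb.reactions)[0]
    f = tmp_path / "d.tsv"
    f.write_text(f"{rxn}\t1\tNA\n")
    ds = parse_datafile(f)
    rr = resolve_rows(ds, searcher.index)
    cm = fit_colormap(ds)
    fs = build_frames(ds, rr, cm, demo_master)
    frame0_colors = {tuple(p.color) for p in fs.frames[0].primitives}
    frame1_colors = {tuple(p.color) for p in fs.frames[1].primitives}
    assert frame0_colors == {cm.color(1.0)}
    assert frame1_colors == {tuple(cm.missing_color)}


def test_same_value_same_color_across_columns(demo_frames):
    _, ds, rr, cm, fs = demo_frames
    assert cm.color(1.7) == cm.color(1.7)
    # shared global scale: colormap domain spans all columns jointly
    all_vals = [v for r in ds.rows for v in r.values if v is not None]
    assert cm.v_min == min(all_vals) and cm.v_max == max(all_vals)


def test_recoloring_one_frame_leaves_others_untouched(demo_frames):
    _, _, _, _, fs = demo_frames
    snapshot = [p.model_dump() for p in fs.frames[1].primitives]
    for p in fs.frames[0].primitives:
        p.color = (1, 2, 3)
    assert [p.model_dump() for p in fs.frames[1].primitives] == snapshot


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def test_compositing_empty_frame_is_identity(demo_build):
    from cellmap.search_highlight import Overlay

    base = demo_build.level_image(2)
    out = composite_frame(base, Overlay(name="empty"), scale=8)
    assert np.array_equal(np.asarray(out), np.asarray(base))


def test_legend_spans_domain_with_ramp_colors(tmp_path):
    ds = _ds("a\t0\nb\t10\n", tmp_path)
    cm = fit_colormap(ds)
    legend = np.asarray(render_legend(cm, width=100, height=30))
    assert tuple(legend[0, 0]) == tuple(cm.ramp[0])
    assert tuple(legend[0, -1]) == tuple(cm.ramp[-1])


def test_frame_export_is_deterministic(demo_frames, demo_build, tmp_path):
    _, _, _, _, fs = demo_frames
    base = demo_build.level_image(2)
    a = export_frames(fs, base, 2, tmp_path / "a")
    b = export_frames(fs, base, 2, tmp_path / "b")
    for pa, pb in zip(a, b):
        assert pa.read_bytes() == pb.read_bytes()
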