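"""Chart tracks: normalization, band geometry in both views, TSV loading."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from phylodraw import (
    BAR,
    BINARY,
    ChartTrack,
    TrackError,
    layout_circular,
    layout_rectangular,
    load_tracks_tsv,
    normalize_track,
    layout_tracks,
    parse_newick,
)
from phylodraw.charts import RectCell, SectorCell


@pytest.mark.parametrize("kind, values, expected", [
    (BAR, [0.0, 5.0, 10.0], [0.0, 0.5, 1.0]),
    (BAR, [7.0, 7.0, 7.0], [1.0, 1.0, 1.0]),
    (BAR, [0.0, 0.0], [0.0, 0.0]),  # all-zero track stays zero
    (BINARY, [1.0, 0.0, 1.0], [1.0, 0.0, 1.0]),
])
def test_normalize_examples(kind, values, expected):
    track = ChartTrack(name="t", kind=kind, values=values)
    assert normalize_track(track).values == pytest.approx(expected)
    assert track.values == values  # original retained for tooltips


def test_invalid_values_rejected():
    with pytest.raises(TrackError):
        ChartTrack("t", BAR, [1.0, -2.0]).validate()
    with pytest.raises(TrackError):
        ChartTrack("t", BINARY, [0.0, 2.0]).validate()
    with pytest.raises(TrackError):
        ChartTrack("t", "pie", [1.0]).validate()


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1e6)),
        min_size=1, max_size=30,
    ),
    st.floats(min_value=1e-3, max_value=1e3),
)
def test_normalization_idempotent_and_scale_invariant(values, k):
    track = ChartTrack("t", BAR, values)
    once = normalize_track(track)
    assert normalize_track(once).values == pytest.approx(once.values)
    scaled = ChartTrack("t", BAR, [k * v for v in values])
    assert normalize_track(scaled).values == pytest.approx(once.values)


def _three_leaf_base(chart_canvas, shape):
    tree = parse_newick("(A:1,B:1,C:1);")
    if shape == "rect":
        return tree, layout_rectangular(tree, chart_canvas)
    return tree, layout_circular(tree, chart_canvas)


def test_binary_track_rect_cells(chart_canvas):
    tree, base = _three_leaf_base(chart_canvas, "rect")
    [geom] = layout_tracks([ChartTrack("t", BINARY, [1.0, 0.0, 1.0])], base)
    assert [c.filled for c in geom.cells] == [True, False, True]
    assert [c.height for c in geom.cells] == pytest.approx(
        [base.leaf_spacing] * 3)
    assert [c.width for c in geom.cells] == pytest.approx(
        [geom.track.thickness] * 3)


def test_declaration_order_banding_both_views(chart_canvas):
    tracks = [
        ChartTrack("presence", BINARY, [1.0, 0.0, 1.0], {"thickness": "20"}),
        ChartTrack("clones", BAR, [1.0, 2.0, 3.0], {"thickness": "20"}),
    ]
    for shape in ("rect", "circular"):
        tree, base = _three_leaf_base(chart_canvas, shape)
        binary_geom, bar_geom = layout_tracks(tracks, base)
        assert binary_geom.band_end <= bar_geom.band_start
        if shape == "rect":
            assert all(isinstance(c, RectCell) for c in binary_geom.cells)
            assert max(c.x for c in binary_geom.cells) < min(c.x for c in bar_geom.cells)
        else:
            assert all(isinstance(c, SectorCell) for c in binary_geom.cells)
            assert (max(c.r_in for c in binary_geom.cells)
                    < min(c.r_in for c in bar_geom.cells))


def test_circular_bar_radial_extents_hand_oracle(chart_canvas):
    tree = parse_newick("(A:1,B:1,C:1,D:1);")
    base = layout_circular(tree, chart_canvas)
    track = ChartTrack("t", BAR, [0.0, 5.0, 10.0, 10.0], {"thickness": "40"})
    [geom] = layout_tracks([track], base)
    extents = [c.r_out - c.r_in for c in geom.cells]
    assert extents == pytest.approx([0.0, 20.0, 40.0, 40.0])


def test_circular_cell_spans_cover_usable_arc_exactly(chart_canvas):
    tree, base = _three_leaf_base(chart_canvas, "circular")
    [geom] = layout_tracks([ChartTrack("t", BINARY, [1.0, 1.0, 0.0])], base)
    spans = [c.theta_end - c.theta_start for c in geom.cells]
    assert sum(spans) == pytest.approx(base.params.usable_arc, abs=1e-6)
    # contiguous, no drift
    for a, b in zip(geom.cells, geom.cells[1:]):
        assert a.theta_end == pytest.approx(b.theta_start, abs=1e-9)


def test_budget_overflow_is_a_validation_error(chart_canvas):
    tree, base = _three_leaf_base(chart_canvas, "rect")
    fat = [ChartTrack(f"t{i}", BINARY, [1.0, 0.0, 1.0], {"thickness": "40"})
           for i in range(3)]  # 3*40 > 60 px gutter
    with pytest.raises(TrackError, match="reserved"):
        layout_tracks(fat, base)


def test_track_length_mismatch_names_the_track(chart_canvas):
    tree, base = _three_leaf_base(chart_canvas, "rect")
    with pytest.raises(TrackError, match="short"):
        layout_tracks([ChartTrack("short", BINARY, [1.0])], base)


def test_load_tracks_tsv_joins_by_label_in_leaf_order():
    tree = parse_newick("(A:1,(B:1,C:1):1);")
    tsv = "#kind\tclones\tbar\nC\tclones\t4\nA\tclones\t1\nB\tclones\t2\n"
    [track] = load_tracks_tsv(tsv, tree)
    assert track.kind == BAR
    assert track.values == [1.0, 2.0, 4.0]  # tree order, not file order


def test_load_tracks_tsv_kind_inference_and_missing_value(caplog):
    tree = parse_newick("(A:1,B:1,C:1);")
    [track] = load_tracks_tsv("A\tp\t1\nB\tp\t0\n", tree)
    assert track.kind == BINARY
    assert track.values == [1.0, 0.0, 0.0]  # missing leaf C defaults to 0


def test_load_tracks_tsv_unmatched_label_errors():
    tree = parse_newick("(A:1,B:1);")
    with pytest.raises(TrackError, match="Zebra"):
        load_tracks_tsv("Zebra\tt\t1\n", tree)


def test_many_random_tracks_normalize_cleanly():
    rng = random.Random(42)
    for _ in range(300):
        n = rng.randrange(1, 40)
        values = [rng.uniform(0, 100) for _ in range(n)]
        norm = normalize_track(ChartTrack("t", BAR, values)).values
        assert all(0.0 <= v <= 1.0 for v in norm)
        if any(values):
            assert max(norm) == pytest.approx(1.0)
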