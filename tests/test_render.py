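"""SVG output: determinism, well-formedness, counts, anchors/tooltips,
style merging."""

import re
import xml.etree.ElementTree as ET

import pytest

from phylodraw import (
    BINARY,
    Canvas,
    ChartTrack,
    StyleSpec,
    layout_circular,
    layout_rectangular,
    layout_tracks,
    merge_styles,
    parse_newick,
    parse_phyloxml,
    render,
)
from phylodraw.render import SVG_NS, fmt

NS = {"svg": SVG_NS}


def render_simple(shape="rect", style=None, tracks=(), newick="((A:1,B:2)80:1,C:3);",
                  canvas=None):
    tree = parse_newick(newick)
    canvas = canvas or Canvas(width=600, height=400, margin=10, label_gutter=100,
                              chart_gutter=60)
    base = (layout_rectangular(tree, canvas) if shape == "rect"
            else layout_circular(tree, canvas))
    geometry = layout_tracks(list(tracks), base)
    return tree, render(base, geometry, tree, style)


@pytest.mark.parametrize("shape", ["rect", "circular"])
def test_output_is_wellformed_svg(shape):
    _, svg = render_simple(shape)
    root = ET.fromstring(svg)
    assert root.tag == f"{{{SVG_NS}}}svg"


@pytest.mark.parametrize("shape", ["rect", "circular"])
def test_render_is_byte_deterministic(shape):
    track = ChartTrack("t", BINARY, [1.0, 0.0, 1.0])
    _, a = render_simple(shape, tracks=[track])
    _, b = render_simple(shape, tracks=[track])
    assert a == b


@pytest.mark.parametrize("shape", ["rect", "circular"])
def test_label_and_cell_counts(shape):
    track = ChartTrack("t", BINARY, [1.0, 0.0, 1.0])
    _, svg = render_simple(shape, tracks=[track])
    root = ET.fromstring(svg)
    labels = root.find("svg:g[@id='leaf-labels']", NS)
    assert len(labels.findall(".//svg:text", NS)) == 3
    cells = [el for el in root.iter()
             if el.get("id", "").startswith("track-0-cell-")]
    assert len(cells) == 3


def test_branch_primitive_counts():
    tree, svg = render_simple("rect")
    root = ET.fromstring(svg)
    branches = root.find("svg:g[@id='branches']", NS)
    paths = branches.findall("svg:path", NS)
    n_plain = sum(1 for p in paths if "-connector" not in p.get("id"))
    n_conn = len(paths) - n_plain
    assert n_plain == tree.n_nodes - 1
    assert n_conn == sum(1 for n in tree.root.preorder() if n.children)


def test_url_becomes_anchor_and_description_becomes_title():
    xml = """<phyloxml><phylogeny rooted="true"><clade>
        <clade><name>A</name><branch_length>1</branch_length>
          <url>https://example.org/A</url><desc>hover text</desc></clade>
        <clade><name>B</name><branch_length>2</branch_length></clade>
      </clade></phylogeny></phyloxml>"""
    doc = parse_phyloxml(xml)
    base = layout_rectangular(doc.tree)
    svg = render(base, [], doc.tree)
    root = ET.fromstring(svg)
    anchors = root.findall(".//svg:a", NS)
    assert len(anchors) == 1
    assert anchors[0].get("href") == "https://example.org/A"
    assert anchors[0].find(".//svg:text", NS) is not None
    titles = root.findall(".//svg:title", NS)
    assert any(t.text == "hover text" for t in titles)


def test_confidence_shown_and_suppressible():
    _, svg = render_simple("rect")
    assert ">80<" in svg
    _, hidden = render_simple("rect", style=StyleSpec(show_confidence=False))
    assert ">80<" not in hidden
    _, floored = render_simple(
        "rect", style=StyleSpec(confidence_font_size=3.0))
    assert ">80<" not in floored  # below the font-size floor


def test_scale_bar_rendered_with_round_length():
    _, svg = render_simple("rect")
    root = ET.fromstring(svg)
    bar = root.find("svg:g[@id='scale-bar']", NS)
    assert bar is not None
    # max depth 3 -> target 0.3; 0.2 is the nearest 1/2/5 value on a log scale
    assert bar.find("svg:text", NS).text == "0.2"


def test_element_order_fixed():
    track = ChartTrack("t", BINARY, [1.0, 0.0, 1.0])
    _, svg = render_simple("rect", tracks=[track])
    ids = re.findall(r'id="(background|branches|confidence-labels|scale-bar'
                     r'|leaf-labels|track-0)"', svg)
    assert ids == ["background", "branches", "confidence-labels", "scale-bar",
                   "leaf-labels", "track-0"]


def test_number_formatting_three_decimals_no_negative_zero():
    assert fmt(1.23456) == "1.235"
    assert fmt(-0.0001) == "0.000"
    assert fmt(2.0) == "2.000"


def test_coordinates_inside_viewport():
    for shape in ("rect", "circular"):
        _, svg = render_simple(shape, canvas=Canvas(width=500, height=500,
                                                    margin=10, label_gutter=100,
                                                    chart_gutter=0))
        root = ET.fromstring(svg)
        for el in root.iter():
            for attr in ("x", "y", "width", "height"):
                v = el.get(attr)
                if v is not None:
                    assert -0.001 <= float(v) <= 500.001


def test_merge_styles_precedence_and_provenance():
    merged, prov = merge_styles(StyleSpec(), {"font_size": "10"}, {"font_size": 12})
    assert merged.font_size == 12.0 and prov["font_size"] == "cli"

    merged, prov = merge_styles(StyleSpec(), {}, {})
    assert merged == StyleSpec()
    assert set(prov.values()) == {"default"}

    merged, prov = merge_styles(StyleSpec(), {"branch_color": "#123456"}, {})
    assert merged.branch_color == "#123456" and prov["branch_color"] == "xml"
    assert merged.font_size == StyleSpec().font_size


def test_merge_styles_unknown_key_warned_and_ignored(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        merged, _ = merge_styles(StyleSpec(), {"glitter": "yes"}, {})
    assert merged == StyleSpec()
    assert any("glitter" in rec.message for rec in caplog.records)


def test_per_label_override_changes_one_text_color():
    style = StyleSpec(overrides={"A": {"label_color": "#cc0000"}})
    _, svg = render_simple("rect", style=style)
    root = ET.fromstring(svg)
    labels = root.find("svg:g[@id='leaf-labels']", NS)
    colors = {t.text: t.get("fill") for t in labels.findall("svg:text", NS)}
    assert colors["A"] == "#cc0000"
    assert colors["B"] == StyleSpec().label_color
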