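"""phyloXML input: trees, embedded styles and chart-track payloads.

The standard elements read per clade are ``name``, ``branch_length`` (as an
attribute or a child element — both accepted), ``confidence`` (first one
wins; its ``type`` attribute is kept as a style hint), ``url``/``uri`` and
``desc``/``description``.  Namespaced and un-namespaced documents are both
accepted; matching is on local element names.  Unknown elements are ignored
with a logged warning, never an error.

Beyond standard phyloXML, this package defines a small chart/style dialect
(documented in docs/phyloxml_dialect.md):

* a document-level ``<render>`` block (child of ``<phylogeny>``) holding a
  ``<style>`` element (children are style fields, e.g.
  ``<font_size>12</font_size>``) and a ``<charts>`` element declaring tracks
  (``<track name="abundance" kind="bar" thickness="30" fill="#446"/>``);
* per-leaf ``<chart name="abundance">7.5</chart>`` children carrying that
  leaf's value for the named track.

Charts are leaf-only; a ``<chart>`` on an internal clade is an error.  Track
order is first-appearance order in document order; a leaf with no value for
a declared track gets 0 with a warning.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .charts import BAR, BINARY, ChartTrack, TrackError
from .tree import Tree, TreeNode, leaves_in_order

logger = logging.getLogger(__name__)

_KNOWN_CLADE_CHILDREN = {
    "clade", "name", "branch_length", "confidence", "url", "uri",
    "desc", "description", "chart", "style",
}


class PhyloXmlParseError(ValueError):
    """Malformed phyloXML (XML error, missing phylogeny, misplaced chart)."""


@dataclass
class PhyloXmlDocument:
    """Everything extracted from one phyloXML file."""

    tree: Tree
    embedded_style: Dict[str, object] = field(default_factory=dict)
    tracks: List[ChartTrack] = field(default_factory=list)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _first_child(el: ET.Element, name: str) -> Optional[ET.Element]:
    for child in el:
        if _local(child.tag) == name:
            return child
    return None


def detect_format(text: str) -> str:
    """'phyloxml' iff the input (after BOM/whitespace) starts with '<'."""
    stripped = text.lstrip("\ufeff \t\r\n")
    if not stripped:
        raise ValueError("empty input")
    return "phyloxml" if stripped.startswith("<") else "newick"


def _parse_clade(
    el: ET.Element,
    chart_data: List[Tuple[TreeNode, str, Optional[str], float]],
) -> TreeNode:
    node = TreeNode()
    if "branch_length" in el.attrib:
        node.branch_length = float(el.attrib["branch_length"])
    charts_here: List[Tuple[str, Optional[str], float]] = []
    for child in el:
        name = _local(child.tag)
        if name == "clade":
            node.children.append(_parse_clade(child, chart_data))
        elif name == "name":
            node.label = (child.text or "").strip() or None
        elif name == "branch_length":
            if node.branch_length is None:  # attribute wins when both given
                node.branch_length = float((child.text or "").strip())
        elif name == "confidence":
            if node.confidence is None:  # only the first confidence is used
                node.confidence = float((child.text or "").strip())
                ctype = child.attrib.get("type")
                if ctype:
                    node.style_hints["confidence_type"] = ctype
        elif name in ("url", "uri"):
            if node.url is None:
                node.url = (child.text or "").strip() or None
        elif name in ("desc", "description"):
            if node.description is None:
                node.description = (child.text or "").strip() or None
        elif name == "chart":
            track = child.attrib.get("name")
            if not track:
                raise PhyloXmlParseError("<chart> element without a name attribute")
            try:
                value = float((child.text or "").strip())
            except ValueError:
                raise PhyloXmlParseError(
                    f"<chart name={track!r}>: non-numeric value {child.text!r}"
                ) from None
            charts_here.append((track, child.attrib.get("kind"), value))
        elif name == "style":
            node.style_hints.update(child.attrib)
        else:
            logger.warning("ignoring unknown phyloXML element <%s>", name)
    if charts_here and node.children:
        raise PhyloXmlParseError(
            f"<chart> on internal clade {node.label or '(unnamed)'}: "
            "charts are leaf-only"
        )
    for track, kind, value in charts_here:
        chart_data.append((node, track, kind, value))
    return node


def _parse_style_block(el: ET.Element) -> Dict[str, object]:
    style: Dict[str, object] = {}
    for child in el:
        key = _local(child.tag)
        style[key] = (child.text or "").strip()
    style.update(el.attrib)
    return style


def parse_phyloxml(text: str) -> PhyloXmlDocument:
    """Parse one phyloXML document (first ``<phylogeny>`` element)."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise PhyloXmlParseError(f"malformed XML: {exc}") from None

    phylogeny = None
    if _local(root.tag) == "phylogeny":
        phylogeny = root
    else:
        for el in root.iter():
            if _local(el.tag) == "phylogeny":
                phylogeny = el
                break
    if phylogeny is None:
        raise PhyloXmlParseError("no <phylogeny> element found")

    is_rooted = phylogeny.attrib.get("rooted", "true").lower() != "false"

    embedded_style: Dict[str, object] = {}
    track_decls: Dict[str, Dict[str, str]] = {}
    decl_order: List[str] = []
    clade_el = None
    for child in phylogeny:
        name = _local(child.tag)
        if name == "clade" and clade_el is None:
            clade_el = child
        elif name == "render":
            style_el = _first_child(child, "style")
            if style_el is not None:
                embedded_style.update(_parse_style_block(style_el))
            charts_el = _first_child(child, "charts")
            if charts_el is not None:
                for tr in charts_el:
                    if _local(tr.tag) != "track":
                        logger.warning(
                            "ignoring unknown charts child <%s>", _local(tr.tag)
                        )
                        continue
                    tname = tr.attrib.get("name")
                    if not tname:
                        raise PhyloXmlParseError("<track> without a name attribute")
                    track_decls[tname] = dict(tr.attrib)
                    if tname not in decl_order:
                        decl_order.append(tname)
        elif name in ("name", "description", "id", "date"):
            pass  # phylogeny-level metadata, not needed for drawing
        else:
            logger.warning("ignoring unknown phylogeny child <%s>", name)
    if clade_el is None:
        raise PhyloXmlParseError("<phylogeny> has no root <clade>")

    chart_data: List[Tuple[TreeNode, str, Optional[str], float]] = []
    root_node = _parse_clade(clade_el, chart_data)
    tree = Tree.from_root(root_node, is_rooted=is_rooted)

    tracks = _assemble_tracks(tree, chart_data, track_decls, decl_order)
    return PhyloXmlDocument(tree=tree, embedded_style=embedded_style, tracks=tracks)


def _assemble_tracks(
    tree: Tree,
    chart_data: List[Tuple[TreeNode, str, Optional[str], float]],
    track_decls: Dict[str, Dict[str, str]],
    decl_order: List[str],
) -> List[ChartTrack]:
    leaves = leaves_in_order(tree)
    rank = {id(leaf): i for i, leaf in enumerate(leaves)}

    order: List[str] = list(decl_order)
    per_track: Dict[str, Dict[int, float]] = {name: {} for name in order}
    kinds: Dict[str, Optional[str]] = {
        name: track_decls.get(name, {}).get("kind") for name in order
    }
    for node, name, kind, value in chart_data:
        if name not in per_track:
            per_track[name] = {}
            kinds[name] = kind
            order.append(name)
        elif kinds[name] is None and kind is not None:
            kinds[name] = kind
        per_track[name][rank[id(node)]] = value

    tracks: List[ChartTrack] = []
    for name in order:
        values: List[float] = []
        for i, leaf in enumerate(leaves):
            if i in per_track[name]:
                values.append(per_track[name][i])
            else:
                logger.warning(
                    "track %r: no value for leaf %r, using 0", name, leaf.label
                )
                values.append(0.0)
        kind = kinds[name]
        if kind is None:
            kind = BINARY if all(v in (0.0, 1.0) for v in values) else BAR
        if kind not in (BINARY, BAR):
            raise TrackError(f"track {name!r}: unknown kind {kind!r}")
        style = {
            k: v
            for k, v in track_decls.get(name, {}).items()
            if k not in ("name", "kind")
        }
        track = ChartTrack(name=name, kind=kind, values=values, style=style)
        track.validate(len(leaves))
        tracks.append(track)
    return tracks
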