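"""Seeded synthetic trees and annotation tracks for testing and examples.

Trees are grown by a Yule-style splitting process: start from one leaf and
repeatedly replace a uniformly chosen current leaf with an internal node
carrying two fresh leaves.  This gives realistically imbalanced topologies
with exactly ``n - 1`` internal nodes for ``n`` leaves.  Branch lengths are
exponential (default mean 0.1 substitutions/site) or absent (cladogram
mode); internal nodes optionally carry bootstrap-like confidences uniform on
50..100.  Everything is deterministic for a given (params, seed).
"""

from __future__ import annotations

import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .charts import BAR, BINARY, ChartTrack
from .tree import Tree, TreeNode, leaves_in_order


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the fixture generator.

    branch_length_distribution: "exponential" (mean ``mean_branch_length``)
    or "unit" (no lengths emitted; parsers apply the cladogram fallback).
    track_specs: chart tracks to synthesize — bar values are lognormal(0, 1)
    (e.g. clone counts), binary values Bernoulli(0.5).
    """

    n_leaves: int = 10
    seed: int = 0
    branch_length_distribution: str = "exponential"  # or "unit"
    mean_branch_length: float = 0.1
    label_scheme: str = "L{k}"
    p_confidence: float = 0.5
    track_specs: Tuple[str, ...] = ()  # each BINARY or BAR


def generate_tree(params: FixtureParams) -> Tree:
    """Grow one random tree; identical output for identical (params, seed)."""
    if params.n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = random.Random(params.seed)

    root = TreeNode()
    leaves: List[TreeNode] = [root]
    for _ in range(params.n_leaves - 1):
        target = leaves.pop(rng.randrange(len(leaves)))
        left, right = TreeNode(), TreeNode()
        target.children = [left, right]
        leaves.append(left)
        leaves.append(right)

    unit = params.branch_length_distribution == "unit"
    k = 1
    for node in root.preorder():
        if node.is_leaf:
            node.label = params.label_scheme.format(k=k)
            k += 1
        if node is root:
            continue
        if unit:
            node.branch_length = None
        else:
            node.branch_length = rng.expovariate(1.0 / params.mean_branch_length)
        if not node.is_leaf and rng.random() < params.p_confidence:
            node.confidence = round(rng.uniform(50.0, 100.0), 1)
    return Tree.from_root(root)


def generate_tracks(params: FixtureParams, tree: Tree) -> List[ChartTrack]:
    """Synthesize the tracks requested in ``params.track_specs``."""
    rng = random.Random(params.seed + 1)
    n = tree.n_leaves
    tracks: List[ChartTrack] = []
    for idx, kind in enumerate(params.track_specs, 1):
        if kind == BAR:
            values = [round(rng.lognormvariate(0.0, 1.0), 6) for _ in range(n)]
        elif kind == BINARY:
            values = [1.0 if rng.random() < 0.5 else 0.0 for _ in range(n)]
        else:
            raise ValueError(f"unknown track kind {kind!r}")
        tracks.append(ChartTrack(name=f"track{idx}", kind=kind, values=values))
    return tracks


def tracks_to_tsv(tracks: Sequence[ChartTrack], tree: Tree) -> str:
    """Serialize tracks in the CLI's TSV format (with kind directives)."""
    leaves = leaves_in_order(tree)
    lines = [f"#kind\t{t.name}\t{t.kind}" for t in tracks]
    for track in tracks:
        for leaf, value in zip(leaves, track.values):
            lines.append(f"{leaf.label}\t{track.name}\t{value:.10g}")
    return "\n".join(lines) + "\n"


def tree_to_phyloxml(tree: Tree, tracks: Sequence[ChartTrack] = ()) -> str:
    """Encode a tree (and optional tracks) in this package's phyloXML dialect.

    Unit-length trees omit branch_length elements so that the Newick and
    phyloXML encodings of one fixture parse to structurally identical trees.
    """
    leaves = leaves_in_order(tree)
    leaf_rank = {id(leaf): i for i, leaf in enumerate(leaves)}

    phyloxml = ET.Element("phyloxml", {"xmlns": "http://www.phyloxml.org"})
    phylogeny = ET.SubElement(
        phyloxml, "phylogeny", {"rooted": "true" if tree.is_rooted else "false"}
    )
    if tracks:
        render_el = ET.SubElement(phylogeny, "render")
        charts_el = ET.SubElement(render_el, "charts")
        for track in tracks:
            attrs = {"name": track.name, "kind": track.kind}
            attrs.update(track.style)
            ET.SubElement(charts_el, "track", attrs)

    def emit(node: TreeNode, parent: ET.Element) -> None:
        clade = ET.SubElement(parent, "clade")
        if node.label is not None:
            ET.SubElement(clade, "name").text = node.label
        if node.branch_length is not None and not tree.unit_lengths:
            ET.SubElement(clade, "branch_length").text = f"{node.branch_length:.10g}"
        if node.confidence is not None:
            ET.SubElement(clade, "confidence", {"type": "bootstrap"}).text = (
                f"{node.confidence:.10g}"
            )
        if node.url:
            ET.SubElement(clade, "url").text = node.url
        if node.description:
            ET.SubElement(clade, "desc").text = node.description
        if node.is_leaf:
            for track in tracks:
                value = track.values[leaf_rank[id(node)]]
                ET.SubElement(
                    clade, "chart", {"name": track.name, "kind": track.kind}
                ).text = f"{value:.10g}"
        for child in node.children:
            emit(child, clade)

    emit(tree.root, phylogeny)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        phyloxml, encoding="unicode"
    ) + "\n"


def emit_fixture(
    tree: Tree,
    tracks: Sequence[ChartTrack],
    fmt: str,
    directory: Path,
    basename: str = "fixture",
) -> List[Path]:
    """Write a fixture to disk as Newick (+ track TSV) or as one phyloXML.

    The two encodings parse back to structurally identical trees and tracks,
    which the cross-format tests rely on.
    """
    from .newick import write_newick

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    if fmt == "newick":
        nwk = directory / f"{basename}.nwk"
        nwk.write_text(write_newick(tree) + "\n", encoding="utf-8")
        paths.append(nwk)
        if tracks:
            tsv = directory / f"{basename}.tsv"
            tsv.write_text(tracks_to_tsv(tracks, tree), encoding="utf-8")
            paths.append(tsv)
    elif fmt == "phyloxml":
        xml = directory / f"{basename}.xml"
        xml.write_text(tree_to_phyloxml(tree, tracks), encoding="utf-8")
        paths.append(xml)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")
    return paths
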