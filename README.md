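# phylodraw

Publication-quality phylogenetic tree figures as standalone, deterministic
SVG — rendered offline from raw Newick or phyloXML, with no browser, plugin
or server in the loop.

Phylogenies are routinely distributed as flattened raster images even though
the underlying inference (a Newick string or a phyloXML document) is small,
structured and machine-readable. `phylodraw` consumes those formats directly
and draws **rectangular and circular phylograms** scaled by branch length,
with integrated **binary and bar chart tracks** aligned to the leaves, leaf
labels that can **hyperlink** to external resources, and **tooltips** from
per-clade descriptions. Because SVG is a vector format the output pans and
zooms without loss of resolution, stays indexable by data-mining tools, and
exposes stable element ids (`node-<k>`, `track-<k>-cell-<i>`) so web pages
can attach their own scripting after the fact.

Intended users: anyone who needs reproducible tree figures in a pipeline —
microbial ecologists annotating clades with presence/absence ribbons or
clone-count bars, database maintainers regenerating thousands of figures
that must be byte-identical run to run, and web developers who want a static
SVG they can progressively enhance.

## The model in brief

Given a rooted tree with edge lengths *b(v) ≥ 0*, define the cumulative
depth *d(v) = d(parent(v)) + b(v)* (root depth = its own edge length, 0 if
absent). With *n* leaves in file order:

* **Rectangular view** — `x(v) = d(v) · s` with `s = W / max_leaf d`,
  where *W* is the branch-area width; leaf *i* gets
  `y = margin + (i + ½) · H/n`; an internal node's *y* is the mean of its
  children's. Branches are right-angle elbows; a scale bar covers the
  1/2/5×10^k length nearest 10 % of the tree depth.
* **Circular view** — same depth scaling on the radius,
  `r(v) = r₀ + d(v) · s`, and leaf *i* gets angle
  `θ = θ₀ + (i + ½) · arc/n` (degrees from 12 o'clock, clockwise); sibling
  connectors are true circular arcs. The two views are interchangeable:
  `x/s` and `(r − r₀)/s` recover the same depths.
* **Charts** — bar values are normalized per track to `v / max(v)`
  (zeros stay zero, so "relative to others" is preserved); binary values
  pass through. Tracks stack outward from the labels in declaration order —
  columns in the rectangular view, concentric annuli in the circular view.
* **Missing lengths** — if any edge lacks a length the whole tree is drawn
  as a cladogram (all unit edges); real and default lengths are never mixed.

## Worked example

```
$ cat demo.nwk
((Ecoli:0.12,Styphi:0.1)98:0.05,(Bsubtilis:0.2,Saureus:0.25)87:0.08,Mtuberculosis:0.3);

$ cat clones.tsv
#kind	clones	bar
Ecoli	clones	42
Styphi	clones	17
...

$ phylodraw --in demo.nwk --out demo.svg --shape circular \
    --chart-gutter 40 --tracks clones.tsv --gap 10 --summary-json
phylodraw: INFO: detected input format: newick
phylodraw: INFO: rendered 5 leaves (max depth 0.33, scale 393.939 px/unit) -> demo.svg
{"cladogram": false, "format": "newick", "input": "demo.nwk", "leaves": 5,
 "max_depth": 0.33, "nodes": 8, "output": "demo.svg",
 "scale_px_per_unit": 393.9393939..., "shape": "circular", "tracks": ["clones"]}
```

Reading the numbers: the deepest leaf (*Mtuberculosis*) sits 0.33
substitutions/site from the root, so with a 130 px tree radius the radial
scale is 393.9 px per unit; the two `98`/`87` internal labels are bootstrap
confidences and are printed at the branch forks; the `clones` bar ring shows
each count relative to the maximum (42), so *Ecoli*'s sector spans the full
40 px chart ring and *Bsubtilis*'s 5/42 of it. Running the command again
produces a byte-identical `demo.svg`.

The same tree renders rectangularly with `--shape rect`; style can come from
a JSON file (`--style`), from the phyloXML file itself, or per-element —
CLI > XML > defaults. phyloXML inputs may embed charts and styles directly;
the dialect is documented in `docs/phyloxml_dialect.md`. Exit codes: 0 ok,
2 parse error, 3 validation error, 4 I/O error.

The same pipeline is available as a library:

```python
from phylodraw import parse_newick, layout_circular, render
tree = parse_newick("((A:1,B:2)90:1,C:3);")
svg = render(layout_circular(tree), [], tree)
```

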