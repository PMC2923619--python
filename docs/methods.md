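# Methods

This note records the geometric model, the parameter choices that matter,
the numerical conventions, and what the synthetic-fixture tests do and do
not demonstrate.

## Tree model and depth

A phylogeny is an ordered rooted tree; child order is file order and is
never re-sorted, since leaf rank drives both layouts and chart alignment.
Depth is cumulative branch length, `d(v) = d(parent) + b(v)`, with the
root's own edge honored when present (default absent → depth 0). Branch
lengths must be ≥ 0; zero-length edges are legal and render as zero-extent
segments.

**Missing lengths.** If any non-root edge lacks a length, *every* non-root
edge is set to 1 and the tree is flagged `unit_lengths` (cladogram mode).
Mixing real and default lengths would silently distort a phylogram, so the
fallback is all-or-nothing; the flag also suppresses the scale bar and makes
the Newick writer omit `:length` fields so the mode survives a round trip.
An absent root edge does **not** trigger the fallback — most files simply
have no root edge, and treating that as "missing data" would make nearly
every phylogram a cladogram.

## Newick dialect

The parser is a recursive-descent implementation of the classic grammar
with single-quote escaping and bracketed-comment stripping. Dialect
ambiguities that real files exhibit are explicit flags rather than silent
guesses: numeric internal labels are read as bootstrap confidences by
default (`--internal-labels name` disables this), `_`→space translation is
off by default, and with comment-stripping disabled a comment is a parse
error (there is no NHX support, so nothing useful could be preserved).
Exactly one tree per file is accepted. The canonical writer quotes labels
only when they contain metacharacters or whitespace, prints lengths with up
to 10 significant digits (trailing zeros trimmed), and re-emits confidence
as the internal label; when a node carries both a confidence and a name,
the confidence wins the single Newick label slot.

## Layout geometry

Both views share one scaling rule — pixel extent per unit branch length is
(available extent) / (max leaf depth) — which is what makes them
interchangeable: dividing a leaf's x (rect) or r − r₀ (circular) by the
view's scale recovers the same depth, and the tests assert agreement to
1e-9.

Rectangular: SVG-native coordinates (origin top-left, y down, first leaf on
top), leaf i of n at `y = margin + (i+½)·H/n`, internal y = arithmetic mean
of children (not the midpoint of extremes; the mean is the standard choice
and is visually balanced for multifurcations). Node x is stored relative to
the branch-area left edge; the renderer adds the margin. The scale bar picks
the 1/2/5×10^k length nearest 10 % of the depth, with nearness measured on
a log scale (ratios, not absolute differences, are what the eye compares).

Circular: angles in degrees from 12 o'clock, clockwise (radians only inside
the trig); leaf i at `θ = θ₀ + (i+½)·arc/n`, internal θ = mean of children,
`r = r₀ + d·s`. The outer tree radius is `min(W,H)/2 − margin −
label_gutter − chart_gutter`. Sibling connectors are genuine SVG arc
commands, not chords. Leaf labels are rotated to their angle and flipped by
180° on the left half (90° < θ < 270°) so text is never upside down. The
`gap` parameter (default 0) leaves unused arc to keep the first and last
labels apart on full circles. Cartesian conversion is
`x = cx + r·sin θ, y = cy − r·cos θ`.

Canvas margins are one uniform value for all four sides; asymmetric margins
added nothing the gutters don't already provide.

## Charts

Bar normalization is 0→max per track, not min→max: bars convey a quantity
relative to others, and a nonzero floor would hide true zeros (a min-max
mode would be a style option, not a different code path). Whether to
normalize per track or globally across tracks was open; per track is the
choice here, since tracks typically carry incommensurable quantities.
A leaf missing a value gets 0 with a warning, keeping each track total so
the one-cell-per-leaf geometry invariant holds. Bands are stacked in
declaration order, innermost first; the stack must fit the reserved chart
gutter, and overflow is a validation error rather than silent clipping.
Default band thickness is 20 px, inter-band gap 4 px.

## SVG rendering

Element order is fixed (background, branches, confidence labels, scale bar,
leaf labels, tracks) and all numbers are printed as fixed-point 3-decimal
strings with `-0.000` normalized to `0.000`, which makes output
byte-identical across runs and platforms — golden-file testing then needs
no tolerance at all. The original interactive behaviors are mapped to their
static SVG equivalents: URLs become `<a href>` anchors around the label,
descriptions become child `<title>` elements (the native browser tooltip),
and deterministic ids let downstream pages attach scripts. Confidence text
is suppressed below a configurable font-size floor (default 5 pt at a 7 pt
confidence font). Since SVG generation has no font metrics, gutter
budgeting uses the standard 0.6 × font-size per character heuristic; it
affects only layout budgeting advice, never correctness.

## Synthetic fixtures

The fixture generator grows trees by Yule-style splitting (repeatedly
replace a uniformly chosen leaf with a two-leaf internal node), giving
realistic topological imbalance with exactly n−1 internal nodes; a specific
null model is not needed because the tests exercise structure, not
inference. Non-root branch lengths are exponential with mean 0.1
substitutions/site — a typical scale for moderately diverged sequence
data — or absent in cladogram mode; internal nodes carry a bootstrap-like
confidence uniform on 50–100 with probability 0.5. Bar tracks are
lognormal(0, 1) (skewed counts, e.g. clones per taxon) and binary tracks
Bernoulli(0.5). Everything is deterministic given (params, seed).

What the fixtures do **not** emulate: real taxon-name distributions (long,
collision-prone labels), multifurcations (growth is strictly binary, though
the layout engines support and are unit-tested on multifurcations from
hand-written inputs), rate heterogeneity, and files from other software
with nonstandard quoting. Passing fixture-based tests therefore shows the
geometry, serialization and determinism contracts hold, not that every
wild file parses.

## Problem sizes and verification

The verification battery runs: 200 trees (5–200 leaves) checked against
Bio.Phylo as an independent reference parser; 500 serialization round
trips; hand-computed coordinate oracles; 50 trees for view
interchangeability; 1000 random tracks for normalization invariants; 20
golden fixtures rendered twice for byte-determinism; and one 2000-leaf,
two-track render of both views as the scalability smoke test (about one
second on a single CPU; the 2000-node scale is where DOM-based renderers
historically start to struggle, which a static generator sidesteps
entirely). These sizes keep the whole battery in the low seconds while each
property is still exercised across a broad spread of shapes.

## Known limitations

* One tree per file; no Nexus, no NHX, no phyloXML writing, and only the
  drawing-relevant subset of phyloXML is read.
* No label-collision avoidance: with many leaves and large fonts labels can
  overlap; the gap/gutter parameters are the manual remedy.
* Only binary and bar tracks; heatmaps, pies and stacked bars are plausible
  extensions, not current formats.
* No rasterization (PNG/PDF) and no animated view swapping; the artifact is
  a figure generator, not a viewer.
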