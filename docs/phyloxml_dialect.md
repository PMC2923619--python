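# phyloXML chart/style dialect (v1)

`phylodraw` reads standard phyloXML clade elements — `name`,
`branch_length` (attribute **or** child element), `confidence` (first one
wins; its `type` attribute is kept as a style hint), `url`/`uri`,
`desc`/`description`, nested `clade` — matching on local names, so
namespaced and un-namespaced documents are both accepted. Unknown elements
(taxonomies, sequences, events, ...) are skipped with a logged warning.

Charts and styles travel in a small extension vocabulary. It is a
self-describing stand-in of this package's own design, versioned with this
document; it is not a claim about any other tool's schema.

## Written schema

```
phylogeny
├── render?                        document-level presentation block
│   ├── style?                     one element per style field:
│   │   ├── font_family?           text        (default "sans-serif")
│   │   ├── font_size?             pt          (default 10)
│   │   ├── branch_stroke_width?   px          (default 1.5)
│   │   ├── branch_color?          CSS color   (default #333333)
│   │   ├── label_color?           CSS color   (default #000000)
│   │   ├── background?            CSS color   (default #ffffff)
│   │   ├── show_confidence?       true|false  (default true)
│   │   └── show_scale_bar?        true|false  (default true)
│   └── charts?                    track declarations, one per track:
│       └── track*                 @name (required), @kind = binary|bar,
│                                  @thickness px, @fill CSS color,
│                                  @groups "label=color,label=color,..."
└── clade                          the root clade (standard phyloXML)
    └── ... leaf clades may carry:
        └── chart*                 @name names the track; element text is
                                   the numeric value (binary: 0 or 1)
```

Rules:

* `chart` elements are **leaf-only**; one on an internal clade is an error.
* Track order is first-appearance order in document order (declarations in
  `render/charts` first, then undeclared tracks as they appear on leaves);
  bands are drawn innermost-first in that order, never reordered.
* Every track gets exactly one value per leaf: a leaf with no `chart`
  element for a track contributes 0, with a logged warning.
* A track's kind comes from its declaration, else from the first `chart`
  element's `@kind`, else it is inferred (all values in {0, 1} → binary,
  otherwise bar).
* Binary values must be 0/1; bar values must be ≥ 0.
* XML-embedded style is overridden field-wise by programmatic/CLI style
  (`--style style.json`), and overrides the built-in defaults.
* A per-clade `<style key="value" .../>` element stores local hints on that
  node (e.g. a label color override).

## Example

```xml
<phyloxml xmlns="http://www.phyloxml.org">
  <phylogeny rooted="true">
    <render>
      <style><font_size>11</font_size><branch_color>#224466</branch_color></style>
      <charts>
        <track name="gut" kind="binary" thickness="14" fill="#66aa55"/>
        <track name="clones" kind="bar" thickness="36" fill="#4477aa"/>
      </charts>
    </render>
    <clade>
      <confidence type="bootstrap">98</confidence>
      <clade branch_length="0.12"><name>Ecoli</name>
        <url>https://example.org/ecoli</url>
        <desc>Escherichia coli K-12</desc>
        <chart name="gut">1</chart>
        <chart name="clones">42</chart>
      </clade>
      <clade><name>Bsubtilis</name><branch_length>0.2</branch_length>
        <chart name="gut">0</chart>
        <chart name="clones">5</chart>
      </clade>
    </clade>
  </phylogeny>
</phyloxml>
```
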