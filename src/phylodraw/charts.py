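"""Per-leaf annotation tracks: binary (presence/absence ribbon) and bar
(relative magnitude) charts, plus their geometry in both tree views.

Values are normalized per track before rendering: bar values are divided by
the track maximum (an all-zero track stays all zero), binary values pass
through unchanged.  Original values are retained on every cell so tooltips can
show the raw figure.  Tracks occupy successive bands outward from the label
zone in declaration order — vertical columns in the rectangular view,
concentric annuli in the circular view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .tree import Tree, leaves_in_order

logger = logging.getLogger(__name__)

#: default band thickness (px) and gap between consecutive bands (px)
DEFAULT_TRACK_THICKNESS = 20.0
DEFAULT_BAND_GAP = 4.0

BINARY = "binary"
BAR = "bar"


class TrackError(ValueError):
    """Track validation failure (bad values, misalignment, budget overflow)."""


@dataclass
class ChartTrack:
    """One annotation track: a value per leaf, aligned to leaf order.

    ``style`` keys understood by the pipeline: ``fill`` (cell color),
    ``thickness`` (band extent in px), ``groups`` (binary ribbon color-coding:
    comma-separated ``label=color`` pairs).
    """

    name: str
    kind: str  # BINARY or BAR
    values: List[float]
    style: Dict[str, str] = field(default_factory=dict)

    def validate(self, n_leaves: Optional[int] = None) -> None:
        if self.kind not in (BINARY, BAR):
            raise TrackError(f"track {self.name!r}: unknown kind {self.kind!r}")
        if n_leaves is not None and len(self.values) != n_leaves:
            raise TrackError(
                f"track {self.name!r}: {len(self.values)} values for "
                f"{n_leaves} leaves"
            )
        for v in self.values:
            if self.kind == BINARY and v not in (0.0, 1.0):
                raise TrackError(
                    f"track {self.name!r}: binary value {v!r} not in {{0, 1}}"
                )
            if self.kind == BAR and v < 0:
                raise TrackError(f"track {self.name!r}: negative bar value {v!r}")

    @property
    def thickness(self) -> float:
        return float(self.style.get("thickness", DEFAULT_TRACK_THICKNESS))


def normalize_track(track: ChartTrack) -> ChartTrack:
    """Return a copy whose values lie in [0, 1].

    Bar: value / max(values); all-zero tracks stay all zero.  Binary:
    identity.  Normalization is idempotent and invariant under positive
    scaling of the input.
    """
    track.validate()
    if track.kind == BINARY:
        return replace(track, values=list(track.values))
    peak = max(track.values, default=0.0)
    if peak == 0.0:
        return replace(track, values=[0.0] * len(track.values))
    return replace(track, values=[v / peak for v in track.values])


@dataclass
class RectCell:
    """One leaf's cell in a rectangular-view track band."""

    x: float
    y: float
    width: float
    height: float
    filled: bool
    value: float
    leaf_id: int


@dataclass
class SectorCell:
    """One leaf's annular-sector cell in a circular-view track band."""

    r_in: float
    r_out: float
    theta_start: float  # degrees
    theta_end: float
    filled: bool
    value: float
    leaf_id: int


@dataclass
class TrackGeometry:
    track: ChartTrack  # normalized copy
    cells: List[Union[RectCell, SectorCell]]
    band_start: float  # offset of band start within the chart gutter/budget
    band_end: float


def _band_offsets(tracks: Sequence[ChartTrack], budget: float, gap: float) -> List[Tuple[float, float]]:
    offsets: List[Tuple[float, float]] = []
    cursor = 0.0
    for track in tracks:
        offsets.append((cursor, cursor + track.thickness))
        cursor += track.thickness + gap
    used = offsets[-1][1] if offsets else 0.0
    if used > budget + 1e-9:
        raise TrackError(
            f"track bands need {used:.1f} px but only {budget:.1f} px are "
            f"reserved (chart gutter); widen the gutter or thin the bands"
        )
    return offsets


def layout_tracks(
    tracks: Sequence[ChartTrack],
    base,  # RectLayout | CircularLayout
    band_gap: float = DEFAULT_BAND_GAP,
) -> List[TrackGeometry]:
    """Compute cell geometry for each track against a finished tree layout.

    Bands are stacked in declaration order, innermost (nearest the labels)
    first.  Exceeding the reserved chart gutter raises :class:`TrackError`
    rather than silently clipping.
    """
    # local imports avoid a module cycle (layouts do not know about charts)
    from .layout_rect import RectLayout
    from .layout_circular import CircularLayout

    tracks = list(tracks)
    if not tracks:
        return []
    n_leaves = len(base.leaf_ids)
    for track in tracks:
        track.validate(n_leaves)
    gap = band_gap if len(tracks) > 1 else 0.0
    normalized = [normalize_track(t) for t in tracks]

    if isinstance(base, RectLayout):
        budget = base.canvas.chart_gutter
        offsets = _band_offsets(tracks, budget, gap)
        x_base = base.branch_area_width + base.canvas.label_gutter
        out: List[TrackGeometry] = []
        spacing = base.leaf_spacing
        for (start, end), raw, norm in zip(offsets, tracks, normalized):
            cells: List[Union[RectCell, SectorCell]] = []
            for i, leaf_id in enumerate(base.leaf_ids):
                y = base.canvas.margin + i * spacing
                nv = norm.values[i]
                if raw.kind == BINARY:
                    cells.append(
                        RectCell(
                            x=x_base + start,
                            y=y,
                            width=raw.thickness,
                            height=spacing,
                            filled=nv == 1.0,
                            value=raw.values[i],
                            leaf_id=leaf_id,
                        )
                    )
                else:
                    cells.append(
                        RectCell(
                            x=x_base + start,
                            y=y,
                            width=nv * raw.thickness,
                            height=spacing,
                            filled=True,
                            value=raw.values[i],
                            leaf_id=leaf_id,
                        )
                    )
            out.append(TrackGeometry(norm, cells, start, end))
        return out

    if isinstance(base, CircularLayout):
        budget = base.canvas.chart_gutter
        offsets = _band_offsets(tracks, budget, gap)
        r_base = base.outer_radius + base.canvas.label_gutter
        out = []
        for (start, end), raw, norm in zip(offsets, tracks, normalized):
            cells = []
            for i, leaf_id in enumerate(base.leaf_ids):
                t0, t1 = base.leaf_slot(i)
                nv = norm.values[i]
                r_in = r_base + start
                if raw.kind == BINARY:
                    r_out = r_in + raw.thickness
                    filled = nv == 1.0
                else:
                    r_out = r_in + nv * raw.thickness
                    filled = True
                cells.append(
                    SectorCell(
                        r_in=r_in,
                        r_out=r_out,
                        theta_start=t0,
                        theta_end=t1,
                        filled=filled,
                        value=raw.values[i],
                        leaf_id=leaf_id,
                    )
                )
            out.append(TrackGeometry(norm, cells, start, end))
        return out

    raise TypeError(f"unsupported layout type {type(base).__name__}")


def load_tracks_tsv(text: str, tree: Tree) -> List[ChartTrack]:
    """Parse tab-separated track data (leaf label, track name, value).

    Optional directive lines ``#kind<TAB>name<TAB>binary|bar`` fix a track's
    kind; otherwise a track whose values are all 0/1 is binary, else bar.
    Rows are joined to the tree by exact leaf-label match; unmatched labels
    are an error.  A leaf with no row gets 0 with a warning so every track
    stays total (one cell per leaf).
    """
    leaves = leaves_in_order(tree)
    label_to_idx: Dict[str, int] = {}
    for i, leaf in enumerate(leaves):
        if leaf.label is not None:
            label_to_idx[leaf.label] = i

    kinds: Dict[str, str] = {}
    data: Dict[str, Dict[int, float]] = {}
    order: List[str] = []
    unmatched: List[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line.split("\t")
            if parts[0] == "#kind" and len(parts) == 3:
                kinds[parts[1]] = parts[2].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TrackError(
                f"tracks TSV line {lineno}: expected 3 tab-separated fields, "
                f"got {len(parts)}"
            )
        label, name, value_s = parts
        try:
            value = float(value_s)
        except ValueError:
            raise TrackError(
                f"tracks TSV line {lineno}: non-numeric value {value_s!r}"
            ) from None
        if label not in label_to_idx:
            unmatched.append(label)
            continue
        if name not in data:
            data[name] = {}
            order.append(name)
        data[name][label_to_idx[label]] = value
    if unmatched:
        raise TrackError(
            "tracks TSV: leaf labels not in tree: " + ", ".join(sorted(set(unmatched)))
        )

    tracks: List[ChartTrack] = []
    for name in order:
        per_leaf = data[name]
        values: List[float] = []
        for i, leaf in enumerate(leaves):
            if i in per_leaf:
                values.append(per_leaf[i])
            else:
                logger.warning(
                    "track %r: no value for leaf %r, using 0", name, leaf.label
                )
                values.append(0.0)
        kind = kinds.get(name)
        if kind is None:
            kind = BINARY if all(v in (0.0, 1.0) for v in values) else BAR
        track = ChartTrack(name=name, kind=kind, values=values)
        track.validate(len(leaves))
        tracks.append(track)
    return tracks
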