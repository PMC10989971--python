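"""Track specifications and glyph construction.

A :class:`TrackSpec` is the rendering recipe for one annulus of the plot:
which glyph to draw (heatmap, bar, line, point, tile, triangle, arrow),
its radial span (``start_pos`` / ``end_pos`` on the 0-100 percent radius
scale), value scaling, colours and background. Glyph builders turn parsed
records plus a spec and a genome layout into :class:`GlyphDatum` lists in
plot coordinates (theta in degrees, radius in percent); the render module
then maps those to the device.

Tracks may overlap in radius — that is the track-stacking feature: a tile
track spanning 90-100 highlights every track whose annulus lies inside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from matplotlib import colormaps as _mpl_colormaps

from .formats_io import ColorSpec, ContinuousRecord, DiscreteRecord
from .layout import GenomeLayout, genomic_to_theta
from .stats_prep import WindowSpec

__all__ = [
    "HeatScale",
    "TrackSpec",
    "GlyphDatum",
    "LegendSpec",
    "normalize_values",
    "color_ramp",
    "build_continuous_glyphs",
    "build_discrete_glyphs",
    "build_legends",
]

DEFAULT_BORDER = ColorSpec(60, 60, 60)
DEFAULT_ABOVE = ColorSpec(214, 39, 40)   # red for values above the sep line
DEFAULT_BELOW = ColorSpec(31, 119, 180)  # blue for values below
_FALLBACK_FILL = ColorSpec(100, 100, 100)


@dataclass(frozen=True)
class HeatScale:
    """Monotone map from data values onto [0, 1] for heat colouring."""

    mode: str = "linear"  # linear | log | quantile
    vmin: float = 0.0
    vmax: float = 1.0

    def __post_init__(self):
        if self.mode not in ("linear", "log", "quantile"):
            raise ValueError(f"unknown heat scale mode {self.mode!r}")


def normalize_values(values: Sequence[float], scale: HeatScale) -> np.ndarray:
    """Normalize values to [0, 1] under the given scale.

    linear: ``(v - vmin) / (vmax - vmin)`` clipped; log: linear in
    ``log10(v - vmin + eps)``; quantile: empirical CDF rank over the passed
    values. All modes send vmin to 0 and vmax to 1 (quantile: the data
    minimum and maximum).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    if scale.mode == "quantile":
        if v.size == 1:
            return np.full(1, 0.5)
        order = np.sort(v)
        below = np.searchsorted(order, v, side="left")
        return np.clip(below / (v.size - 1), 0.0, 1.0)
    vmin, vmax = scale.vmin, scale.vmax
    if not vmin < vmax:
        raise ValueError(f"need vmin < vmax, got ({vmin}, {vmax})")
    if scale.mode == "linear":
        return np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
    eps = max((vmax - vmin) * 1e-3, 1e-12)
    u = np.log10(np.clip(v - vmin, 0.0, None) + eps)
    lo, hi = math.log10(eps), math.log10(vmax - vmin + eps)
    return np.clip((u - lo) / (hi - lo), 0.0, 1.0)


def color_ramp(palette: Union[str, Sequence[ColorSpec], None], t: float) -> ColorSpec:
    """Colour at position ``t`` in [0, 1] on a named matplotlib ramp or a
    piecewise-linear ramp through an explicit colour list."""
    t = min(1.0, max(0.0, float(t)))
    if palette is None:
        palette = "viridis"
    if isinstance(palette, str):
        r, g, b, _ = _mpl_colormaps[palette](t)
        return ColorSpec(round(r * 255), round(g * 255), round(b * 255))
    colors = list(palette)
    if len(colors) == 1:
        return colors[0]
    x = t * (len(colors) - 1)
    i = min(int(x), len(colors) - 2)
    f = x - i
    a, b = colors[i], colors[i + 1]
    return ColorSpec(
        round(a.r + f * (b.r - a.r)),
        round(a.g + f * (b.g - a.g)),
        round(a.b + f * (b.b - a.b)),
    )


@dataclass(frozen=True)
class TrackSpec:
    """Rendering recipe for one track annulus."""

    glyph: str  # heatmap | bar | line | point | tile | triangle | arrow | text | link
    start_pos: float = 0.0
    end_pos: float = 100.0
    bin: Optional[WindowSpec] = None
    bin_mode: str = "none"
    palette: Union[str, tuple[ColorSpec, ...], None] = None
    color_by_chr: bool = False
    sep_line_value: Optional[float] = None
    above_color: ColorSpec = DEFAULT_ABOVE
    below_color: ColorSpec = DEFAULT_BELOW
    bar_fill: Optional[ColorSpec] = None          # track background
    bar_border: Optional[ColorSpec] = DEFAULT_BORDER  # None == "null" (no border)
    fill: Optional[ColorSpec] = None              # flat glyph colour
    value_range: Optional[tuple[float, float]] = None
    heat_scale: str = "linear"
    invert: bool = False  # upside-down bars: drawn from the outer edge inward
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start_pos < self.end_pos <= 100):
            raise ValueError(
                f"need 0 <= start_pos < end_pos <= 100, got "
                f"({self.start_pos}, {self.end_pos})"
            )
        known = {"heatmap", "bar", "line", "point", "tile", "triangle", "arrow", "text", "link"}
        if self.glyph not in known:
            raise ValueError(f"unknown glyph {self.glyph!r}")


@dataclass(frozen=True)
class GlyphDatum:
    """One drawable glyph in plot coordinates (theta deg, radius percent)."""

    kind: str
    chrom_id: str
    theta_start: float
    theta_end: float
    r_inner: float
    r_outer: float
    fill: Optional[ColorSpec] = None
    border: Optional[ColorSpec] = None
    value: Optional[float] = None
    label: Optional[str] = None
    reversed: bool = False
    points: Optional[tuple[tuple[float, float], ...]] = None  # (theta, r) vertices


@dataclass(frozen=True)
class LegendSpec:
    kind: str  # color_scale | categorical
    title: str = ""
    entries: tuple[tuple[str, ColorSpec], ...] = ()
    ramp: Union[str, tuple[ColorSpec, ...], None] = None
    vmin: float = 0.0
    vmax: float = 1.0
    anchor: tuple[float, float] = (0.0, 0.0)


def _value_range(records: Sequence[ContinuousRecord], spec: TrackSpec) -> tuple[float, float]:
    if spec.value_range is not None:
        return spec.value_range
    vals = [r.value for r in records]
    lo, hi = min(vals), max(vals)
    if lo == hi:  # flat tracks still need a non-degenerate scale
        lo, hi = lo - 0.5, hi + 0.5
    return lo, hi


def _skeleton_colors(layout: GenomeLayout) -> dict[str, ColorSpec]:
    return {c.chrom_id: c.color or _FALLBACK_FILL for c in layout.chromosomes}


def _record_thetas(rec, layout: GenomeLayout) -> tuple[float, float]:
    lo = max(1, min(rec.start, rec.end))
    hi = min(layout.span(rec.chrom_id).length, max(rec.start, rec.end))
    return (
        genomic_to_theta(layout, rec.chrom_id, lo),
        genomic_to_theta(layout, rec.chrom_id, hi),
    )


def build_continuous_glyphs(
    records: Sequence[ContinuousRecord], spec: TrackSpec, layout: GenomeLayout
) -> list[GlyphDatum]:
    """Glyphs for a continuous track: heatmap sectors, radial bars, value
    points, or a sep-line-split polyline.

    Bars rise from the annulus base (or fall from the outer edge when
    ``spec.invert``); radial extent is the linearly normalized value. Line
    tracks place each record at its interval midpoint and split segments
    exactly where the value crosses ``sep_line_value``, colouring the above
    and below parts differently.
    """
    if not records:
        return []
    known = {c.chrom_id for c in layout.chromosomes}
    records = [r for r in records if r.chrom_id in known]
    if not records:
        return []
    vmin, vmax = _value_range(records, spec)
    chrom_colors = _skeleton_colors(layout)
    h = spec.end_pos - spec.start_pos
    lin = normalize_values([r.value for r in records], HeatScale("linear", vmin, vmax))

    if spec.glyph == "heatmap":
        heat = normalize_values([r.value for r in records], HeatScale(spec.heat_scale, vmin, vmax))
        out = []
        for rec, t in zip(records, heat):
            th0, th1 = _record_thetas(rec, layout)
            out.append(
                GlyphDatum(
                    "sector", rec.chrom_id, th0, th1, spec.start_pos, spec.end_pos,
                    fill=color_ramp(spec.palette, float(t)), border=None, value=rec.value,
                )
            )
        return out

    if spec.glyph == "bar":
        out = []
        for rec, t in zip(records, lin):
            th0, th1 = _record_thetas(rec, layout)
            if spec.invert:
                r0, r1 = spec.end_pos - float(t) * h, spec.end_pos
            else:
                r0, r1 = spec.start_pos, spec.start_pos + float(t) * h
            fill = (
                chrom_colors[rec.chrom_id] if spec.color_by_chr
                else (spec.fill or _FALLBACK_FILL)
            )
            out.append(
                GlyphDatum(
                    "sector", rec.chrom_id, th0, th1, r0, r1,
                    fill=fill, border=spec.bar_border, value=rec.value,
                )
            )
        return out

    if spec.glyph == "point":
        out = []
        for rec, t in zip(records, lin):
            th0, th1 = _record_thetas(rec, layout)
            mid = (th0 + th1) / 2.0
            r = spec.start_pos + float(t) * h
            fill = (
                chrom_colors[rec.chrom_id] if spec.color_by_chr
                else (spec.fill or _FALLBACK_FILL)
            )
            out.append(
                GlyphDatum("marker", rec.chrom_id, mid, mid, r, r, fill=fill, value=rec.value)
            )
        return out

    if spec.glyph == "line":
        return _line_glyphs(records, spec, layout, lin)
    raise ValueError(f"glyph {spec.glyph!r} is not a continuous glyph")


def _line_glyphs(records, spec: TrackSpec, layout: GenomeLayout, lin) -> list[GlyphDatum]:
    """Per-chromosome polylines, split at sep_line_value crossings."""
    h = spec.end_pos - spec.start_pos
    sep = spec.sep_line_value
    vmin, vmax = _value_range(records, spec)
    sep_r = None
    if sep is not None and vmax > vmin:
        sep_t = (sep - vmin) / (vmax - vmin)
        sep_r = spec.start_pos + min(1.0, max(0.0, sep_t)) * h
    out = []
    by_chrom: dict[str, list[tuple[float, float, float]]] = {}
    for rec, t in zip(records, lin):
        th0, th1 = _record_thetas(rec, layout)
        mid = (th0 + th1) / 2.0
        by_chrom.setdefault(rec.chrom_id, []).append((mid, spec.start_pos + float(t) * h, rec.value))
    for chrom, pts in by_chrom.items():
        if sep is None or sep_r is None:
            out.append(
                GlyphDatum(
                    "polyline", chrom, pts[0][0], pts[-1][0], spec.start_pos, spec.end_pos,
                    fill=None, border=spec.fill or DEFAULT_ABOVE,
                    points=tuple((p[0], p[1]) for p in pts),
                )
            )
            continue
        # split exactly at crossings, interpolating the crossing point
        seg: list[tuple[float, float]] = []
        seg_above = pts[0][2] >= sep
        def flush(above, seg):
            if len(seg) >= 2:
                out.append(
                    GlyphDatum(
                        "polyline", chrom, seg[0][0], seg[-1][0],
                        spec.start_pos, spec.end_pos, fill=None,
                        border=spec.above_color if above else spec.below_color,
                        points=tuple(seg),
                    )
                )
        prev = None
        for mid, r, v in pts:
            above = v >= sep
            if prev is not None and above != seg_above:
                pm, pr, pv = prev
                f = (sep - pv) / (v - pv) if v != pv else 0.5
                cross = (pm + f * (mid - pm), sep_r)
                seg.append(cross)
                flush(seg_above, seg)
                seg = [cross]
                seg_above = above
            seg.append((mid, r))
            prev = (mid, r, v)
        flush(seg_above, seg)
    return out


def build_discrete_glyphs(
    records: Sequence[DiscreteRecord], spec: TrackSpec, layout: GenomeLayout
) -> list[GlyphDatum]:
    """Glyphs for a discrete track: tiles, TAD triangles, or oriented arrows.

    Tiles fill the interval across the annulus. Triangles put their base on
    the interval at the inner radius and the apex at the interval midpoint on
    the outer radius. Arrows point from the record's written start coordinate
    towards its written end, so a record with start > end (flagged reversed)
    points towards lower genomic positions.
    """
    known = {c.chrom_id for c in layout.chromosomes}
    out = []
    for rec in records:
        if rec.chrom_id not in known:
            continue
        th_lo, th_hi = _record_thetas(rec, layout)
        r0, r1 = spec.start_pos, spec.end_pos
        if spec.glyph == "tile":
            out.append(
                GlyphDatum(
                    "sector", rec.chrom_id, th_lo, th_hi, r0, r1,
                    fill=rec.color, border=spec.bar_border, label=rec.category,
                )
            )
        elif spec.glyph == "triangle":
            mid = (th_lo + th_hi) / 2.0
            out.append(
                GlyphDatum(
                    "polygon", rec.chrom_id, th_lo, th_hi, r0, r1,
                    fill=rec.color, border=spec.bar_border, label=rec.category,
                    points=((th_lo, r0), (th_hi, r0), (mid, r1)),
                )
            )
        elif spec.glyph == "arrow":
            length = layout.span(rec.chrom_id).length
            tail = genomic_to_theta(layout, rec.chrom_id, min(max(rec.start, 1), length))
            tip = genomic_to_theta(layout, rec.chrom_id, min(max(rec.end, 1), length))
            rm = (r0 + r1) / 2.0
            head = tip - 0.25 * (tip - tail)  # head base 25% back from the tip
            out.append(
                GlyphDatum(
                    "polygon", rec.chrom_id, tail, tip, r0, r1,
                    fill=rec.color, border=spec.bar_border, label=rec.category,
                    reversed=rec.reversed,
                    points=(
                        (tail, r0), (head, r0), (tip, rm), (head, r1), (tail, r1),
                    ),
                )
            )
        else:
            raise ValueError(f"glyph {spec.glyph!r} is not a discrete glyph")
    return out


def build_legends(
    track_entries: Sequence[tuple[TrackSpec, Sequence]],
    anchors: Optional[Sequence[tuple[float, float]]] = None,
) -> list[LegendSpec]:
    """Automatic legends: one colour-scale legend per heatmap track and one
    categorical legend per discrete track whose records carry a category
    column (entries in first-appearance order). Other tracks get none.
    """
    legends = []
    for spec, records in track_entries:
        if spec.glyph == "heatmap" and records:
            vmin, vmax = _value_range(list(records), spec)
            legends.append(
                LegendSpec(
                    "color_scale", title=spec.name or "value",
                    ramp=spec.palette, vmin=vmin, vmax=vmax,
                )
            )
        elif spec.glyph in ("tile", "triangle", "arrow"):
            entries: list[tuple[str, ColorSpec]] = []
            seen = set()
            for rec in records:
                if rec.category is not None and rec.category not in seen:
                    seen.add(rec.category)
                    entries.append((rec.category, rec.color))
            if entries:
                legends.append(
                    LegendSpec("categorical", title=spec.name, entries=tuple(entries))
                )
    if anchors:
        legends = [
            LegendSpec(
                lg.kind, lg.title, lg.entries, lg.ramp, lg.vmin, lg.vmax,
                anchor=anchors[i] if i < len(anchors) else lg.anchor,
            )
            for i, lg in enumerate(legends)
        ]
    return legends
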