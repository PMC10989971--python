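"""Scene composition and export.

:func:`compose` turns a :class:`~circleplot.project.Project` into a
:class:`RenderScene` — an ordered, device-independent list of primitives
(arc bands, sectors, polylines, markers, polygons, bézier ribbons, text,
leader lines, legend boxes) in plot coordinates (theta degrees, radius
percent). The same primitives serve circular and straight mode; only the
final coordinate transform differs, so switching modes never changes the
primitive census.

Z-order follows the stacking users expect: skeleton, track backgrounds,
track glyphs outer-to-inner, association ribbons, feature labels with
leader lines, legends. :func:`export` writes SVG (deterministic: the same
scene always produces identical bytes) or PNG at a chosen dpi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

from . import formats_io as fio
from .formats_io import ColorSpec, LinkRecord, RegionTagRecord
from .layout import GenomeLayout, build_layout, genomic_to_theta, make_ticks, polar_to_xy
from .project import DEFAULT_SETTINGS, Project
from .stats_prep import bin_continuous
from .tracks import (
    GlyphDatum,
    LegendSpec,
    build_continuous_glyphs,
    build_discrete_glyphs,
    build_legends,
    color_ramp,
)

__all__ = [
    "Primitive",
    "RenderScene",
    "PlacedLabel",
    "LabelPlacement",
    "render_skeleton",
    "render_links",
    "place_labels",
    "compose",
    "export",
]

_GRAY = ColorSpec(180, 180, 180)
_DARK = ColorSpec(40, 40, 40)
_LEADER = ColorSpec(120, 120, 120)
_LINK_FILL = ColorSpec(160, 160, 160)

ARC_STEP_DEG = 2.0  # angular sampling of arc approximations


@dataclass(frozen=True)
class Primitive:
    """One drawable element in plot coordinates."""

    kind: str  # arc_band|sector|polyline|marker|polygon|ribbon|text|leader_line|legend_box
    points: tuple[tuple[float, float], ...] = ()  # (theta, r) vertices
    fill: Optional[ColorSpec] = None
    stroke: Optional[ColorSpec] = None
    stroke_width: float = 1.0
    text: Optional[str] = None
    font_size: float = 10.0
    marker_size: float = 2.5
    opacity: float = 1.0
    legend: Optional[LegendSpec] = None
    anchor_xy: Optional[tuple[float, float]] = None  # canvas coords (legends)


@dataclass
class RenderScene:
    primitives: list[Primitive]
    width: float
    height: float
    mode: str  # "circular" | "straight"
    start_angle: float
    clockwise: bool
    background: ColorSpec = ColorSpec(255, 255, 255)
    warnings: list[str] = field(default_factory=list)

    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.primitives:
            out[p.kind] = out.get(p.kind, 0) + 1
        return out

    # ---- device transform -------------------------------------------------

    def to_xy(self, theta: float, r: float) -> tuple[float, float]:
        if self.mode == "circular":
            rmax = 0.45 * min(self.width, self.height)
            x, y = polar_to_xy(theta, rmax * r / 100.0)
            return (self.width / 2.0 + x, self.height / 2.0 - y)
        u = (self.start_angle - theta) if self.clockwise else (theta - self.start_angle)
        ml, mr, mt, mb = 40.0, 40.0, 40.0, 40.0
        x = ml + u / 360.0 * (self.width - ml - mr)
        y = self.height - mb - r / 100.0 * (self.height - mt - mb)
        return (x, y)


def _arc_thetas(t0: float, t1: float) -> list[float]:
    n = max(1, int(math.ceil(abs(t1 - t0) / ARC_STEP_DEG)))
    return [t0 + (t1 - t0) * i / n for i in range(n + 1)]


def _band_points(t0: float, t1: float, r_in: float, r_out: float):
    ts = _arc_thetas(t0, t1)
    return tuple([(t, r_out) for t in ts] + [(t, r_in) for t in reversed(ts)])


# ---------------------------------------------------------------------------
# skeleton


def render_skeleton(layout: GenomeLayout, settings: Optional[dict] = None) -> list[Primitive]:
    """Arc band, name label and ticks per chromosome."""
    settings = settings or DEFAULT_SETTINGS
    r_in, r_out = settings.get("skeleton_span", [92.0, 97.0])
    target = settings.get("tick_target_major_count", 5)
    prims: list[Primitive] = []
    ticks = make_ticks(layout, target)
    for c in layout.chromosomes:
        prims.append(
            Primitive(
                "arc_band",
                points=_band_points(c.span_start, c.span_end, r_in, r_out),
                fill=c.color or _GRAY,
                stroke=_DARK,
                stroke_width=0.5,
            )
        )
    for c in layout.chromosomes:
        mid = genomic_to_theta(layout, c.chrom_id, max(1, (c.length + 1) // 2))
        prims.append(
            Primitive("text", points=((mid, r_out + 5.0),), text=c.chrom_id,
                      fill=_DARK, font_size=11.0)
        )
        for pos, major, label in ticks.ticks[c.chrom_id]:
            th = genomic_to_theta(layout, c.chrom_id, pos)
            tick_len = 1.5 if major else 0.8
            prims.append(
                Primitive(
                    "polyline",
                    points=((th, r_out), (th, r_out + tick_len)),
                    stroke=_DARK, stroke_width=0.6 if major else 0.3,
                )
            )
    return prims


# ---------------------------------------------------------------------------
# links


def render_links(
    links: Sequence[LinkRecord],
    layout: GenomeLayout,
    settings: Optional[dict] = None,
    radius: float = 40.0,
    control_fraction: float = 0.3,
) -> tuple[list[Primitive], list[str]]:
    """Closed bézier ribbons for association links, drawn in file order.

    Each ribbon runs: arc along interval A at the link radius, cubic bézier
    to interval B (control points pulled to ``control_fraction`` of the link
    radius), arc along B, bézier back. A self-link of two identical
    intervals encloses no area and is skipped with a warning. The first
    four stored points are the four anchor angles, each at the link radius.
    """
    prims: list[Primitive] = []
    warnings: list[str] = []
    known = {c.chrom_id for c in layout.chromosomes}
    for lk in links:
        if lk.chrom_a not in known or lk.chrom_b not in known:
            warnings.append(f"link on unknown chromosome skipped: {lk.chrom_a}/{lk.chrom_b}")
            continue
        if (
            lk.chrom_a == lk.chrom_b
            and sorted((lk.start_a, lk.end_a)) == sorted((lk.start_b, lk.end_b))
        ):
            warnings.append(
                f"degenerate self-link {lk.chrom_a}:{lk.start_a}-{lk.end_a} skipped"
            )
            continue

        def th(chrom, pos):
            length = layout.span(chrom).length
            return genomic_to_theta(layout, chrom, min(max(pos, 1), length))

        a0, a1 = th(lk.chrom_a, lk.start_a), th(lk.chrom_a, lk.end_a)
        b0, b1 = th(lk.chrom_b, lk.start_b), th(lk.chrom_b, lk.end_b)
        prims.append(
            Primitive(
                "ribbon",
                points=((a0, radius), (a1, radius), (b0, radius), (b1, radius),
                        (0.0, radius * control_fraction)),
                fill=lk.color or _LINK_FILL,
                opacity=0.55,
            )
        )
    return prims, warnings


# ---------------------------------------------------------------------------
# label placement


@dataclass(frozen=True)
class PlacedLabel:
    label: str
    color: Optional[ColorSpec]
    anchor_theta: float
    placed_theta: float
    width_deg: float  # angular bounding width of the text at its radius
    leader: tuple[tuple[float, float], ...]
    radius: float


@dataclass
class LabelPlacement:
    labels: list[PlacedLabel]
    iterations: int
    warnings: list[str] = field(default_factory=list)


def _isotonic(b: list[float], w: Optional[list[float]] = None) -> tuple[list[float], int]:
    """Pool-adjacent-violators: non-decreasing fit minimizing squared error.
    Returns (fitted values, number of pool merges)."""
    weight = [1.0] * len(b) if w is None else list(w)
    merges = 0
    blocks: list[tuple[float, float]] = []  # (mean, weight)
    sizes: list[int] = []
    for bi, wi in zip(b, weight):
        mean, wt, size = bi, wi, 1
        while blocks and blocks[-1][0] > mean:
            pmean, pwt = blocks.pop()
            psize = sizes.pop()
            mean = (mean * wt + pmean * pwt) / (wt + pwt)
            wt += pwt
            size += psize
            merges += 1
        blocks.append((mean, wt))
        sizes.append(size)
    out: list[float] = []
    for (mean, _), size in zip(blocks, sizes):
        out.extend([mean] * size)
    return out, merges


def label_width_deg(label: str, font_size: float, radius: float,
                    canvas_radius_px: float = 360.0) -> float:
    """Angular bounding width of a text label at the given radius percent."""
    text_px = max(1.0, 0.62 * font_size * len(label))
    r_px = max(1.0, canvas_radius_px * radius / 100.0)
    return text_px / (2.0 * math.pi * r_px) * 360.0


def place_labels(
    tags: Sequence[RegionTagRecord],
    layout: GenomeLayout,
    overlap_weight: float = -4.0,
    radius: float = 99.0,
    font_size: float = 10.0,
    anchor_radius: float = 97.0,
    canvas_radius_px: float = 360.0,
) -> LabelPlacement:
    """Displace overlapping feature labels along the circle.

    Labels keep their angular order and are moved as little as possible
    (in the least-squares sense) subject to a minimum separation of half the
    two neighbouring label widths plus an interspace of ``2**overlap_weight``
    degrees — larger overlap weights spread labels further apart. Labels
    with no conflict stay exactly at their anchors. Deterministic; the
    number of relaxation (pooling) steps never exceeds the label count.
    """
    if not tags:
        return LabelPlacement([], 0)
    dirsign = -1.0 if layout.clockwise else 1.0

    def to_u(theta: float) -> float:
        return dirsign * (theta - layout.start_angle)

    def to_theta(u: float) -> float:
        return layout.start_angle + dirsign * u

    items = []
    for i, tag in enumerate(tags):
        length = layout.span(tag.chrom_id).length
        mid = min(max((tag.start + tag.end) // 2, 1), length)
        anchor = genomic_to_theta(layout, tag.chrom_id, mid)
        width = label_width_deg(tag.label, font_size, radius, canvas_radius_px)
        items.append((to_u(anchor), i, tag, anchor, width))
    items.sort(key=lambda it: (it[0], it[1]))  # stable in input order on ties

    pad = min(10.0, 2.0 ** overlap_weight)
    warnings = []
    total_needed = sum(it[4] for it in items) + pad * len(items)
    if total_needed > 360.0:
        warnings.append(
            f"labels need {total_needed:.1f} degrees, more than the full circle; "
            "overlaps may remain"
        )

    # Non-overlap <=> p[k+1] - p[k] >= req[k]; substitute q[k] = p[k] - offset[k]
    # with offset accumulating the separations: q must be non-decreasing.
    req = [
        (items[k][4] + items[k + 1][4]) / 2.0 + pad
        for k in range(len(items) - 1)
    ]
    offsets = [0.0]
    for r in req:
        offsets.append(offsets[-1] + r)
    b = [it[0] - off for it, off in zip(items, offsets)]
    q, iterations = _isotonic(b)
    placed_u = [qi + off for qi, off in zip(q, offsets)]

    placed = [None] * len(tags)
    for (u_anchor, i, tag, anchor_theta, width), u_new in zip(items, placed_u):
        theta_new = to_theta(u_new)
        placed[i] = PlacedLabel(
            label=tag.label,
            color=tag.color,
            anchor_theta=anchor_theta,
            placed_theta=theta_new,
            width_deg=width,
            leader=((anchor_theta, anchor_radius), (theta_new, radius - 1.0)),
            radius=radius,
        )
    return LabelPlacement(list(placed), iterations, warnings)


# ---------------------------------------------------------------------------
# composition


_CONTINUOUS = {"heatmap", "bar", "line", "point"}
_DISCRETE = {"tile", "triangle", "arrow"}


def _glyph_to_primitive(g: GlyphDatum) -> Primitive:
    if g.kind == "sector":
        return Primitive(
            "sector",
            points=_band_points(g.theta_start, g.theta_end, g.r_inner, g.r_outer),
            fill=g.fill, stroke=g.border,
            stroke_width=0.4,
        )
    if g.kind == "marker":
        return Primitive("marker", points=((g.theta_start, g.r_inner),), fill=g.fill)
    if g.kind == "polyline":
        return Primitive("polyline", points=g.points, stroke=g.border, stroke_width=1.0)
    if g.kind == "polygon":
        return Primitive("polygon", points=g.points, fill=g.fill, stroke=g.border,
                         stroke_width=0.4)
    raise ValueError(f"unknown glyph kind {g.kind!r}")


def compose(project: Project) -> RenderScene:
    """Build the full scene from a project; see module docstring for z-order."""
    s = project.settings
    layout = build_layout(
        project.skeleton,
        gap_fraction=s.get("gap_fraction", 0.005),
        start_angle=s.get("start_angle", 90.0),
        clockwise=s.get("clockwise", True),
        circularized=s.get("circularized", True),
    )
    canvas = s.get("canvas", DEFAULT_SETTINGS["canvas"])
    scene = RenderScene(
        primitives=[],
        width=canvas.get("width", 800.0),
        height=canvas.get("height", 800.0),
        mode="circular" if s.get("circularized", True) else "straight",
        start_angle=layout.start_angle,
        clockwise=layout.clockwise,
        background=fio.parse_color(canvas.get("background", "255,255,255")),
    )
    prims = scene.primitives
    prims.extend(render_skeleton(layout, s))

    # track backgrounds, then glyphs with outer tracks first
    order = sorted(
        range(len(project.tracks)),
        key=lambda i: -project.tracks[i][1].start_pos,
    )
    for i in order:
        _, spec = project.tracks[i]
        if spec.bar_fill is not None:
            for c in layout.chromosomes:
                prims.append(
                    Primitive(
                        "arc_band",
                        points=_band_points(c.span_start, c.span_end,
                                            spec.start_pos, spec.end_pos),
                        fill=spec.bar_fill,
                    )
                )
    legend_tracks = []
    for i in order:
        records, spec = project.tracks[i]
        records, warns = fio.validate_against_skeleton(records, project.skeleton)
        scene.warnings.extend(warns)
        if spec.glyph in _CONTINUOUS:
            if spec.bin is not None and spec.bin_mode != "none":
                records = bin_continuous(records, project.skeleton, spec.bin, spec.bin_mode)
            glyphs = build_continuous_glyphs(records, spec, layout)
        elif spec.glyph in _DISCRETE:
            glyphs = build_discrete_glyphs(records, spec, layout)
        else:
            raise ValueError(f"track glyph {spec.glyph!r} cannot be composed")
        prims.extend(_glyph_to_primitive(g) for g in glyphs)
        legend_tracks.append((spec, records))

    if project.links:
        links, warns = fio.validate_against_skeleton(project.links, project.skeleton)
        scene.warnings.extend(warns)
        ribbons, warns = render_links(links, layout, s, radius=s.get("link_radius", 40.0))
        scene.warnings.extend(warns)
        prims.extend(ribbons)

    if project.tags:
        tags, warns = fio.validate_against_skeleton(project.tags, project.skeleton)
        scene.warnings.extend(warns)
        lp = place_labels(
            tags, layout,
            overlap_weight=project.setting("label", "overlap_weight", default=-4.0),
            radius=project.setting("label", "radius", default=99.0),
            font_size=project.setting("label", "font_size", default=10.0),
            anchor_radius=s.get("skeleton_span", [92.0, 97.0])[1],
            canvas_radius_px=0.45 * min(scene.width, scene.height),
        )
        scene.warnings.extend(lp.warnings)
        for pl in lp.labels:
            prims.append(Primitive("leader_line", points=pl.leader, stroke=_LEADER,
                                   stroke_width=0.5))
            prims.append(
                Primitive(
                    "text",
                    points=((pl.placed_theta, pl.radius),),
                    text=pl.label,
                    fill=pl.color or _DARK,
                    font_size=project.setting("label", "font_size", default=10.0),
                )
            )

    anchors = [tuple(a) for a in s.get("legend_anchors", [])]
    legends = build_legends(legend_tracks, anchors or None)
    for i, lg in enumerate(legends):
        xy = lg.anchor if lg.anchor != (0.0, 0.0) else (scene.width - 150.0, 20.0 + 70.0 * i)
        prims.append(Primitive("legend_box", legend=lg, anchor_xy=xy))
    return scene


# ---------------------------------------------------------------------------
# export


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _svg_path(scene: RenderScene, pts, close=True) -> str:
    xy = [scene.to_xy(t, r) for t, r in pts]
    d = "M " + " L ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in xy)
    return d + (" Z" if close else "")


def _paint(fill: Optional[ColorSpec], stroke: Optional[ColorSpec],
           stroke_width: float, opacity: float) -> str:
    parts = []
    parts.append(f'fill="{fill.css()}"' if fill else 'fill="none"')
    if opacity < 1.0 and fill:
        parts.append(f'fill-opacity="{opacity:g}"')
    if stroke:
        parts.append(f'stroke="{stroke.css()}" stroke-width="{stroke_width:g}"')
    return " ".join(parts)


def _ribbon_path(scene: RenderScene, prim: Primitive) -> str:
    (a0, r), (a1, _), (b0, _), (b1, _), (_, rc) = prim.points
    p = [scene.to_xy(t, r) for t in (a0, a1, b0, b1)]
    c = {t: scene.to_xy(t, rc) for t in (a0, a1, b0, b1)}
    arc_a = [scene.to_xy(t, r) for t in _arc_thetas(a0, a1)]
    arc_b = [scene.to_xy(t, r) for t in _arc_thetas(b0, b1)]
    d = "M " + " L ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in arc_a)
    d += (
        f" C {_fmt(c[a1][0])},{_fmt(c[a1][1])}"
        f" {_fmt(c[b0][0])},{_fmt(c[b0][1])}"
        f" {_fmt(arc_b[0][0])},{_fmt(arc_b[0][1])}"
    )
    d += " L " + " L ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in arc_b[1:])
    d += (
        f" C {_fmt(c[b1][0])},{_fmt(c[b1][1])}"
        f" {_fmt(c[a0][0])},{_fmt(c[a0][1])}"
        f" {_fmt(arc_a[0][0])},{_fmt(arc_a[0][1])} Z"
    )
    return d


def _legend_svg(prim: Primitive) -> list[str]:
    lg = prim.legend
    x0, y0 = prim.anchor_xy
    rows = [f'<g class="legend">']
    rows.append(
        f'<text x="{_fmt(x0)}" y="{_fmt(y0)}" font-size="10" fill="rgb(40,40,40)">'
        f"{_esc(lg.title)}</text>"
    )
    if lg.kind == "categorical":
        for i, (label, color) in enumerate(lg.entries):
            y = y0 + 6 + 14 * i
            rows.append(
                f'<rect x="{_fmt(x0)}" y="{_fmt(y)}" width="10" height="10" '
                f'fill="{color.css()}"/>'
            )
            rows.append(
                f'<text x="{_fmt(x0 + 14)}" y="{_fmt(y + 9)}" font-size="9" '
                f'fill="rgb(40,40,40)">{_esc(label)}</text>'
            )
    else:  # color_scale: 10 swatches + endpoint labels
        for i in range(10):
            color = color_ramp(lg.ramp, i / 9.0)
            rows.append(
                f'<rect x="{_fmt(x0 + 10 * i)}" y="{_fmt(y0 + 6)}" width="10" '
                f'height="10" fill="{color.css()}"/>'
            )
        rows.append(
            f'<text x="{_fmt(x0)}" y="{_fmt(y0 + 28)}" font-size="9" '
            f'fill="rgb(40,40,40)">{lg.vmin:g}</text>'
        )
        rows.append(
            f'<text x="{_fmt(x0 + 100)}" y="{_fmt(y0 + 28)}" font-size="9" '
            f'fill="rgb(40,40,40)" text-anchor="end">{lg.vmax:g}</text>'
        )
    rows.append("</g>")
    return rows


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def scene_to_svg(scene: RenderScene) -> str:
    """Serialize a scene to SVG 1.1 text. Deterministic for a given scene."""
    w, h = scene.width, scene.height
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w:g}" height="{h:g}" viewBox="0 0 {w:g} {h:g}">',
        f'<rect x="0" y="0" width="{w:g}" height="{h:g}" '
        f'fill="{scene.background.css()}"/>',
    ]
    for prim in scene.primitives:
        paint = _paint(prim.fill, prim.stroke, prim.stroke_width, prim.opacity)
        if prim.kind in ("arc_band", "sector", "polygon"):
            out.append(f'<path d="{_svg_path(scene, prim.points)}" {paint}/>')
        elif prim.kind in ("polyline", "leader_line"):
            out.append(
                f'<path d="{_svg_path(scene, prim.points, close=False)}" '
                f'fill="none" stroke="{(prim.stroke or _DARK).css()}" '
                f'stroke-width="{prim.stroke_width:g}"/>'
            )
        elif prim.kind == "marker":
            x, y = scene.to_xy(*prim.points[0])
            out.append(
                f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{prim.marker_size:g}" '
                f'fill="{(prim.fill or _DARK).css()}"/>'
            )
        elif prim.kind == "ribbon":
            out.append(f'<path d="{_ribbon_path(scene, prim)}" {paint}/>')
        elif prim.kind == "text":
            x, y = scene.to_xy(*prim.points[0])
            out.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{prim.font_size:g}" '
                f'text-anchor="middle" fill="{(prim.fill or _DARK).css()}">'
                f"{_esc(prim.text or '')}</text>"
            )
        elif prim.kind == "legend_box":
            out.extend(_legend_svg(prim))
        else:
            raise ValueError(f"unknown primitive kind {prim.kind!r}")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _export_png(scene: RenderScene, path: Union[str, Path], dpi: float) -> None:
    import matplotlib
    from matplotlib.figure import Figure
    from matplotlib.patches import Circle as MplCircle, PathPatch, Polygon as MplPolygon
    from matplotlib.path import Path as MplPath

    fig = Figure(figsize=(scene.width / 100.0, scene.height / 100.0))
    ax = fig.add_axes((0, 0, 1, 1))
    ax.set_xlim(0, scene.width)
    ax.set_ylim(scene.height, 0)  # SVG-style y-down
    ax.axis("off")
    ax.add_patch(
        MplPolygon(
            [(0, 0), (scene.width, 0), (scene.width, scene.height), (0, scene.height)],
            closed=True, facecolor=_rgb01(scene.background), edgecolor="none",
        )
    )

    for prim in scene.primitives:
        if prim.kind in ("arc_band", "sector", "polygon"):
            xy = [scene.to_xy(t, r) for t, r in prim.points]
            ax.add_patch(
                MplPolygon(
                    xy, closed=True,
                    facecolor=_rgb01(prim.fill) if prim.fill else "none",
                    edgecolor=_rgb01(prim.stroke) if prim.stroke else "none",
                    linewidth=prim.stroke_width, alpha=prim.opacity,
                )
            )
        elif prim.kind in ("polyline", "leader_line"):
            xy = [scene.to_xy(t, r) for t, r in prim.points]
            ax.plot(
                [p[0] for p in xy], [p[1] for p in xy],
                color=_rgb01(prim.stroke or _DARK), linewidth=prim.stroke_width,
            )
        elif prim.kind == "marker":
            x, y = scene.to_xy(*prim.points[0])
            ax.add_patch(MplCircle((x, y), prim.marker_size,
                                   facecolor=_rgb01(prim.fill or _DARK), edgecolor="none"))
        elif prim.kind == "ribbon":
            (a0, r), (a1, _), (b0, _), (b1, _), (_, rc) = prim.points
            verts, codes = [], []
            arc_a = [scene.to_xy(t, r) for t in _arc_thetas(a0, a1)]
            arc_b = [scene.to_xy(t, r) for t in _arc_thetas(b0, b1)]
            c = {t: scene.to_xy(t, rc) for t in (a0, a1, b0, b1)}
            verts.append(arc_a[0]); codes.append(MplPath.MOVETO)
            for p in arc_a[1:]:
                verts.append(p); codes.append(MplPath.LINETO)
            verts.extend([c[a1], c[b0], arc_b[0]]); codes.extend([MplPath.CURVE4] * 3)
            for p in arc_b[1:]:
                verts.append(p); codes.append(MplPath.LINETO)
            verts.extend([c[b1], c[a0], arc_a[0]]); codes.extend([MplPath.CURVE4] * 3)
            ax.add_patch(
                PathPatch(MplPath(verts, codes), facecolor=_rgb01(prim.fill or _LINK_FILL),
                          edgecolor="none", alpha=prim.opacity)
            )
        elif prim.kind == "text":
            x, y = scene.to_xy(*prim.points[0])
            ax.text(x, y, prim.text or "", fontsize=prim.font_size,
                    ha="center", va="center", color=_rgb01(prim.fill or _DARK))
        elif prim.kind == "legend_box":
            lg, (x0, y0) = prim.legend, prim.anchor_xy
            ax.text(x0, y0, lg.title, fontsize=8, color=_rgb01(_DARK))
            if lg.kind == "categorical":
                for i, (label, color) in enumerate(lg.entries):
                    y = y0 + 6 + 14 * i
                    ax.add_patch(MplPolygon(
                        [(x0, y), (x0 + 10, y), (x0 + 10, y + 10), (x0, y + 10)],
                        closed=True, facecolor=_rgb01(color), edgecolor="none"))
                    ax.text(x0 + 14, y + 9, label, fontsize=7, color=_rgb01(_DARK))
            else:
                for i in range(10):
                    color = color_ramp(lg.ramp, i / 9.0)
                    x = x0 + 10 * i
                    ax.add_patch(MplPolygon(
                        [(x, y0 + 6), (x + 10, y0 + 6), (x + 10, y0 + 16), (x, y0 + 16)],
                        closed=True, facecolor=_rgb01(color), edgecolor="none"))
    fig.savefig(path, dpi=dpi, format="png")


def _rgb01(c: ColorSpec):
    return (c.r / 255.0, c.g / 255.0, c.b / 255.0)


def export(scene: RenderScene, path: Union[str, Path], format: Optional[str] = None,
           dpi: float = 100.0) -> Path:
    """Write the scene to ``path`` as SVG (vector) or PNG (bitmap).

    SVG output depends only on the scene contents: exporting the same scene
    twice produces byte-identical files. PNG pixel dimensions scale with
    ``dpi`` (canvas units are hundredths of an inch).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        path.write_bytes(scene_to_svg(scene).encode("utf-8"))
    elif fmt == "png":
        _export_png(scene, path, dpi)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected svg or png)")
    return path
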