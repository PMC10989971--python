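"""Genomic-to-plot coordinate mapping.

A :class:`GenomeLayout` assigns every chromosome an angular span on a circle
(circular mode) or an x-extent on a shared axis (straight mode). Span widths
are proportional to chromosome length; equal gaps separate consecutive
chromosomes, with one gap after the last so the circle closes. Radii are
expressed on a 0-100 percent scale so track spans use the same units the
``Start Pos`` / ``End Pos`` track settings expose.

Angles are degrees. With ``clockwise=True`` (the default, the conventional
Circos orientation) angles decrease as genomic position advances, starting
from ``start_angle`` at 12 o'clock (90 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .formats_io import ColorSpec, SkeletonRecord

__all__ = [
    "ChromSpan",
    "GenomeLayout",
    "TickSet",
    "build_layout",
    "genomic_to_theta",
    "polar_to_xy",
    "make_ticks",
]

DEFAULT_GAP_FRACTION = 0.005
DEFAULT_START_ANGLE = 90.0


@dataclass(frozen=True)
class ChromSpan:
    chrom_id: str
    length: int
    color: Optional[ColorSpec]
    span_start: float  # plot angle (deg) at genomic position 1
    span_end: float    # plot angle (deg) at genomic position `length`


@dataclass(frozen=True)
class GenomeLayout:
    chromosomes: tuple[ChromSpan, ...]
    gap_fraction: float
    circularized: bool
    start_angle: float
    clockwise: bool

    def span(self, chrom_id: str) -> ChromSpan:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(f"unknown chromosome {chrom_id!r}")

    @property
    def chrom_ids(self) -> list[str]:
        return [c.chrom_id for c in self.chromosomes]


@dataclass(frozen=True)
class TickSet:
    """Per-chromosome tick positions with a single label unit for the plot."""

    ticks: dict[str, list[tuple[int, bool, str]]]  # (genomic pos, major?, label)
    unit: str  # "Mb" or "kb"


def build_layout(
    skeleton: Sequence[SkeletonRecord],
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    start_angle: float = DEFAULT_START_ANGLE,
    clockwise: bool = True,
    circularized: bool = True,
) -> GenomeLayout:
    """Allocate angular (or linear) spans to the skeleton's chromosomes.

    ``gap_fraction`` is the fraction of the full 360 degrees consumed by each
    of the ``n`` inter-chromosome gaps, so chromosome ``i`` receives
    ``(1 - n*gap_fraction) * 360 * length_i / total_length`` degrees.
    """
    if not skeleton:
        raise ValueError("skeleton is empty")
    n = len(skeleton)
    if not (0 <= gap_fraction < 0.5):
        raise ValueError(f"gap_fraction {gap_fraction} outside [0, 0.5)")
    if n * gap_fraction * 360.0 >= 0.9 * 360.0:
        raise ValueError("gaps consume more than 90% of the circle")
    total = sum(s.length for s in skeleton)
    if total <= 0:
        raise ValueError("zero total chromosome length")
    gap_deg = gap_fraction * 360.0
    usable = 360.0 - n * gap_deg
    direction = -1.0 if clockwise else 1.0
    spans = []
    cursor = start_angle
    for s in skeleton:
        width = usable * s.length / total
        spans.append(
            ChromSpan(s.chrom_id, s.length, s.color, cursor, cursor + direction * width)
        )
        cursor += direction * (width + gap_deg)
    return GenomeLayout(tuple(spans), gap_fraction, circularized, start_angle, clockwise)


def genomic_to_theta(layout: GenomeLayout, chrom_id: str, pos: float) -> float:
    """Map a genomic position (1-based bp) to a plot angle in degrees.

    Affine within the chromosome: position 1 maps to ``span_start``, the
    chromosome length to ``span_end``. In straight mode the returned value is
    the x coordinate on the shared axis (same units).
    """
    c = layout.span(chrom_id)
    if not (1 <= pos <= c.length):
        raise ValueError(f"position {pos} outside [1, {c.length}] on {chrom_id}")
    if c.length == 1:
        return c.span_start
    frac = (pos - 1) / (c.length - 1)
    return c.span_start + frac * (c.span_end - c.span_start)


def polar_to_xy(theta: float, radius: float, straight: bool = False) -> tuple[float, float]:
    """Standard polar transform; in straight mode theta becomes x, radius y."""
    if straight:
        return (theta, radius)
    t = math.radians(theta)
    return (radius * math.cos(t), radius * math.sin(t))


_NICE_STEPS = (1.0, 2.0, 5.0)


def _nice_spacing(length: int, target_major_count: int) -> int:
    """Pick a 1/2/5 x 10^k bp spacing giving about target_major_count majors."""
    if target_major_count < 1:
        target_major_count = 1
    raw = length / target_major_count
    best, best_err = 1, float("inf")
    k = 0
    while 10 ** k <= length * 10:
        for s in _NICE_STEPS:
            spacing = int(s * 10 ** k)
            if spacing < 1:
                continue
            err = abs(length / spacing - target_major_count)
            if err < best_err:
                best, best_err = spacing, err
        k += 1
    return best


def make_ticks(layout: GenomeLayout, target_major_count: int = 5) -> TickSet:
    """Generate major/minor tick positions with nice-number spacing.

    The major spacing (1/2/5 x 10^k bp) is chosen on the longest chromosome
    to produce roughly ``target_major_count`` majors, then applied to every
    chromosome; 4 minor ticks subdivide each major interval. Labels use Mb
    when the longest chromosome is at least 2 Mb, kb otherwise.
    """
    longest = max(c.length for c in layout.chromosomes)
    spacing = _nice_spacing(longest, target_major_count)
    unit, unit_div = ("Mb", 1e6) if longest >= 2_000_000 else ("kb", 1e3)
    minor = spacing / 5.0
    ticks: dict[str, list[tuple[int, bool, str]]] = {}
    for c in layout.chromosomes:
        rows: list[tuple[int, bool, str]] = []
        if c.length == 1:
            ticks[c.chrom_id] = [(1, True, f"{1 / unit_div:g}")]
            continue
        pos = 0.0
        while pos <= c.length:
            p = max(1, int(round(pos)))
            is_major = (pos / minor) % 5 == 0
            label = f"{pos / unit_div:g}" if is_major else ""
            if not rows or rows[-1][0] != p:
                rows.append((p, is_major, label))
            pos += minor
        ticks[c.chrom_id] = rows
    return TickSet(ticks, unit)
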