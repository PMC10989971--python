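"""Readers and writers for the five tab-delimited track-data categories.

All track inputs are plain TSV. Coordinates are 1-based inclusive, matching
the GFF convention; they are kept 1-based in memory and only converted to
half-open intervals inside binning arithmetic. Blank lines and lines whose
first non-whitespace character is ``#`` are skipped everywhere. Every parse
error names the offending 1-based line number.

The five categories:

* chromosome skeleton  — ``chrom  length  [rgb]``
* region tags          — ``chrom  label  start  end  [rgb]``
* links (associations) — ``chromA startA endA chromB startB endB [rgb] [ignored]``
* continuous values    — ``chrom  start  end  value``
* discrete features    — ``chrom  start  end  rgb  [category]``

Link files tolerate the 8-column MCScanX-derived dialect whose last column
(a homologous gene pair) is always dropped; a 7th column that does not parse
as a colour is likewise treated as that ignorable annotation column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Union

__all__ = [
    "TrackFormatError",
    "ColorSpec",
    "SkeletonRecord",
    "RegionTagRecord",
    "LinkRecord",
    "ContinuousRecord",
    "DiscreteRecord",
    "parse_color",
    "parse_skeleton",
    "parse_region_tags",
    "parse_links",
    "parse_continuous",
    "parse_discrete",
    "write_skeleton",
    "write_region_tags",
    "write_links",
    "write_continuous",
    "write_discrete",
    "validate_against_skeleton",
    "save_project",
    "load_project",
]


class TrackFormatError(ValueError):
    """Malformed track file; ``line_no`` is 1-based."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ColorSpec:
    """An RGB colour as given in a track file's ``RGB Code`` column."""

    r: int
    g: int
    b: int
    source_text: str = ""

    def __post_init__(self):
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0 <= int(v) <= 255):
                raise ValueError(f"colour channel {name}={v} outside [0, 255]")

    @property
    def text(self) -> str:
        """Canonical decimal-triplet form, e.g. ``"255,0,0"``."""
        return f"{self.r},{self.g},{self.b}"

    @property
    def hex(self) -> str:
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}"

    def css(self, alpha: Optional[float] = None) -> str:
        if alpha is None:
            return f"rgb({self.r},{self.g},{self.b})"
        return f"rgba({self.r},{self.g},{self.b},{alpha:g})"

    def __eq__(self, other):
        if not isinstance(other, ColorSpec):
            return NotImplemented
        return (self.r, self.g, self.b) == (other.r, other.g, other.b)

    def __hash__(self):
        return hash((self.r, self.g, self.b))


@dataclass(frozen=True)
class SkeletonRecord:
    chrom_id: str
    length: int
    color: Optional[ColorSpec] = None

    def __post_init__(self):
        if not self.chrom_id:
            raise ValueError("empty chromosome id")
        if self.length < 1:
            raise ValueError(f"chromosome length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class RegionTagRecord:
    chrom_id: str
    label: str
    start: int
    end: int
    color: Optional[ColorSpec] = None


@dataclass(frozen=True)
class LinkRecord:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    color: Optional[ColorSpec] = None


@dataclass(frozen=True)
class ContinuousRecord:
    chrom_id: str
    start: int
    end: int
    value: float


@dataclass(frozen=True)
class DiscreteRecord:
    """Coloured interval; ``start > end`` in the file marks a reversed
    (direction-flipped) feature and is preserved, not swapped."""

    chrom_id: str
    start: int
    end: int
    color: ColorSpec
    category: Optional[str] = None
    reversed: bool = False

    @property
    def lo(self) -> int:
        return min(self.start, self.end)

    @property
    def hi(self) -> int:
        return max(self.start, self.end)


_HEX_RE = re.compile(r"^#([0-9a-fA-F]{6})$")
_TRIPLET_RE = re.compile(r"^(\d{1,3}),(\d{1,3}),(\d{1,3})$")


def parse_color(token: str, line_no: Optional[int] = None) -> ColorSpec:
    """Parse an RGB code: decimal triplet ``r,g,b`` or hex ``#RRGGBB``."""
    token = token.strip()
    if not token:
        raise TrackFormatError("empty colour token", line_no)
    m = _HEX_RE.match(token)
    if m:
        v = int(m.group(1), 16)
        return ColorSpec((v >> 16) & 0xFF, (v >> 8) & 0xFF, v & 0xFF, token)
    m = _TRIPLET_RE.match(token)
    if m:
        r, g, b = (int(x) for x in m.groups())
        if max(r, g, b) > 255:
            raise TrackFormatError(f"colour channel out of range in {token!r}", line_no)
        return ColorSpec(r, g, b, token)
    raise TrackFormatError(f"malformed colour token {token!r}", line_no)


def _try_color(token: str) -> Optional[ColorSpec]:
    try:
        return parse_color(token)
    except (TrackFormatError, ValueError):
        return None


def _iter_data_lines(lines: Union[str, Iterable[str]]) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields) for non-blank, non-comment lines.

    Accepts a path-like string pointing at a file, a newline-joined blob, or an
    iterable of lines.
    """
    if isinstance(lines, str):
        import os

        if "\n" not in lines and "\t" not in lines and os.path.exists(lines):
            with open(lines, "rt") as fh:
                yield from _iter_data_lines(list(fh))
            return
        lines = lines.splitlines()
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line.split("\t")


def _int_field(token: str, what: str, line_no: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise TrackFormatError(f"non-integer {what} {token!r}", line_no) from None


def parse_skeleton(lines: Union[str, Iterable[str]]) -> list[SkeletonRecord]:
    """Parse the chromosome-skeleton table (ID, length[, RGB])."""
    records: list[SkeletonRecord] = []
    seen: set[str] = set()
    for ln, fields in _iter_data_lines(lines):
        if len(fields) < 2:
            raise TrackFormatError("skeleton lines need at least 2 columns", ln)
        chrom, length_s = fields[0].strip(), fields[1].strip()
        if not chrom:
            raise TrackFormatError("empty chromosome id", ln)
        if chrom in seen:
            raise TrackFormatError(f"duplicate chromosome id {chrom!r}", ln)
        length = _int_field(length_s, "chromosome length", ln)
        if length < 1:
            raise TrackFormatError(f"chromosome length must be positive, got {length}", ln)
        color = parse_color(fields[2], ln) if len(fields) >= 3 and fields[2].strip() else None
        seen.add(chrom)
        records.append(SkeletonRecord(chrom, length, color))
    if not records:
        raise TrackFormatError("no skeleton records found")
    return records


def parse_region_tags(lines: Union[str, Iterable[str]]) -> list[RegionTagRecord]:
    """Parse region tags (ID, label, start, end[, RGB])."""
    records = []
    for ln, fields in _iter_data_lines(lines):
        if len(fields) < 4:
            raise TrackFormatError("region-tag lines need at least 4 columns", ln)
        chrom, label = fields[0].strip(), fields[1].strip()
        start = _int_field(fields[2], "start coordinate", ln)
        end = _int_field(fields[3], "end coordinate", ln)
        color = parse_color(fields[4], ln) if len(fields) >= 5 and fields[4].strip() else None
        records.append(RegionTagRecord(chrom, label, start, end, color))
    return records


def parse_links(lines: Union[str, Iterable[str]]) -> list[LinkRecord]:
    """Parse association links (6, 7 or 8 tab-separated columns).

    Column 7, when present, is a colour if it parses as one and an ignorable
    annotation otherwise; column 8 (MCScanX homologous gene pair) is always
    dropped. File order is preserved: drawing order equals line order.
    """
    records = []
    for ln, fields in _iter_data_lines(lines):
        if len(fields) < 6 or len(fields) > 8:
            raise TrackFormatError(
                f"link lines need 6, 7 or 8 columns, got {len(fields)}", ln
            )
        chrom_a = fields[0].strip()
        start_a = _int_field(fields[1], "start coordinate", ln)
        end_a = _int_field(fields[2], "end coordinate", ln)
        chrom_b = fields[3].strip()
        start_b = _int_field(fields[4], "start coordinate", ln)
        end_b = _int_field(fields[5], "end coordinate", ln)
        color: Optional[ColorSpec] = None
        if len(fields) == 8:
            # col 7 is the colour, col 8 the ignored gene pair
            if fields[6].strip():
                color = parse_color(fields[6], ln)
        elif len(fields) == 7:
            color = _try_color(fields[6])  # else: ignorable annotation column
        records.append(LinkRecord(chrom_a, start_a, end_a, chrom_b, start_b, end_b, color))
    return records


def parse_continuous(lines: Union[str, Iterable[str]]) -> list[ContinuousRecord]:
    """Parse continuous statistics (ID, start, end, value)."""
    records = []
    for ln, fields in _iter_data_lines(lines):
        if len(fields) < 4:
            raise TrackFormatError("continuous lines need 4 columns", ln)
        chrom = fields[0].strip()
        start = _int_field(fields[1], "start coordinate", ln)
        end = _int_field(fields[2], "end coordinate", ln)
        try:
            value = float(fields[3])
        except ValueError:
            raise TrackFormatError(f"non-numeric value {fields[3]!r}", ln) from None
        if value != value or value in (float("inf"), float("-inf")):
            raise TrackFormatError("value must be finite", ln)
        records.append(ContinuousRecord(chrom, start, end, value))
    return records


def parse_discrete(lines: Union[str, Iterable[str]]) -> list[DiscreteRecord]:
    """Parse discrete features (ID, start, end, RGB[, category]).

    ``start > end`` flags the record as reversed (used by the arrow glyph);
    the raw coordinates are kept as written.
    """
    records = []
    for ln, fields in _iter_data_lines(lines):
        if len(fields) < 4:
            raise TrackFormatError("discrete lines need at least 4 columns", ln)
        chrom = fields[0].strip()
        start = _int_field(fields[1], "start coordinate", ln)
        end = _int_field(fields[2], "end coordinate", ln)
        color = parse_color(fields[3], ln)
        category = fields[4].strip() if len(fields) >= 5 and fields[4].strip() else None
        records.append(
            DiscreteRecord(chrom, start, end, color, category, reversed=start > end)
        )
    return records


# ---------------------------------------------------------------------------
# writers — canonical TSV (tabs, decimal-triplet colours)


def _color_cols(color: Optional[ColorSpec]) -> list[str]:
    return [color.text] if color is not None else []


def write_skeleton(records: Sequence[SkeletonRecord]) -> str:
    return "".join(
        "\t".join([r.chrom_id, str(r.length)] + _color_cols(r.color)) + "\n"
        for r in records
    )


def write_region_tags(records: Sequence[RegionTagRecord]) -> str:
    return "".join(
        "\t".join([r.chrom_id, r.label, str(r.start), str(r.end)] + _color_cols(r.color))
        + "\n"
        for r in records
    )


def write_links(records: Sequence[LinkRecord]) -> str:
    return "".join(
        "\t".join(
            [r.chrom_a, str(r.start_a), str(r.end_a), r.chrom_b, str(r.start_b), str(r.end_b)]
            + _color_cols(r.color)
        )
        + "\n"
        for r in records
    )


def write_continuous(records: Sequence[ContinuousRecord]) -> str:
    return "".join(
        "\t".join([r.chrom_id, str(r.start), str(r.end), repr(float(r.value))]) + "\n"
        for r in records
    )


def write_discrete(records: Sequence[DiscreteRecord]) -> str:
    lines = []
    for r in records:
        cols = [r.chrom_id, str(r.start), str(r.end), r.color.text]
        if r.category is not None:
            cols.append(r.category)
        lines.append("\t".join(cols) + "\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# skeleton validation


def validate_against_skeleton(records, skeleton: Sequence[SkeletonRecord]):
    """Drop records on unknown chromosomes and clip coordinates to [1, length].

    Returns ``(validated_records, warnings)``. Works on any of the record
    types above; links are checked on both of their intervals. Reversed
    discrete records keep their orientation when clipped.
    """
    lengths = {s.chrom_id: s.length for s in skeleton}
    out = []
    warnings: list[str] = []

    def clip(chrom: str, pos: int) -> int:
        return max(1, min(pos, lengths[chrom]))

    for rec in records:
        if isinstance(rec, LinkRecord):
            if rec.chrom_a not in lengths or rec.chrom_b not in lengths:
                missing = rec.chrom_a if rec.chrom_a not in lengths else rec.chrom_b
                warnings.append(f"dropped link on unknown chromosome {missing!r}")
                continue
            ca, cb = rec.chrom_a, rec.chrom_b
            clipped = replace(
                rec,
                start_a=clip(ca, rec.start_a),
                end_a=clip(ca, rec.end_a),
                start_b=clip(cb, rec.start_b),
                end_b=clip(cb, rec.end_b),
            )
            if clipped != rec:
                warnings.append(f"clipped link {ca}:{rec.start_a}-{rec.end_a}")
            out.append(clipped)
            continue
        chrom = rec.chrom_id
        if chrom not in lengths:
            warnings.append(f"dropped record on unknown chromosome {chrom!r}")
            continue
        clipped = replace(rec, start=clip(chrom, rec.start), end=clip(chrom, rec.end))
        if clipped != rec:
            warnings.append(f"clipped {chrom}:{rec.start}-{rec.end} to chromosome bounds")
        out.append(clipped)
    return out, warnings


# save_project / load_project live in circleplot.project and are re-exported
# here so all table+bundle persistence is reachable from one module.
from .project import load_project, save_project  # noqa: E402,F401
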