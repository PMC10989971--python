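"""Upstream per-window genome statistics feeding the track formats.

These are the data-preparation kernels a Circos figure is usually built
from: sequence lengths for the skeleton, sliding-window base composition
(GC content, GC skew, N-ratio), per-window feature/read/variant counts from
GFF3/GTF, SAM and VCF, gene-position extraction for text tags, and a
deterministic categorical colour generator.

Counting conventions (chosen so tiling-window totals are exactly
conservative): a feature, alignment or variant belongs to the window
containing its START position. SAM counting excludes unmapped (0x4),
secondary (0x100) and supplementary (0x800) records. GC content is computed
over called bases only (the denominator excludes N), GC skew is the
standard (G - C) / (G + C), and any character outside ACGT (case
insensitive) counts as unknown.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pysam
from Bio import SeqIO
from gffutils.iterators import DataIterator

from .formats_io import (
    ColorSpec,
    ContinuousRecord,
    RegionTagRecord,
    SkeletonRecord,
)

__all__ = [
    "WindowSpec",
    "WindowComposition",
    "iter_windows",
    "fasta_lengths",
    "window_composition",
    "gene_density",
    "coverage_bins",
    "vcf_bins",
    "gene_positions",
    "discrete_color_scheme",
    "bin_continuous",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding (step < window) or tiling (step == window) window grid, bp."""

    window: int
    step: Optional[int] = None

    def __post_init__(self):
        step = self.step if self.step is not None else self.window
        if self.window < 1 or step < 1:
            raise ValueError("window and step must be positive")
        object.__setattr__(self, "step", step)

    @property
    def tiling(self) -> bool:
        return self.step == self.window


def iter_windows(length: int, spec: WindowSpec):
    """Yield 1-based inclusive (start, end) windows covering [1, length].

    The final window is clipped at the chromosome end and kept even when
    partial. Window starts are 1, 1+step, 1+2*step, ...
    """
    start = 1
    while start <= length:
        yield start, min(start + spec.window - 1, length)
        if start + spec.window - 1 >= length:
            break
        start += spec.step
    # a window is emitted even when length < window


class WindowComposition(NamedTuple):
    gc_content: list[ContinuousRecord]
    gc_skew: list[ContinuousRecord]
    n_ratio: list[ContinuousRecord]


def fasta_lengths(fasta: str) -> list[SkeletonRecord]:
    """Sequence lengths in file order — the chromosome-skeleton table."""
    records = []
    seen = set()
    for rec in SeqIO.parse(fasta, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {fasta}")
        seen.add(rec.id)
        records.append(SkeletonRecord(rec.id, len(rec.seq)))
    if not records:
        raise ValueError(f"no sequences found in {fasta}")
    return records


# base classification lookup: index by uppercase byte
_BASE_LUT = np.zeros((256, 5), dtype=np.int64)  # columns: A C G T N-or-other
for i in range(256):
    _BASE_LUT[i, 4] = 1
for col, chars in enumerate("ACGT"):
    for ch in (chars, chars.lower()):
        _BASE_LUT[ord(ch), 4] = 0
        _BASE_LUT[ord(ch), col] = 1


def window_composition(fasta: str, spec: WindowSpec) -> WindowComposition:
    """Sliding-window GC content, GC skew and N-ratio for every sequence.

    Per window: ``n_ratio = #unknown / window_size``,
    ``gc_content = (#G + #C) / (#A + #C + #G + #T)`` (0 when the window has
    no called base), ``gc_skew = (#G - #C) / (#G + #C)`` (0 when G + C = 0).
    """
    gc_rows: list[ContinuousRecord] = []
    skew_rows: list[ContinuousRecord] = []
    n_rows: list[ContinuousRecord] = []
    any_seq = False
    for rec in SeqIO.parse(fasta, "fasta"):
        any_seq = True
        seq = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
        counts = _BASE_LUT[seq]  # (L, 5)
        cum = np.zeros((len(seq) + 1, 5), dtype=np.int64)
        np.cumsum(counts, axis=0, out=cum[1:])
        for start, end in iter_windows(len(seq), spec):
            a, c, g, t, n = cum[end] - cum[start - 1]
            size = end - start + 1
            called = a + c + g + t
            gc = (g + c) / called if called else 0.0
            skew = (g - c) / (g + c) if (g + c) else 0.0
            if not called:
                log.warning("window %s:%d-%d has no called base", rec.id, start, end)
            gc_rows.append(ContinuousRecord(rec.id, start, end, gc))
            skew_rows.append(ContinuousRecord(rec.id, start, end, skew))
            n_rows.append(ContinuousRecord(rec.id, start, end, n / size))
    if not any_seq:
        raise ValueError(f"no sequences found in {fasta}")
    return WindowComposition(gc_rows, skew_rows, n_rows)


def _window_grid(lengths: dict[str, int], spec: WindowSpec):
    """Per-chromosome window list plus a start-position -> window index map."""
    grids = {}
    for chrom, length in lengths.items():
        grids[chrom] = list(iter_windows(length, spec))
    return grids


def _count_starts(
    positions: Iterable[tuple[str, int]],
    lengths: dict[str, int],
    spec: WindowSpec,
    what: str,
) -> list[ContinuousRecord]:
    """Count items whose (chrom, start) falls in each window."""
    grids = _window_grid(lengths, spec)
    counts = {chrom: np.zeros(len(ws), dtype=np.int64) for chrom, ws in grids.items()}
    for chrom, pos in positions:
        if chrom not in grids:
            log.warning("skipping %s on unknown chromosome %r", what, chrom)
            continue
        if not (1 <= pos <= lengths[chrom]):
            log.warning("skipping %s at out-of-range position %s:%d", what, chrom, pos)
            continue
        for i, (s, e) in enumerate(grids[chrom]):
            if s <= pos <= e:
                counts[chrom][i] += 1
                if spec.tiling:
                    break  # windows are disjoint
    rows = []
    for chrom, ws in grids.items():
        for (s, e), v in zip(ws, counts[chrom]):
            rows.append(ContinuousRecord(chrom, s, e, float(v)))
    return rows


def _lengths_from(skeleton: Optional[Sequence[SkeletonRecord]]) -> Optional[dict[str, int]]:
    if skeleton is None:
        return None
    return {s.chrom_id: s.length for s in skeleton}


def gene_density(
    gff_or_gtf: str,
    spec: WindowSpec,
    feature_type: str = "gene",
    skeleton: Optional[Sequence[SkeletonRecord]] = None,
) -> list[ContinuousRecord]:
    """Per-window count of annotation features, keyed on feature start.

    Windows are laid over the skeleton when one is given; otherwise each
    chromosome's extent is taken as the maximum feature end seen on it.
    """
    feats = [
        (f.seqid, int(f.start))
        for f in DataIterator(gff_or_gtf)
        if f.featuretype == feature_type
    ]
    lengths = _lengths_from(skeleton)
    if lengths is None:
        lengths = {}
        for f in DataIterator(gff_or_gtf):
            if f.featuretype == feature_type:
                lengths[f.seqid] = max(lengths.get(f.seqid, 0), int(f.end))
    return _count_starts(feats, lengths, spec, "feature")


def coverage_bins(
    sam: str,
    spec: WindowSpec,
    skeleton: Optional[Sequence[SkeletonRecord]] = None,
) -> list[ContinuousRecord]:
    """Per-window count of primary mapped alignments by leftmost position.

    Unmapped, secondary and supplementary records are excluded. References
    present in the SAM header but absent from the skeleton are skipped with
    a warning.
    """
    positions = []
    with pysam.AlignmentFile(sam, "r", check_sq=False) as af:
        header_lengths = {name: af.get_reference_length(name) for name in af.references}
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            positions.append((aln.reference_name, aln.reference_start + 1))
    lengths = _lengths_from(skeleton) or header_lengths
    for name in header_lengths:
        if name not in lengths:
            log.warning("reference %r in SAM header absent from skeleton; skipped", name)
    return _count_starts(positions, lengths, spec, "alignment")


def vcf_bins(
    vcf: str,
    spec: WindowSpec,
    skeleton: Optional[Sequence[SkeletonRecord]] = None,
) -> list[ContinuousRecord]:
    """Per-window count of variant records by POS. All records count
    regardless of the FILTER column."""
    positions = []
    contig_lengths: dict[str, int] = {}
    with pysam.VariantFile(vcf) as vf:
        for name, contig in vf.header.contigs.items():
            if contig.length:
                contig_lengths[name] = contig.length
        for rec in vf:
            positions.append((rec.chrom, rec.pos))
    lengths = _lengths_from(skeleton) or contig_lengths
    if not lengths:
        # no skeleton and no ##contig lengths: fall back to observed maxima
        for chrom, pos in positions:
            lengths[chrom] = max(lengths.get(chrom, 0), pos)
    return _count_starts(positions, lengths, spec, "variant")


def gene_positions(
    gff_or_gtf: str, id_list: Sequence[str]
) -> tuple[list[RegionTagRecord], list[str]]:
    """Extract genomic regions for the requested gene identifiers.

    Matches GFF3 ``ID=`` / ``Name=`` attributes and GTF ``gene_id``. Output
    preserves the order of ``id_list``; identifiers not found are reported in
    the returned warning list rather than raising.
    """
    found: dict[str, RegionTagRecord] = {}
    wanted = set(id_list)
    for f in DataIterator(gff_or_gtf):
        for key in ("ID", "Name", "gene_id"):
            for ident in f.attributes.get(key, []):
                if ident in wanted and ident not in found:
                    found[ident] = RegionTagRecord(f.seqid, ident, int(f.start), int(f.end))
    records = [found[i] for i in id_list if i in found]
    warnings = [f"id {i!r} not found in annotation" for i in id_list if i not in found]
    return records, warnings


def discrete_color_scheme(n: int) -> list[ColorSpec]:
    """``n`` visually distinct colours: hues evenly spaced over the wheel at
    fixed saturation 0.65 and value 0.85. Deterministic in ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    colors = []
    for i in range(n):
        r, g, b = colorsys.hsv_to_rgb(i / n, 0.65, 0.85)
        colors.append(ColorSpec(round(r * 255), round(g * 255), round(b * 255)))
    return colors


_BIN_MODES = ("none", "count", "sum", "mean", "max", "min")


def bin_continuous(
    records: Sequence[ContinuousRecord],
    skeleton: Sequence[SkeletonRecord],
    spec: WindowSpec,
    mode: str = "none",
) -> list[ContinuousRecord]:
    """Re-bin continuous records onto a window grid.

    ``mode="none"`` passes records through unchanged (data already windowed
    upstream). Otherwise each record is assigned to the window containing its
    interval midpoint and aggregated; empty windows get 0 for count/sum and
    are omitted for mean/max/min.
    """
    if mode not in _BIN_MODES:
        raise ValueError(f"unknown bin mode {mode!r}; expected one of {_BIN_MODES}")
    if mode == "none":
        return list(records)
    lengths = {s.chrom_id: s.length for s in skeleton}
    grids = _window_grid(lengths, spec)
    bucket: dict[tuple[str, int], list[float]] = {}
    for rec in records:
        if rec.chrom_id not in grids:
            log.warning("skipping record on unknown chromosome %r", rec.chrom_id)
            continue
        mid = (rec.start + rec.end) // 2  # integer midpoint so it lands in a window
        for i, (s, e) in enumerate(grids[rec.chrom_id]):
            if s <= mid <= e:
                bucket.setdefault((rec.chrom_id, i), []).append(rec.value)
                if spec.tiling:
                    break
    out = []
    for chrom, ws in grids.items():
        for i, (s, e) in enumerate(ws):
            vals = bucket.get((chrom, i), [])
            if mode == "count":
                out.append(ContinuousRecord(chrom, s, e, float(len(vals))))
            elif mode == "sum":
                out.append(ContinuousRecord(chrom, s, e, float(sum(vals))))
            elif vals:  # mean / max / min omit empty windows
                agg = {"mean": lambda v: sum(v) / len(v), "max": max, "min": min}[mode]
                out.append(ContinuousRecord(chrom, s, e, float(agg(vals))))
    return out
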