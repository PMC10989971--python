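"""Deterministic synthetic inputs with known ground truth.

Every generator emulates one of the input kinds a Circos figure is built
from — a genome FASTA with controlled base composition, a GFF3 gene
annotation, a SAM alignment file, a VCF variant file, MCScanX-style link
tables and QTL-style discrete tables — and emits the exact ground truth
alongside (window compositions, per-bin counts), always computed from the
realized records by an independent brute-force scan, never from the
sampling distribution. Identical seeds give identical bytes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import ColorSpec, ContinuousRecord, DiscreteRecord, LinkRecord
from .stats_prep import WindowSpec, discrete_color_scheme, iter_windows

__all__ = [
    "SyntheticGenomeSpec",
    "GenomeFixture",
    "AnnotationFixture",
    "AlignmentFixture",
    "VariantFixture",
    "make_genome",
    "make_annotation",
    "make_alignments",
    "make_variants",
    "make_links",
    "make_qtl_table",
    "brute_force_composition",
]

# Default study genome: 4 chromosomes, 200 kb total, moderate GC with a mild
# strand skew and a few percent of assembly-gap N blocks.
DEFAULT_LENGTHS = (60_000, 50_000, 50_000, 40_000)
DEFAULT_GC = 0.40
DEFAULT_SKEW = 0.10
DEFAULT_N_FRACTION = 0.02


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    gc: float = DEFAULT_GC           # target GC fraction of called bases
    skew: float = DEFAULT_SKEW       # target (G-C)/(G+C) of called bases
    n_fraction: float = DEFAULT_N_FRACTION  # fraction of bases in N blocks
    n_segments: int = 4              # composition segments per chromosome
    seed: int = 0

    @property
    def chrom_ids(self) -> tuple[str, ...]:
        return tuple(f"Chr{i + 1}" for i in range(len(self.lengths)))


@dataclass
class GenomeFixture:
    spec: SyntheticGenomeSpec
    sequences: dict[str, str]

    @property
    def fasta(self) -> str:
        out = []
        for chrom, seq in self.sequences.items():
            out.append(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                out.append(seq[i : i + 70] + "\n")
        return "".join(out)

    def write_fasta(self, path) -> str:
        with open(path, "wt") as fh:
            fh.write(self.fasta)
        return str(path)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def make_genome(spec: SyntheticGenomeSpec = SyntheticGenomeSpec()) -> GenomeFixture:
    """Sample a genome segment-wise at the spec's G:C:A:T odds.

    Each chromosome is split into ``n_segments`` segments whose GC targets
    oscillate around ``spec.gc`` (so windowed GC varies along the
    chromosome), with the G:C ratio set by ``spec.skew``; N blocks totalling
    about ``n_fraction`` of each chromosome are placed at seeded positions.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    for ci, (chrom, length) in enumerate(zip(spec.chrom_ids, spec.lengths)):
        parts = []
        seg_len = length // spec.n_segments
        for si in range(spec.n_segments):
            n = seg_len if si < spec.n_segments - 1 else length - seg_len * (spec.n_segments - 1)
            gc = float(
                np.clip(
                    spec.gc + 0.12 * math.sin(2 * math.pi * si / max(1, spec.n_segments)),
                    0.05, 0.95,
                )
            )
            g = gc * (1 + spec.skew) / 2.0
            c = gc * (1 - spec.skew) / 2.0
            at = (1 - gc) / 2.0
            bases = rng.choice(
                np.frombuffer(b"GCAT", dtype=np.uint8), size=n, p=[g, c, at, at]
            )
            parts.append(bases)
        seq = np.concatenate(parts)
        # N blocks: a few seeded gaps summing to ~n_fraction of the chromosome
        n_total = int(spec.n_fraction * length)
        if n_total > 0:
            n_blocks = max(1, n_total // 500)
            block = n_total // n_blocks
            starts = rng.integers(0, max(1, length - block), size=n_blocks)
            for s in starts:
                seq[s : s + block] = ord("N")
        sequences[chrom] = seq.tobytes().decode("ascii")
    return GenomeFixture(spec, sequences)


def brute_force_composition(sequences: dict[str, str], spec: WindowSpec):
    """Independent per-base counting oracle for window GC/skew/N statistics.

    Walks every window character by character — deliberately naive, shared
    by tests as the reference for the vectorized implementation.
    """
    gc_rows, skew_rows, n_rows = [], [], []
    for chrom, seq in sequences.items():
        for start, end in iter_windows(len(seq), spec):
            a = c = g = t = n = 0
            for ch in seq[start - 1 : end].upper():
                if ch == "A":
                    a += 1
                elif ch == "C":
                    c += 1
                elif ch == "G":
                    g += 1
                elif ch == "T":
                    t += 1
                else:
                    n += 1
            called = a + c + g + t
            gc_rows.append(
                ContinuousRecord(chrom, start, end, (g + c) / called if called else 0.0)
            )
            skew_rows.append(
                ContinuousRecord(chrom, start, end, (g - c) / (g + c) if g + c else 0.0)
            )
            n_rows.append(ContinuousRecord(chrom, start, end, n / (end - start + 1)))
    return gc_rows, skew_rows, n_rows


@dataclass
class AnnotationFixture:
    gff3: str
    gene_ids: list[str]
    positions: list[tuple[str, int, int]]  # (chrom, start, end) per gene

    def true_density(self, lengths: dict[str, int], spec: WindowSpec) -> list[ContinuousRecord]:
        return _true_start_counts(
            [(c, s) for c, s, _ in self.positions], lengths, spec
        )

    def write(self, path) -> str:
        with open(path, "wt") as fh:
            fh.write(self.gff3)
        return str(path)


def _true_start_counts(
    positions: Sequence[tuple[str, int]], lengths: dict[str, int], spec: WindowSpec
) -> list[ContinuousRecord]:
    rows = []
    for chrom, length in lengths.items():
        for start, end in iter_windows(length, spec):
            count = sum(1 for c, p in positions if c == chrom and start <= p <= end)
            rows.append(ContinuousRecord(chrom, start, end, float(count)))
    return rows


def make_annotation(genome: GenomeFixture, n_genes: int, seed: int = 0) -> AnnotationFixture:
    """GFF3 gene models at seeded positions, one mRNA child per gene."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    weights = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    lines = ["##gff-version 3\n"]
    ids, positions = [], []
    per_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    for i in range(n_genes):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = len(genome.sequences[chrom])
        gene_len = int(rng.integers(500, 3000))
        start = int(rng.integers(1, max(2, length - gene_len)))
        gid = f"gene{i + 1:04d}"
        per_chrom[chrom].append((start, start + gene_len - 1, gid))
    i = 0
    for chrom in chroms:
        for start, end, gid in sorted(per_chrom[chrom]):
            strand = "+" if i % 2 == 0 else "-"
            lines.append(
                f"{chrom}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid};Name={gid.upper()}\n"
            )
            lines.append(
                f"{chrom}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.1;Parent={gid}\n"
            )
            ids.append(gid)
            positions.append((chrom, start, end))
            i += 1
    return AnnotationFixture("".join(lines), ids, positions)


@dataclass
class AlignmentFixture:
    sam: str
    counted: list[tuple[str, int]]  # (chrom, POS) of primary mapped records
    n_excluded: int

    def true_bins(self, lengths: dict[str, int], spec: WindowSpec) -> list[ContinuousRecord]:
        return _true_start_counts(self.counted, lengths, spec)

    def write(self, path) -> str:
        with open(path, "wt") as fh:
            fh.write(self.sam)
        return str(path)


def make_alignments(
    genome: GenomeFixture,
    n_reads: int,
    seed: int = 0,
    read_len: int = 50,
    unmapped_fraction: float = 0.05,
    secondary_fraction: float = 0.05,
    supplementary_fraction: float = 0.03,
) -> AlignmentFixture:
    """SAM file of uniform single-end reads including a known fraction of
    unmapped/secondary/supplementary records that coverage binning must
    exclude."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    weights = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    lines = ["@HD\tVN:1.6\tSO:unsorted\n"]
    for c in chroms:
        lines.append(f"@SQ\tSN:{c}\tLN:{len(genome.sequences[c])}\n")
    counted, n_excluded = [], 0
    qual = "I" * read_len
    for i in range(n_reads):
        u = rng.random()
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = len(genome.sequences[chrom])
        pos = int(rng.integers(1, max(2, length - read_len)))
        seq = genome.sequences[chrom][pos - 1 : pos - 1 + read_len].replace("N", "A")
        if u < unmapped_fraction:
            flag, n_excluded = 4, n_excluded + 1
            lines.append(f"read{i:05d}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
            continue
        if u < unmapped_fraction + secondary_fraction:
            flag, n_excluded = 256, n_excluded + 1
        elif u < unmapped_fraction + secondary_fraction + supplementary_fraction:
            flag, n_excluded = 2048, n_excluded + 1
        else:
            flag = 0
            counted.append((chrom, pos))
        lines.append(
            f"read{i:05d}\t{flag}\t{chrom}\t{pos}\t60\t{read_len}M\t*\t0\t0\t{seq}\t{qual}\n"
        )
    return AlignmentFixture("".join(lines), counted, n_excluded)


@dataclass
class VariantFixture:
    vcf: str
    sites: list[tuple[str, int]]

    def true_bins(self, lengths: dict[str, int], spec: WindowSpec) -> list[ContinuousRecord]:
        return _true_start_counts(self.sites, lengths, spec)

    def write(self, path) -> str:
        with open(path, "wt") as fh:
            fh.write(self.vcf)
        return str(path)


_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


def make_variants(genome: GenomeFixture, n_sites: int, seed: int = 0) -> VariantFixture:
    """Plain-text VCF v4.2 of seeded SNVs (mixed PASS / LowQual filters —
    binning counts them all)."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    weights = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    lines = ["##fileformat=VCFv4.2\n", '##FILTER=<ID=LowQual,Description="Low quality">\n']
    for c in chroms:
        lines.append(f"##contig=<ID={c},length={len(genome.sequences[c])}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    sites = []
    rows = []
    for i in range(n_sites):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = len(genome.sequences[chrom])
        pos = int(rng.integers(1, length + 1))
        ref = genome.sequences[chrom][pos - 1].upper()
        if ref not in _ALT:
            ref = "A"
        filt = "PASS" if rng.random() > 0.2 else "LowQual"
        rows.append((chrom, pos, ref, filt))
        sites.append((chrom, pos))
    order = {c: i for i, c in enumerate(chroms)}
    for chrom, pos, ref, filt in sorted(rows, key=lambda r: (order[r[0]], r[1])):
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{_ALT[ref]}\t30\t{filt}\t.\n")
    return VariantFixture("".join(lines), sites)


def make_links(
    genome: GenomeFixture, n_links: int, seed: int = 0, columns: int = 8
) -> tuple[str, list[LinkRecord]]:
    """MCScanX-style link table (7- or 8-column dialect) plus the expected
    parsed records."""
    if columns not in (6, 7, 8):
        raise ValueError("columns must be 6, 7 or 8")
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    colors = discrete_color_scheme(max(3, min(n_links, 10)))
    lines, expected = [], []
    for i in range(n_links):
        ca, cb = (chroms[int(j)] for j in rng.choice(len(chroms), size=2))
        la, lb = len(genome.sequences[ca]), len(genome.sequences[cb])
        span = int(rng.integers(2000, 10000))
        sa = int(rng.integers(1, max(2, la - span)))
        sb = int(rng.integers(1, max(2, lb - span)))
        color = colors[i % len(colors)]
        cols = [ca, str(sa), str(sa + span), cb, str(sb), str(sb + span)]
        if columns >= 7:
            cols.append(color.text)
        if columns == 8:
            cols.append(f"geneA{i:03d};geneB{i:03d}")
        lines.append("\t".join(cols) + "\n")
        expected.append(
            LinkRecord(ca, sa, sa + span, cb, sb, sb + span,
                       color if columns >= 7 else None)
        )
    return "".join(lines), expected


def make_qtl_table(
    genome: GenomeFixture,
    n_records: int,
    seed: int = 0,
    categories: Optional[Sequence[str]] = ("QTL-A", "QTL-B", "QTL-C"),
    reversed_fraction: float = 0.0,
) -> tuple[str, list[DiscreteRecord]]:
    """Discrete (tile/arrow) table with optional category column; a seeded
    fraction of records is written start > end (reversed orientation)."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    cats = list(categories) if categories else []
    palette = {c: col for c, col in zip(cats, discrete_color_scheme(max(1, len(cats))))}
    lines, expected = [], []
    for i in range(n_records):
        chrom = chroms[int(rng.choice(len(chroms)))]
        length = len(genome.sequences[chrom])
        span = int(rng.integers(1000, 6000))
        s = int(rng.integers(1, max(2, length - span)))
        e = s + span
        cat = cats[i % len(cats)] if cats else None
        color = palette[cat] if cat else ColorSpec(0, 0, 200)
        if rng.random() < reversed_fraction:
            s, e = e, s
        cols = [chrom, str(s), str(e), color.text] + ([cat] if cat else [])
        lines.append("\t".join(cols) + "\n")
        expected.append(DiscreteRecord(chrom, s, e, color, cat, reversed=s > e))
    return "".join(lines), expected
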