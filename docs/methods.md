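# Methods

This note records the conventions, numerical choices and open design
decisions behind circleplot, and what the synthetic test data does and does
not establish about behaviour on real genomes.

## Coordinates and formats

Track files use 1-based inclusive coordinates, matching the GFF convention
of the annotation files the statistics are derived from; they are stored
unchanged and converted to half-open intervals only inside binning
arithmetic. Colours accept decimal triplets (`255,0,0`) and hex
(`#FF0000`); the canonical written form is the decimal triplet. Blank
lines and `#`-comments are skipped; every parse error carries a 1-based
line number.

The link dialect is deliberately permissive: 6 mandatory coordinate
columns, then an optional colour, then an optional annotation column
(MCScanX emits a homologous gene pair there) that is always discarded. A
7th column is disambiguated by attempting a colour parse first — the only
rule that honours both the 7-column coloured dialect and 7-column annotated
exports. File order is preserved end to end; links are drawn first-to-last,
so lines moved to the head of a file are drawn first (underneath later
ribbons).

## Layout

Each chromosome receives an angular span proportional to its length:
`width_i = (1 - n·gap_fraction) · 360° · L_i / ΣL`, with one equal gap
after every chromosome so the circle closes exactly (verified to 1e-9).
Defaults: `gap_fraction = 0.005`, `start_angle = 90°` (12 o'clock),
clockwise — the conventional Circos orientation. Radii run on a 0–100
percent scale so track spans use the same units as the `start_pos` /
`end_pos` track settings. Straight mode maps the directed angular
coordinate to x and radius to y; because both modes transform the same
device-independent primitives, switching modes can never change what is
drawn, only where.

Tick spacing picks the 1/2/5 × 10^k bp value giving closest to the target
major count on the longest chromosome (default 5), with 4 minor ticks per
interval; labels use Mb when the longest chromosome is ≥ 2 Mb, else kb.

## Window statistics

Windows start at 1, 1+step, ...; the final partial window is kept with its
true shorter extent. Per window, with counts over the window's characters
(case-insensitive; any character outside ACGT counts as uncalled):

- `n_ratio = #uncalled / window_size`
- `gc_content = (#G + #C) / (#A + #C + #G + #T)` — the denominator excludes
  uncalled bases, so an all-G window reports 1 regardless of gaps; windows
  with no called base report 0 and are logged.
- `gc_skew = (#G − #C) / (#G + #C)`, the standard strand-asymmetry
  definition (0 when G+C = 0).

Feature, alignment and variant binning assign each record to the window
containing its start position (alignments: leftmost mapped base; records
re-binned from continuous tracks: the integer interval midpoint). The
alternative — overlap-weighted assignment — was rejected because
start-keying makes tiling-window totals exactly equal the record count, a
property the tests rely on. SAM counting keeps primary mapped records only
(excludes flags 0x4, 0x100, 0x800); VCF counting ignores the FILTER column.
SAM is the supported alignment text dialect; BAM/CRAM decoding is out of
scope (pysam would accept BAM transparently, but it is not exercised).

## Tracks and glyphs

Heat scaling offers linear, log (`log10(v − vmin + ε)` with
`ε = max(10⁻³·range, 10⁻¹²)`) and quantile (empirical CDF) modes; all map
vmin→0 and vmax→1 and are monotone. Radial positions of bars, points and
lines always use the linear map; the heat scale only recolours heatmaps.
`value_range` defaults to the track's data extent (padded by ±0.5 when the
track is constant).

Bars rise from the annulus base; `invert` hangs them from the outer edge
(the upside-down variant-density style). Line tracks plot each record at
its interval midpoint and, when `sep_line_value` is set, split segments by
linear interpolation exactly at the crossing so above/below colours change
at the threshold. Triangles (TAD style) put the base on the interval at the
inner radius and the apex at the interval midpoint on the outer radius —
apex position, not fill, encodes the domain extent. Arrows point from the
written start to the written end coordinate, so a reversed record
(start > end) points toward lower positions. Tile tracks spanning e.g.
90–100 act as region highlights over every track inside that annulus;
overlapping radial spans are allowed by design, they are the
track-stacking mechanism.

Ribbons connect two genomic intervals with two cubic béziers whose control
points sit at 0.3 of the link radius toward the centre — a conventional
chord-tightening fraction chosen for legibility — closed by the two
anchoring arcs. Degenerate
self-links (identical intervals) enclose no area and are skipped with a
warning.

## Label placement

Feature labels repel along the circle until no two overlap. The placement
solves the order-preserving 1-D packing problem directly: with labels
sorted by anchor angle and a required separation of half the two
neighbouring label widths plus an interspace of `2^overlap_weight` degrees
(capped at 10°), positions minimizing total squared displacement subject to
the separations are found by pool-adjacent-violators on the
offset-transformed anchors. This is deterministic, never reorders labels,
touches non-conflicting labels not at all, displaces a coincident pair
symmetrically, and finishes in at most one pooling step per label — far
below the 500-iteration budget. An iterative pairwise-repulsion scheme
with the step scaled by `2^overlap_weight` was considered and rejected: for
strongly negative weights the step becomes so small that a 20-label
cluster cannot separate within any reasonable iteration cap, whereas the
weight's observable effect — larger values spread labels further — is
exactly the interspace term, which this formulation keeps. If the padded
labels need more than 360°, a warning is attached and residual overlaps
are accepted.

Label text width is estimated as 0.62 · font-size · characters (a
monospace-ish bound); the angular width follows from the label radius on
the canvas.

## Rendering and export

A scene is an ordered primitive list; z-order is skeleton, track
backgrounds (`bar_fill`), track glyphs outer-to-inner, ribbons, labels with
leader lines, legends. Arcs are approximated by 2° polyline sampling —
identical geometry in the SVG and PNG backends. SVG is written by direct
string serialization with fixed 3-decimal coordinate formatting, so a given
scene always produces identical bytes; PNG rendering goes through
matplotlib's Agg canvas with canvas units of 1/100 inch, so pixel
dimensions scale linearly with dpi. Legends default to a stacked top-right
column and are movable via `legend_anchors` in the project settings.

Projects serialize to `project.json` (schema-versioned settings and track
specs) plus canonical TSV copies of all tables under `data/`, with relative
paths only; save → relocate → load → render is byte-identical to a direct
render.

## Synthetic data

The generators default to a 4-chromosome, 200 kb genome (GC 0.40, strand
skew 0.10, ~2 % N in gap blocks, 4 composition segments per chromosome so
windowed GC varies along each chromosome), 100 genes, 1000 reads of 50 bp
with ~13 % unmapped/secondary/supplementary records, and 300 variant
sites — sizes chosen so a full-pipeline run completes in seconds while
every code path (partial windows, excluded flags, reversed records,
multi-chromosome links) is exercised. Ground truth is always computed from
the realized records by an independent brute-force scan (per-base counting
for composition, direct membership counting for bins), never from the
sampling distribution, so oracle comparisons are exact rather than
statistical.

What passing tests show: the arithmetic, parsing, layout and rendering
contracts hold exactly on well-formed inputs. What they do not show:
behaviour on chromosome-scale (100 Mb+) inputs is correct but not
benchmarked for speed; real-world malformed files (mixed encodings,
nonstandard attribute keys) beyond the tested error paths; and visual
quality judgements (font metrics are estimated, not measured).

## Known limitations

- No per-base pileup coverage — coverage bins count read starts.
- No axis breaks or per-chromosome zoom factors.
- GTF matching keys on `gene_id`/`ID`/`Name` attributes only.
- PDF export and interactive editing are out of scope; SVG output is the
  editable vector form.
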