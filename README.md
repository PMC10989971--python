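# circleplot

Scriptable Circos-style genome figures: parse simple tab-delimited track
tables, compute the per-window genome statistics the tracks are built from,
and render multi-track circular (or straight) plots with bézier association
ribbons, automatic legends and a portable, reloadable project format.

Circos plots arrange chromosomes around a circle and stack data tracks in
concentric annuli — the standard way to inspect genome-scale patterns
(gene density, sequencing coverage, variant hotspots, synteny) at a glance.
The usual pain is upstream: converting FASTA/GFF/SAM/VCF into per-window
track tables and keeping a figure reproducible across re-plots. circleplot
covers that whole path as a library plus a thin `circleplot` CLI.

## Data model

Five TSV track categories, coordinates 1-based inclusive, optional RGB codes
written either `r,g,b` or `#RRGGBB`:

| category    | columns                                              |
|-------------|------------------------------------------------------|
| skeleton    | `chrom  length  [rgb]`                               |
| region tags | `chrom  label  start  end  [rgb]`                    |
| links       | `chrA  startA  endA  chrB  startB  endB  [rgb] [gene-pair]` |
| continuous  | `chrom  start  end  value`                           |
| discrete    | `chrom  start  end  rgb  [category]`                 |

Link files tolerate the 8-column MCScanX-derived dialect (the trailing
homologous-gene-pair column is always ignored). A discrete record written
`start > end` is flagged as reversed and flips the arrow glyph. A category
column on a discrete track automatically triggers a legend, as does every
heatmap track.

## Statistics

The preparation kernels emit those track formats directly:

- **window composition** — sliding-window GC content
  $\mathrm{GC} = \frac{\#G + \#C}{\#A+\#C+\#G+\#T}$, GC skew
  $\mathrm{skew} = \frac{\#G - \#C}{\#G + \#C}$ (strand-asymmetry statistic,
  bounded in $[-1, 1]$, negated by reverse complement) and N-ratio
  (fraction of uncalled bases, a gap proxy);
- **gene density**, **alignment coverage** and **variant density** — counts
  of GFF3/GTF features, primary mapped SAM records, and VCF sites per
  window, keyed on start position so tiling-window totals are exactly
  conservative (unmapped/secondary/supplementary alignments excluded);
- **gene positions** — region tags for an ID list, plus a deterministic
  distinct-colour generator for chromosome palettes.

## Worked example

Generate a small synthetic study (4 chromosomes, 200 kb) and build a figure:

```python
from circleplot import fixtures
g = fixtures.make_genome()                      # deterministic, seed 0
g.write_fasta("genome.fa")
fixtures.make_annotation(g, 80, seed=1).write("genes.gff3")
fixtures.make_alignments(g, 500, seed=2).write("reads.sam")
fixtures.make_variants(g, 200, seed=3).write("variants.vcf")
open("links.tsv", "w").write(fixtures.make_links(g, 6, seed=4)[0])
```

```sh
circleplot prep fasta-len genome.fa -o skel.tsv
circleplot prep window-stat genome.fa -o ws --window 2000
circleplot prep gene-density genes.gff3 -o dens.tsv --window 5000 --skeleton skel.tsv
circleplot prep cov-bin reads.sam -o cov.tsv --window 5000 --skeleton skel.tsv
circleplot prep vcf-bin variants.vcf -o var.tsv --window 5000 --skeleton skel.tsv
circleplot plot --config config.json -o fig.svg      # see docs for the config schema
circleplot project save --config config.json -o proj
circleplot project load proj
```

The last command prints the bundle summary:

```
skeleton=4 tags=2 links=6 tracks=5 schema=1
```

meaning the saved project holds a 4-chromosome skeleton, 2 feature labels,
6 association ribbons and 5 statistic tracks. `circleplot plot --project
proj -o fig2.svg` reproduces `fig.svg` byte-for-byte — SVG export is fully
deterministic, and project directories are relocatable (only relative paths
inside), so a bundle can be zipped and re-plotted anywhere.

A typical `config.json` names the input tables and one spec per track
(`glyph`, `start_pos`/`end_pos` radial span in percent, optional
`sep_line_value`, `color_by_chr`, `invert`, `bar_fill`, `bar_border`,
binning):

```json
{
  "skeleton": "skel.tsv",
  "links": "links.tsv",
  "tracks": [
    {"data": "ws.nratio", "kind": "continuous",
     "spec": {"glyph": "point", "start_pos": 78, "end_pos": 88}},
    {"data": "ws.skew", "kind": "continuous",
     "spec": {"glyph": "line", "start_pos": 66, "end_pos": 76, "sep_line_value": 0.0}},
    {"data": "dens.tsv", "kind": "continuous",
     "spec": {"glyph": "heatmap", "start_pos": 54, "end_pos": 64, "name": "gene density"}}
  ]
}
```

Add `--straight` to unroll the circle into a linear multi-track view with
the identical elements.

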