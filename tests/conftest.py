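import pytest

from circleplot import fixtures
from circleplot.formats_io import SkeletonRecord
from circleplot.stats_prep import discrete_color_scheme


@pytest.fixture(scope="session")
def genome():
    """Default 200 kb, 4-chromosome synthetic genome (seed 0)."""
    return fixtures.make_genome()


@pytest.fixture(scope="session")
def genome_dir(genome, tmp_path_factory):
    """Directory with the genome FASTA plus annotation, SAM, VCF files."""
    d = tmp_path_factory.mktemp("genome")
    genome.write_fasta(d / "genome.fa")
    fixtures.make_annotation(genome, 100, seed=1).write(d / "genes.gff3")
    fixtures.make_alignments(genome, 1000, seed=2).write(d / "reads.sam")
    fixtures.make_variants(genome, 300, seed=3).write(d / "variants.vcf")
    return d


@pytest.fixture(scope="session")
def skeleton(genome):
    colors = discrete_color_scheme(len(genome.sequences))
    return [
        SkeletonRecord(c, l, col)
        for (c, l), col in zip(genome.lengths.items(), colors)
    ]
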