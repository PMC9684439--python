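import numpy as np
import pytest

from tecre.genome_io import (
    Gene,
    GeneAnnotation,
    Genome,
    GenomicInterval,
    TEAnnotation,
    TEIntegrant,
)


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    """Small hand-laid annotation: one gene with an exon, four TE loci."""
    gene = Gene(
        "G1",
        "protein_coding",
        GenomicInterval("chr1", 400_000, 410_000, "+"),
        (GenomicInterval("chr1", 401_000, 402_000, "+"),),
    )
    genes = GeneAnnotation(toy_genome, [gene])
    tes = TEAnnotation(
        toy_genome,
        [
            TEIntegrant(GenomicInterval("chr1", 401_500, 401_800), "te_exonic", "SFA"),
            TEIntegrant(GenomicInterval("chr1", 100_000, 100_500), "te_far", "SFA"),
            TEIntegrant(GenomicInterval("chr1", 415_000, 415_400), "te_flank", "SFB"),
            TEIntegrant(GenomicInterval("chr2", 80_000, 80_300), "te_low", "SFB"),
        ],
    )
    return tes, genes


def random_intervals(rng: np.random.Generator, n: int, genome: Genome):
    """Uniform random intervals over a genome, for oracle comparisons."""
    chroms = list(genome.sizes)
    out = []
    for _ in range(n):
        ch = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(50, 5_000))
        start = int(rng.integers(0, genome.sizes[ch] - length))
        out.append(GenomicInterval(ch, start, start + length))
    return out
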