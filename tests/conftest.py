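from __future__ import annotations

import numpy as np
import pytest

from spliceratio.annotation_io import GeneModel, SplicedAlignment, junctions_of


@pytest.fixture
def three_exon_gene() -> GeneModel:
    return GeneModel("gA", "chrI", "+", ((0, 100), (200, 300), (400, 500)))


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("gA", "chrI", "+", ((0, 100), (200, 300), (400, 500))),
        GeneModel("gB", "chrI", "-", ((1000, 1150), (1250, 1400))),
        GeneModel("gC", "chrII", "+", ((50, 250),)),
    ]


def make_read(
    read_id: str,
    blocks,
    chrom: str = "chrI",
    sample: str = "S",
    strand: str = "+",
) -> SplicedAlignment:
    return SplicedAlignment(
        read_id=read_id, sample_id=sample, chrom=chrom,
        blocks=tuple(tuple(b) for b in blocks), strand=strand,
    )


def random_gene_models(rng: np.random.Generator, n: int) -> list[GeneModel]:
    """Small random but valid gene models for property tests."""
    genes = []
    cursor = 0
    for i in range(n):
        n_exons = int(rng.integers(1, 6))
        exons = []
        pos = cursor + int(rng.integers(10, 100))
        for k in range(n_exons):
            length = int(rng.integers(20, 200))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(10, 120))
        chrom = f"chr{int(rng.integers(1, 4))}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"rg{i:03d}", chrom, strand, tuple(exons)))
        cursor = pos + 200
    return genes


def random_reads(
    rng: np.random.Generator,
    genes: list[GeneModel],
    n_reads: int,
    sample: str = "S",
) -> list[SplicedAlignment]:
    """Random spliced/unspliced/partial reads over the given gene space,
    including some reads that match no annotated junction."""
    reads = []
    for i in range(n_reads):
        gene = genes[int(rng.integers(0, len(genes)))]
        junctions = junctions_of(gene)
        mode = rng.random()
        if junctions and mode < 0.5:
            j = junctions[int(rng.integers(0, len(junctions)))]
            left = int(rng.integers(1, 40))
            right = int(rng.integers(1, 40))
            blocks = [
                (j.intron_start - left, j.intron_start),
                (j.intron_end, j.intron_end + right),
            ]
        elif mode < 0.8:
            span = gene.span
            start = int(rng.integers(span[0], max(span[0] + 1, span[1] - 30)))
            length = int(rng.integers(10, 60))
            blocks = [(start, start + length)]
        else:
            # a gap that is not an annotated intron
            start = gene.span[0] + int(rng.integers(0, 50))
            blocks = [
                (start, start + int(rng.integers(5, 30))),
            ]
            gap = int(rng.integers(5, 80))
            last = blocks[-1][1] + gap
            blocks.append((last, last + int(rng.integers(5, 30))))
        reads.append(make_read(f"{sample}.r{i}", blocks, gene.chrom, sample, gene.strand))
    return reads
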