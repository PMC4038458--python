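"""Independent brute-force oracles used to check the streaming implementations.

Everything here is deliberately naive — exhaustive loops over (read, junction)
pairs and full enumeration of discrete distributions — and shares no code with
the package internals it verifies.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from spliceratio.annotation_io import GeneModel, Junction, SplicedAlignment


def brute_junction_counts(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    junctions: Sequence[Junction],
    min_overhang: int,
) -> dict[tuple[int, str], int]:
    """Exhaustive (read x junction) spliced-evidence counts."""
    out: dict[tuple[int, str], int] = {}
    for sample, reads in alignments_by_sample.items():
        for j_idx, junction in enumerate(junctions):
            total = 0
            for read in reads:
                if read.chrom != junction.chrom:
                    continue
                hit = False
                for b in range(len(read.blocks) - 1):
                    left = read.blocks[b]
                    right = read.blocks[b + 1]
                    if (
                        left[1] == junction.intron_start
                        and right[0] == junction.intron_end
                        and left[1] - left[0] >= min_overhang
                        and right[1] - right[0] >= min_overhang
                    ):
                        hit = True
                if hit:
                    total += 1
            out[(j_idx, sample)] = total
    return out


def brute_retention_counts(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    junctions: Sequence[Junction],
    min_overhang: int,
) -> dict[tuple[int, str], int]:
    """Exhaustive boundary-crossing (retained) evidence counts."""
    out: dict[tuple[int, str], int] = {}
    for sample, reads in alignments_by_sample.items():
        for j_idx, junction in enumerate(junctions):
            total = 0
            for read in reads:
                if read.chrom != junction.chrom:
                    continue
                crossed = False
                for bs, be in read.blocks:
                    for boundary in (junction.intron_start, junction.intron_end):
                        if bs <= boundary - min_overhang and boundary + min_overhang <= be:
                            crossed = True
                if crossed:
                    total += 1
            out[(j_idx, sample)] = total
    return out


def brute_gene_assignment(
    reads: Sequence[SplicedAlignment], genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Span-containment gene counts by scanning every (read, gene) pair."""
    counts = {g.gene_id: 0 for g in genes}
    for read in reads:
        rs, re = read.blocks[0][0], read.blocks[-1][1]
        owners = [
            g.gene_id
            for g in genes
            if g.chrom == read.chrom and g.span[0] <= rs and re <= g.span[1]
        ]
        if len(owners) == 1:
            counts[owners[0]] += 1
    return counts


def enum_binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by full outcome enumeration:
    sum of P(X = x) over all x with P(X = x) <= P(X = k) (with a relative
    tolerance for ties, as is conventional)."""
    probs = [math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(n + 1)]
    observed = probs[k]
    return min(1.0, sum(q for q in probs if q <= observed * (1 + 1e-9)))


def enum_hypergeom_tail(k: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= k) for the overlap of two sets by full enumeration."""
    total = math.comb(universe, size_b)
    acc = 0.0
    for x in range(max(0, size_a + size_b - universe), min(size_a, size_b) + 1):
        if x >= k:
            acc += math.comb(size_a, x) * math.comb(universe - size_a, size_b - x) / total
    return min(1.0, acc)


def enum_hypergeom_pmf_sum(universe: int, size_a: int, size_b: int) -> float:
    total = math.comb(universe, size_b)
    return sum(
        math.comb(size_a, x) * math.comb(universe - size_a, size_b - x) / total
        for x in range(max(0, size_a + size_b - universe), min(size_a, size_b) + 1)
    )
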