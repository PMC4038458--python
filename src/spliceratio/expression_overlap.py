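"""Per-gene expression counts, up-regulation calls, and set-overlap test.

With one library per condition and no replicates, differential expression of
a gene between two samples is assessed by an exact conditional test: given
the total count n = k1 + k2 of the gene across both libraries, k2 is
binomial(n, N2/(N1+N2)) under the null of equal relative expression, where
N1, N2 are the library sizes. The two-sided p-value is the sum of the
probabilities of all outcomes no more likely than the observed one.

The overlap of the two mutants' up-regulated gene sets is scored with the
hypergeometric tail P(X >= k) over the detectable-gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import GeneModel, SplicedAlignment

__all__ = [
    "DEResult",
    "OverlapResult",
    "gene_counts",
    "de_test",
    "upregulated_set",
    "overlap_test",
    "detectable_universe",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DEResult:
    """One gene's two-sample differential-expression call."""

    gene_id: str
    baseline_count: int
    test_count: int
    log2_fold_change: float  # after library-size scaling
    p_value: float
    up_flag: bool


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets within a finite universe."""

    size_a: int
    size_b: int
    intersection: int
    universe: int
    p_value: float  # hypergeometric P(X >= k)


def gene_counts(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Assign reads to genes by span containment.

    A read counts for gene g iff every aligned block lies within g's span
    (first exon start to last exon end). Reads fitting zero or multiple gene
    spans are discarded; the per-sample tally of both kinds is returned next
    to the genes × samples count matrix.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(genes):
        start, end = gene.span
        trees.setdefault(gene.chrom, IntervalTree()).addi(start, end, idx)
    samples = list(alignments_by_sample)
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    discarded = {s: {"unassigned": 0, "ambiguous": 0} for s in samples}
    for s_idx, sample in enumerate(samples):
        for read in alignments_by_sample[sample]:
            tree = trees.get(read.chrom)
            rs, re = read.span
            if tree is None:
                discarded[sample]["unassigned"] += 1
                continue
            hits = [
                iv.data for iv in tree.overlap(rs, re)
                if iv.begin <= rs and re <= iv.end
            ]
            if len(hits) == 1:
                counts[hits[0], s_idx] += 1
            elif not hits:
                discarded[sample]["unassigned"] += 1
            else:
                discarded[sample]["ambiguous"] += 1
    frame = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=samples)
    return frame, discarded


def de_test(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    baseline: str,
    test: str,
    alpha: float = DEFAULT_ALPHA,
) -> list[DEResult]:
    """Exact binomial two-sample test per gene (no replicates).

    For counts k1 (baseline), k2 (test) and library sizes N1, N2, k2 is
    tested against binomial(k1+k2, N2/(N1+N2)), two-sided. Genes with
    k1 + k2 = 0 get p = 1. ``up_flag`` requires both a higher scaled rate in
    the test sample and p < alpha.
    """
    if baseline not in counts.columns or test not in counts.columns:
        raise ValueError("baseline or test sample missing from count matrix")
    n1 = library_sizes[baseline]
    n2 = library_sizes[test]
    p_null = n2 / (n1 + n2)
    results: list[DEResult] = []
    for gene_id, row in counts[[baseline, test]].iterrows():
        k1, k2 = int(row[baseline]), int(row[test])
        if k1 < 0 or k2 < 0:
            raise ValueError(f"gene {gene_id}: negative count")
        n = k1 + k2
        if n == 0:
            results.append(DEResult(str(gene_id), 0, 0, 0.0, 1.0, False))
            continue
        p_value = float(stats.binomtest(k2, n, p_null).pvalue)
        rate1, rate2 = k1 / n1, k2 / n2
        if k1 == 0:
            lfc = math.inf
        elif k2 == 0:
            lfc = -math.inf
        else:
            lfc = math.log2(rate2 / rate1)
        up = rate2 > rate1 and p_value < alpha
        results.append(DEResult(str(gene_id), k1, k2, lfc, p_value, up))
    return results


def upregulated_set(results: Iterable[DEResult], alpha: float = DEFAULT_ALPHA) -> set[str]:
    """Gene ids up-regulated at the given raw-p threshold.

    Raw p-values are thresholded deliberately (no multiplicity correction);
    apply a correction upstream if a corrected set is wanted.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    return {r.gene_id for r in results if r.p_value < alpha and r.log2_fold_change > 0}


def detectable_universe(counts: pd.DataFrame) -> set[str]:
    """Genes with a nonzero total count across samples (the overlap
    universe: conditioning on detectability)."""
    total = counts.sum(axis=1)
    return set(map(str, total.index[total > 0]))


def overlap_test(
    set_a: Set[str], set_b: Set[str], universe_size: int
) -> OverlapResult:
    """Hypergeometric enrichment of the intersection of two gene sets.

    P(X >= k) where X counts shared genes when |A| and |B| genes are drawn
    without replacement from a universe of ``universe_size``.
    """
    size_a, size_b = len(set_a), len(set_b)
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("set larger than universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, size_a, size_b))
    return OverlapResult(size_a, size_b, k, universe_size, p)


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "baseline_count": [r.baseline_count for r in results],
            "test_count": [r.test_count for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "up_flag": [r.up_flag for r in results],
        }
    )
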