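"""Per-junction spliced / retained read counting and library-size scaling.

Two kinds of evidence are tallied for every annotated intron:

* **spliced** — a read whose alignment contains a gap exactly matching the
  intron, with at least ``min_overhang`` aligned nucleotides on each side of
  the gap (the exon–exon junction read of the spliced product);
* **retained** — a read with one contiguous aligned block crossing an
  exon–intron boundary of the intron by at least ``min_overhang`` on both
  sides (the in-silico analog of an RT-PCR product from unspliced RNA).

Gap-to-intron matching is exact: simulated and splice-aware-mapper gaps are
annotated introns, and a fuzzy tolerance would silently merge neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Junction, SplicedAlignment

__all__ = [
    "JunctionCountTable",
    "RetentionTable",
    "count_junctions",
    "count_retention",
    "cpm_normalize",
]

DEFAULT_MIN_OVERHANG = 3


@dataclass(frozen=True)
class JunctionCountTable:
    """Junctions × samples matrix of junction-spanning read counts."""

    junctions: tuple[Junction, ...]
    samples: tuple[str, ...]
    counts: np.ndarray  # int, shape (n_junctions, n_samples)
    library_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError("count matrix shape does not match junctions × samples")
        if (self.counts < 0).any():
            raise ValueError("negative junction counts")
        for sample in self.samples:
            if self.library_sizes.get(sample, 0) < 1:
                raise ValueError(f"sample {sample}: library size must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene_id": [j.gene_id for j in self.junctions],
                "intron_index": [j.intron_index for j in self.junctions],
                "chrom": [j.chrom for j in self.junctions],
                "start": [j.intron_start for j in self.junctions],
                "end": [j.intron_end for j in self.junctions],
                "strand": [j.strand for j in self.junctions],
            }
        )
        for k, sample in enumerate(self.samples):
            frame[sample] = self.counts[:, k]
        return frame

    def to_tsv(self) -> str:
        out = StringIO()
        for sample in self.samples:
            out.write(f"# library_size\t{sample}\t{self.library_sizes[sample]}\n")
        self.to_frame().to_csv(out, sep="\t", index=False)
        return out.getvalue()


@dataclass(frozen=True)
class RetentionTable:
    """Spliced vs retained evidence per junction per sample.

    ``retention_fraction`` is retained/(spliced+retained), NaN where no
    evidence of either kind was seen.
    """

    junctions: tuple[Junction, ...]
    samples: tuple[str, ...]
    spliced: np.ndarray
    retained: np.ndarray

    def retention_fraction(self) -> np.ndarray:
        total = self.spliced + self.retained
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, self.retained / np.maximum(total, 1), np.nan)
        return frac

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene_id": [j.gene_id for j in self.junctions],
                "intron_index": [j.intron_index for j in self.junctions],
                "chrom": [j.chrom for j in self.junctions],
                "start": [j.intron_start for j in self.junctions],
                "end": [j.intron_end for j in self.junctions],
            }
        )
        frac = self.retention_fraction()
        for k, sample in enumerate(self.samples):
            frame[f"{sample}_spliced"] = self.spliced[:, k]
            frame[f"{sample}_retained"] = self.retained[:, k]
            frame[f"{sample}_retention_fraction"] = frac[:, k]
        return frame


def _junction_index(
    junctions: Sequence[Junction], stranded: bool
) -> dict[tuple, list[int]]:
    index: dict[tuple, list[int]] = {}
    for i, j in enumerate(junctions):
        key = j.key + ((j.strand,) if stranded else ())
        index.setdefault(key, []).append(i)
    return index


def _resolve_library_sizes(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    library_sizes: Mapping[str, int] | None,
) -> dict[str, int]:
    if library_sizes is not None:
        return dict(library_sizes)
    return {s: max(len(reads), 1) for s, reads in alignments_by_sample.items()}


def count_junctions(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    junctions: Sequence[Junction],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    stranded: bool = False,
    library_sizes: Mapping[str, int] | None = None,
) -> JunctionCountTable:
    """Count junction-spanning reads per annotated junction per sample.

    A read increments junction ``j`` once iff some gap between consecutive
    blocks equals ``j``'s intron interval exactly and the flanking blocks
    align at least ``min_overhang`` nt on each side; a read with several
    matching gaps increments each matched junction once.
    """
    if not junctions:
        raise ValueError("empty junction set")
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    samples = tuple(alignments_by_sample)
    index = _junction_index(junctions, stranded)
    counts = np.zeros((len(junctions), len(samples)), dtype=int)
    for s_idx, sample in enumerate(samples):
        for read in alignments_by_sample[sample]:
            blocks = read.blocks
            for b in range(len(blocks) - 1):
                left_len = blocks[b][1] - blocks[b][0]
                right_len = blocks[b + 1][1] - blocks[b + 1][0]
                if left_len < min_overhang or right_len < min_overhang:
                    continue
                key = (read.chrom, blocks[b][1], blocks[b + 1][0])
                if stranded:
                    key = key + (read.strand,)
                for j_idx in index.get(key, ()):
                    counts[j_idx, s_idx] += 1
    return JunctionCountTable(
        junctions=tuple(junctions),
        samples=samples,
        counts=counts,
        library_sizes=_resolve_library_sizes(alignments_by_sample, library_sizes),
    )


def count_retention(
    alignments_by_sample: Mapping[str, Sequence[SplicedAlignment]],
    junctions: Sequence[Junction],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    stranded: bool = False,
) -> RetentionTable:
    """Tally spliced vs boundary-crossing (retained) reads per junction.

    A read is retention evidence for junction ``j`` when one contiguous block
    covers ``[intron_start - min_overhang, intron_start + min_overhang)`` or
    ``[intron_end - min_overhang, intron_end + min_overhang)``. Each read is
    counted at most once per junction per category.
    """
    if not junctions:
        raise ValueError("empty junction set")
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    spliced_table = count_junctions(
        alignments_by_sample, junctions, min_overhang, stranded
    )
    samples = spliced_table.samples
    # per chromosome: sorted boundary positions -> junction indices
    boundaries: dict[str, tuple[np.ndarray, list[list[int]]]] = {}
    by_chrom: dict[str, dict[int, list[int]]] = {}
    for i, j in enumerate(junctions):
        cmap = by_chrom.setdefault(j.chrom, {})
        cmap.setdefault(j.intron_start, []).append(i)
        cmap.setdefault(j.intron_end, []).append(i)
    for chrom, cmap in by_chrom.items():
        positions = np.array(sorted(cmap), dtype=int)
        boundaries[chrom] = (positions, [cmap[p] for p in positions])

    retained = np.zeros((len(junctions), len(samples)), dtype=int)
    for s_idx, sample in enumerate(samples):
        for read in alignments_by_sample[sample]:
            entry = boundaries.get(read.chrom)
            if entry is None:
                continue
            positions, idx_lists = entry
            hit: set[int] = set()
            for bs, be in read.blocks:
                # boundaries p with bs <= p - oh and p + oh <= be
                lo = np.searchsorted(positions, bs + min_overhang, side="left")
                hi = np.searchsorted(positions, be - min_overhang, side="right")
                for p_idx in range(lo, hi):
                    for j_idx in idx_lists[p_idx]:
                        if stranded and junctions[j_idx].strand != read.strand:
                            continue
                        hit.add(j_idx)
            for j_idx in hit:
                retained[j_idx, s_idx] += 1
    return RetentionTable(
        junctions=tuple(junctions),
        samples=samples,
        spliced=spliced_table.counts,
        retained=retained,
    )


def cpm_normalize(table: JunctionCountTable) -> np.ndarray:
    """Counts per million mapped reads: counts(j,s) * 1e6 / library_size(s)."""
    sizes = np.array([table.library_sizes[s] for s in table.samples], dtype=float)
    return table.counts * 1e6 / sizes
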