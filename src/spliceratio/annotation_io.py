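"""Gene annotations, spliced alignments, and annotated junctions.

All coordinates are 0-based half-open internally. GTF I/O converts at the
boundary (GTF is 1-based inclusive), so interval arithmetic elsewhere in the
package never has to reason about coordinate conventions.

A :class:`SplicedAlignment` is the minimal representation of one mapped read:
its chromosome and the ordered, gapless genomic blocks it aligns to. Gaps
between consecutive blocks are candidate spliced introns; a gap that exactly
matches an annotated intron is junction-spanning evidence for the spliced
product of that intron.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam
from gffutils.feature import feature_from_line

__all__ = [
    "GeneModel",
    "Junction",
    "SplicedAlignment",
    "AnnotationError",
    "SamParseError",
    "parse_gtf",
    "write_gtf",
    "junctions_of",
    "parse_alignments",
]


class AnnotationError(ValueError):
    """Malformed annotation input (bad GTF line, inconsistent gene model)."""


class SamParseError(ValueError):
    """Malformed spliced-alignment input (bad SAM record or CIGAR)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon structure on one chromosome.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, sorted by
    start and pairwise disjoint. Adjacent exon pairs define the gene's
    annotated introns.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"gene {self.gene_id}: empty or inverted exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Junction:
    """One annotated intron, the unit of junction-ratio analysis.

    ``intron_start`` is the first intronic base (0-based), ``intron_end`` one
    past the last. ``(chrom, intron_start, intron_end)`` is the unique key;
    strand is carried for optional stranded matching but is not part of the
    key.
    """

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    gene_id: str
    intron_index: int

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class SplicedAlignment:
    """One read's gapless aligned genomic blocks (0-based half-open).

    Blocks are sorted and non-overlapping; every gap between consecutive
    blocks has length >= 1 and is a candidate spliced intron.
    """

    read_id: str
    sample_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"
    chrom_known: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise SamParseError(f"read {self.read_id}: no aligned blocks")
        prev_end = None
        for start, end in self.blocks:
            if end <= start:
                raise SamParseError(
                    f"read {self.read_id}: empty block ({start}, {end})"
                )
            if prev_end is not None and start <= prev_end:
                raise SamParseError(
                    f"read {self.read_id}: blocks overlap or touch at {start}"
                )
            prev_end = end

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        """Intervals skipped between consecutive blocks (candidate introns)."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


# ---------------------------------------------------------------------------
# GTF I/O


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of intervals: overlapping or book-ended exon records are merged."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def parse_gtf(annotation_text: str) -> list[GeneModel]:
    """Parse GTF exon records into :class:`GeneModel` objects.

    Only ``exon`` feature lines are used; each must carry a ``gene_id``
    attribute. GTF 1-based inclusive coordinates are converted to 0-based
    half-open. Exon records of one gene are unioned and sorted. Genes are
    returned sorted by gene_id.

    Raises :class:`AnnotationError` naming the offending line number on a
    malformed line (wrong field count, end < start, unknown strand).
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    for lineno, raw in enumerate(annotation_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            feature = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise AnnotationError(f"line {lineno}: unparseable GTF line: {exc}") from exc
        if feature.featuretype != "exon":
            continue
        if feature.end < feature.start:
            raise AnnotationError(
                f"line {lineno}: end ({feature.end}) < start ({feature.start})"
            )
        if feature.strand not in ("+", "-"):
            raise AnnotationError(
                f"line {lineno}: unknown strand symbol {feature.strand!r}"
            )
        gene_ids = feature.attributes.get("gene_id")
        if not gene_ids:
            raise AnnotationError(f"line {lineno}: exon without gene_id attribute")
        gene_id = gene_ids[0]
        start0, end0 = feature.start - 1, feature.end  # 1-based incl -> 0-based half-open
        if gene_id in meta:
            chrom, strand = meta[gene_id]
            if feature.seqid != chrom:
                raise AnnotationError(
                    f"line {lineno}: gene {gene_id} spans multiple chromosomes"
                )
            if feature.strand != strand:
                raise AnnotationError(
                    f"line {lineno}: gene {gene_id} has inconsistent strand"
                )
        else:
            meta[gene_id] = (feature.seqid, feature.strand)
        exons.setdefault(gene_id, []).append((start0, end0))

    genes = []
    for gene_id in sorted(exons):
        chrom, strand = meta[gene_id]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=_merge_intervals(exons[gene_id]),
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], source: str = "spliceratio") -> str:
    """Serialize gene models as GTF exon lines (1-based inclusive)."""
    lines = []
    for gene in genes:
        for i, (start, end) in enumerate(gene.exons, start=1):
            attrs = f'gene_id "{gene.gene_id}"; exon_number "{i}";'
            lines.append(
                "\t".join(
                    [
                        gene.chrom,
                        source,
                        "exon",
                        str(start + 1),
                        str(end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Junctions


def junctions_of(gene: GeneModel) -> list[Junction]:
    """Annotated introns of a gene, one per adjacent exon pair.

    ``intron_index`` is numbered 1..n in genomic order. A single-exon gene
    yields an empty list.
    """
    junctions = []
    for i in range(len(gene.exons) - 1):
        junctions.append(
            Junction(
                chrom=gene.chrom,
                strand=gene.strand,
                intron_start=gene.exons[i][1],
                intron_end=gene.exons[i + 1][0],
                gene_id=gene.gene_id,
                intron_index=i + 1,
            )
        )
    return junctions


# ---------------------------------------------------------------------------
# SAM parsing

# CIGAR operation codes (pysam numeric encoding)
_CIGAR_REF_EXTEND = {0, 2, 7, 8}  # M, D, =, X extend the current block
_CIGAR_SKIP = 3  # N closes a block and opens the next
_CIGAR_QUERY_ONLY = {1, 4, 5, 6}  # I, S, H, P consume no reference


def blocks_from_cigar(
    reference_start: int, cigartuples: Sequence[tuple[int, int]], read_id: str = "?"
) -> tuple[tuple[int, int], ...]:
    """Aligned genomic blocks of a record from its CIGAR.

    Match/mismatch and deletion operations extend the current block; skipped
    regions (N) close a block and open the next. Insertions and clips consume
    no reference. Note this deliberately differs from pysam's ``get_blocks``,
    which splits blocks at deletions.
    """
    blocks: list[tuple[int, int]] = []
    pos = reference_start
    block_start = reference_start
    for op, length in cigartuples:
        if op in _CIGAR_REF_EXTEND:
            pos += length
        elif op == _CIGAR_SKIP:
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += length
            block_start = pos
        elif op in _CIGAR_QUERY_ONLY:
            continue
        else:
            raise SamParseError(f"read {read_id}: invalid CIGAR operation code {op}")
    if pos > block_start:
        blocks.append((block_start, pos))
    if not blocks:
        raise SamParseError(f"read {read_id}: CIGAR consumes no reference bases")
    return tuple(blocks)


def parse_alignments(
    sam_text: str,
    sample_map: Mapping[str, str] | None = None,
    default_sample: str | None = None,
    known_chroms: Iterable[str] | None = None,
) -> dict[str, list[SplicedAlignment]]:
    """Parse SAM text into spliced alignments grouped by sample.

    Sample identity is taken from each record's read group (RG tag), falling
    back through ``sample_map`` (read group -> sample) to ``default_sample``.
    Unmapped, secondary and supplementary records are skipped; the per-sample
    library size is the number of retained primary records, i.e.
    ``len(result[sample])``.

    Records on a chromosome not in ``known_chroms`` (when given) are retained
    but flagged via :attr:`SplicedAlignment.chrom_known`.
    """
    known = set(known_chroms) if known_chroms is not None else None
    by_sample: dict[str, list[SplicedAlignment]] = {}
    # The header is optional in our inputs but pysam needs @SQ lines to
    # resolve reference names, so synthesize them when absent.
    if "@SQ" not in sam_text:
        chroms: list[str] = []
        seen: set[str] = set()
        for line in sam_text.splitlines():
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamParseError("SAM record with fewer than 11 fields")
            rname = fields[2]
            if rname != "*" and rname not in seen:
                seen.add(rname)
                chroms.append(rname)
        sq_lines = "".join(f"@SQ\tSN:{c}\tLN:536870911\n" for c in chroms)
        sam_text = sq_lines + sam_text
    # pysam wants a file; SAM text is spooled through a temporary file.
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as handle:
        handle.write(sam_text)
        path = handle.name
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for record in sam:
                if record.is_unmapped or record.is_secondary or record.is_supplementary:
                    continue
                if record.has_tag("RG"):
                    group = str(record.get_tag("RG"))
                else:
                    group = ""
                if sample_map is not None and group in sample_map:
                    sample = sample_map[group]
                elif group:
                    sample = group
                elif default_sample is not None:
                    sample = default_sample
                else:
                    raise SamParseError(
                        f"read {record.query_name}: no read group and no default sample"
                    )
                if record.cigartuples is None:
                    raise SamParseError(f"read {record.query_name}: missing CIGAR")
                blocks = blocks_from_cigar(
                    record.reference_start, record.cigartuples, record.query_name
                )
                chrom = record.reference_name
                alignment = SplicedAlignment(
                    read_id=record.query_name,
                    sample_id=sample,
                    chrom=chrom,
                    blocks=blocks,
                    strand="-" if record.is_reverse else "+",
                    chrom_known=(known is None or chrom in known),
                )
                by_sample.setdefault(sample, []).append(alignment)
    finally:
        os.unlink(path)
    return by_sample
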