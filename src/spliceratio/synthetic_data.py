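"""Synthetic spliced-read generator for a three-library mis-splicing study.

Emulates stranded total-RNA libraries from an intron-rich genome under three
conditions — a wild type and two mutants — where one mutant reduces the
splicing efficiency of a chosen subset of introns (intron retention) and each
mutant up-regulates a chosen subset of genes. The generative model:

* every intron ``j`` has a splicing efficiency ``theta(j, condition)`` — the
  probability that a transcript molecule has that intron removed;
* every gene ``g`` has a relative expression weight ``lam(g, condition)``;
* a read is produced by choosing a gene proportionally to ``lam``, splicing
  each of its introns independently with probability ``theta``, and placing a
  single-end read of fixed length uniformly on the resulting transcript.

Reads are emitted pre-aligned (perfect alignment, no sequencing error): a
spliced intron spanned by a read produces a gap exactly matching the
annotated intron, a retained intron produces a contiguous block through it.
The truth object records which junctions were mis-spliced and which genes
up-regulated, so downstream recovery can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, Junction, SplicedAlignment, junctions_of

__all__ = ["SimConfig", "SimTruth", "make_truth", "simulate_sample",
           "write_truth", "read_truth", "sam_text_of"]

WT = "WT"
MUT_A = "mutA"
MUT_B = "mutB"
CONDITIONS = (WT, MUT_A, MUT_B)

JunctionKey = tuple[str, int, int]


class ConfigError(ValueError):
    """Infeasible simulation geometry or parameters."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study-like conditions.

    Lengths are in nucleotides. ``frac_misspliced_*`` is the fraction of all
    annotated introns whose efficiency drops from ``theta_wt`` to
    ``theta_mut`` in that mutant; ``frac_up_*`` the fraction of genes whose
    expression weight is multiplied by ``fold_change``; ``frac_up_shared``
    of the genes are up-regulated in both mutants.
    """

    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (50, 150)
    frac_misspliced_a: float = 0.1
    frac_misspliced_b: float = 0.0
    theta_wt: float = 0.9
    theta_mut: float = 0.3
    frac_up_a: float = 0.1
    frac_up_b: float = 0.1
    frac_up_shared: float = 0.05
    fold_change: float = 4.0
    depth: int = 20000
    read_length: int = 100  # matches the emulated libraries' read length
    seed: int = 0
    decouple_classes: bool = True  # mis-spliced introns drawn from non-up genes

    def __post_init__(self) -> None:
        for name in ("frac_misspliced_a", "frac_misspliced_b", "frac_up_a",
                     "frac_up_b", "frac_up_shared"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        for name in ("theta_wt", "theta_mut"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_genes < 1 or self.depth < 1 or self.read_length < 1:
            raise ConfigError("n_genes, depth and read_length must be >= 1")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[1] < self.exons_per_gene[0]:
            raise ConfigError(f"bad exons_per_gene range {self.exons_per_gene}")
        if self.exon_length[0] < 1 or self.intron_length[0] < 1:
            raise ConfigError("exon and intron lengths must be >= 1")
        if self.fold_change <= 0:
            raise ConfigError("fold_change must be > 0")
        # the fully spliced transcript of the shortest possible gene must
        # still accommodate one read
        min_transcript = self.exons_per_gene[0] * self.exon_length[0]
        if min_transcript < self.read_length:
            raise ConfigError(
                f"shortest transcript ({min_transcript} nt) cannot hold a "
                f"{self.read_length} nt read"
            )
        if self.frac_up_shared > min(self.frac_up_a, self.frac_up_b):
            raise ConfigError("frac_up_shared exceeds a per-mutant up fraction")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth generative parameters of one simulated study."""

    genes: tuple[GeneModel, ...]
    theta: Mapping[tuple[JunctionKey, str], float]
    lam: Mapping[tuple[str, str], float]  # (gene_id, condition) -> weight
    read_length: int
    depth: int
    seed: int
    misspliced: Mapping[str, frozenset[JunctionKey]]
    upregulated: Mapping[str, frozenset[str]]
    chrom_lengths: Mapping[str, int]
    conditions: tuple[str, ...] = CONDITIONS

    @property
    def junctions(self) -> list[Junction]:
        out: list[Junction] = []
        for gene in self.genes:
            out.extend(junctions_of(gene))
        return out


def make_truth(config: SimConfig) -> SimTruth:
    """Draw gene models and truth parameters; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    chrom = "chrI"
    genes: list[GeneModel] = []
    cursor = 1000
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons: list[tuple[int, int]] = []
        pos = cursor
        for k in range(n_exons):
            exon_len = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((pos, pos + exon_len))
            pos += exon_len
            if k < n_exons - 1:
                pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i + 1:04d}", chrom, strand, tuple(exons)))
        cursor = pos + 500  # intergenic gap

    gene_ids = [g.gene_id for g in genes]

    # up-regulated gene sets: a shared core plus per-mutant additions
    n_sh = round(config.frac_up_shared * config.n_genes)
    n_a = round(config.frac_up_a * config.n_genes)
    n_b = round(config.frac_up_b * config.n_genes)
    perm = list(rng.permutation(gene_ids))
    up_a = frozenset(perm[:n_a])
    up_b = frozenset(perm[:n_sh] + perm[n_a : n_a + (n_b - n_sh)])

    # mis-spliced junction sets; by default drawn from genes not up-regulated
    # in the same mutant so the splicing and expression signals stay distinct
    all_junctions = [j for g in genes for j in junctions_of(g)]
    mis: dict[str, frozenset[JunctionKey]] = {}
    for cond, frac, up_set in ((MUT_A, config.frac_misspliced_a, up_a),
                               (MUT_B, config.frac_misspliced_b, up_b)):
        n_mis = round(frac * len(all_junctions))
        if config.decouple_classes:
            pool = [j.key for j in all_junctions if j.gene_id not in up_set]
        else:
            pool = [j.key for j in all_junctions]
        if n_mis > len(pool):
            raise ConfigError(f"cannot pick {n_mis} mis-spliced introns from {len(pool)}")
        chosen = rng.permutation(len(pool))[:n_mis]
        mis[cond] = frozenset(pool[i] for i in chosen)

    theta: dict[tuple[JunctionKey, str], float] = {}
    for j in all_junctions:
        for cond in CONDITIONS:
            flagged = cond in mis and j.key in mis[cond]
            theta[(j.key, cond)] = config.theta_mut if flagged else config.theta_wt

    lam: dict[tuple[str, str], float] = {}
    for gid in gene_ids:
        for cond in CONDITIONS:
            up = (cond == MUT_A and gid in up_a) or (cond == MUT_B and gid in up_b)
            lam[(gid, cond)] = config.fold_change if up else 1.0

    chrom_len = max(g.span[1] for g in genes) + 1000
    return SimTruth(
        genes=tuple(genes),
        theta=theta,
        lam=lam,
        read_length=config.read_length,
        depth=config.depth,
        seed=config.seed,
        misspliced=mis,
        upregulated={MUT_A: up_a, MUT_B: up_b},
        chrom_lengths={chrom: chrom_len},
    )


def _read_blocks(
    gene: GeneModel, spliced: np.ndarray, start: int, read_length: int
) -> tuple[tuple[int, int], ...]:
    """Genomic blocks of a read at transcript offset ``start``.

    ``spliced`` marks, per intron, whether this molecule had it removed.
    Retained introns fuse flanking exons into one contiguous genomic piece.
    """
    # genomic pieces of the molecule, merging across retained introns
    pieces: list[tuple[int, int]] = []  # (genomic start, genomic end)
    for i, (es, ee) in enumerate(gene.exons):
        if pieces and pieces[-1][1] == es:  # previous intron retained
            pieces[-1] = (pieces[-1][0], ee)
        else:
            pieces.append((es, ee))
        if i < len(gene.exons) - 1 and not spliced[i]:
            intron_end = gene.exons[i + 1][0]
            pieces[-1] = (pieces[-1][0], intron_end)
    blocks: list[tuple[int, int]] = []
    offset = 0
    remaining = read_length
    for ps, pe in pieces:
        plen = pe - ps
        if start < offset + plen and remaining > 0:
            take_from = max(start - offset, 0)
            take = min(plen - take_from, remaining)
            blocks.append((ps + take_from, ps + take_from + take))
            remaining -= take
        offset += plen
        if remaining == 0:
            break
    return tuple(blocks)


def simulate_sample(
    truth: SimTruth,
    condition: str,
    seed: int,
    sample_id: str | None = None,
) -> list[SplicedAlignment]:
    """Simulate one library of ``truth.depth`` single-end reads.

    Deterministic given (truth, condition, seed). ``sample_id`` defaults to
    the condition label; pass an explicit id to simulate replicate libraries
    of one condition.
    """
    if condition not in truth.conditions:
        raise ConfigError(f"unknown condition {condition!r}")
    sample = condition if sample_id is None else sample_id
    rng = np.random.default_rng(seed)
    genes = truth.genes
    weights = np.array([truth.lam[(g.gene_id, condition)] for g in genes], float)
    probs = weights / weights.sum()
    gene_choice = rng.choice(len(genes), size=truth.depth, p=probs)

    # per-gene cached geometry
    thetas: list[np.ndarray] = []
    for g in genes:
        keys = [j.key for j in junctions_of(g)]
        thetas.append(np.array([truth.theta[(k, condition)] for k in keys], float))

    reads: list[SplicedAlignment] = []
    rl = truth.read_length
    for i in range(truth.depth):
        g = genes[gene_choice[i]]
        th = thetas[gene_choice[i]]
        spliced = rng.random(len(th)) < th if len(th) else np.empty(0, bool)
        exon_total = sum(e - s for s, e in g.exons)
        intron_lens = [g.exons[k + 1][0] - g.exons[k][1] for k in range(len(g.exons) - 1)]
        tlen = exon_total + int(sum(l for l, sp in zip(intron_lens, spliced) if not sp))
        start = int(rng.integers(0, tlen - rl + 1))
        blocks = _read_blocks(g, spliced, start, rl)
        reads.append(
            SplicedAlignment(
                read_id=f"{sample}.r{i:06d}",
                sample_id=sample,
                chrom=g.chrom,
                blocks=blocks,
                strand=g.strand,
            )
        )
    return reads


def sam_text_of(
    reads: Sequence[SplicedAlignment],
    chrom_lengths: Mapping[str, int],
    sample_id: str,
) -> str:
    """Serialize simulated reads as SAM text with a minimal header."""
    out = StringIO()
    out.write("@HD\tVN:1.6\tSO:unsorted\n")
    for chrom in sorted(chrom_lengths):
        out.write(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}\n")
    out.write(f"@RG\tID:{sample_id}\tSM:{sample_id}\n")
    for read in reads:
        cigar_parts = []
        for k, (bs, be) in enumerate(read.blocks):
            if k:
                cigar_parts.append(f"{bs - read.blocks[k - 1][1]}N")
            cigar_parts.append(f"{be - bs}M")
        seq_len = sum(be - bs for bs, be in read.blocks)
        flag = 16 if read.strand == "-" else 0
        out.write(
            "\t".join(
                [
                    read.read_id,
                    str(flag),
                    read.chrom,
                    str(read.blocks[0][0] + 1),
                    "60",
                    "".join(cigar_parts),
                    "*",
                    "0",
                    "0",
                    "A" * seq_len,
                    "*",
                    f"RG:Z:{sample_id}",
                ]
            )
            + "\n"
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Truth I/O


def write_truth(truth: SimTruth) -> str:
    """Lossless TSV dump of theta and lam (one row per parameter value)."""
    rows = []
    for (key, cond), value in sorted(truth.theta.items()):
        chrom, start, end = key
        rows.append(("theta", chrom, start, end, "", cond, value))
    for (gid, cond), value in sorted(truth.lam.items()):
        rows.append(("lam", "", -1, -1, gid, cond, value))
    frame = pd.DataFrame(
        rows, columns=["kind", "chrom", "start", "end", "gene_id", "condition", "value"]
    )
    return frame.to_csv(sep="\t", index=False)


def read_truth(tsv_text: str) -> tuple[dict, dict]:
    """Inverse of :func:`write_truth`: returns (theta, lam) mappings."""
    frame = pd.read_csv(StringIO(tsv_text), sep="\t", keep_default_na=False)
    theta: dict[tuple[JunctionKey, str], float] = {}
    lam: dict[tuple[str, str], float] = {}
    for row in frame.itertuples(index=False):
        if row.kind == "theta":
            theta[((str(row.chrom), int(row.start), int(row.end)), row.condition)] = float(row.value)
        else:
            lam[(str(row.gene_id), row.condition)] = float(row.value)
    return theta, lam
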