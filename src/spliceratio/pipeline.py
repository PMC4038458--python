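"""End-to-end orchestration: simulate → quantify → ratios/filters → DE/overlap.

Every stage reads and writes flat files (TSV/JSON/SAM/GTF) so each can be
re-run and tested independently; the report bundle is a pure function of
config + seed, and the log records every filter count and decision
parameter. Identical config and seed reproduce the bundle byte for byte
(the log carries no timestamps for this reason).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import annotation_io, expression_overlap, junction_quant, ratio_analysis
from . import synthetic_data
from .annotation_io import SplicedAlignment
from .ratio_analysis import FilterConfig
from .synthetic_data import WT, SimConfig

__all__ = ["PipelineConfig", "PipelineError", "run"]

log = logging.getLogger("spliceratio")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``"simulate"`` (generate the three libraries from ``sim``)
    or ``"ingest"`` (read ``gtf_path`` and ``sam_paths``). The baseline
    sample is compared against every other sample; the first two comparison
    samples feed the overlap analysis.
    """

    outdir: str
    mode: str = "simulate"
    sim: SimConfig = field(default_factory=SimConfig)
    gtf_path: str | None = None
    sam_paths: Mapping[str, str] | None = None  # sample_id -> path
    baseline: str = WT
    comparisons: tuple[str, ...] | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    min_overhang: int = junction_quant.DEFAULT_MIN_OVERHANG
    stranded: bool = False
    use_normalized: bool = True
    tail_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and (self.gtf_path is None or not self.sam_paths):
            raise ValueError("ingest mode requires gtf_path and sam_paths")


def _sample_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _stage(name: str):
    log.info("stage: %s", name)


def run(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict it also writes.

    Outputs under ``config.outdir``: annotation.gtf, per-sample SAM files and
    truth.tsv (simulate mode), junction_counts.tsv, retention.tsv,
    ratio_report.tsv, ranked_junctions.tsv, de_<sample>.tsv, up_<sample>.txt,
    overlap.json, summary.json and pipeline.log. Partial outputs are removed
    on failure.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        truth = None
        if config.mode == "simulate":
            stage = "simulate"
            _stage(stage)
            truth = synthetic_data.make_truth(config.sim)
            genes = list(truth.genes)
            (outdir / "annotation.gtf").write_text(annotation_io.write_gtf(genes))
            (outdir / "truth.tsv").write_text(synthetic_data.write_truth(truth))
            seeds = _sample_seeds(config.seed, len(truth.conditions))
            alignments: dict[str, list[SplicedAlignment]] = {}
            for cond, cond_seed in zip(truth.conditions, seeds):
                reads = synthetic_data.simulate_sample(truth, cond, cond_seed)
                alignments[cond] = reads
                sam = synthetic_data.sam_text_of(reads, truth.chrom_lengths, cond)
                (outdir / f"{cond}.sam").write_text(sam)
                log.info("simulated %s: %d reads (seed %d)", cond, len(reads), cond_seed)
        else:
            stage = "ingest"
            _stage(stage)
            genes = annotation_io.parse_gtf(Path(config.gtf_path).read_text())
            chroms = {g.chrom for g in genes}
            alignments = {}
            for sample, path in config.sam_paths.items():
                parsed = annotation_io.parse_alignments(
                    Path(path).read_text(), default_sample=sample, known_chroms=chroms
                )
                reads = [a for group in parsed.values() for a in group]
                alignments[sample] = reads
                log.info("ingested %s: %d primary records", sample, len(reads))

        junctions = [j for g in genes for j in annotation_io.junctions_of(g)]
        samples = list(alignments)
        baseline = config.baseline
        if baseline not in alignments:
            raise ValueError(f"baseline sample {baseline!r} not among {samples}")
        comparisons = (
            list(config.comparisons)
            if config.comparisons is not None
            else [s for s in samples if s != baseline]
        )

        stage = "count"
        _stage(stage)
        table = junction_quant.count_junctions(
            alignments, junctions, config.min_overhang, config.stranded
        )
        (outdir / "junction_counts.tsv").write_text(table.to_tsv())
        retention = junction_quant.count_retention(
            alignments, junctions, config.min_overhang, config.stranded
        )
        retention.to_frame().to_csv(outdir / "retention.tsv", sep="\t", index=False)
        log.info("counted %d junctions in %d samples (min_overhang=%d, stranded=%s)",
                 len(junctions), len(samples), config.min_overhang, config.stranded)

        stage = "ratios"
        _stage(stage)
        records = ratio_analysis.compute_ratios(
            table, baseline, comparisons, config.use_normalized
        )
        records = ratio_analysis.apply_filters(records, config.filters)
        summary = ratio_analysis.summarize(records, config.filters)
        for status, count in summary["status_counts"].items():
            log.info("filter status %s: %d junctions", status, count)
        ratio_analysis.records_to_frame(records).to_csv(
            outdir / "ratio_report.tsv", sep="\t", index=False
        )
        tails = {}
        ranked_frame = None
        for test in comparisons:
            label = ratio_analysis.comparison_label(test, baseline)
            tails[label] = ratio_analysis.tail_fraction(
                records, config.tail_threshold, label
            )
        primary_label = ratio_analysis.comparison_label(comparisons[0], baseline)
        ranked = ratio_analysis.rank_junctions(records, primary_label)
        ranked_frame = ratio_analysis.records_to_frame(ranked)
        ranked_frame.to_csv(outdir / "ranked_junctions.tsv", sep="\t", index=False)
        log.info("tail fractions below %.2f: %s", config.tail_threshold,
                 json.dumps(tails, sort_keys=True))

        stage = "expression"
        _stage(stage)
        counts, discarded = expression_overlap.gene_counts(alignments, genes)
        library_sizes = {s: max(len(alignments[s]), 1) for s in samples}
        up_sets = {}
        for test in comparisons:
            results = expression_overlap.de_test(
                counts, library_sizes, baseline, test, config.alpha
            )
            expression_overlap.de_results_to_frame(results).to_csv(
                outdir / f"de_{test}.tsv", sep="\t", index=False
            )
            up = expression_overlap.upregulated_set(results, config.alpha)
            up_sets[test] = up
            (outdir / f"up_{test}.txt").write_text(
                "".join(f"{g}\n" for g in sorted(up))
            )
            log.info("%s vs %s: %d genes up at p<%g (discarded reads: %s)",
                     test, baseline, len(up), config.alpha,
                     json.dumps(discarded[test], sort_keys=True))

        stage = "overlap"
        _stage(stage)
        overlap_summary = None
        if len(comparisons) >= 2:
            universe = expression_overlap.detectable_universe(counts)
            a, b = comparisons[0], comparisons[1]
            overlap = expression_overlap.overlap_test(
                up_sets[a] & universe, up_sets[b] & universe, len(universe)
            )
            overlap_summary = dataclasses.asdict(overlap)
            overlap_summary["set_a"] = a
            overlap_summary["set_b"] = b
            (outdir / "overlap.json").write_text(
                json.dumps(overlap_summary, indent=2, sort_keys=True) + "\n"
            )
            log.info("overlap %s ∩ %s: %d of %d/%d in universe %d (P=%.3g)",
                     a, b, overlap.intersection, overlap.size_a, overlap.size_b,
                     overlap.universe, overlap.p_value)

        stage = "summary"
        _stage(stage)
        bundle = {
            "mode": config.mode,
            "seed": config.seed,
            "baseline": baseline,
            "comparisons": comparisons,
            "min_overhang": config.min_overhang,
            "alpha": config.alpha,
            "use_normalized": config.use_normalized,
            "filter_config": summary["filter_config"],
            "status_counts": summary["status_counts"],
            "tail_threshold": config.tail_threshold,
            "tail_fractions": tails,
            "library_sizes": library_sizes,
            "overlap": overlap_summary,
        }
        (outdir / "summary.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True) + "\n"
        )
        return bundle
    except Exception as exc:
        log.removeHandler(handler)
        handler.close()
        shutil.rmtree(outdir, ignore_errors=True)
        raise PipelineError(f"[{stage}] {exc}") from exc
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()
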