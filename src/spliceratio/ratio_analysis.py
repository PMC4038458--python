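"""Cross-sample junction-count ratios, the three dot-plot filters, ranking.

For each annotated junction the mutant/wild-type ratio of junction-spanning
read counts measures the change in splicing of that intron: a ratio of 1
means no difference, ratios well below 1 mean the mutant splices the intron
less efficiently (mis-splicing / intron retention).

Three filters clean the ratio set before plotting or ranking, applied in
order with the first matching reason recorded:

F1. junctions with a zero count in any sample (possible mapping noise);
F2. junctions whose raw-count sum over all samples is below ``min_total``
    (default 30; guards against small-sample randomness);
F3. junctions with any ratio above ``max_ratio`` (default 150; keeps the
    view focused on splicing reduction rather than activation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .annotation_io import Junction
from .junction_quant import JunctionCountTable, cpm_normalize

__all__ = [
    "FilterConfig",
    "RatioRecord",
    "STATUS_PASS",
    "compute_ratios",
    "apply_filters",
    "rank_junctions",
    "tail_fraction",
    "summarize",
    "records_to_frame",
]

STATUS_PASS = "pass"
STATUS_F1 = "removed_F1_zero"
STATUS_F2 = "removed_F2_lowsum"
STATUS_F3 = "removed_F3_highratio"
STATUSES = (STATUS_PASS, STATUS_F1, STATUS_F2, STATUS_F3)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the F2/F3 filters (F1 has none)."""

    min_total: int = 30
    max_ratio: float = 150.0

    def __post_init__(self) -> None:
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        if self.max_ratio <= 0:
            raise ValueError("max_ratio must be > 0")


@dataclass(frozen=True)
class RatioRecord:
    """One junction's counts, cross-sample ratios and filter status."""

    junction: Junction
    raw_counts: dict[str, int]
    norm_counts: dict[str, float]
    ratios: dict[str, float]
    status: str

    @property
    def passing(self) -> bool:
        return self.status == STATUS_PASS


def comparison_label(test: str, baseline: str) -> str:
    return f"{test}_vs_{baseline}"


def compute_ratios(
    table: JunctionCountTable,
    baseline: str,
    tests: Sequence[str] | None = None,
    use_normalized: bool = True,
) -> list[RatioRecord]:
    """Per-junction test/baseline count ratios.

    Junctions with a zero raw count in any sample of the table get status
    ``removed_F1_zero`` and no ratios (filter F1; no pseudocounts are used).
    Ratios use library-size-normalized counts by default, which equals the
    raw-count ratio when library sizes match.
    """
    if baseline not in table.samples:
        raise ValueError(f"baseline sample {baseline!r} not in table")
    if tests is None:
        tests = [s for s in table.samples if s != baseline]
    for t in tests:
        if t not in table.samples:
            raise ValueError(f"test sample {t!r} not in table")
    norm = cpm_normalize(table)
    col = {s: k for k, s in enumerate(table.samples)}
    records: list[RatioRecord] = []
    for i, junction in enumerate(table.junctions):
        raw = {s: int(table.counts[i, col[s]]) for s in table.samples}
        norm_counts = {s: float(norm[i, col[s]]) for s in table.samples}
        if any(v == 0 for v in raw.values()):
            records.append(
                RatioRecord(junction, raw, norm_counts, {}, STATUS_F1)
            )
            continue
        values = norm_counts if use_normalized else raw
        ratios = {
            comparison_label(t, baseline): values[t] / values[baseline] for t in tests
        }
        records.append(RatioRecord(junction, raw, norm_counts, ratios, STATUS_PASS))
    return records


def apply_filters(
    records: Sequence[RatioRecord], config: FilterConfig = FilterConfig()
) -> list[RatioRecord]:
    """Apply F2 (low total count) and F3 (extreme ratio) after F1.

    Order is F1 -> F2 -> F3; each junction keeps the first matching removal
    reason. F2 operates on the raw-count sum over exactly the samples in the
    table.
    """
    out: list[RatioRecord] = []
    for record in records:
        if record.status == STATUS_F1:
            out.append(record)
        elif sum(record.raw_counts.values()) < config.min_total:
            out.append(replace(record, status=STATUS_F2))
        elif any(r > config.max_ratio for r in record.ratios.values()):
            out.append(replace(record, status=STATUS_F3))
        else:
            out.append(replace(record, status=STATUS_PASS))
    return out


def _single_comparison(records: Sequence[RatioRecord]) -> str:
    labels = {label for r in records for label in r.ratios}
    if len(labels) != 1:
        raise ValueError(
            f"comparison must be named explicitly; records carry {sorted(labels)}"
        )
    return labels.pop()


def rank_junctions(
    records: Sequence[RatioRecord], comparison: str | None = None
) -> list[RatioRecord]:
    """Passing records sorted ascending by ratio (strongest splicing
    reduction first); ties broken by genomic coordinate."""
    passing = [r for r in records if r.passing]
    if comparison is None:
        comparison = _single_comparison(passing)
    return sorted(
        passing,
        key=lambda r: (r.ratios[comparison], r.junction.chrom,
                       r.junction.intron_start, r.junction.intron_end),
    )


def tail_fraction(
    records: Sequence[RatioRecord], threshold: float, comparison: str | None = None
) -> float:
    """Fraction of passing records with ratio below ``threshold``.

    The bottom tail of the ratio distribution is the mis-splicing signal: a
    heavier tail means more introns with reduced junction usage.
    """
    passing = [r for r in records if r.passing]
    if not passing:
        raise ValueError("no passing records")
    if comparison is None:
        comparison = _single_comparison(passing)
    below = sum(1 for r in passing if r.ratios[comparison] < threshold)
    return below / len(passing)


def summarize(records: Sequence[RatioRecord], config: FilterConfig) -> dict:
    """Counts per filter status plus the filter thresholds used."""
    counts = {status: 0 for status in STATUSES}
    for record in records:
        counts[record.status] += 1
    return {
        "n_junctions": len(records),
        "status_counts": counts,
        "filter_config": {"min_total": config.min_total, "max_ratio": config.max_ratio},
    }


def records_to_frame(records: Sequence[RatioRecord]) -> pd.DataFrame:
    """Flat report table: annotation, raw and normalized counts, ratios,
    status. Also serves as dot-plot data (x = row order, y = ratio)."""
    rows = []
    for record in records:
        j = record.junction
        row: dict = {
            "gene_id": j.gene_id,
            "intron_index": j.intron_index,
            "chrom": j.chrom,
            "start": j.intron_start,
            "end": j.intron_end,
            "strand": j.strand,
        }
        for s, v in record.raw_counts.items():
            row[f"raw_{s}"] = v
        for s, v in record.norm_counts.items():
            row[f"cpm_{s}"] = v
        for label, v in record.ratios.items():
            row[f"ratio_{label}"] = v
        row["status"] = record.status
        rows.append(row)
    return pd.DataFrame(rows)
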