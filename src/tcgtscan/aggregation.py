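"""Cohort-level aggregation and recurrence filtering.

Per-sample TcGT calls for the same gene whose TSSs lie within a linking
distance (default 100 bp, single-linkage/transitive chaining) are merged
into one aggregate — one putative TE promoter for that gene. Occurrence is
then counted per sample group (tumor, normal, tissue, ...), counting each
sample once per aggregate regardless of how many isoforms it contributed.

The cancer-specificity filter keeps aggregates detected in *more than*
``min_tumor_frac`` of tumors and *less than* ``max_normal_frac`` of normal
samples (strict inequalities on both sides). The gene summary table then
reports, per gene with at least one passing aggregate, the union of
contributing samples per group and the corresponding percentages, rounded
half-up to one decimal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .detection import TcGTCall
from .intervals import GenomicInterval
from .models import SampleSheet


@dataclass
class TcGTAggregate:
    """A cluster of same-gene calls with nearby TSSs."""

    aggregate_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss_window: GenomicInterval
    member_calls: list[TcGTCall]
    samples_by_group: dict[str, set[str]] = field(default_factory=dict)

    def count(self, group: str) -> int:
        return len(self.samples_by_group.get(group, ()))

    @property
    def n_members(self) -> int:
        return len(self.member_calls)


@dataclass
class RecurrenceRow:
    """One gene row of the cohort summary (the tumor/normal recurrence table)."""

    gene_name: str
    gene_id: str
    nN: int
    nT: int
    pctN: float
    pctT: float
    product_classes: set[str] = field(default_factory=set)
    n_aggregates: int = 0


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (55.55 -> 55.6), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_percentage(count: int, total: int) -> float:
    """Percentage of ``count``/``total`` rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, 1)


def aggregate_calls(calls: Sequence[TcGTCall], window: int = 100) -> list[TcGTAggregate]:
    """Cluster calls per (gene, chrom, strand) by single-linkage on TSS.

    Two calls join the same aggregate when a chain of calls connects them
    with consecutive TSS distances <= ``window``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_key: dict[tuple[str, str, str], list[TcGTCall]] = {}
    for c in calls:
        by_key.setdefault((c.gene_id, c.chrom, c.strand), []).append(c)

    aggregates: list[TcGTAggregate] = []
    for (gene_id, chrom, strand), members in sorted(by_key.items()):
        members.sort(key=lambda c: (c.tss_pos, c.sample_id, c.transcript_id))
        cluster: list[TcGTCall] = []
        for call in members:
            if cluster and call.tss_pos - cluster[-1].tss_pos > window:
                aggregates.append(_build_aggregate(cluster))
                cluster = []
            cluster.append(call)
        if cluster:
            aggregates.append(_build_aggregate(cluster))
    aggregates.sort(key=lambda a: (a.chrom, a.tss_window.start, a.gene_id))
    return aggregates


def _build_aggregate(cluster: list[TcGTCall]) -> TcGTAggregate:
    first = cluster[0]
    lo = min(c.tss_pos for c in cluster)
    hi = max(c.tss_pos for c in cluster)
    return TcGTAggregate(
        aggregate_id=f"{first.gene_id}@{first.chrom}:{lo}",
        gene_id=first.gene_id,
        gene_name=first.gene_name,
        chrom=first.chrom,
        strand=first.strand,
        tss_window=GenomicInterval(first.chrom, lo, hi + 1, first.strand),
        member_calls=list(cluster),
    )


def count_by_group(
    aggregates: Sequence[TcGTAggregate], sheet: SampleSheet
) -> list[TcGTAggregate]:
    """Fill ``samples_by_group``: distinct contributing samples per group."""
    missing = {
        c.sample_id
        for a in aggregates
        for c in a.member_calls
        if c.sample_id not in sheet.entries
    }
    if missing:
        raise ValueError(f"sample(s) absent from sample sheet: {sorted(missing)}")
    for a in aggregates:
        groups: dict[str, set[str]] = {}
        for c in a.member_calls:
            groups.setdefault(sheet.group_of(c.sample_id), set()).add(c.sample_id)
        a.samples_by_group = groups
    return list(aggregates)


def recurrence_filter(
    aggregates: Sequence[TcGTAggregate],
    n_per_group: Mapping[str, int],
    min_tumor_frac: float = 0.20,
    max_normal_frac: float = 0.10,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
) -> list[TcGTAggregate]:
    """Keep aggregates seen in > ``min_tumor_frac`` of tumors and
    < ``max_normal_frac`` of normals (both strict)."""
    for name, frac in (("min_tumor_frac", min_tumor_frac), ("max_normal_frac", max_normal_frac)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    for group in (tumor_group, normal_group):
        if n_per_group.get(group, 0) <= 0:
            raise ValueError(f"group {group!r} missing or empty in n_per_group")
    n_tumor = n_per_group[tumor_group]
    n_normal = n_per_group[normal_group]
    return [
        a
        for a in aggregates
        if a.count(tumor_group) / n_tumor > min_tumor_frac
        and a.count(normal_group) / n_normal < max_normal_frac
    ]


def gene_table(
    aggregates: Sequence[TcGTAggregate],
    sheet: SampleSheet,
    product_calls: Mapping[tuple[str, str], str] | None = None,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
    n_per_group: Mapping[str, int] | None = None,
) -> list[RecurrenceRow]:
    """Build the per-gene summary from (already filtered) aggregates.

    ``product_calls`` maps (sample_id, transcript_id) to a product-class
    label; each gene row reports the union of labels over member calls.
    Rows are sorted by descending tumor count, then gene name.
    """
    totals = dict(n_per_group) if n_per_group else sheet.n_per_group()
    for group in (tumor_group, normal_group):
        if totals.get(group, 0) <= 0:
            raise ValueError(f"group {group!r} missing from sample sheet")
    by_gene: dict[str, list[TcGTAggregate]] = {}
    for a in aggregates:
        by_gene.setdefault(a.gene_id, []).append(a)

    rows: list[RecurrenceRow] = []
    for gene_id, aggs in by_gene.items():
        tumor_samples: set[str] = set()
        normal_samples: set[str] = set()
        classes: set[str] = set()
        for a in aggs:
            tumor_samples |= a.samples_by_group.get(tumor_group, set())
            normal_samples |= a.samples_by_group.get(normal_group, set())
            if product_calls is not None:
                for c in a.member_calls:
                    label = product_calls.get((c.sample_id, c.transcript_id))
                    if label is not None:
                        classes.add(label)
        rows.append(
            RecurrenceRow(
                gene_name=aggs[0].gene_name,
                gene_id=gene_id,
                nN=len(normal_samples),
                nT=len(tumor_samples),
                pctN=format_percentage(len(normal_samples), totals[normal_group]),
                pctT=format_percentage(len(tumor_samples), totals[tumor_group]),
                product_classes=classes,
                n_aggregates=len(aggs),
            )
        )
    rows.sort(key=lambda r: (-r.nT, r.gene_name))
    return rows


def write_gene_table(rows: Iterable[RecurrenceRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Gene", "nN", "nT", "%N", "%T", "Protein product", "n_aggregates"])
        for r in rows:
            writer.writerow(
                [
                    r.gene_name,
                    r.nN,
                    r.nT,
                    f"{r.pctN:.1f}",
                    f"{r.pctT:.1f}",
                    "; ".join(sorted(r.product_classes)) or ".",
                    r.n_aggregates,
                ]
            )
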