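"""File-level pipeline driver: curate -> detect -> aggregate -> classify.

Runs the full TcGT discovery chain from standard files (RepeatMasker
``.out``, gene GTF, genome FASTA, per-sample transcript GTFs, sample-sheet
TSV) and returns all intermediate and final objects. Both the CLI and the
synthetic end-to-end checker are thin layers over this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .aggregation import (
    RecurrenceRow,
    TcGTAggregate,
    aggregate_calls,
    count_by_group,
    gene_table,
    recurrence_filter,
)
from .detection import DetectionResult, TcGTCall, detect_tcgts
from .gtf import read_gtf
from .models import GeneModel, SampleSheet, TranscriptModel
from .orf import ProductClass, classify_calls
from .rmsk import CuratedTE, curate, parse_rmsk_out, read_curated_bed
from .sequences import open_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    tes: list[CuratedTE]
    genes: list[GeneModel]
    transcripts: list[TranscriptModel]
    calls: list[TcGTCall]
    discards_per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    aggregates: list[TcGTAggregate] = field(default_factory=list)
    passing: list[TcGTAggregate] = field(default_factory=list)
    products: dict[tuple[str, str], ProductClass] = field(default_factory=dict)
    table: list[RecurrenceRow] = field(default_factory=list)


def load_curated_tes(
    rmsk_path: str | Path | None = None,
    curated_bed: str | Path | None = None,
    max_fuse_gap: int = 10_000,
    max_ltr_int_gap: int = 2_000,
) -> list[CuratedTE]:
    """Curated TEs from a raw ``.out`` file or a pre-curated BED."""
    if curated_bed is not None:
        return read_curated_bed(curated_bed)
    if rmsk_path is None:
        raise ValueError("need either rmsk_path or curated_bed")
    records = parse_rmsk_out(rmsk_path)
    return curate(records, max_fuse_gap=max_fuse_gap, max_ltr_int_gap=max_ltr_int_gap)


def run_pipeline(
    sample_gtfs: Mapping[str, str | Path],
    genes_gtf: str | Path,
    genome_fasta: str | Path,
    sheet: SampleSheet,
    rmsk_path: str | Path | None = None,
    curated_bed: str | Path | None = None,
    window: int = 100,
    min_tumor_frac: float = 0.20,
    max_normal_frac: float = 0.10,
    tumor_group: str = "tumor",
    normal_group: str = "normal",
    min_orf_codons: int = 30,
    first_exon_mask: str = "body",
) -> PipelineResult:
    """Execute the full chain on a cohort.

    ``sample_gtfs`` maps sample_id to its assembled-transcript GTF path.
    All samples must appear in the sample sheet.
    """
    tes = load_curated_tes(rmsk_path, curated_bed)
    genes = read_gtf(genes_gtf, kind="genes")
    genome = open_genome(genome_fasta)

    all_transcripts: list[TranscriptModel] = []
    all_calls: list[TcGTCall] = []
    discards: dict[str, dict[str, int]] = {}
    for sample_id, path in sorted(sample_gtfs.items()):
        transcripts = read_gtf(path, kind="transcripts", sample_id=sample_id)
        result: DetectionResult = detect_tcgts(
            transcripts, genes, tes, first_exon_mask=first_exon_mask
        )
        all_transcripts.extend(transcripts)
        all_calls.extend(result.calls)
        discards[sample_id] = dict(result.discards)

    aggregates = count_by_group(aggregate_calls(all_calls, window=window), sheet)
    passing = recurrence_filter(
        aggregates,
        sheet.n_per_group(),
        min_tumor_frac=min_tumor_frac,
        max_normal_frac=max_normal_frac,
        tumor_group=tumor_group,
        normal_group=normal_group,
    )
    products = classify_calls(
        all_calls, all_transcripts, genes, genome, min_orf_codons=min_orf_codons
    )
    table = gene_table(
        passing,
        sheet,
        product_calls={k: v.value for k, v in products.items()},
        tumor_group=tumor_group,
        normal_group=normal_group,
    )
    return PipelineResult(
        tes=tes,
        genes=genes,
        transcripts=all_transcripts,
        calls=all_calls,
        discards_per_sample=discards,
        aggregates=aggregates,
        passing=passing,
        products=products,
        table=table,
    )


def discover_sample_gtfs(sample_dir: str | Path) -> dict[str, Path]:
    """Map sample_id -> GTF path for every ``<sample_id>.gtf`` in a directory."""
    out = {p.stem: p for p in sorted(Path(sample_dir).glob("*.gtf"))}
    if not out:
        raise FileNotFoundError(f"no .gtf files under {sample_dir}")
    return out
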