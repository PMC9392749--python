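"""Per-sample TcGT calling.

A transpochimeric gene transcript (TcGT) is an assembled transcript that

1. starts inside a transposable element — its 1-bp TSS overlaps a fragment
   of a curated TE unit (any TE strand);
2. initiates outside annotated genes — its first exon overlaps no annotated
   gene body (so the promoter is cryptic, not a known gene promoter); and
3. splices into a gene — at least one downstream exon overlaps >= 1 bp of
   coding exons of a gene on the *same strand* as the transcript.

Transcripts failing any test are discarded with a tallied reason
(``tss_not_te``, ``first_exon_in_gene``, ``no_coding_target``; unstranded
transcripts are set aside under ``unstranded``). The target gene is the one
with maximal coding-exon overlap; ties break by total exon/gene-body
overlap, then lexicographic gene_id, so output is deterministic.

Mono-exonic transcripts get a modified rule (the first-exon test cannot
apply verbatim): the TSS must be in a TE, the 5' stretch of the exon up to
its first coding-exon overlap must lie outside all gene bodies, and the
exon must overlap coding sequence. Such calls carry ``monoexonic=True``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, overlap_bp
from .models import GeneModel, TranscriptModel
from .rmsk import CuratedTE

DISCARD_REASONS = ("unstranded", "tss_not_te", "first_exon_in_gene", "no_coding_target")


@dataclass
class TcGTCall:
    """One per-sample chimeric transcript call."""

    sample_id: str
    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: GenomicInterval
    tss_te_unit_id: str
    tss_te_name: str
    te_chain: list[str]
    n_exons: int
    coding_overlap_bp: int
    monoexonic: bool = False

    def __post_init__(self) -> None:
        if self.coding_overlap_bp < 1:
            raise ValueError("call without coding overlap")
        if self.tss.length() != 1:
            raise ValueError("TSS must be a 1-bp interval")

    @property
    def tss_pos(self) -> int:
        return self.tss.start


@dataclass
class DetectionResult:
    """Calls plus discard accounting for one detection run."""

    calls: list[TcGTCall]
    discards: dict[str, int] = field(default_factory=dict)
    discarded_transcripts: list[tuple[str, str, str]] = field(default_factory=list)
    # (sample_id, transcript_id, reason)

    @property
    def n_input(self) -> int:
        return len(self.calls) + sum(self.discards.values())


class _Trees:
    """Interval indexes over TE fragments, gene bodies and coding exons."""

    def __init__(self, genes: Sequence[GeneModel], tes: Sequence[CuratedTE]):
        self.te_frag: dict[str, IntervalTree] = {}
        for te in tes:
            for frag in te.fragments:
                self.te_frag.setdefault(frag.chrom, IntervalTree()).addi(
                    frag.start, frag.end, te
                )
        self.gene_body: dict[str, IntervalTree] = {}
        self.coding: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            self.gene_body.setdefault(g.chrom, IntervalTree()).addi(
                g.body.start, g.body.end, g
            )
            for ce in g.coding_exons:
                self.coding.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                    ce.start, ce.end, g
                )

    def tes_at(self, iv: GenomicInterval) -> list[CuratedTE]:
        tree = self.te_frag.get(iv.chrom)
        if tree is None:
            return []
        hits = tree.overlap(iv.start, iv.end)
        # deterministic: smallest overlapping fragment first, then unit_id
        return [
            h.data
            for h in sorted(hits, key=lambda h: (h.end - h.begin, h.data.unit_id))
        ]

    def genes_overlapping_body(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self.gene_body.get(iv.chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.overlap(iv.start, iv.end)), key=lambda g: g.gene_id)

    def coding_hits(self, iv: GenomicInterval, strand: str) -> list[tuple[GeneModel, int]]:
        tree = self.coding.get((iv.chrom, strand))
        if tree is None:
            return []
        out = []
        for h in tree.overlap(iv.start, iv.end):
            out.append((h.data, min(iv.end, h.end) - max(iv.start, h.begin)))
        return out


def _te_chain(t: TranscriptModel, trees: _Trees) -> list[str]:
    """Unit names of curated TEs overlapped by any exon, in transcript order."""
    chain: list[str] = []
    seen: set[str] = set()
    for exon in t.exons:
        hits = trees.tes_at(exon)
        # order TEs within an exon along the transcript direction
        hits.sort(
            key=lambda te: -te.span.start if t.strand == "-" else te.span.start
        )
        for te in hits:
            if te.unit_id not in seen:
                seen.add(te.unit_id)
                chain.append(te.unit_name)
    return chain


def _pick_target(
    t: TranscriptModel,
    candidate_exons: Sequence[GenomicInterval],
    trees: _Trees,
) -> tuple[GeneModel, int] | None:
    per_gene: dict[str, int] = {}
    genes: dict[str, GeneModel] = {}
    for exon in candidate_exons:
        for gene, bp in trees.coding_hits(exon, t.strand):
            per_gene[gene.gene_id] = per_gene.get(gene.gene_id, 0) + bp
            genes[gene.gene_id] = gene
    if not per_gene:
        return None

    def _key(gid: str):
        gene = genes[gid]
        body_overlap = overlap_bp(list(t.exons), [gene.body])
        return (-per_gene[gid], -body_overlap, gid)

    best = min(per_gene, key=_key)
    return genes[best], per_gene[best]


def detect_tcgts(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    tes: Sequence[CuratedTE],
    first_exon_mask: Literal["body", "exons"] = "body",
) -> DetectionResult:
    """Call TcGTs among per-sample transcripts.

    ``first_exon_mask`` selects what "annotated gene" means for the
    first-exon discard: whole gene bodies (default) or coding exons only.
    """
    if not tes:
        raise ValueError("empty curated TE list — run repeat curation first")
    if not genes:
        raise ValueError("empty gene list")
    trees = _Trees(genes, tes)
    result = DetectionResult(calls=[], discards={r: 0 for r in DISCARD_REASONS})

    for t in transcripts:
        reason = _classify_transcript(t, trees, first_exon_mask, result)
        if reason is not None:
            result.discards[reason] += 1
            result.discarded_transcripts.append((t.sample_id, t.transcript_id, reason))

    result.calls.sort(key=lambda c: (c.sample_id, c.chrom, c.tss_pos, c.gene_id))
    return result


def _first_exon_hits_gene(
    exon: GenomicInterval, trees: _Trees, mask: str
) -> bool:
    if mask == "exons":
        for strand in ("+", "-"):
            if trees.coding_hits(exon, strand):
                return True
        return False
    return bool(trees.genes_overlapping_body(exon))


def _classify_transcript(
    t: TranscriptModel, trees: _Trees, first_exon_mask: str, result: DetectionResult
) -> str | None:
    """Apply the three TcGT tests; append a call or return a discard reason."""
    if t.strand not in ("+", "-"):
        return "unstranded"

    tss = t.tss
    tss_tes = trees.tes_at(tss)
    if not tss_tes:
        return "tss_not_te"
    tss_te = tss_tes[0]

    if t.n_exons == 1:
        return _classify_monoexonic(t, tss_te, trees, result)

    if _first_exon_hits_gene(t.exons[0], trees, first_exon_mask):
        return "first_exon_in_gene"

    target = _pick_target(t, t.exons[1:], trees)
    if target is None:
        return "no_coding_target"
    gene, bp = target
    result.calls.append(_make_call(t, gene, bp, tss_te, trees))
    return None


def _classify_monoexonic(
    t: TranscriptModel, tss_te, trees: _Trees, result: DetectionResult
) -> str | None:
    exon = t.exons[0]
    target = _pick_target(t, [exon], trees)
    if target is None:
        return "no_coding_target"
    gene, bp = target
    # 5' stretch of the exon before its first coding-exon overlap must lie
    # outside all gene bodies (the analogue of the first-exon test).
    hit_bounds = [
        (min(exon.end, h.end) , max(exon.start, h.begin))
        for h in trees.coding.get((exon.chrom, t.strand), IntervalTree()).overlap(
            exon.start, exon.end
        )
    ]
    if t.strand == "-":
        first_overlap = max(hi for hi, _ in hit_bounds)  # 5'-most on -
        head = (
            GenomicInterval(exon.chrom, first_overlap, exon.end, t.strand)
            if first_overlap < exon.end
            else None
        )
    else:
        first_overlap = min(lo for _, lo in hit_bounds)
        head = (
            GenomicInterval(exon.chrom, exon.start, first_overlap, t.strand)
            if first_overlap > exon.start
            else None
        )
    if head is not None and trees.genes_overlapping_body(head):
        return "first_exon_in_gene"
    result.calls.append(_make_call(t, gene, bp, tss_te, trees, monoexonic=True))
    return None


def _make_call(
    t: TranscriptModel,
    gene: GeneModel,
    coding_bp: int,
    tss_te: CuratedTE,
    trees: _Trees,
    monoexonic: bool = False,
) -> TcGTCall:
    return TcGTCall(
        sample_id=t.sample_id,
        transcript_id=t.transcript_id,
        gene_id=gene.gene_id,
        gene_name=gene.gene_name,
        chrom=t.chrom,
        strand=t.strand,
        tss=t.tss,
        tss_te_unit_id=tss_te.unit_id,
        tss_te_name=tss_te.unit_name,
        te_chain=_te_chain(t, trees),
        n_exons=t.n_exons,
        coding_overlap_bp=coding_bp,
        monoexonic=monoexonic,
    )


CALL_COLUMNS = [
    "sample_id",
    "transcript_id",
    "chrom",
    "strand",
    "tss_pos",
    "gene_id",
    "gene_name",
    "tss_te_unit_id",
    "tss_te_name",
    "te_chain",
    "n_exons",
    "coding_overlap_bp",
    "monoexonic",
]


def write_calls(calls: Iterable[TcGTCall], path: str | Path) -> None:
    """Write calls as TSV, sorted by (sample_id, chrom, tss, gene_id)."""
    rows = sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.tss_pos, c.gene_id))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for c in rows:
            writer.writerow(
                [
                    c.sample_id,
                    c.transcript_id,
                    c.chrom,
                    c.strand,
                    c.tss_pos,
                    c.gene_id,
                    c.gene_name,
                    c.tss_te_unit_id,
                    c.tss_te_name,
                    ",".join(c.te_chain),
                    c.n_exons,
                    c.coding_overlap_bp,
                    int(c.monoexonic),
                ]
            )


def read_calls(path: str | Path) -> list[TcGTCall]:
    calls: list[TcGTCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        unknown = set(header) - set(CALL_COLUMNS)
        if unknown:
            raise ValueError(f"{path}: unknown column(s): {sorted(unknown)}")
        missing = set(CALL_COLUMNS) - set(header)
        if missing:
            raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
        idx = {name: header.index(name) for name in CALL_COLUMNS}
        for row in reader:
            tss_pos = int(row[idx["tss_pos"]])
            strand = row[idx["strand"]]
            chrom = row[idx["chrom"]]
            chain = row[idx["te_chain"]]
            calls.append(
                TcGTCall(
                    sample_id=row[idx["sample_id"]],
                    transcript_id=row[idx["transcript_id"]],
                    gene_id=row[idx["gene_id"]],
                    gene_name=row[idx["gene_name"]],
                    chrom=chrom,
                    strand=strand,
                    tss=GenomicInterval(chrom, tss_pos, tss_pos + 1, strand),
                    tss_te_unit_id=row[idx["tss_te_unit_id"]],
                    tss_te_name=row[idx["tss_te_name"]],
                    te_chain=chain.split(",") if chain else [],
                    n_exons=int(row[idx["n_exons"]]),
                    coding_overlap_bp=int(row[idx["coding_overlap_bp"]]),
                    monoexonic=bool(int(row[idx["monoexonic"]])),
                )
            )
    return calls
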