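"""GTF reading and writing.

Parsing is delegated to :mod:`gffutils` (in-memory database); this module
only converts between the GTF convention (1-based, closed) and the
package-internal 0-based half-open intervals, and assembles the parsed
features into :class:`TranscriptModel` / :class:`GeneModel` objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import gffutils

from .intervals import GenomicInterval, merge_intervals
from .models import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)


def _open_db(path: str | Path) -> gffutils.FeatureDB:
    try:
        return gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"failed to parse GTF {path}: {exc}") from exc


def _attr(feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def _interval(feature) -> GenomicInterval:
    strand = feature.strand if feature.strand in ("+", "-") else "."
    # GTF is 1-based inclusive; internal convention is 0-based half-open.
    return GenomicInterval(feature.seqid, feature.start - 1, feature.end, strand)


def read_gtf(
    path: str | Path,
    kind: Literal["transcripts", "genes"] = "transcripts",
    sample_id: str = "",
) -> list[TranscriptModel] | list[GeneModel]:
    """Read a GTF file as transcript models or gene models.

    ``kind="transcripts"`` parses StringTie-style ``transcript``/``exon``
    records into :class:`TranscriptModel` (``sample_id`` is attached to every
    transcript). ``kind="genes"`` additionally requires ``CDS`` records with
    a valid frame column and returns :class:`GeneModel` objects.
    """
    db = _open_db(path)
    if kind == "transcripts":
        return _read_transcripts(db, sample_id, path)
    if kind == "genes":
        return _read_genes(db, path)
    raise ValueError(f"unknown kind {kind!r}")


def _read_transcripts(db, sample_id: str, path) -> list[TranscriptModel]:
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    declared: set[str] = set()
    for feat in db.all_features():
        tid = _attr(feat, "transcript_id")
        if feat.featuretype == "transcript":
            if tid is None:
                raise ValueError(f"{path}: transcript record without transcript_id")
            declared.add(tid)
            if tid not in exons_by_tid:
                exons_by_tid[tid] = []
                order.append(tid)
        elif feat.featuretype == "exon":
            if tid is None:
                raise ValueError(f"{path}: exon record without transcript_id")
            if tid not in exons_by_tid:
                exons_by_tid[tid] = []
                order.append(tid)
            exons_by_tid[tid].append(_interval(feat))

    transcripts: list[TranscriptModel] = []
    n_skipped = 0
    for tid in order:
        exons = exons_by_tid[tid]
        if not exons:
            n_skipped += 1
            continue
        strand = exons[0].strand
        reverse = strand == "-"
        exons = sorted(exons, key=lambda e: e.start, reverse=reverse)
        transcripts.append(
            TranscriptModel(transcript_id=tid, sample_id=sample_id, strand=strand, exons=exons)
        )
    if n_skipped:
        logger.warning("%s: skipped %d transcript(s) without exon records", path, n_skipped)
    return transcripts


def _read_genes(db, path) -> list[GeneModel]:
    spans: dict[str, list[GenomicInterval]] = {}
    names: dict[str, str] = {}
    strands: dict[str, str] = {}
    cds_by_transcript: dict[str, dict[str, list[tuple[GenomicInterval, int]]]] = {}

    for feat in db.all_features():
        gid = _attr(feat, "gene_id")
        if gid is None:
            continue
        iv = _interval(feat)
        spans.setdefault(gid, []).append(iv)
        name = _attr(feat, "gene_name")
        if name:
            names.setdefault(gid, name)
        if iv.strand != ".":
            strands.setdefault(gid, iv.strand)
        if feat.featuretype == "CDS":
            if feat.frame not in ("0", "1", "2"):
                raise ValueError(
                    f"{path}: CDS without frame for gene {gid!r} at "
                    f"{feat.seqid}:{feat.start}-{feat.end}"
                )
            tid = _attr(feat, "transcript_id") or gid
            cds_by_transcript.setdefault(gid, {}).setdefault(tid, []).append(
                (iv, int(feat.frame))
            )

    genes: list[GeneModel] = []
    for gid, ivs in spans.items():
        chrom = ivs[0].chrom
        strand = strands.get(gid, ".")
        body = GenomicInterval(chrom, min(i.start for i in ivs), max(i.end for i in ivs), strand)
        per_transcript = cds_by_transcript.get(gid, {})
        coding = merge_intervals(
            iv for segs in per_transcript.values() for iv, _ in segs
        )
        cds_segments: list[tuple[GenomicInterval, int]] = []
        if per_transcript:
            # canonical transcript = longest total CDS, ties broken by id
            def _key(tid: str) -> tuple[int, str]:
                return (-sum(iv.length() for iv, _ in per_transcript[tid]), tid)

            canonical_tid = min(per_transcript, key=_key)
            segs = per_transcript[canonical_tid]
            cds_segments = sorted(segs, key=lambda s: s[0].start, reverse=(strand == "-"))
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=names.get(gid, gid),
                strand=strand,
                body=body,
                coding_exons=coding,
                cds_segments=cds_segments,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.body.start, g.gene_id))
    return genes


def _fmt_attrs(**attrs: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items() if v is not None)


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "tcgtscan",
) -> None:
    """Write StringTie-style transcript/exon GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            span = t.span()
            attrs = _fmt_attrs(transcript_id=t.transcript_id)
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}"
                f"\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for exon in sorted(t.exons, key=lambda e: e.start):
                fh.write(
                    f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_genes_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "tcgtscan") -> None:
    """Write gene annotation (gene/transcript/exon/CDS) for GeneModels whose
    exon structure equals their CDS structure plus any surrounding exons
    recorded in ``coding_exons`` — used mainly by the synthetic generator."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = _fmt_attrs(gene_id=g.gene_id, gene_name=g.gene_name)
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            tattrs = _fmt_attrs(gene_id=g.gene_id, transcript_id=tid, gene_name=g.gene_name)
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t{g.strand}\t.\t{tattrs}\n"
            )
            for iv, frame in sorted(g.cds_segments, key=lambda s: s[0].start):
                fh.write(
                    f"{iv.chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{g.strand}\t{frame}\t{tattrs}\n"
                )
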