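"""Sequence extraction and translation helpers (FASTA access via pyfaidx)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from pyfaidx import Fasta

from .intervals import GenomicInterval
from .models import GeneModel, TranscriptModel


def open_genome(path: str | Path) -> Fasta:
    """Open a FASTA file with random access (builds the .fai index if absent)."""
    return Fasta(str(path), sequence_always_upper=True)


def fetch(genome: Fasta, iv: GenomicInterval) -> str:
    """Fetch the + strand sequence of an interval, uppercase."""
    if iv.chrom not in genome:
        raise KeyError(f"contig {iv.chrom!r} not in genome")
    contig = genome[iv.chrom]
    if iv.end > len(contig):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} beyond contig end ({len(contig)})"
        )
    return str(contig[iv.start : iv.end]).upper()


def extract_spliced_sequence(t: TranscriptModel, genome: Fasta) -> str:
    """Spliced cDNA of a transcript: exon sequences concatenated 5'->3',
    reverse-complemented for - strand transcripts."""
    parts = [fetch(genome, e) for e in sorted(t.exons, key=lambda e: e.start)]
    seq = "".join(parts)
    if t.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def cds_sequence(segments: Sequence[tuple[GenomicInterval, int]], strand: str, genome: Fasta) -> str:
    """Concatenated CDS nucleotide sequence in translation orientation."""
    ivs = sorted((iv for iv, _ in segments), key=lambda iv: iv.start)
    seq = "".join(fetch(genome, iv) for iv in ivs)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(segments, strand: str, genome: Fasta) -> str:
    """Translate a CDS (stop codon, if present, is stripped from the protein)."""
    nt = cds_sequence(segments, strand, genome)
    nt = nt[: len(nt) - len(nt) % 3]
    protein = str(Seq(nt).translate())
    return protein.rstrip("*")


def attach_proteins(genes: Sequence[GeneModel], genome: Fasta) -> None:
    """Fill ``canonical_protein`` for every gene that has CDS segments."""
    for gene in genes:
        if gene.cds_segments and gene.canonical_protein is None:
            gene.canonical_protein = translate_cds(gene.cds_segments, gene.strand, genome)


def cdna_to_genomic(
    t: TranscriptModel, cdna_start: int, cdna_end: int
) -> list[GenomicInterval]:
    """Map a half-open cDNA offset range to ordered genomic intervals.

    Offsets are in transcript orientation (0 = the TSS base); the returned
    intervals are ordered 5'->3' along the transcript.
    """
    if not (0 <= cdna_start < cdna_end):
        raise ValueError("bad cdna range")
    out: list[GenomicInterval] = []
    offset = 0
    for exon in t.exons:  # already 5'->3'
        elen = exon.length()
        lo = max(cdna_start, offset)
        hi = min(cdna_end, offset + elen)
        if lo < hi:
            if t.strand == "-":
                g_end = exon.end - (lo - offset)
                g_start = exon.end - (hi - offset)
            else:
                g_start = exon.start + (lo - offset)
                g_end = exon.start + (hi - offset)
            out.append(GenomicInterval(exon.chrom, g_start, g_end, t.strand))
        offset += elen
    if offset < cdna_end:
        raise ValueError("cdna range beyond transcript length")
    return out


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
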