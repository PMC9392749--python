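"""ORF prediction and protein-product classification.

A chimeric transcript may still encode the target gene's full protein (when
the TE promoter merely replaces the 5' UTR), or a modified derivative. Each
transcript's predicted ORF — the longest ATG-initiated open reading frame
with an in-frame stop — is compared with the gene's canonical CDS *in
genomic coordinates*, so splice-altered isoforms that happen to share
sequence are not mislabeled. The resulting label vocabulary:

===========  ==========================================================
canonical    predicted CDS identical to the canonical CDS
N-ext        same stop and frame, start upstream in-frame
C-ext        same start, stop downstream in-frame
N-trunc      same stop and frame, start downstream in-frame
C-trunc      same start, stop upstream in-frame
N-C-trunc    both ends strictly inside, frame preserved
out-of-frame ORF overlaps the canonical CDS but >= half of the shared
             bases are read in a shifted frame
non-coding   no ORF, or an ORF with no genomic CDS overlap
===========  ==========================================================

Mixed end changes outside this vocabulary (e.g. extended at both ends) are
labeled by their 5'-end change, since TcGTs are 5'-end events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .detection import TcGTCall
from .intervals import GenomicInterval
from .models import GeneModel, TranscriptModel
from .sequences import cdna_to_genomic, extract_spliced_sequence, translate_cds

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


class ProductClass(str, Enum):
    CANONICAL = "canonical"
    N_TRUNC = "N-trunc"
    C_TRUNC = "C-trunc"
    N_C_TRUNC = "N-C-trunc"
    N_EXT = "N-ext"
    C_EXT = "C-ext"
    OUT_OF_FRAME = "out-of-frame"
    NON_CODING = "non-coding"


@dataclass
class OrfPrediction:
    """A predicted ORF on a spliced transcript.

    ``cdna_start``/``cdna_end`` are 0-based half-open offsets on the spliced
    sequence; the start is at the A of the ATG and the end is *after* the
    stop codon. ``genomic_cds`` excludes the stop codon (the GTF CDS
    convention), each segment carrying its frame (bases to skip to the next
    codon boundary).
    """

    cdna_start: int
    cdna_end: int
    genomic_cds: list[tuple[GenomicInterval, int]]
    protein: str

    def __post_init__(self) -> None:
        if (self.cdna_end - self.cdna_start) % 3 != 0:
            raise ValueError("ORF length not a multiple of 3")
        if not self.protein.startswith("M") or "*" in self.protein:
            raise ValueError("invalid ORF protein")


def predict_orf(cdna: str, min_orf_codons: int = 30) -> OrfPrediction | None:
    """Longest ATG-initiated, stop-terminated ORF of a spliced transcript.

    Ties on length break to the 5'-most start. Returns None when no ORF
    reaches ``min_orf_codons`` protein codons (stop excluded). The returned
    prediction carries no genomic segments (see :func:`orf_with_genomic`).
    """
    if len(cdna) < 3:
        raise ValueError("cdna shorter than one codon")
    seq = cdna.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN character(s) in cdna: {sorted(bad)}")

    best: tuple[int, int] | None = None  # (start, end-after-stop)
    # earliest in-frame stop per frame, computed lazily while scanning
    pos = seq.find("ATG")
    while pos != -1:
        end = _first_stop_after(seq, pos)
        if end is not None:
            length = end - pos
            if best is None or length > best[1] - best[0]:
                best = (pos, end)
        pos = seq.find("ATG", pos + 1)
    if best is None:
        return None
    start, end = best
    n_codons = (end - start) // 3 - 1  # protein codons, stop excluded
    if n_codons < min_orf_codons:
        return None
    protein = str(Seq(seq[start : end - 3]).translate())
    return OrfPrediction(cdna_start=start, cdna_end=end, genomic_cds=[], protein=protein)


def _first_stop_after(seq: str, start: int) -> int | None:
    for i in range(start + 3, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i + 3
    return None


def orf_with_genomic(orf: OrfPrediction, transcript: TranscriptModel) -> OrfPrediction:
    """Attach genomic CDS segments (stop codon excluded) to a prediction."""
    segments = cdna_to_genomic(transcript, orf.cdna_start, orf.cdna_end - 3)
    out: list[tuple[GenomicInterval, int]] = []
    cds_pos = 0
    for seg in segments:
        frame = (3 - cds_pos % 3) % 3
        out.append((seg, frame))
        cds_pos += seg.length()
    orf.genomic_cds = out
    return orf


def _phase_map(
    segments: Sequence[tuple[GenomicInterval, int]], strand: str
) -> dict[int, int]:
    """Map each genomic CDS base to its codon phase (0/1/2), walking the
    segments in translation orientation."""
    ordered = sorted((iv for iv, _ in segments), key=lambda iv: iv.start, reverse=(strand == "-"))
    phases: dict[int, int] = {}
    pos = 0
    for iv in ordered:
        coords = range(iv.end - 1, iv.start - 1, -1) if strand == "-" else range(iv.start, iv.end)
        for g in coords:
            phases[g] = pos % 3
            pos += 1
    return phases


def _terminal_coords(
    segments: Sequence[tuple[GenomicInterval, int]], strand: str
) -> tuple[int, int]:
    """(5'-most, 3'-most) genomic base of a CDS, in translation orientation."""
    starts = [iv.start for iv, _ in segments]
    ends = [iv.end for iv, _ in segments]
    if strand == "-":
        return max(ends) - 1, min(starts)
    return min(starts), max(ends) - 1


def classify_product(orf: OrfPrediction | None, gene: GeneModel) -> ProductClass:
    """Classify a predicted ORF against the gene's canonical CDS.

    Comparison is on genomic coordinates and frames (see module docstring).
    For the ext/trunc classes a protein-string containment check runs as a
    secondary consistency check when the canonical protein is available;
    a mismatch is logged but never changes the label.
    """
    if not gene.cds_segments:
        raise ValueError(f"{gene.gene_id}: gene has no CDS segments")
    if orf is None or not orf.genomic_cds:
        return ProductClass.NON_CODING

    strand = gene.strand
    pred_phase = _phase_map(orf.genomic_cds, strand)
    canon_phase = _phase_map(gene.cds_segments, strand)
    shared = pred_phase.keys() & canon_phase.keys()
    if not shared:
        return ProductClass.NON_CODING

    shifted = sum(1 for g in shared if pred_phase[g] != canon_phase[g])
    if shifted * 2 >= len(shared):
        return ProductClass.OUT_OF_FRAME

    pred5, pred3 = _terminal_coords(orf.genomic_cds, strand)
    canon5, canon3 = _terminal_coords(gene.cds_segments, strand)

    def upstream(a: int, b: int) -> bool:  # a strictly 5' of b
        return a > b if strand == "-" else a < b

    if pred5 == canon5 and pred3 == canon3:
        return ProductClass.CANONICAL
    if pred3 == canon3:
        label = ProductClass.N_EXT if upstream(pred5, canon5) else ProductClass.N_TRUNC
    elif pred5 == canon5:
        label = ProductClass.C_TRUNC if upstream(pred3, canon3) else ProductClass.C_EXT
    elif upstream(canon5, pred5) and upstream(pred3, canon3):
        label = ProductClass.N_C_TRUNC
    else:
        # mixed change outside the table vocabulary: label by the 5' end
        label = ProductClass.N_EXT if upstream(pred5, canon5) else ProductClass.N_TRUNC

    _check_protein_containment(label, orf, gene)
    return label


def _check_protein_containment(label: ProductClass, orf: OrfPrediction, gene: GeneModel) -> None:
    canonical = gene.canonical_protein
    if canonical is None:
        return
    ok = True
    if label is ProductClass.N_EXT:
        ok = orf.protein.endswith(canonical)
    elif label is ProductClass.C_EXT:
        ok = orf.protein.startswith(canonical) and len(orf.protein) > len(canonical)
    elif label is ProductClass.N_TRUNC:
        ok = canonical.endswith(orf.protein)
    elif label is ProductClass.C_TRUNC:
        ok = canonical.startswith(orf.protein)
    if not ok:
        logger.warning(
            "%s: %s label without protein containment (splice-altered interior?)",
            gene.gene_id,
            label.value,
        )


def classify_calls(
    calls: Sequence[TcGTCall],
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    genome,
    min_orf_codons: int = 30,
) -> dict[tuple[str, str], ProductClass]:
    """Classify every call's product: extract cDNA, predict the ORF, compare
    with the target gene. Returns {(sample_id, transcript_id): ProductClass}.

    Calls on genes without annotated CDS are labeled non-coding with a
    warning rather than failing the batch.
    """
    by_id = {(t.sample_id, t.transcript_id): t for t in transcripts}
    by_gene = {g.gene_id: g for g in genes}
    out: dict[tuple[str, str], ProductClass] = {}
    for call in calls:
        key = (call.sample_id, call.transcript_id)
        transcript = by_id.get(key)
        if transcript is None:
            raise KeyError(f"call references unknown transcript {key}")
        gene = by_gene.get(call.gene_id)
        if gene is None:
            raise KeyError(f"call references unknown gene {call.gene_id!r}")
        if not gene.cds_segments:
            logger.warning("%s: target gene %s has no CDS; labeling non-coding",
                           call.transcript_id, gene.gene_id)
            out[key] = ProductClass.NON_CODING
            continue
        if gene.canonical_protein is None:
            gene.canonical_protein = translate_cds(gene.cds_segments, gene.strand, genome)
        cdna = extract_spliced_sequence(transcript, genome)
        orf = predict_orf(cdna, min_orf_codons=min_orf_codons)
        if orf is not None:
            orf = orf_with_genomic(orf, transcript)
        out[key] = classify_product(orf, gene)
    return out
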