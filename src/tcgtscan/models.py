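"""Shared domain types: transcripts, genes and sample sheets."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .intervals import GenomicInterval


@dataclass
class TranscriptModel:
    """One assembled transcript: ordered exons plus its 1-bp TSS.

    Exons are ordered 5'->3' along the transcript: ascending genomic
    coordinate on ``+``, descending on ``-``. The TSS is the strand-
    appropriate terminus of the first exon.
    """

    transcript_id: str
    sample_id: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        for a, b in zip(self.exons, self.exons[1:]):
            forward = b.start >= a.end
            if self.strand == "-" and forward:
                raise ValueError(f"{self.transcript_id}: exons not in - orientation")
            if self.strand == "+" and not forward:
                raise ValueError(f"{self.transcript_id}: exons not in + orientation")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def tss(self) -> GenomicInterval:
        """The 5'-most transcribed base, as a 1-bp interval."""
        first = self.exons[0]
        if self.strand == "-":
            return GenomicInterval(first.chrom, first.end - 1, first.end, self.strand)
        return GenomicInterval(first.chrom, first.start, first.start + 1, self.strand)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class GeneModel:
    """An annotated gene with its coding exons and canonical CDS.

    ``cds_segments`` is the canonical transcript's CDS in transcript
    orientation, each with its GTF frame (bases to skip to the next codon
    boundary). ``coding_exons`` is the merged union of CDS intervals over
    all transcripts. ``canonical_protein`` is filled lazily once a genome
    is available (see :func:`tcgtscan.sequences.attach_proteins`).
    """

    gene_id: str
    gene_name: str
    strand: str
    body: GenomicInterval
    coding_exons: list[GenomicInterval] = field(default_factory=list)
    cds_segments: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    canonical_protein: str | None = None

    @property
    def chrom(self) -> str:
        return self.body.chrom


@dataclass
class SampleSheet:
    """Mapping of sample_id to group label (tumor / normal / tissue / ...)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty sample sheet")

    def group_of(self, sample_id: str) -> str:
        return self.entries[sample_id]

    def groups(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def n_per_group(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for group in self.entries.values():
            counts[group] = counts.get(group, 0) + 1
        return counts

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        entries: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "sample_id":  # optional header
                    continue
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected sample_id<TAB>group")
                sample, group = fields[0], fields[1]
                if sample in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
                entries[sample] = group
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgroup\n")
            for sample, group in self.entries.items():
                fh.write(f"{sample}\t{group}\n")
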