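"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each result from first principles (exhaustive
enumeration, transitive closure, naive interval arithmetic) without calling
the implementation under test.
"""

from __future__ import annotations

from tcgtscan.intervals import GenomicInterval
from tcgtscan.models import GeneModel, TranscriptModel
from tcgtscan.rmsk import CuratedTE, RepeatRecord


def orf_enumeration(seq: str, min_orf_codons: int = 30) -> tuple[int, int, str] | None:
    """Exhaustively enumerate every ATG..stop span; return the longest
    (5'-most on ties) as (start, end_after_stop, protein)."""
    from Bio.Seq import Seq

    stops = {"TAA", "TAG", "TGA"}
    seq = seq.upper()
    candidates = []
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for pos in range(start + 3, len(seq) - 2, 3):
            if seq[pos : pos + 3] in stops:
                end = pos + 3
                if (end - start) // 3 - 1 >= min_orf_codons:
                    candidates.append((start, end))
                break
    if not candidates:
        return None
    start, end = max(candidates, key=lambda c: (c[1] - c[0], -c[0]))
    protein = str(Seq(seq[start : end - 3]).translate())
    return start, end, protein


def single_linkage_clusters(positions: list[int], window: int) -> list[list[int]]:
    """Transitive closure of the pairwise |a-b| <= window relation."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i, p in enumerate(positions):
        clusters.setdefault(find(i), []).append(p)
    return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])


def fusion_closure(records: list[RepeatRecord], max_gap: int) -> list[frozenset[int]]:
    """Brute-force transitive closure of the pairwise fusion relation.

    Returns the partition of record indices. Mirrors the documented rule:
    same chrom/strand/name AND (shared linkage id OR, when linkage ids are
    absent or never shared, gap <= max_gap).
    """
    ids = [r.linkage_id for r in records if r.linkage_id is not None]
    gap_fallback = not ids or len(set(ids)) == len(ids)

    def related(a: RepeatRecord, b: RepeatRecord) -> bool:
        if (
            a.repeat_name != b.repeat_name
            or a.interval.chrom != b.interval.chrom
            or a.interval.strand != b.interval.strand
        ):
            return False
        if a.linkage_id is not None and a.linkage_id == b.linkage_id:
            return True
        if gap_fallback:
            gap = max(a.interval.start, b.interval.start) - min(
                a.interval.end, b.interval.end
            )
            return gap <= max_gap
        return False

    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if related(records[i], records[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def covered_bases(intervals) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            out.add((iv.chrom, p))
    return out


def naive_detect(
    transcripts: list[TranscriptModel],
    genes: list[GeneModel],
    tes: list[CuratedTE],
) -> dict[tuple[str, str], str | None]:
    """Naive re-derivation of the chimera-calling decision per transcript.

    Returns {(sample_id, transcript_id): target_gene_id or discard reason}.
    Tests every (transcript, TE, gene) combination with plain interval
    arithmetic; mirrors the documented rules including the mono-exonic
    variant and the deterministic target tie-break.
    """

    def point_in(iv: GenomicInterval, chrom: str, pos: int) -> bool:
        return iv.chrom == chrom and iv.start <= pos < iv.end

    def olap(a: GenomicInterval, b: GenomicInterval) -> int:
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start))

    out: dict[tuple[str, str], str | None] = {}
    for t in transcripts:
        key = (t.sample_id, t.transcript_id)
        if t.strand not in ("+", "-"):
            out[key] = "unstranded"
            continue
        tss = t.tss
        in_te = any(
            point_in(frag, tss.chrom, tss.start) for te in tes for frag in te.fragments
        )
        if not in_te:
            out[key] = "tss_not_te"
            continue

        def coding_bp(gene: GeneModel, exons) -> int:
            if gene.strand != t.strand:
                return 0
            return sum(olap(e, ce) for e in exons for ce in gene.coding_exons)

        if t.n_exons > 1:
            if any(olap(t.exons[0], g.body) for g in genes):
                out[key] = "first_exon_in_gene"
                continue
            candidates = {g.gene_id: coding_bp(g, t.exons[1:]) for g in genes}
        else:
            candidates = {g.gene_id: coding_bp(g, t.exons) for g in genes}
        candidates = {gid: bp for gid, bp in candidates.items() if bp > 0}
        if not candidates:
            out[key] = "no_coding_target"
            continue
        by_id = {g.gene_id: g for g in genes}

        def body_olap(gid: str) -> int:
            return sum(olap(e, by_id[gid].body) for e in t.exons)

        target = min(candidates, key=lambda gid: (-candidates[gid], -body_olap(gid), gid))
        if t.n_exons == 1:
            exon = t.exons[0]
            overlaps = [
                (max(exon.start, ce.start), min(exon.end, ce.end))
                for g in genes
                if g.strand == t.strand
                for ce in g.coding_exons
                if olap(exon, ce)
            ]
            if t.strand == "-":
                first = max(hi for _, hi in overlaps)
                head = (first, exon.end)
            else:
                first = min(lo for lo, _ in overlaps)
                head = (exon.start, first)
            if head[0] < head[1] and any(
                olap(GenomicInterval(exon.chrom, head[0], head[1]), g.body) for g in genes
            ):
                out[key] = "first_exon_in_gene"
                continue
        out[key] = target
    return out
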