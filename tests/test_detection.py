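"""Per-sample TcGT calling: discard rules, target choice, I/O, oracle parity."""

import numpy as np
import pytest

from _oracles import naive_detect
from tcgtscan.detection import detect_tcgts, read_calls, write_calls
from tcgtscan.intervals import GenomicInterval
from tcgtscan.models import GeneModel, TranscriptModel
from tcgtscan.rmsk import CuratedTE


def _gene(gid, start, end, cds, strand="+", name=None):
    cds_ivs = [GenomicInterval("c", s, e, strand) for s, e in cds]
    ordered = sorted(cds_ivs, key=lambda iv: iv.start, reverse=(strand == "-"))
    segs, pos = [], 0
    for iv in ordered:
        segs.append((iv, (3 - pos % 3) % 3))
        pos += iv.length()
    return GeneModel(
        gene_id=gid,
        gene_name=name or gid,
        strand=strand,
        body=GenomicInterval("c", start, end, strand),
        coding_exons=sorted(cds_ivs, key=lambda iv: iv.start),
        cds_segments=segs,
    )


def _te(uid, name, start, end, strand="+"):
    return CuratedTE(uid, name, "LTR/ERVL", [GenomicInterval("c", start, end, strand)], strand)


def _t(tid, strand, exons, sample="s1"):
    ivs = [GenomicInterval("c", s, e, strand) for s, e in exons]
    if strand == "-":
        ivs = sorted(ivs, key=lambda iv: iv.start, reverse=True)
    return TranscriptModel(tid, sample, strand, ivs)


@pytest.fixture()
def scenario():
    genes = [
        _gene("gA", 10_000, 12_000, [(10_100, 10_400), (11_000, 11_400)]),
        _gene("gB", 20_000, 21_000, [(20_100, 20_700)]),
    ]
    tes = [
        _te("TE000001", "LTR66", 5_000, 5_600),
        _te("TE000002", "AluSx1", 7_000, 7_300),
        _te("TE000003", "AluY", 10_500, 10_800, "-"),  # inside gA's intron
    ]
    return genes, tes


def test_chimera_called_with_te_chain(scenario):
    """A TE-initiated transcript splicing through another TE into coding
    exons is called, with the TE chain in transcript order."""
    genes, tes = scenario
    t = _t("t1", "+", [(5_100, 5_300), (7_050, 7_200), (10_100, 10_400)])
    result = detect_tcgts([t], genes, tes)
    assert len(result.calls) == 1
    call = result.calls[0]
    assert call.gene_id == "gA"
    assert call.tss_te_name == "LTR66"
    assert call.te_chain == ["LTR66", "AluSx1"]
    assert call.coding_overlap_bp == 300
    assert result.discards == {r: 0 for r in result.discards}


def test_discard_tss_not_te(scenario):
    """A TSS one base outside every TE fragment is discarded."""
    genes, tes = scenario
    t = _t("t1", "+", [(5_600, 5_800), (10_100, 10_400)])  # TE ends at 5600
    result = detect_tcgts([t], genes, tes)
    assert not result.calls and result.discards["tss_not_te"] == 1
    # one base earlier, inside the TE: called
    t2 = _t("t2", "+", [(5_599, 5_800), (10_100, 10_400)])
    assert len(detect_tcgts([t2], genes, tes).calls) == 1


def test_discard_first_exon_in_gene(scenario):
    """Starting inside a TE that lies within another gene's body fails the
    first-exon test."""
    genes, tes = scenario
    t = _t("t1", "+", [(10_550, 10_700), (20_100, 20_400)])  # TSS in intronic AluY
    result = detect_tcgts([t], genes, tes)
    assert not result.calls and result.discards["first_exon_in_gene"] == 1


def test_discard_no_coding_target_and_strand_concordance(scenario):
    genes, tes = scenario
    t = _t("t1", "+", [(5_100, 5_300), (30_000, 30_200)])  # splices into desert
    result = detect_tcgts([t], genes, tes)
    assert result.discards["no_coding_target"] == 1
    # antisense target gene does not count
    t2 = _t("t2", "-", [(20_100, 20_400), (5_100, 5_300)])
    # TSS of the minus transcript = rightmost base of its first exon (20_399):
    # not in a TE -> use a TE on the right instead
    tes2 = tes + [_te("TE000009", "MER4A", 20_350, 20_900)]
    result2 = detect_tcgts([t2], genes, tes2)
    assert result2.discards["first_exon_in_gene"] == 1  # exon inside gB body
    t3 = _t("t3", "-", [(25_000, 25_200), (20_100, 20_400)])
    tes3 = tes + [_te("TE000009", "MER4A", 24_900, 25_300)]
    result3 = detect_tcgts([t3], genes, tes3)
    assert result3.discards["no_coding_target"] == 1  # gB is + strand


def test_unstranded_transcripts_are_set_aside(scenario):
    genes, tes = scenario
    t = TranscriptModel("t1", "s1", ".", [GenomicInterval("c", 5_100, 5_300, ".")])
    result = detect_tcgts([t], genes, tes)
    assert result.discards["unstranded"] == 1


def test_empty_te_or_gene_list_errors(scenario):
    genes, tes = scenario
    t = _t("t1", "+", [(5_100, 5_300), (10_100, 10_400)])
    with pytest.raises(ValueError, match="TE"):
        detect_tcgts([t], genes, [])
    with pytest.raises(ValueError, match="gene"):
        detect_tcgts([t], [], tes)


def test_monoexonic_rule(scenario):
    """A mono-exonic transcript is a TcGT only when its TSS is in a TE and
    the 5' stretch before the coding overlap is outside gene bodies."""
    genes, tes = scenario
    # gC is a retrogene-like target whose body starts at its CDS (no 5' UTR)
    genes = genes + [_gene("gC", 24_000, 24_600, [(24_000, 24_600)])]
    tes = tes + [_te("TE000004", "MLT1F1", 23_300, 23_900)]
    # starts in MLT1F1 (gene desert), runs into gC's coding exon
    t = _t("t1", "+", [(23_800, 24_600)])
    result = detect_tcgts([t], genes, tes)
    assert len(result.calls) == 1
    assert result.calls[0].monoexonic and result.calls[0].gene_id == "gC"
    # same TE start but the target has an annotated 5' UTR (gB body begins
    # 100 bp before its CDS): the 5' head crosses the gene body -> rejected
    tes2 = tes + [_te("TE000005", "MLT1F2", 19_300, 19_900)]
    t2 = _t("t2", "+", [(19_800, 20_700)])
    result2 = detect_tcgts([t2], genes, tes2)
    assert result2.discards["first_exon_in_gene"] == 1


def test_discard_accounting_partition(scenario):
    """inputs = calls + sum of discard tallies."""
    genes, tes = scenario
    transcripts = [
        _t("a", "+", [(5_100, 5_300), (10_100, 10_400)]),
        _t("b", "+", [(6_000, 6_200), (10_100, 10_400)]),
        _t("c", "+", [(10_550, 10_700), (20_100, 20_400)]),
        _t("d", "+", [(5_100, 5_300), (30_000, 30_200)]),
        TranscriptModel("e", "s1", ".", [GenomicInterval("c", 5_100, 5_300, ".")]),
    ]
    result = detect_tcgts(transcripts, genes, tes)
    assert result.n_input == len(transcripts)
    assert len(result.calls) + sum(result.discards.values()) == len(transcripts)


def test_detection_matches_bruteforce_oracle(scenario):
    """On randomized cohorts the detector equals a naive implementation that
    tests every (transcript, TE, gene) combination."""
    genes, tes = scenario
    rng = np.random.default_rng(42)
    transcripts = []
    for i in range(200):
        strand = "+" if rng.random() < 0.8 else "-"
        n_exons = int(rng.integers(1, 4))
        starts = sorted(rng.integers(4_000, 30_000, size=n_exons))
        exons, prev = [], 0
        for s in starts:
            s = max(int(s), prev)
            length = int(rng.integers(50, 600))
            exons.append((s, s + length))
            prev = s + length + 10
        transcripts.append(_t(f"t{i}", strand, exons))
    result = detect_tcgts(transcripts, genes, tes)
    expected = naive_detect(transcripts, genes, tes)
    got = {(c.sample_id, c.transcript_id): c.gene_id for c in result.calls}
    for (sid, tid, reason) in result.discarded_transcripts:
        got[(sid, tid)] = reason
    assert got == expected


def test_calls_round_trip_and_sorting(tmp_path, scenario):
    genes, tes = scenario
    transcripts = [
        _t("z", "+", [(5_100, 5_300), (10_100, 10_400)], sample="s2"),
        _t("a", "+", [(7_050, 7_200), (20_100, 20_400)], sample="s1"),
        _t("m", "+", [(5_200, 5_400), (20_100, 20_400)], sample="s1"),
    ]
    calls = detect_tcgts(transcripts, genes, tes).calls
    path = tmp_path / "calls.tsv"
    write_calls(reversed(calls), path)
    again = read_calls(path)
    keys = [(c.sample_id, c.chrom, c.tss_pos, c.gene_id) for c in again]
    assert keys == sorted(keys)
    assert [
        (c.sample_id, c.transcript_id, c.gene_id, c.tss_pos, c.te_chain, c.monoexonic)
        for c in again
    ] == [
        (c.sample_id, c.transcript_id, c.gene_id, c.tss_pos, c.te_chain, c.monoexonic)
        for c in sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.tss_pos, c.gene_id))
    ]


def test_calls_empty_and_unknown_column(tmp_path):
    path = tmp_path / "calls.tsv"
    write_calls([], path)
    assert read_calls(path) == []
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tnot_a_column\n")
    with pytest.raises(ValueError, match="not_a_column"):
        read_calls(bad)


def test_detection_deterministic_output(tmp_path, scenario):
    genes, tes = scenario
    transcripts = [
        _t("a", "+", [(5_100, 5_300), (10_100, 10_400)]),
        _t("b", "+", [(7_050, 7_200), (20_100, 20_400)]),
    ]
    p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
    write_calls(detect_tcgts(transcripts, genes, tes).calls, p1)
    write_calls(detect_tcgts(list(reversed(transcripts)), genes, tes).calls, p2)
    assert p1.read_bytes() == p2.read_bytes()
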