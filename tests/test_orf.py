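"""ORF prediction and protein-product classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import orf_enumeration
from tcgtscan.intervals import GenomicInterval
from tcgtscan.models import GeneModel, TranscriptModel
from tcgtscan.orf import (
    OrfPrediction,
    ProductClass,
    classify_product,
    orf_with_genomic,
    predict_orf,
)
from tcgtscan.sequences import extract_spliced_sequence, translate_cds


def test_predict_orf_direct_translation():
    orf = predict_orf("ATGGCTGCTTAA", min_orf_codons=2)
    assert orf is not None and orf.protein == "MAA"
    assert (orf.cdna_start, orf.cdna_end) == (0, 12)


def test_predict_orf_longest_wins_over_upstream():
    """A longer downstream ORF beats a shorter upstream one."""
    seq = "CCATGTAAATGGCTGCTGCTGCTTAA"  # short ATG..TAA then a longer one
    orf = predict_orf(seq, min_orf_codons=2)
    expected = orf_enumeration(seq, 2)
    assert (orf.cdna_start, orf.cdna_end, orf.protein) == expected
    assert orf.protein == "MAAAA"


def test_predict_orf_requires_stop_and_min_length():
    assert predict_orf("ATG" + "GCT" * 50, min_orf_codons=2) is None  # no stop
    assert predict_orf("ATGGCTTAA", min_orf_codons=5) is None  # too short
    assert predict_orf("N" * 60) is None
    with pytest.raises(ValueError):
        predict_orf("ATGXXTAA")
    with pytest.raises(ValueError):
        predict_orf("AT")


def test_predict_orf_tie_breaks_5prime():
    seq = "ATGGCTTAACCCATGGCTTAA"  # two equal-length ORFs
    orf = predict_orf(seq, min_orf_codons=2)
    assert orf.cdna_start == 0


@settings(deadline=None, max_examples=80, derandomize=True)
@given(st.integers(0, 10_000))
def test_predict_orf_matches_exhaustive_enumeration(seed):
    """predict_orf equals brute-force enumeration of all ATG..stop spans."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 600))
    seq = "".join(rng.choice(list("ACGT"), size=n))
    got = predict_orf(seq, min_orf_codons=5)
    expected = orf_enumeration(seq, 5)
    if expected is None:
        assert got is None
    else:
        assert (got.cdna_start, got.cdna_end, got.protein) == expected


# ---------------------------------------------------------------------------
# classification


def _gene(cds, strand="+", chrom="c"):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in cds]
    ordered = sorted(ivs, key=lambda iv: iv.start, reverse=(strand == "-"))
    segs, pos = [], 0
    for iv in ordered:
        segs.append((iv, (3 - pos % 3) % 3))
        pos += iv.length()
    lo, hi = min(iv.start for iv in ivs), max(iv.end for iv in ivs)
    return GeneModel("g", "g", strand, GenomicInterval(chrom, lo, hi, strand),
                     coding_exons=sorted(ivs, key=lambda iv: iv.start), cds_segments=segs)


def _orf(segments, strand="+", protein="M" + "A" * 10, chrom="c"):
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in segments]
    ordered = sorted(ivs, key=lambda iv: iv.start, reverse=(strand == "-"))
    segs, pos = [], 0
    for iv in ordered:
        segs.append((iv, (3 - pos % 3) % 3))
        pos += iv.length()
    total = sum(iv.length() for iv in ivs)
    assert total % 3 == 0
    return OrfPrediction(0, total + 3, segs, protein)


CANON = [(1000, 1300)]  # 100 codons on +


@pytest.mark.parametrize(
    "pred_segments,expected",
    [
        ([(1000, 1300)], ProductClass.CANONICAL),
        ([(988, 1300)], ProductClass.N_EXT),       # 4 extra in-frame upstream codons
        ([(1150, 1300)], ProductClass.N_TRUNC),    # starts at codon 50, same stop
        ([(1000, 1150)], ProductClass.C_TRUNC),    # same start, earlier in-frame stop
        ([(1000, 1390)], ProductClass.C_EXT),      # same start, later in-frame stop
        ([(1090, 1210)], ProductClass.N_C_TRUNC),  # both ends strictly inside
        ([(1001, 1298)], ProductClass.OUT_OF_FRAME),  # +1 shift across the CDS
        ([(5000, 5300)], ProductClass.NON_CODING),    # no genomic overlap
    ],
)
def test_classify_product_categories(pred_segments, expected):
    gene = _gene(CANON)
    assert classify_product(_orf(pred_segments), gene) is expected


def test_classify_none_orf_and_missing_cds():
    gene = _gene(CANON)
    assert classify_product(None, gene) is ProductClass.NON_CODING
    bare = GeneModel("g", "g", "+", GenomicInterval("c", 0, 10, "+"))
    with pytest.raises(ValueError, match="CDS"):
        classify_product(_orf([(0, 9)]), bare)


def test_out_of_frame_requires_half_shifted():
    """A shift over less than half of the shared bases keeps the in-frame
    label (partial frameshift from alternative splicing)."""
    gene = _gene([(1000, 1150), (1200, 1350)])  # two 50-codon segments
    # same first segment in frame; second segment shifted by +1 but shorter
    pred = _orf([(1000, 1150), (1201, 1312)])
    label = classify_product(pred, gene)
    assert label is not ProductClass.OUT_OF_FRAME
    # fully shifted second segment dominating the overlap -> out-of-frame
    pred2 = _orf([(1201, 1348)])
    # prediction covers only the shifted segment: every shared base shifted
    assert classify_product(pred2, gene) is ProductClass.OUT_OF_FRAME


def test_minus_strand_classification():
    gene = _gene([(2000, 2300)], strand="-")
    assert classify_product(_orf([(2000, 2300)], strand="-"), gene) is ProductClass.CANONICAL
    # N-trunc on minus strand: start (5' = high coordinate) moves downstream
    assert classify_product(_orf([(2000, 2150)], strand="-"), gene) is ProductClass.N_TRUNC
    # C-trunc: stop (low coordinate) retreats upstream
    assert classify_product(_orf([(2150, 2300)], strand="-"), gene) is ProductClass.C_TRUNC


def test_spliced_orf_genomic_mapping():
    """cDNA offsets map to genomic CDS segments across splice junctions."""
    t = TranscriptModel("t", "s", "+", [GenomicInterval("c", 0, 30, "+"),
                                        GenomicInterval("c", 100, 130, "+")])
    orf = OrfPrediction(15, 45 + 3, [], "M" + "A" * 14)
    orf = orf_with_genomic(orf, t)
    # 30 coding bases (stop excluded): 15 in exon 1, 15 in exon 2
    assert [(iv.start, iv.end) for iv, _ in orf.genomic_cds] == [(15, 30), (100, 115)]
    assert [f for _, f in orf.genomic_cds] == [0, 0]


def test_canonical_self_consistency_on_generated_genes(reference, genome):
    """For every gene of the synthetic reference, the exact canonical mRNA
    classifies as canonical — including the minus-strand gene."""
    for gene in reference.genes:
        exons = sorted(gene.coding_exons, key=lambda iv: iv.start,
                       reverse=(gene.strand == "-"))
        # append the stop codon region so the ORF terminates
        if gene.strand == "-":
            last = exons[-1]
            exons[-1] = GenomicInterval(last.chrom, last.start - 3, last.end, "-")
        else:
            last = exons[-1]
            exons[-1] = GenomicInterval(last.chrom, last.start, last.end + 3, "+")
        t = TranscriptModel("t", "s", gene.strand, exons)
        cdna = extract_spliced_sequence(t, genome)
        orf = predict_orf(cdna)
        assert orf is not None
        orf = orf_with_genomic(orf, t)
        assert classify_product(orf, gene) is ProductClass.CANONICAL, gene.gene_id
        assert orf.protein == translate_cds(gene.cds_segments, gene.strand, genome)
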