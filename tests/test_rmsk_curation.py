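"""RepeatMasker parsing, fragment fusion and LTR-internal grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from _oracles import covered_bases, fusion_closure
from tcgtscan.intervals import GenomicInterval
from tcgtscan.rmsk import (
    CuratedTE,
    RepeatRecord,
    curate,
    fuse_fragments,
    pair_ltr_internal,
    parse_rmsk_out,
    read_curated_bed,
    write_curated_bed,
)

HEADER = (
    "   SW  perc perc perc  query      position in query  matching repeat\n"
    "score  div. del. ins.  sequence   begin end (left)   repeat class/family begin end (left) ID\n"
    "\n"
)


def _out_row(chrom, begin1, end1, strand, name, family, linkage):
    return (
        f"  463  10.1  0.0  0.0  {chrom} {begin1} {end1} (0) {strand} {name} "
        f"{family} 1 {end1 - begin1 + 1} (0) {linkage}\n"
    )


def test_parse_rmsk_out_fixture(tmp_path):
    """12 rows parse to 12 records in coordinate order; C maps to -."""
    rows = []
    for i in range(12):
        # write in reverse order to check sorting
        start1 = 128_000_001 - i * 10_000
        strand = "C" if i % 3 == 0 else "+"
        rows.append(_out_row("chr8", start1, start1 + 399, strand, f"LTR{i}", "LTR/ERVL", i + 1))
    path = tmp_path / "r.out"
    path.write_text(HEADER + "".join(rows))
    records = parse_rmsk_out(path)
    assert len(records) == 12
    assert [r.interval.start for r in records] == sorted(r.interval.start for r in records)
    first = records[0]
    assert first.interval.chrom == "chr8"
    # 1-based inclusive 127890001..127890400 -> 0-based half-open
    assert (first.interval.start, first.interval.end) == (127_890_000, 127_890_400)
    assert {r.interval.strand for r in records} == {"+", "-"}


def test_parse_rmsk_bad_coordinate(tmp_path):
    path = tmp_path / "r.out"
    path.write_text(HEADER + "  463 10.1 0.0 0.0 chr8 xxx 100 (0) + A LTR/ERVL 1 1 (0) 1\n")
    with pytest.raises(ValueError, match=":4"):
        parse_rmsk_out(path)


def _rec(chrom, start, end, strand="+", name="LTR66", family="LTR/ERVL", linkage=None):
    return RepeatRecord(GenomicInterval(chrom, start, end, strand), name, family, linkage)


def test_fuse_shared_linkage_id():
    """Two fragments of one insertion (shared .out ID) become one unit."""
    records = [_rec("c", 0, 400, linkage=7), _rec("c", 2400, 2800, linkage=7)]
    units = fuse_fragments(records)
    assert len(units) == 1
    assert len(units[0].fragments) == 2
    assert units[0].role == "fused-fragment-unit"


def test_no_fusion_across_distinct_ids():
    records = [
        _rec("c", 0, 300, name="AluSx1", family="SINE/Alu", linkage=1),
        _rec("c", 50_000, 50_300, name="AluSx1", family="SINE/Alu", linkage=2),
        _rec("c", 100, 200, name="AluSx1", family="SINE/Alu", linkage=1),  # shared with #1
    ]
    units = fuse_fragments(records)
    assert len(units) == 2


def test_gap_fallback_when_ids_uninformative():
    records = [_rec("c", 0, 400, linkage=1), _rec("c", 2_000, 2_400, linkage=2)]
    assert len(fuse_fragments(records, max_gap=10_000)) == 1  # all ids distinct -> gap rule
    records = [_rec("c", 0, 400, linkage=1), _rec("c", 50_000, 50_400, linkage=2)]
    assert len(fuse_fragments(records, max_gap=10_000)) == 2
    with pytest.raises(ValueError):
        fuse_fragments(records, max_gap=-1)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.sampled_from(["c1", "c2"]),
            st.integers(0, 40),  # start in units of 1 kb
            st.sampled_from(["+", "-"]),
            st.sampled_from(["LTR66", "L1PA3"]),
            st.one_of(st.none(), st.integers(1, 4)),
        ),
        min_size=1,
        max_size=12,
    )
)
def test_fusion_matches_transitive_closure_oracle(data):
    """Fusion equals brute-force transitive closure of the pairwise relation,
    and never gains or loses covered bases."""
    records = [
        _rec(chrom, s * 1000, s * 1000 + 500, strand, name, linkage=lid)
        for chrom, s, strand, name, lid in data
    ]
    max_gap = 3_000
    units = fuse_fragments(records, max_gap=max_gap)
    expected = fusion_closure(sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)), max_gap)
    assert len(units) == len(expected)
    assert covered_bases(f for u in units for f in u.fragments) == covered_bases(
        r.interval for r in records
    )


def test_fusion_idempotent():
    records = [
        _rec("c", 0, 400, linkage=7),
        _rec("c", 2_400, 2_800, linkage=7),
        _rec("c", 9_000, 9_300, name="AluY", family="SINE/Alu", linkage=3),
    ]
    units = fuse_fragments(records)
    rerecords = [
        RepeatRecord(frag, u.unit_name, u.unit_class, linkage_id=i)
        for i, u in enumerate(units)
        for frag in u.fragments
    ]
    again = fuse_fragments(rerecords)
    assert [(u.unit_name, [(f.start, f.end) for f in u.fragments]) for u in again] == [
        (u.unit_name, [(f.start, f.end) for f in u.fragments]) for u in units
    ]


def _unit(uid, name, family, start, end, strand="+"):
    return CuratedTE(uid, name, family, [GenomicInterval("c", start, end, strand)], strand)


@pytest.mark.parametrize(
    "layout,expected_roles",
    [
        # full provirus: LTR - int - LTR within gaps
        (
            [("LTR7", 0, 450), ("HERVH-int", 500, 2500), ("LTR7", 2600, 3050)],
            {"ltr5", "internal", "ltr3"},
        ),
        # internal flanked only on its 3' side
        ([("HERVH-int", 500, 2500), ("LTR7", 2600, 3050)], {"internal", "ltr3"}),
        # internal flanked only on its 5' side
        ([("LTR7", 0, 450), ("HERVH-int", 500, 2500)], {"ltr5", "internal"}),
        # gap too large: nothing groups
        ([("LTR7", 0, 450), ("HERVH-int", 5_000, 7_000)], set()),
        # intervening foreign unit breaks adjacency
        ([("LTR7", 0, 450), ("AluY", 460, 480), ("HERVH-int", 500, 2500)], {"internal"} ),
    ],
)
def test_ltr_internal_grouping_cases(layout, expected_roles):
    units = [
        _unit(f"TE{i}", name, "SINE/Alu" if name == "AluY" else "LTR/ERV1", s, e)
        for i, (name, s, e) in enumerate(layout)
    ]
    out = pair_ltr_internal(units, max_gap=2000)
    roles = {u.role for u in out if u.erv_group_id}
    if expected_roles == {"internal"}:
        # a lone internal with no adjacent LTR stays ungrouped
        assert all(u.erv_group_id is None for u in out)
    else:
        assert roles == expected_roles
        gids = {u.erv_group_id for u in out if u.erv_group_id}
        assert len(gids) <= 1


def test_solo_ltr_stays_solo():
    out = pair_ltr_internal([_unit("TE1", "LTR66", "LTR/ERVL", 0, 600)])
    assert out[0].role == "solo" and out[0].erv_group_id is None


def test_minus_strand_roles_follow_transcription_direction():
    units = [
        _unit("TE1", "LTR7", "LTR/ERV1", 0, 450, "-"),
        _unit("TE2", "HERVH-int", "LTR/ERV1", 500, 2500, "-"),
        _unit("TE3", "LTR7", "LTR/ERV1", 2600, 3050, "-"),
    ]
    out = pair_ltr_internal(units)
    by_start = sorted(out, key=lambda u: u.span.start)
    assert [u.role for u in by_start] == ["ltr3", "internal", "ltr5"]


def test_pairing_idempotent_and_strand_aware():
    units = [
        _unit("TE1", "LTR7", "LTR/ERV1", 0, 450, "+"),
        _unit("TE2", "HERVH-int", "LTR/ERV1", 500, 2500, "-"),  # strand mismatch
    ]
    once = pair_ltr_internal(units)
    assert all(u.erv_group_id is None for u in once)
    units = [
        _unit("TE1", "LTR7", "LTR/ERV1", 0, 450),
        _unit("TE2", "HERVH-int", "LTR/ERV1", 500, 2500),
    ]
    once = pair_ltr_internal(units)
    twice = pair_ltr_internal(once)
    assert [(u.role, u.erv_group_id) for u in twice] == [(u.role, u.erv_group_id) for u in once]


def test_bed_round_trip(tmp_path):
    units = [
        CuratedTE(
            "TE000001",
            "LTR66",
            "LTR/ERVL",
            [GenomicInterval("c", 0, 400), GenomicInterval("c", 2400, 2800)],
            "+",
            role="fused-fragment-unit",
        ),
        CuratedTE("TE000002", "HERVH-int", "LTR/ERV1",
                  [GenomicInterval("c", 5000, 7000)], "-", role="internal",
                  erv_group_id="ERV00001"),
    ]
    path = tmp_path / "te.bed"
    write_curated_bed(units, path)
    lines = path.read_text().splitlines()
    assert lines[1].split("\t")[9] == "2"  # blockCount of the 2-fragment unit
    again = read_curated_bed(path)
    assert [
        (u.unit_id, u.unit_name, u.unit_class, u.role, u.erv_group_id,
         [(f.start, f.end) for f in u.fragments], u.strand)
        for u in again
    ] == [
        (u.unit_id, u.unit_name, u.unit_class, u.role, u.erv_group_id,
         [(f.start, f.end) for f in u.fragments], u.strand)
        for u in units
    ]


def test_bed_empty_unit_list(tmp_path):
    path = tmp_path / "te.bed"
    write_curated_bed([], path)
    assert path.read_text().startswith("#chrom")
    assert read_curated_bed(path) == []


def test_curation_on_generated_reference(reference):
    """The generated .out file curates into the designed unit count with one
    full LTR-internal-LTR provirus group."""
    records = parse_rmsk_out(reference.rmsk_out_path)
    units = curate(records)
    from tcgtscan.synthetic import N_CURATED_UNITS

    assert len(units) == N_CURATED_UNITS
    grouped = [u for u in units if u.erv_group_id]
    assert sorted(u.role for u in grouped) == ["internal", "ltr3", "ltr5"]
    assert covered_bases(f for u in units for f in u.fragments) == covered_bases(
        r.interval for r in records
    )
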