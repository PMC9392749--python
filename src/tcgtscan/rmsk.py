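"""RepeatMasker annotation curation.

Raw RepeatMasker output describes repeat *fragments*: a single genomic
insertion interrupted by later insertions or deletions appears as several
rows (sharing the ``.out`` ID column), and an endogenous retrovirus appears
as separate rows for its internal sequence ("<family>-int") and its two
flanking LTRs. For promoter analysis these pieces are one biological unit,
so curation proceeds in two passes:

1. :func:`fuse_fragments` — rows of the same repeat on the same
   chromosome/strand that share a linkage ID (or, when IDs are uninformative,
   lie within a gap threshold) are fused into one multi-fragment unit.
2. :func:`pair_ltr_internal` — an internal ERV unit is grouped with the
   same-strand LTR units immediately flanking it, yielding an
   LTR5-internal-LTR3 provirus group; unmatched LTRs stay "solo".

Downstream overlap tests (the TSS-in-TE test) are always made against the
*fragments* of a unit, never its fused span, because the span may include
interior bases belonging to other elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

ROLES = ("solo", "ltr5", "internal", "ltr3", "fused-fragment-unit")


@dataclass(frozen=True)
class RepeatRecord:
    """One row of a RepeatMasker ``.out`` file, in internal coordinates."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class_family: str
    linkage_id: int | None = None
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("empty repeat_name")


@dataclass
class CuratedTE:
    """A curated repeat unit: fused fragments plus optional ERV grouping."""

    unit_id: str
    unit_name: str
    unit_class: str
    fragments: list[GenomicInterval]
    strand: str
    role: str = "solo"
    erv_group_id: str | None = None

    def __post_init__(self) -> None:
        self.fragments = merge_intervals(self.fragments)
        if self.role not in ROLES:
            raise ValueError(f"bad role {self.role!r}")
        if self.role in ("ltr5", "internal", "ltr3") and not self.erv_group_id:
            raise ValueError(f"{self.unit_id}: ERV role without erv_group_id")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.fragments[0].chrom,
            self.fragments[0].start,
            self.fragments[-1].end,
            self.strand,
        )

    @property
    def chrom(self) -> str:
        return self.fragments[0].chrom

    def is_internal(self) -> bool:
        return self.unit_name.endswith("-int") and self.unit_class.startswith("LTR")

    def is_ltr(self) -> bool:
        return self.unit_class.startswith("LTR") and not self.unit_name.endswith("-int")


def parse_rmsk_out(path: str | Path) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` file into records sorted by coordinate.

    The standard layout has 3 header lines and whitespace-delimited columns;
    the strand column uses ``+``/``C`` (C = reverse complement, mapped to -).
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("SW", "score") or fields[0].startswith("score"):
                continue  # header
            try:
                divergence = float(fields[1])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed .out row: {exc}") from exc
            strand = "-" if fields[8] == "C" else "+"
            name = fields[9]
            class_family = fields[10]
            linkage: int | None = None
            if len(fields) >= 15:
                try:
                    linkage = int(fields[14])
                except ValueError:
                    linkage = None
            records.append(
                RepeatRecord(
                    interval=GenomicInterval(chrom, start, end, strand),
                    repeat_name=name,
                    repeat_class_family=class_family,
                    linkage_id=linkage,
                    divergence=divergence,
                )
            )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return records


def _gap_fallback_active(records: Sequence[RepeatRecord]) -> bool:
    """Linkage IDs are uninformative when absent or never shared."""
    ids = [r.linkage_id for r in records if r.linkage_id is not None]
    if not ids:
        return True
    return len(set(ids)) == len(ids)


def fusion_relation(a: RepeatRecord, b: RepeatRecord, max_gap: int, gap_fallback: bool) -> bool:
    """Pairwise fuse test: same name/chrom/strand and linked by ID or gap."""
    if (
        a.repeat_name != b.repeat_name
        or a.interval.chrom != b.interval.chrom
        or a.interval.strand != b.interval.strand
    ):
        return False
    if a.linkage_id is not None and a.linkage_id == b.linkage_id:
        return True
    if gap_fallback:
        gap = max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end)
        return gap <= max_gap
    return False


def fuse_fragments(records: Sequence[RepeatRecord], max_gap: int = 10_000) -> list[CuratedTE]:
    """Fuse fragmented repeat rows into curated units.

    Fragments fuse when they share chromosome, strand and repeat name and
    either share a RepeatMasker linkage ID, or — when linkage IDs are absent
    or all distinct — lie within ``max_gap`` bp of each other (transitively).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    gap_fallback = _gap_fallback_active(records)
    recs = sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))

    # group by (chrom, strand, name); chain adjacent-in-sort pairs.
    # Within a group, the fuse relation is transitive over the sorted order
    # for the gap rule; linkage IDs are handled with a union-find.
    parent = list(range(len(recs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple, list[int]] = {}
    for idx, r in enumerate(recs):
        key = (r.interval.chrom, r.interval.strand, r.repeat_name)
        by_key.setdefault(key, []).append(idx)
    for idxs in by_key.values():
        by_linkage: dict[int, int] = {}
        for i in idxs:
            lid = recs[i].linkage_id
            if lid is not None:
                if lid in by_linkage:
                    union(by_linkage[lid], i)
                else:
                    by_linkage[lid] = i
        if gap_fallback:
            for i, j in zip(idxs, idxs[1:]):
                if fusion_relation(recs[i], recs[j], max_gap, gap_fallback):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(recs)):
        clusters.setdefault(find(i), []).append(i)

    units: list[CuratedTE] = []
    ordered = sorted(clusters.values(), key=lambda idxs: (recs[idxs[0]].interval.chrom, min(recs[i].interval.start for i in idxs)))
    for n, idxs in enumerate(ordered, 1):
        members = [recs[i] for i in idxs]
        fragments = sorted((m.interval for m in members), key=lambda iv: iv.start)
        role = "fused-fragment-unit" if len(merge_intervals(fragments)) > 1 else "solo"
        units.append(
            CuratedTE(
                unit_id=f"TE{n:06d}",
                unit_name=members[0].repeat_name,
                unit_class=members[0].repeat_class_family,
                fragments=list(fragments),
                strand=members[0].interval.strand,
                role=role,
            )
        )
    units.sort(key=lambda u: (u.chrom, u.span.start, u.span.end))
    return units


def pair_ltr_internal(
    units: Sequence[CuratedTE],
    max_gap: int = 2_000,
    pairing_table: dict[str, str] | None = None,
) -> list[CuratedTE]:
    """Group internal ERV units with their flanking LTRs.

    An internal unit (name ending "-int", class ``LTR/*``) captures the
    nearest same-strand LTR unit on each side if it is immediately adjacent
    (no intervening unit) and within ``max_gap`` bp. ``pairing_table`` may
    restrict which LTR names pair with which internal names
    (``{ltr_name: internal_name}``); by default any LTR-class unit may flank
    any internal unit. The operation is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = [replace_unit(u) for u in units]
    out.sort(key=lambda u: (u.chrom, u.span.start, u.span.end))
    n_groups = sum(1 for u in out if u.erv_group_id)  # keep ids unique on re-runs
    group_n = 0
    for i, unit in enumerate(out):
        if not unit.is_internal() or unit.erv_group_id:
            continue
        members: dict[str, CuratedTE] = {}
        for side, j in (("5", i - 1), ("3", i + 1)):
            if not (0 <= j < len(out)):
                continue
            cand = out[j]
            if cand.chrom != unit.chrom or cand.strand != unit.strand:
                continue
            if not cand.is_ltr() or cand.erv_group_id:
                continue
            if pairing_table is not None:
                if pairing_table.get(cand.unit_name) != unit.unit_name:
                    continue
            gap = (
                unit.span.start - cand.span.end
                if j < i
                else cand.span.start - unit.span.end
            )
            if 0 <= gap <= max_gap or cand.span.overlaps(unit.span):
                members[side] = cand
        if not members:
            continue
        group_n += 1
        gid = f"ERV{n_groups + group_n:05d}"
        unit.role, unit.erv_group_id = "internal", gid
        # genomic left = 5' LTR on +, 3' LTR on -
        for side, cand in members.items():
            left = side == "5"
            if unit.strand == "-":
                cand.role = "ltr3" if left else "ltr5"
            else:
                cand.role = "ltr5" if left else "ltr3"
            cand.erv_group_id = gid
    return out


def replace_unit(u: CuratedTE) -> CuratedTE:
    return CuratedTE(
        unit_id=u.unit_id,
        unit_name=u.unit_name,
        unit_class=u.unit_class,
        fragments=list(u.fragments),
        strand=u.strand,
        role=u.role,
        erv_group_id=u.erv_group_id,
    )


def curate(
    records: Sequence[RepeatRecord],
    max_fuse_gap: int = 10_000,
    max_ltr_int_gap: int = 2_000,
    pairing_table: dict[str, str] | None = None,
) -> list[CuratedTE]:
    """Full curation: fragment fusion followed by LTR-internal grouping."""
    return pair_ltr_internal(
        fuse_fragments(records, max_gap=max_fuse_gap),
        max_gap=max_ltr_int_gap,
        pairing_table=pairing_table,
    )


BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd\titemRgb\tblockCount\tblockSizes\tblockStarts"


def write_curated_bed(units: Iterable[CuratedTE], path: str | Path) -> None:
    """Write curated units as BED12 (blocks = fragments).

    The name field packs ``unit_name|unit_class|unit_id|role|erv_group_id``
    so that a round-trip through :func:`read_curated_bed` is lossless.
    """
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for u in sorted(units, key=lambda u: (u.chrom, u.span.start, u.span.end)):
            span = u.span
            name = "|".join(
                [u.unit_name, u.unit_class, u.unit_id, u.role, u.erv_group_id or "."]
            )
            sizes = ",".join(str(f.length()) for f in u.fragments)
            starts = ",".join(str(f.start - span.start) for f in u.fragments)
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{name}\t0\t{u.strand}"
                f"\t{span.start}\t{span.end}\t0\t{len(u.fragments)}\t{sizes}\t{starts}\n"
            )


def read_curated_bed(path: str | Path) -> list[CuratedTE]:
    units: list[CuratedTE] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start = fields[0], int(fields[1])
            name_parts = fields[3].split("|")
            if len(name_parts) != 5:
                raise ValueError(f"{path}:{lineno}: bad name field {fields[3]!r}")
            unit_name, unit_class, unit_id, role, gid = name_parts
            strand = fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            fragments = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
            units.append(
                CuratedTE(
                    unit_id=unit_id,
                    unit_name=unit_name,
                    unit_class=unit_class,
                    fragments=fragments,
                    strand=strand,
                    role=role,
                    erv_group_id=None if gid == "." else gid,
                )
            )
    return units
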