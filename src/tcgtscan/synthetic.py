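"""Synthetic cohort generator.

Builds a fully self-contained toy dataset — genome FASTA, gene GTF,
RepeatMasker-style ``.out``, per-sample transcript GTFs, sample sheet and
machine-readable ground truth — so that every pipeline stage can be tested
end to end without external data.

The reference emulates the genomic architecture around a TE-driven
retrogene locus: a mono-exonic retrogene (``POU5F1B_like``) with an LTR
promoter unit in a gene desert far upstream, whose planted chimeric
transcript splices through a chain of TE-overlapping exons
(LTR66 -> AluSx1 -> LTR33 -> L2b -> MLT1F1) into the retrogene's coding
exon; plus multi-exon protein-coding genes, a fragmented LTR (two ``.out``
rows sharing a linkage ID), an LTR-internal-LTR provirus, scattered
repeats, and a repeat inside a gene intron.

Planted chimeras carry designed sequence features so their predicted
protein product is unambiguous: every non-final chimeric exon ends in a
12-mer containing stop codons in all three frames (no reading frame can
run through a splice junction from upstream), and the three default events
are engineered to yield a canonical, an N-truncated and an out-of-frame
product respectively. Each sample also receives decoy transcripts that map
one-to-one onto the detector's discard reasons, and the canonical
transcripts of all genes as background. Event presence is a recorded
Bernoulli draw per sample; downstream expectations in the ground truth are
computed from the *realized* draws, so stage tests are exact rather than
statistical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregation import format_percentage
from .gtf import write_genes_gtf, write_transcripts_gtf
from .intervals import GenomicInterval
from .models import GeneModel, SampleSheet, TranscriptModel
from .orf import ProductClass, orf_with_genomic, predict_orf, classify_product
from .sequences import extract_spliced_sequence, translate_cds, write_fasta

CONTIG = "chrS1"
STOP_BLOCK = "TTAATTAATTAA"  # stop codons in all 3 frames
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in CODONS if c not in STOPS]


# --------------------------------------------------------------------------
# designs


@dataclass
class PlantedEvent:
    """One TcGT to plant at controlled tumor/normal prevalence."""

    event_id: str
    gene_id: str
    tss_te: str
    te_chain: list[str]
    tumor_prevalence: float
    normal_prevalence: float
    tss_jitter_bp: int = 40
    tss_modes: list[int] = field(default_factory=lambda: [0])
    product_class_truth: ProductClass = ProductClass.CANONICAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_prevalence <= 1.0:
            raise ValueError("tumor_prevalence outside [0,1]")
        if not 0.0 <= self.normal_prevalence <= 1.0:
            raise ValueError("normal_prevalence outside [0,1]")
        if self.tss_jitter_bp < 0:
            raise ValueError("negative tss_jitter_bp")


def default_events() -> list[PlantedEvent]:
    return [
        PlantedEvent(
            event_id="ev_retro",
            gene_id="RGENE1",
            tss_te="LTR66",
            te_chain=["LTR66", "AluSx1", "LTR33", "L2b", "MLT1F1"],
            tumor_prevalence=0.40,
            normal_prevalence=0.0,
            product_class_truth=ProductClass.CANONICAL,
        ),
        PlantedEvent(
            event_id="ev_ntrunc",
            gene_id="GENE2",
            tss_te="MER41B",
            te_chain=["MER41B"],
            tumor_prevalence=0.25,
            normal_prevalence=0.05,
            product_class_truth=ProductClass.N_TRUNC,
        ),
        PlantedEvent(
            event_id="ev_frameshift",
            gene_id="GENE3",
            tss_te="LTR10A",
            te_chain=["LTR10A"],
            tumor_prevalence=0.10,
            normal_prevalence=0.0,
            product_class_truth=ProductClass.OUT_OF_FRAME,
        ),
    ]


@dataclass
class CohortDesign:
    seed: int = 1
    n_tumor: int = 50
    n_normal: int = 50
    events: list[PlantedEvent] = field(default_factory=default_events)
    n_decoys_per_sample: int = 3
    genome_size: int = 200_000

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one tumor and one normal sample")
        known = set(_EVENT_TEMPLATES)
        for ev in self.events:
            if ev.event_id not in known:
                raise ValueError(f"no template for event {ev.event_id!r}")


# --------------------------------------------------------------------------
# fixed toy-genome layout (coordinates 0-based half-open on chrS1)

_GENES: dict[str, dict] = {
    "GENE1": {
        "strand": "+",
        "exons": [(10_000, 10_400), (10_900, 11_200), (11_700, 12_300)],
        "cds": [(10_100, 10_400), (10_900, 11_200), (11_700, 12_051)],
    },
    "GENE2": {
        "strand": "+",
        "exons": [(40_000, 41_000)],
        "cds": [(40_100, 40_700)],
        "forbid_internal_atg": True,
        "designed_atg_codon": 40,
    },
    "GENE3": {
        "strand": "+",
        "exons": [(60_000, 61_100)],
        "cds": [(60_100, 60_850)],
        "forbid_internal_atg": True,
        "shifted_stop_codon": 120,  # first offset-2-frame stop at trigram 120
    },
    "GENE4": {
        "strand": "+",
        "exons": [(80_000, 80_500), (81_000, 81_600)],
        "cds": [(80_100, 80_500), (81_000, 81_500)],
    },
    "GENE5": {
        "strand": "-",
        "exons": [(95_000, 96_200)],
        "cds": [(95_100, 96_000)],
    },
    "RGENE1": {  # mono-exonic retrogene, the POU5F1B-like target
        "name": "POU5F1B_like",
        "strand": "+",
        "exons": [(150_000, 151_200)],
        "cds": [(150_050, 150_950)],
    },
}

# (name, class/family, start, end, strand, linkage_id)
_REPEATS: list[tuple[str, str, int, int, str, int]] = [
    ("AluY", "SINE/Alu", 10_500, 10_800, "C", 10),
    ("L2b", "LINE/L2", 30_000, 30_250, "+", 11),
    ("MER41B", "LTR/ERV1", 38_000, 38_600, "+", 13),
    ("LTR10A", "LTR/ERV1", 58_000, 58_500, "+", 14),
    ("AluSx1", "SINE/Alu", 70_000, 70_300, "+", 12),
    ("LTR12C", "LTR/ERV1", 112_000, 112_500, "+", 6),
    ("LTR12C", "LTR/ERV1", 114_500, 115_000, "+", 6),
    ("LTR66", "LTR/ERVL", 120_000, 120_800, "+", 1),
    ("AluSx1", "SINE/Alu", 127_000, 127_300, "+", 2),
    ("LTR33", "LTR/ERVL", 132_000, 132_400, "+", 3),
    ("L2b", "LINE/L2", 138_000, 138_300, "+", 4),
    ("MLT1F1", "LTR/ERVL-MaLR", 149_300, 149_900, "+", 5),
    ("LTR7", "LTR/ERV1", 165_000, 165_450, "+", 7),
    ("HERVH-int", "LTR/ERV1", 165_500, 167_500, "+", 8),
    ("LTR7", "LTR/ERV1", 167_600, 168_050, "+", 9),
    ("MER4A", "LTR/ERV1", 178_000, 178_400, "+", 15),
]
N_CURATED_UNITS = 15  # 16 rows, LTR12C pair fuses into one unit
N_ERV_GROUPS = 1  # LTR7 / HERVH-int / LTR7

# chimeric transcript templates: exon list with the first exon's maximal
# start (the TSS offset is added to the first exon's start only)
_EVENT_TEMPLATES: dict[str, dict] = {
    "ev_retro": {
        "exons": [
            (120_100, 120_700),
            (127_050, 127_200),
            (132_100, 132_250),
            (138_050, 138_200),
            (149_400, 149_600),
            (150_050, 151_200),
        ],
        "tss_te_interval": (120_000, 120_800),
    },
    "ev_ntrunc": {
        "exons": [(38_200, 38_450), (40_200, 41_000)],
        "tss_te_interval": (38_000, 38_600),
    },
    "ev_frameshift": {
        "exons": [(58_100, 58_350), (60_103, 61_100)],
        "tss_te_interval": (58_000, 58_500),
        "atgg_tail": True,  # first exon ends stop-block + ATGG (frameshifted start)
    },
}

_DECOYS: list[tuple[str, str, list[tuple[int, int]]]] = [
    # (decoy kind = expected discard reason, strand, exons)
    ("tss_not_te", "+", [(122_000, 122_150), (150_050, 150_500)]),
    ("first_exon_in_gene", "+", [(10_550, 10_700), (11_700, 12_051)]),
    ("no_coding_target", "+", [(178_100, 178_300), (185_000, 185_200)]),
]


# --------------------------------------------------------------------------
# reference generation


@dataclass
class Reference:
    contigs: dict[str, str]
    genes: list[GeneModel]
    genome_path: Path
    genes_gtf_path: Path
    rmsk_out_path: Path


def _sample_codon(rng, allow_atg: bool, force_t3: bool = False, prev_b2: str | None = None) -> str:
    """Draw a sense codon honoring frame-0 and offset-2-frame constraints."""
    pool = SENSE_CODONS if allow_atg else [c for c in SENSE_CODONS if c != "ATG"]
    while True:
        codon = pool[int(rng.integers(len(pool)))]
        if force_t3 and codon[2] != "T":
            continue
        if prev_b2 == "T" and codon[:2] in ("AA", "AG", "GA"):
            continue  # would create a stop in the offset-2 reading frame
        return codon


def _design_cds(layout: dict, n_codons: int, rng) -> str:
    """Design a CDS: ATG .. sense codons .. TAA, honoring per-gene constraints."""
    allow_atg = not layout.get("forbid_internal_atg", False)
    shifted_stop = layout.get("shifted_stop_codon")
    codons = ["ATG"]
    for i in range(1, n_codons - 1):
        if shifted_stop is not None and i == shifted_stop + 1:
            codons.append("AAA")  # with prev b2 == T this spells TAA in offset-2 frame
            continue
        constrain_shift = shifted_stop is not None and i <= shifted_stop + 1
        codons.append(
            _sample_codon(
                rng,
                allow_atg=allow_atg,
                force_t3=(shifted_stop is not None and i == shifted_stop),
                prev_b2=codons[-1][2] if constrain_shift else None,
            )
        )
    designed = layout.get("designed_atg_codon")
    if designed is not None:
        codons[designed] = "ATG"
    codons.append("TAA")
    return "".join(codons)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_contig(design: CohortDesign, rng) -> str:
    if design.genome_size < 190_000:
        raise ValueError(
            f"genome_size {design.genome_size} too small for the reference layout "
            "(needs >= 190000 bp)"
        )
    seq = rng.choice(list("ACGT"), size=design.genome_size)
    seq = "".join(seq)
    chars = list(seq)

    for layout in _GENES.values():
        total = sum(e - s for s, e in layout["cds"])
        if total % 3:
            raise AssertionError("layout error: CDS length not a multiple of 3")
        cds = _design_cds(layout, total // 3, rng)
        if layout["strand"] == "-":
            cds = _revcomp(cds)
        pos = 0
        for s, e in layout["cds"]:
            chars[s:e] = cds[pos : pos + (e - s)]
            pos += e - s

    for template in _EVENT_TEMPLATES.values():
        exons = template["exons"]
        for s, e in exons[:-1]:
            block = STOP_BLOCK + ("ATGG" if template.get("atgg_tail") and (s, e) == exons[-2] else "")
            chars[e - len(block) : e] = block
    return "".join(chars)


def _gene_models() -> list[GeneModel]:
    genes = []
    for gid, layout in _GENES.items():
        strand = layout["strand"]
        exons = layout["exons"]
        body = GenomicInterval(CONTIG, exons[0][0], exons[-1][1], strand)
        cds = [GenomicInterval(CONTIG, s, e, strand) for s, e in layout["cds"]]
        if strand == "-":
            cds = sorted(cds, key=lambda iv: iv.start, reverse=True)
        # the layout's CDS coordinates include the stop codon (that is what
        # is written into the genome); annotated CDS excludes it (Ensembl
        # convention), so trim 3 bases off the 3' end
        last = cds[-1]
        cds[-1] = (
            GenomicInterval(last.chrom, last.start + 3, last.end, strand)
            if strand == "-"
            else GenomicInterval(last.chrom, last.start, last.end - 3, strand)
        )
        segments = []
        pos = 0
        for iv in cds:
            segments.append((iv, (3 - pos % 3) % 3))
            pos += iv.length()
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=layout.get("name", gid),
                strand=strand,
                body=body,
                coding_exons=sorted(cds, key=lambda iv: iv.start),
                cds_segments=segments,
            )
        )
    return genes


def _write_rmsk_out(path: Path, rng) -> None:
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for name, family, start, end, strand, linkage in _REPEATS:
            div = round(float(rng.uniform(2.0, 25.0)), 1)
            length = end - start
            fh.write(
                f"  450  {div:4.1f}  0.0  0.0  {CONTIG} {start + 1:9d} {end:9d} (0) "
                f"{strand} {name:<12s} {family:<16s} 1 {length} (0) {linkage}\n"
            )


def generate_reference(design: CohortDesign, outdir: str | Path) -> Reference:
    """Write genome.fa, genes.gtf and repeats.out; deterministic per seed.

    The designed gene sequences are re-validated after generation: every
    canonical CDS must translate from ATG to stop without internal stops,
    and every planted chimera must classify to its designed product class
    (rare random-sequence collisions trigger a deterministic re-draw).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_models()

    contig = None
    for attempt in range(20):
        rng = np.random.default_rng((design.seed + 100_000 * attempt) % (2**31))
        candidate = _build_contig(design, rng)
        if _validate_reference(candidate, genes, design):
            contig = candidate
            break
    if contig is None:
        raise RuntimeError("could not generate a valid reference in 20 attempts")

    genome_path = outdir / "genome.fa"
    genes_gtf_path = outdir / "genes.gtf"
    rmsk_out_path = outdir / "repeats.out"
    write_fasta({CONTIG: contig}, genome_path)
    write_genes_gtf(genes, genes_gtf_path)
    _write_rmsk_out(rmsk_out_path, np.random.default_rng(design.seed % (2**31)))
    return Reference(
        contigs={CONTIG: contig},
        genes=genes,
        genome_path=genome_path,
        genes_gtf_path=genes_gtf_path,
        rmsk_out_path=rmsk_out_path,
    )


class _StringGenome:
    """Minimal in-memory genome with the pyfaidx access pattern used here."""

    class _Contig:
        def __init__(self, seq: str):
            self._seq = seq

        def __len__(self) -> int:
            return len(self._seq)

        def __getitem__(self, sl):
            return self._seq[sl]

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {k: self._Contig(v) for k, v in contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __getitem__(self, name: str):
        return self._contigs[name]


def _event_transcript(event_id: str, tss_offset: int, transcript_id: str, sample_id: str) -> TranscriptModel:
    template = _EVENT_TEMPLATES[event_id]
    exons = [GenomicInterval(CONTIG, s, e, "+") for s, e in template["exons"]]
    first = exons[0]
    te_lo, te_hi = template["tss_te_interval"]
    new_start = first.start + tss_offset
    if not (te_lo <= new_start < te_hi and new_start + 50 <= first.end):
        raise ValueError(
            f"{event_id}: TSS offset {tss_offset} pushes the first exon out of its TE"
        )
    exons[0] = GenomicInterval(CONTIG, new_start, first.end, "+")
    return TranscriptModel(
        transcript_id=transcript_id, sample_id=sample_id, strand="+", exons=exons
    )


def _validate_reference(contig: str, genes: list[GeneModel], design: CohortDesign) -> bool:
    genome = _StringGenome({CONTIG: contig})
    by_id = {g.gene_id: g for g in genes}
    for gene in genes:
        protein = translate_cds(gene.cds_segments, gene.strand, genome)
        if not protein.startswith("M") or "*" in protein:
            return False
        gene.canonical_protein = protein
    for ev in design.events:
        offsets = {mode + j for mode in ev.tss_modes for j in (0, ev.tss_jitter_bp)}
        for off in offsets:
            t = _event_transcript(ev.event_id, off, "probe", "probe")
            orf = predict_orf(extract_spliced_sequence(t, genome))
            if orf is not None:
                orf = orf_with_genomic(orf, t)
            if classify_product(orf, by_id[ev.gene_id]) is not ev.product_class_truth:
                return False
    return True


# --------------------------------------------------------------------------
# cohort generation


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to find, from the realized draws."""

    design: dict
    n_curated_units: int
    n_erv_groups: int
    samples: dict[str, dict]  # sid -> {planted, decoys, background}
    expected_calls: list[dict]  # one per planted transcript
    expected_discards: dict[str, dict[str, int]]
    events: dict[str, dict]  # event_id -> realized membership / clusters
    expected_gene_table: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Cohort:
    sample_dir: Path
    sheet: SampleSheet
    sheet_path: Path
    truth: GroundTruth
    truth_path: Path


def _single_linkage_clusters(positions: list[int], window: int = 100) -> list[list[int]]:
    """Brute-force transitive-closure clustering of TSS positions."""
    if not positions:
        return []
    pos = sorted(positions)
    clusters = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def generate_cohort(design: CohortDesign, reference: Reference, outdir: str | Path) -> Cohort:
    """Write per-sample GTFs, the sample sheet and ground truth."""
    outdir = Path(outdir)
    sample_dir = outdir / "samples"
    sample_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng((design.seed + 777) % (2**31))

    sheet_entries: dict[str, str] = {}
    samples: dict[str, dict] = {}
    expected_calls: list[dict] = []
    expected_discards: dict[str, dict[str, int]] = {}
    event_membership: dict[str, dict] = {
        ev.event_id: {"tumor": [], "normal": [], "tss_by_sample": {}} for ev in design.events
    }
    planted_counter = {ev.event_id: 0 for ev in design.events}
    genes_by_id = {g.gene_id: g for g in reference.genes}

    sample_ids = [f"T{i:03d}" for i in range(1, design.n_tumor + 1)] + [
        f"N{i:03d}" for i in range(1, design.n_normal + 1)
    ]
    groups = ["tumor"] * design.n_tumor + ["normal"] * design.n_normal

    for sid, group in zip(sample_ids, groups):
        sheet_entries[sid] = group
        transcripts: list[TranscriptModel] = []
        record = {"planted": {}, "decoys": {}, "background": []}
        n = 0

        # background: canonical transcript of every annotated gene
        for gene in reference.genes:
            n += 1
            tid = f"{sid}.t{n}"
            layout = _GENES[gene.gene_id]
            exons = [GenomicInterval(CONTIG, s, e, gene.strand) for s, e in layout["exons"]]
            if gene.strand == "-":
                exons = sorted(exons, key=lambda iv: iv.start, reverse=True)
            transcripts.append(
                TranscriptModel(transcript_id=tid, sample_id=sid, strand=gene.strand, exons=exons)
            )
            record["background"].append(tid)

        # planted events: recorded Bernoulli draw per event
        for ev in design.events:
            prevalence = ev.tumor_prevalence if group == "tumor" else ev.normal_prevalence
            present = bool(rng.random() < prevalence)
            if not present:
                continue
            mode = ev.tss_modes[planted_counter[ev.event_id] % len(ev.tss_modes)]
            planted_counter[ev.event_id] += 1
            offset = mode + int(rng.integers(0, ev.tss_jitter_bp + 1))
            n += 1
            tid = f"{sid}.t{n}"
            t = _event_transcript(ev.event_id, offset, tid, sid)
            transcripts.append(t)
            record["planted"][ev.event_id] = {"transcript_id": tid, "tss_pos": t.tss.start}
            event_membership[ev.event_id][group].append(sid)
            event_membership[ev.event_id]["tss_by_sample"][sid] = t.tss.start
            gene = genes_by_id[ev.gene_id]
            expected_calls.append(
                {
                    "sample_id": sid,
                    "transcript_id": tid,
                    "gene_id": ev.gene_id,
                    "gene_name": gene.gene_name,
                    "tss_pos": t.tss.start,
                    "tss_te_name": ev.tss_te,
                    "te_chain": list(ev.te_chain),
                    "product_class": ev.product_class_truth.value,
                    "event_id": ev.event_id,
                }
            )

        # decoys, cycling through the discard-reason taxonomy
        discards = {"unstranded": 0, "tss_not_te": len(record["background"]),
                    "first_exon_in_gene": 0, "no_coding_target": 0}
        for d in range(design.n_decoys_per_sample):
            kind, strand, exon_coords = _DECOYS[d % len(_DECOYS)]
            n += 1
            tid = f"{sid}.t{n}"
            exons = [GenomicInterval(CONTIG, s, e, strand) for s, e in exon_coords]
            transcripts.append(
                TranscriptModel(transcript_id=tid, sample_id=sid, strand=strand, exons=exons)
            )
            record["decoys"][tid] = kind
            discards[kind] += 1

        write_transcripts_gtf(transcripts, sample_dir / f"{sid}.gtf", source="StringTie")
        samples[sid] = record
        expected_discards[sid] = discards

    sheet = SampleSheet(sheet_entries)
    sheet_path = outdir / "samples.tsv"
    sheet.write_tsv(sheet_path)

    events_truth, gene_table_truth = _expected_cohort_outcome(
        design, event_membership, genes_by_id
    )

    truth = GroundTruth(
        design={
            "seed": design.seed,
            "n_tumor": design.n_tumor,
            "n_normal": design.n_normal,
            "n_decoys_per_sample": design.n_decoys_per_sample,
            "genome_size": design.genome_size,
            "events": [dataclasses.asdict(ev) for ev in design.events],
        },
        n_curated_units=N_CURATED_UNITS,
        n_erv_groups=N_ERV_GROUPS,
        samples=samples,
        expected_calls=expected_calls,
        expected_discards=expected_discards,
        events=events_truth,
        expected_gene_table=gene_table_truth,
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return Cohort(
        sample_dir=sample_dir, sheet=sheet, sheet_path=sheet_path, truth=truth, truth_path=truth_path
    )


def _expected_cohort_outcome(design, event_membership, genes_by_id):
    """Realized per-event aggregate clusters, filter outcome and gene table."""
    events_truth: dict[str, dict] = {}
    passing_by_gene: dict[str, dict[str, set]] = {}
    for ev in design.events:
        members = event_membership[ev.event_id]
        tss_by_sample: dict[str, int] = members["tss_by_sample"]
        clusters = _single_linkage_clusters(list(tss_by_sample.values()))
        cluster_info = []
        for cluster in clusters:
            cluster_set = set(cluster)
            t_samples = sorted(
                s for s in members["tumor"] if tss_by_sample[s] in cluster_set
            )
            n_samples = sorted(
                s for s in members["normal"] if tss_by_sample[s] in cluster_set
            )
            passes = (
                len(t_samples) / design.n_tumor > 0.20
                and len(n_samples) / design.n_normal < 0.10
            )
            cluster_info.append(
                {
                    "tss_min": min(cluster),
                    "tss_max": max(cluster),
                    "tumor_samples": t_samples,
                    "normal_samples": n_samples,
                    "passes_filter": passes,
                }
            )
            if passes:
                entry = passing_by_gene.setdefault(
                    ev.gene_id, {"tumor": set(), "normal": set(), "classes": set()}
                )
                entry["tumor"] |= set(t_samples)
                entry["normal"] |= set(n_samples)
                entry["classes"].add(ev.product_class_truth.value)
        events_truth[ev.event_id] = {
            "gene_id": ev.gene_id,
            "n_tumor_samples": len(members["tumor"]),
            "n_normal_samples": len(members["normal"]),
            "tumor_samples": sorted(members["tumor"]),
            "normal_samples": sorted(members["normal"]),
            "n_aggregates": len(clusters),
            "clusters": cluster_info,
            "passes_filter": any(c["passes_filter"] for c in cluster_info),
        }

    table = []
    for gene_id, entry in passing_by_gene.items():
        table.append(
            {
                "gene_id": gene_id,
                "gene_name": genes_by_id[gene_id].gene_name,
                "nN": len(entry["normal"]),
                "nT": len(entry["tumor"]),
                "pctN": format_percentage(len(entry["normal"]), design.n_normal),
                "pctT": format_percentage(len(entry["tumor"]), design.n_tumor),
                "product_classes": sorted(entry["classes"]),
            }
        )
    table.sort(key=lambda r: (-r["nT"], r["gene_name"]))
    return events_truth, table


def generate(design: CohortDesign, outdir: str | Path) -> tuple[Reference, Cohort]:
    """Generate reference and cohort into ``outdir`` in one call."""
    reference = generate_reference(design, outdir)
    cohort = generate_cohort(design, reference, outdir)
    return reference, cohort


# --------------------------------------------------------------------------
# end-to-end self check


@dataclass
class EndToEndReport:
    """Per-stage diff between pipeline output and ground truth."""

    mismatches: dict[str, list[str]]
    n_calls: int = 0
    n_aggregates: int = 0
    n_passing: int = 0
    table: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(self.mismatches.values())

    def summary(self) -> str:
        lines = [f"calls={self.n_calls} aggregates={self.n_aggregates} passing={self.n_passing}"]
        for stage, items in self.mismatches.items():
            lines.append(f"{stage}: {'OK' if not items else f'{len(items)} mismatch(es)'}")
            lines.extend(f"  - {item}" for item in items[:20])
        return "\n".join(lines)


def end_to_end_check(design: CohortDesign, outdir: str | Path | None = None) -> EndToEndReport:
    """Generate a cohort, run the full pipeline on the emitted files, and
    diff every stage against the recorded ground truth.

    Expected outcome on any generated design: zero false positives and zero
    false negatives at every stage (planted structures are unambiguous by
    construction).
    """
    import tempfile

    from .pipeline import discover_sample_gtfs, run_pipeline

    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(outdir) if outdir is not None else Path(tmp)
        reference, cohort = generate(design, workdir)
        truth = cohort.truth
        result = run_pipeline(
            sample_gtfs=discover_sample_gtfs(cohort.sample_dir),
            genes_gtf=reference.genes_gtf_path,
            genome_fasta=reference.genome_path,
            sheet=cohort.sheet,
            rmsk_path=reference.rmsk_out_path,
        )

    mismatches: dict[str, list[str]] = {
        "curation": [],
        "detection": [],
        "discards": [],
        "aggregation": [],
        "filter": [],
        "classification": [],
        "gene_table": [],
    }

    if len(result.tes) != truth.n_curated_units:
        mismatches["curation"].append(
            f"expected {truth.n_curated_units} curated units, got {len(result.tes)}"
        )
    n_groups = len({u.erv_group_id for u in result.tes if u.erv_group_id})
    if n_groups != truth.n_erv_groups:
        mismatches["curation"].append(
            f"expected {truth.n_erv_groups} ERV group(s), got {n_groups}"
        )

    expected_by_key = {
        (c["sample_id"], c["transcript_id"]): c for c in truth.expected_calls
    }
    got_by_key = {(c.sample_id, c.transcript_id): c for c in result.calls}
    for key in sorted(expected_by_key.keys() - got_by_key.keys()):
        mismatches["detection"].append(f"false negative: {key}")
    for key in sorted(got_by_key.keys() - expected_by_key.keys()):
        mismatches["detection"].append(f"false positive: {key}")
    for key in sorted(expected_by_key.keys() & got_by_key.keys()):
        exp, got = expected_by_key[key], got_by_key[key]
        if got.gene_id != exp["gene_id"]:
            mismatches["detection"].append(
                f"{key}: target {got.gene_id} != {exp['gene_id']}"
            )
        if got.te_chain != exp["te_chain"]:
            mismatches["detection"].append(
                f"{key}: te_chain {got.te_chain} != {exp['te_chain']}"
            )
        if got.tss_te_name != exp["tss_te_name"]:
            mismatches["detection"].append(
                f"{key}: tss TE {got.tss_te_name} != {exp['tss_te_name']}"
            )

    for sid, expected in sorted(truth.expected_discards.items()):
        got = result.discards_per_sample.get(sid, {})
        if {k: v for k, v in got.items() if v} != {k: v for k, v in expected.items() if v}:
            mismatches["discards"].append(f"{sid}: {got} != {expected}")

    agg_by_gene: dict[str, list] = {}
    for a in result.aggregates:
        agg_by_gene.setdefault(a.gene_id, []).append(a)
    passing_ids = {id(a) for a in result.passing}
    for event_id, ev_truth in sorted(truth.events.items()):
        gene_aggs = agg_by_gene.get(ev_truth["gene_id"], [])
        if len(gene_aggs) != ev_truth["n_aggregates"]:
            mismatches["aggregation"].append(
                f"{event_id}: {len(gene_aggs)} aggregate(s), expected "
                f"{ev_truth['n_aggregates']}"
            )
            continue
        for cluster, agg in zip(
            ev_truth["clusters"], sorted(gene_aggs, key=lambda a: a.tss_window.start)
        ):
            got_t = sorted(agg.samples_by_group.get("tumor", set()))
            got_n = sorted(agg.samples_by_group.get("normal", set()))
            if got_t != cluster["tumor_samples"] or got_n != cluster["normal_samples"]:
                mismatches["aggregation"].append(
                    f"{event_id}@{cluster['tss_min']}: member samples differ"
                )
            if (id(agg) in passing_ids) != cluster["passes_filter"]:
                mismatches["filter"].append(
                    f"{event_id}@{cluster['tss_min']}: filter outcome != expected "
                    f"({cluster['passes_filter']})"
                )

    for c in truth.expected_calls:
        key = (c["sample_id"], c["transcript_id"])
        got_class = result.products.get(key)
        if got_class is None or got_class.value != c["product_class"]:
            mismatches["classification"].append(
                f"{key}: {got_class and got_class.value} != {c['product_class']}"
            )

    got_table = [
        {
            "gene_id": r.gene_id,
            "nN": r.nN,
            "nT": r.nT,
            "pctN": r.pctN,
            "pctT": r.pctT,
            "product_classes": sorted(r.product_classes),
        }
        for r in result.table
    ]
    exp_table = [
        {k: row[k] for k in ("gene_id", "nN", "nT", "pctN", "pctT", "product_classes")}
        for row in truth.expected_gene_table
    ]
    if got_table != exp_table:
        mismatches["gene_table"].append(f"table {got_table} != expected {exp_table}")

    return EndToEndReport(
        mismatches=mismatches,
        n_calls=len(result.calls),
        n_aggregates=len(result.aggregates),
        n_passing=len(result.passing),
        table=got_table,
    )
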