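# Methods

This note documents the models, rules and numerical choices behind
`tcgtscan`, and what the synthetic-data tests do and do not demonstrate
about real cohorts.

## Coordinates and input contracts

All internal coordinates are 0-based, half-open, on named contigs; GTF and
RepeatMasker `.out` (both 1-based inclusive) are converted only at the I/O
boundary, so no stage ever mixes conventions. Overlap is half-open interval
intersection with a 1-bp threshold everywhere — no rule in the method
states a minimum overlap, so none is imposed.

Transcripts are StringTie-style `transcript`/`exon` GTF records; exons are
re-ordered into transcript orientation on read and the TSS is defined as a
1-bp interval at the strand-appropriate terminus of the first exon. The
TSS is deliberately *not* the whole first exon: the TSS-in-TE test and the
first-exon-outside-genes test need distinct anchors. Transcripts with
unknown strand (`.`) are excluded from chimera calling and tallied under
the `unstranded` discard reason — target-gene strand concordance is
undefined for them. Transcript records without exon lines are skipped with
a logged count.

Gene models come from a GTF with `CDS` records carrying a valid frame.
The gene body is the min-start..max-end span over all the gene's features;
coding exons are the merged union of CDS intervals over all transcripts;
the canonical CDS is the transcript with the longest total CDS (ties by
transcript id). CDS coordinates follow the Ensembl convention (stop codon
excluded), and predicted ORFs are trimmed to the same convention before
comparison.

## Repeat curation

RepeatMasker reports fragments, not biological units. Two passes rebuild
units:

* **Fragment fusion.** Rows with the same repeat name on the same
  chromosome and strand fuse when they share the `.out` linkage ID. When
  linkage IDs are absent or never shared (some exports renumber per
  chromosome, making IDs useless), a fallback fuses same-name neighbors
  within `max_fuse_gap` (default 10 kb, chosen to span typical
  nested-insertion interruptions without bridging unrelated copies). The
  fused unit keeps its fragment list; fusion conserves the covered base
  set exactly and is idempotent.
* **LTR–internal grouping.** A unit whose name ends `-int` with class
  `LTR/*` captures the nearest same-strand LTR-class unit on each side if
  it is immediately adjacent (no intervening unit of any family) and
  within `max_ltr_int_gap` (default 2 kb). Members share an `erv_group_id`
  with transcription-direction-aware roles `ltr5`/`internal`/`ltr3`;
  unmatched LTRs are `solo`. An optional pairing table can restrict which
  LTR names flank which internal names (Repbase pairings are not
  universal; the name-suffix convention is the default).

Downstream TSS tests run against unit *fragments*, never the fused span,
because a span may contain interior bases belonging to other elements.
Detection treats all curated units equally regardless of role; the role is
recorded for downstream interpretation.

## Chimera calling

Per transcript, three ordered tests (first failure is the recorded discard
reason): TSS ∩ TE fragment (any TE strand — an LTR can promote in either
orientation relative to its consensus); first exon ∩ no gene body (the
"annotated gene" mask defaults to whole gene bodies of the supplied
annotation; `first_exon_mask="exons"` exposes the coding-exon-only
alternative, and the choice is a genuine sensitivity for loci where
lncRNAs overlap the TE promoter region); and ≥1 bp coding-exon overlap by
a downstream exon with a same-strand gene. The target gene maximizes
summed coding overlap, with ties broken by total exon∩gene-body overlap
and then lexicographic gene id, so output is fully deterministic. The
discard tallies partition the input exactly
(inputs = calls + Σ reasons), which makes per-sample accounting testable.

Mono-exonic transcripts get an adapted rule, since their single exon must
overlap the target gene: the TSS must be in a TE, the exon must overlap
coding sequence, and the 5' stretch of the exon *before its first coding
overlap* must avoid all gene bodies. This is strict — a target gene with
an annotated 5' UTR will reject mono-exonic chimeras whose head crosses
the UTR — and calls passing it are flagged `monoexonic=True` so they can
be separated downstream.

## Aggregation, recurrence, reporting

Same-gene calls cluster by single-linkage (transitive chaining) on TSS
position with a 100 bp link distance: "within 100 bp of each other" is a
pairwise relation, and transitive closure is its standard clustering. The
number of aggregates is non-increasing in the window, and each call
belongs to exactly one aggregate. Per aggregate, occurrence per sample
group counts distinct samples (isoforms count once).

The filter keeps aggregates with tumor fraction strictly greater than 20%
and normal fraction strictly less than 10% — strict on both sides, per
the defining wording of the rule. The per-gene summary unions contributing
samples over the gene's *passing* aggregates (configurable to all
aggregates), reports percentages rounded half-up to one decimal (verified
to reproduce the published table arithmetic: 186/286 → 65.0, 11/286 → 3.8,
175/286 → 61.2, 159/286 → 55.6, 85/286 → 29.7), and the union over member
transcripts of the predicted product classes — a gene can legitimately
carry several (different chimeric isoforms in different samples).

## ORF prediction and product classes

No standard defines "the" ORF of a chimeric transcript; the package uses
the conventional longest-ORF rule: the longest ATG-initiated reading frame
terminated by an in-frame stop within the transcript, ties to the 5'-most
start, minimum 30 protein codons (configurable; screens spurious
micro-ORFs in random UTR sequence). The prediction is verified against
exhaustive enumeration of all ATG→stop spans in the test suite.

Classification compares the predicted ORF with the canonical CDS **in
genomic coordinates and frames**, not as protein strings, so that isoforms
sharing sequence by coincidence are not mislabeled. Per genomic base of
each CDS a codon phase is computed by walking the CDS in translation
orientation; over the shared bases, if ≥ 50% disagree in phase the product
is `out-of-frame` (the threshold is a deterministic tie-break for partial
frameshifts caused by alternative splicing — below it, the frame-preserving
classes are tested). Otherwise the 5' and 3' CDS termini decide:
equal/equal → `canonical`; start upstream/downstream with the same stop →
`N-ext`/`N-trunc`; same start with stop upstream/downstream →
`C-trunc`/`C-ext`; both strictly inside → `N-C-trunc`. No genomic overlap,
or no ORF, → `non-coding`. Mixed cases outside this vocabulary (e.g. both
ends extended) take the label of their 5'-end change, because TcGTs are
5'-end events; protein-string containment is asserted as a secondary check
for the ext/trunc classes and logged (never label-changing) when violated.
Exactly one label is produced for every (ORF, gene) pair.

## Synthetic cohort generator

The generator emulates the structure of a matched tumor/normal cohort at
desk scale: a 200 kb toy contig (`chrS1`, named to prevent accidental
mixing with real builds), six protein-coding genes including a mono-exonic
retrogene (`POU5F1B_like`) and a minus-strand gene, and a repeat
complement containing the retrogene's upstream promoter chain
(LTR66 → AluSx1 → LTR33 → L2b → MLT1F1), a fragmented LTR sharing a
linkage ID, an LTR–internal–LTR provirus, an intronic repeat and scattered
copies — 16 `.out` rows curating to 15 units with one ERV group.

Default design: 50 tumors, 50 normals, three planted events at tumor/normal
prevalences 0.40/0.0 (canonical product, retrogene), 0.25/0.05
(N-truncated) and 0.10/0.0 (out-of-frame), each with ≤ 40 bp uniform TSS
jitter inside its LTR (well under the 100 bp clustering window; a
`tss_modes` list can force a bimodal TSS spread to exercise the
two-aggregate case), plus three decoys per sample mapping one-to-one onto
the discard reasons, and every gene's canonical transcript as background.
Prevalences are realized as *recorded* Bernoulli draws, and all downstream
expectations (aggregate memberships, filter outcomes, the gene table) are
computed from the realized draws — stage tests are exact, not statistical.

Planted chimeras are made unambiguous by sequence design: every non-final
chimeric exon ends in a 12-mer containing stop codons in all three frames,
so no reading frame survives a splice junction from upstream; the
N-truncation gene has no internal in-frame ATG except one designed restart
codon; the frameshift gene is built codon-by-codon so its +2-shifted frame
is stop-free up to a designed stop, and the chimera splices in past the
canonical ATG after contributing `ATG` + 1 nt. Designed sequences are
re-validated at generation time (canonical CDSs translate cleanly; every
planted chimera classifies to its designed class); the rare random-sequence
collision triggers a deterministic re-draw. All outputs are byte-identical
under a fixed seed.

What the synthetic tests show: that every rule of the pipeline — curation
arithmetic, the three discard tests, target choice, clustering, the strict
filter boundaries, product classification — is implemented exactly as
specified, with zero tolerance. What they do not show: robustness to
assembly noise (fragmented or merged transcripts), annotation
incompleteness, read-depth-dependent detection sensitivity, or ambiguous
TE boundaries in real RepeatMasker tracks; none of these are modeled, and
real-cohort prevalence estimates inherit the upstream assembler's
behaviour.

## Problem sizes and degenerate inputs

Tests and the acceptance script run cohorts of 24–100 samples on a 200 kb
genome — sizes chosen so every brute-force oracle (exhaustive ORF
enumeration, transitive-closure clustering, naive per-triple detection)
remains exact and the whole suite completes in seconds. Degenerate inputs
are defined errors, not silent behaviour: empty curated-TE or gene lists
fail detection loudly (a missed curation step), samples missing from the
sample sheet abort counting with the offending ids, fraction parameters
outside [0, 1] and negative gaps/windows are rejected, and calls on genes
without CDS are labeled `non-coding` with a warning rather than failing a
batch.
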