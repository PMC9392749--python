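"""Predict and classify the protein product of chimeric transcripts.

For each called chimera the spliced cDNA is extracted, its longest
ATG-initiated ORF predicted, and the ORF compared with the target gene's
canonical CDS in genomic coordinates.
"""

import tempfile

from tcgtscan import (
    classify_calls,
    detect_tcgts,
    load_curated_tes,
    open_genome,
    read_gtf,
)
from tcgtscan.synthetic import CohortDesign, generate

with tempfile.TemporaryDirectory() as tmp:
    design = CohortDesign(seed=7, n_tumor=6, n_normal=2)
    reference, cohort = generate(design, tmp)
    tes = load_curated_tes(rmsk_path=reference.rmsk_out_path)
    genes = read_gtf(reference.genes_gtf_path, kind="genes")
    genome = open_genome(reference.genome_path)

    calls, transcripts = [], []
    for sid in sorted(cohort.sheet.entries):
        ts = read_gtf(cohort.sample_dir / f"{sid}.gtf", kind="transcripts", sample_id=sid)
        transcripts.extend(ts)
        calls.extend(detect_tcgts(ts, genes, tes).calls)
    products = classify_calls(calls, transcripts, genes, genome)

by_gene = {}
for call in calls:
    label = products[(call.sample_id, call.transcript_id)]
    by_gene.setdefault(call.gene_name, []).append(label.value)
for gene, labels in sorted(by_gene.items()):
    print(f"{gene:<14} {len(labels)} chimera(s): {sorted(set(labels))}")

# canonical = the TE promoter only replaces the 5' UTR, the full protein
# is kept; N-trunc = translation restarts at an internal ATG; out-of-frame
# = the splice shifts the reading frame across the coding sequence.
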