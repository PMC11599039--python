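"""Produce the standard-format artifacts for one simulated sample.

Builds the locus, renders both reference builds as FASTA, simulates a case-1
sample at 30x, writes truth (VCF + BED), reads (FASTQ pair), alignments
(SAM) and calls (VCF) into ./paraclone_demo/ — the file set a downstream
tool chain would consume.
"""

import os

import paraclone as pc

out = "paraclone_demo"
os.makedirs(out, exist_ok=True)

locus = pc.build_locus(1)
refs = {b: pc.render_reference(locus, b) for b in ("buildA", "buildB")}
for name, ref in refs.items():
    pc.reference_to_fasta(ref, f"{out}/{name}.fa")

sample = pc.make_sample(locus, "case1_pseudolike_het_snv", seed=11)
vcf_path, bed_path = pc.write_truth(sample, out)

pairs = list(pc.simulate_reads(sample, pc.SimConfig(seed=11)))
pc.write_fastq(pairs, f"{out}/reads_R1.fastq", f"{out}/reads_R2.fastq")

for name, ref in refs.items():
    idx = pc.ReferenceIndex(ref)
    records = pc.map_reads(pairs, ref, idx.config)
    pc.write_sam(records, ref, f"{out}/{sample.sample_id}.{name}.sam")
    cols = pc.build_pileup(records, ref, mapq_min=20)
    calls = pc.call_small_variants(cols)
    pc.write_vcf(calls, ref, f"{out}/{sample.sample_id}.{name}.vcf")
    print(f"{name}: {len(records)} alignment records, {len(calls)} calls")

print(f"\nwrote references, truth ({os.path.basename(vcf_path)}, "
      f"{os.path.basename(bed_path)}), FASTQ, SAM and call VCFs under {out}/")
print("The two per-build VCFs differ at the gene variant — that difference "
      "is the whole point.")
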