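# Methods

## The locus model

The simulated contig carries, on one strand, a 7.6-kb gene and, 16 kb
downstream, a 6.6-kb pseudogene that mirrors the gene from 1 kb inside its
5' end to its 3' end. The homologous span has two regimes:

* a **core block** of 1,614 bp of perfect identity broken only by five
  paralogous sequence variants (PSVs) at core offsets 266, 276, 576, 590 and
  625 — the geometry of the extreme-homology block shared by the 3' exons of
  *GBA1* and *GBA1LP*;
* a **diverged tail** over the rest of the span with i.i.d. substitutions at
  2.5% per base, emulating the ~96–98% identity of the wider
  gene–pseudogene region, within which 150-bp reads are uniquely assignable.

Background sequence is i.i.d. uniform ACGT from the seed; GC content plays
no role in any mechanism modelled here. Both paralogs are on the same
strand: the real pair's strand relationship does not affect the read-level
arithmetic, and a same-strand encoding keeps every coordinate lift a
constant displacement.

**PSV letters.** The five sites carry gene alleles (A, C, C, C, A) against
pseudogene majors (G, T, G, G, G). Four sites (266, 276, 576, 590) are
*registration-discordant*: "buildA" (GRCh37-like) registers the pseudogene
major, "buildB" (GRCh38-like) registers the gene-like minor allele. The site
at 625 is build-concordant and is the gene position of the case-1 variant.
The letters are chosen so the diagnostic read triples across the three 3'
sites are internally consistent: a variant-carrying gene read (C–C–G)
scores 1 mismatch against the gene copy, 0 against the buildB pseudogene
copy and 2 against the buildA copy; a pseudogene-derived read carrying the
gene-like base at the concordant site (G–G–A) scores 2/3/1. These score
patterns, not the specific letters, drive every downstream behaviour.

Population minor-allele frequencies on PSV sites (0.213, 0.0108, 0.0017,
0.0107) are carried as metadata only: the mechanisms depend on reference
registration, not on sample-level PSV polymorphism, so simulated pseudogene
haplotypes carry the major allele unless a scenario states otherwise.

## Case archetypes

Each sample is diploid; haplotype 0 is always the buildA-like reference
haplotype and the scenario variant sits heterozygously on haplotype 1.

* **case1_pseudolike_het_snv** — a het gene SNV at the concordant-PSV
  homolog whose alternate allele *is* the pseudogene base (a
  gene-conversion-derived allele, the p.L483P pattern).
* **case2_control** — no gene variant; the pseudogene haplotype carries the
  gene-like base at the concordant site. This is the minimal state that
  produces the published read arithmetic (3 mismatches against the buildB
  pseudogene copy), and it is why the "control" shows spurious gene calls
  under buildB only. The allele is recorded as pseudogene-copy truth;
  gene-copy truth is empty.
* **case3_gene_delins** — a het 20-bp deletion plus TG insertion at core
  offsets 480–500, positioned so junction-spanning reads can reach the
  discordant PSVs but not the concordant one: callable under buildA,
  depth-starved under buildB.
* **case4_gene_conversion_sv** — one pseudogene haplotype's sequence from
  core offset 600 onward is replaced by the homologous gene-derived interval
  carrying a 3-bp (CAC) deletion in the diverged tail. Copy numbers over the
  tract become 3 gene-like / 1 pseudogene-like. The conversion start sits
  just downstream of two PSVs, so breakpoint-spanning reads mix retained
  pseudogene bases with gene-anchoring bases — the source of the spurious
  near-breakpoint SNVs. The conversion also copies the downstream
  "gene-specific" primer site, the mechanism by which the Sanger arm
  amplifies the converted segment and miscalls the embedded deletion. (The
  real event's amplification path is not described mechanistically in the
  literature; primer-site copying is one consistent mechanism and is flagged
  as a model choice.)

## Read simulation

150-bp paired-end reads at 30× mean depth; fragment lengths are truncated
normal (mean 450 bp, sd 60 bp) — chosen so pairs can span the conversion
breakpoint — drawn uniformly along each haplotype; pair count is Poisson
around `depth · total_len / (4 · read_len)`. Sequencing noise is i.i.d.
substitution at 0.001/base; base qualities are constant Q30 and ignored
downstream, because every calling behaviour studied here is driven by
mapping quality, not base quality. No indel errors, PCR duplicates or
adapter artifacts are simulated.

## Mapper

Candidates come from exact 21-mer seeds on either strand, and the
homologous window at the other paralog is always scored even without a seed
hit (the displacement between paralogs is constant by construction). Edit
costs are mismatch 1, gap open 2, gap extend 1; a read whose best score
exceeds 30% of its length is unmapped. Because the error model is
substitution-only, a read carries at most one indel junction, so candidate
scoring uses an exact single-gap search within a 32-bp band, anchored from
both read ends — equivalent to a full banded alignment under these costs
for every read the simulator can produce (the brute-force oracle test
checks exactly this).

MAPQ is the phred-scaled posterior that the best placement is wrong, with
per-base error probability 0.005 in the posterior, capped at 60, and exact
score ties mapped to 0. The 0.005 value makes a single diagnostic base worth
MAPQ 23, just above the downstream filter of 20 — one discriminating PSV in
a read is enough to keep it, zero is not, which is the published threshold
behaviour. Ties are reported at the mate-concordant placement if one exists
(FR orientation, insert within mean ± 4 sd), else at the lowest coordinate;
the reported position of a MAPQ-0 read matters only to the copy-number
scan, which is exactly where the pooled depth of ambiguous reads is the
evidence.

Alignment ends whose mismatch run scores positive under (3·mismatch −
match) are soft-clipped, as a local aligner would: without this, reads
ending inside an unmodelled junction spray mismatches into the pileup and
create artifact SNVs no real pipeline would emit.

## Caller

Pileup includes only reads with MAPQ ≥ 20 (configurable), walks CIGARs, and
merges runs of reference-adjacent differences containing an indel — allowing
up to two matching bases inside the run — into one complex (delins) allele,
normalized to its minimal left-most VCF representation; this is how
haplotype-based callers effectively represent the 20-bp delins, and it makes
call/truth comparison exact. Variants are emitted where the alternate
allele reaches 20% of the allele depth with ≥ 8 passing reads; het calls
below allele balance 0.3 are flagged `biased_ab`. These thresholds are the
minimal mechanism reproducing the published call/no-call outcomes; no
genotype likelihoods are computed, and joint calling is out of scope.

The depth track counts all primary alignments per 100-bp window with no
MAPQ filter by default (conversion products generate MAPQ-0 reads whose
depth is the signal). The ratio track divides a sample's windows by the
mean of ≥ 1 control tracks, after rescaling every track to unit mean
coverage (library-size correction; a reciprocal gain/loss event leaves the
total unchanged, so the correction is unbiased for this signature). Windows
with zero control depth are undefined and skipped with a warning; undefined
windows do not break segment runs. CN segments are maximal runs of ≥ 3
consecutive windows at ratio ≥ 1.25 (gain) or ≤ 0.75 (loss), with
`cn = round(2 · mean ratio)`.

**Where the 1.5 / 0.5 signature lives.** Inside the perfect-identity core,
reads cannot be assigned between the copies; the mapper necessarily pools
the depth of both, and the ratio is ~1 there *by construction* regardless of
the true copy numbers. The tract-level measurement (`tract_ratios`, used by
the acceptance script) therefore averages windows of the converted interval
beyond the core block plus one read length of margin — the locus-assignable
portion, which is where the published ratio plot shows its ~1.5 and ~0.5
plateaus. At 30× with five controls the per-window ratio noise is ~13%, so
isolated noise segments of a few windows do occur in unaffected regions;
they are never reciprocal across the two paralogs, which is what the
classifier requires.

## Sanger arm

Primers are exact-match 20-mers; each pair is gene-specific by construction
because one primer covers a PSV. Amplification requires both primers to
match exactly in the correct orientation within 8 kb on the same haplotype;
every match site yields one amplicon. Consensus genotyping aligns amplicons
to the intended gene interval with the same single-gap diff used elsewhere,
reports every disagreement, and calls het when an allele is absent from at
least one amplicon. Amplicons with more than 25 differences fail the edit
threshold and are skipped with a warning — which is what keeps a
chance-matching primer pair from genotyping a diverged pseudogene segment.
The arm is noise-free: for scenarios without structural variation its calls
equal the gene-copy truth exactly, so every deviation it shows is
mechanistic, not stochastic.

## Adjudication

One record per variant seen in truth or any arm (Sanger, short-read vs
buildA, short-read vs buildB), on gene-copy coordinates, normalized.
Classification applies rules in order: (1) reciprocal gain/loss CN segments
over the paralogs → `structural_variant_artifact`; (2) real variant, called
under buildA, missed under buildB, alternate allele equal to the pseudogene
base at the homologous offset → `registration_missed`; (3) no truth, called
under buildB, alternate equal to a pseudogene major at a discordant-PSV
homolog → `registration_spurious`; (4) real variant missed with MAPQ-passing
depth below 8 over the site → `low_mapq_dropout`. Structural evidence goes
first because a conversion generates registration-like artifacts that rules
2–3 would otherwise claim. The long-read arm of a real study is represented
by truth records — the simulator knows the haplotypes — rather than by a
simulated long-read pipeline.

## Problem sizes and determinism

Default runs use the full ~32-kb contig at 30× (≈ 3,200 pairs per sample).
The rate-style checks run 20 read-simulation seeds per scenario for the
case-1/case-2 rates and 5 for the case-3 modal outcome; the copy-number
scan uses one case sample against 5 diploid controls. All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`, so every
number in the tests and the acceptance script is reproducible bit-for-bit.
The mapper's brute-force oracle comparison runs on a ~2-kb preset with the
same PSV structure.

## Known limitations

* The mapper is not a BWA-MEM reimplementation: no split/supplementary
  alignments, no base-quality-aware scoring, single-gap alignments only.
  Published real-data read counts (allele depths 13/4 or 15/3, 3 vs 12
  passing reads) are properties of real libraries and are reproduced only
  directionally.
* The caller has no genotype likelihoods, no joint calling, no gVCF; its
  thresholds stand in for an unparameterized production filter stack.
* The Sanger arm has no chromatogram or thermodynamic model; specificity
  and its case-4 failure are purely combinatorial.
* Synthetic uniform-ACGT backgrounds lack repeats, GC bias and mappability
  structure; passing tests demonstrate the paralog-registration mechanisms,
  not performance on real genomes.
* Only substitution sequencing errors are modelled; homopolymer indel
  errors would add pileup noise the thresholds here have not been exercised
  against.
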