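"""Gene-specific PCR plus Sanger consensus genotyping, in silico.

The wet-lab arm this emulates amplifies the functional gene but not its
pseudogene, using primers that sit on paralog-diagnostic bases, then reads
the amplicons by capillary sequencing. Here primers are exact-match k-mers
(no thermodynamics); gene specificity is enforced structurally by requiring
one primer of each pair to cover a PSV, and the arm is noise-free: its
failure modes are purely combinatorial, e.g. a gene conversion copying a
primer site into the pseudogene locus makes the "gene-specific" pair amplify
the converted segment and miscall its embedded variant as heterozygous in
the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from ._variants import trim_and_left_align
from .locus_forge import LocusModel, SampleGenome


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """An exact-match primer pair with its intended gene-copy amplicon.

    ``forward`` is the top-strand sequence at the amplicon 5' end;
    ``reverse`` is the bottom-strand primer (given 5'->3', i.e. the reverse
    complement of the top strand at the amplicon 3' end).
    ``gene_interval`` is the intended product on the locus contig.
    """

    name: str
    forward: str
    reverse: str
    gene_interval: tuple[int, int]

    def validate(self, locus: LocusModel) -> None:
        if min(len(self.forward), len(self.reverse)) < 15:
            raise PrimerError(f"{self.name}: primers must be >= 15 nt")
        contig = locus.contig()
        s, e = self.gene_interval
        if contig[s:s + len(self.forward)] != self.forward:
            raise PrimerError(f"{self.name}: forward primer does not match the gene copy")
        if contig[e - len(self.reverse):e] != revcomp(self.reverse):
            raise PrimerError(f"{self.name}: reverse primer does not match the gene copy")
        psv_pos = [locus.gene_pos(site.gene_offset) for site in locus.psv_sites]
        f_span = (s, s + len(self.forward))
        r_span = (e - len(self.reverse), e)
        if not any(f_span[0] <= p < f_span[1] or r_span[0] <= p < r_span[1]
                   for p in psv_pos):
            raise PrimerError(
                f"{self.name}: neither primer covers a PSV — the pair is not gene-specific"
            )


@dataclass(frozen=True)
class Amplicon:
    seq: str
    hap_index: int
    hap_start: int
    primer_name: str


@dataclass(frozen=True)
class SangerCall:
    pos: int                     # 0-based contig coordinate (gene copy)
    ref: str
    alt: str
    zygosity: str                # het iff both alleles observed among amplicons
    source_amplicons: int

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def default_primer_pairs(locus: LocusModel, primer_len: int = 20) -> list[PrimerPair]:
    """Two pairs covering the core block and the downstream gene body.

    The core pair anchors its forward primer on the 5'-most PSV; the
    downstream pair anchors on the build-concordant PSV, which the case-4
    conversion copies into the pseudogene locus — reproducing the wet-lab
    pair's failure mode by construction.
    """
    contig = locus.contig()
    sites = sorted(locus.psv_sites, key=lambda s: s.gene_offset)
    first = sites[0]
    conc = locus.concordant_sites[0]
    # core pair: forward ends just after the first PSV
    f1_start = locus.gene_pos(first.gene_offset) - primer_len + 10
    core_end = locus.gene_pos(locus.params.core_start + locus.core_block_len) + 150
    p1 = PrimerPair(
        name="core",
        forward=contig[f1_start:f1_start + primer_len],
        reverse=revcomp(contig[core_end - primer_len:core_end]),
        gene_interval=(f1_start, core_end),
    )
    # downstream pair: forward sits on the concordant PSV, reverse deep in the
    # gene-specific (diverged-homology) region
    f2_start = locus.gene_pos(conc.gene_offset) - primer_len + 10
    down_end = locus.gene_pos(locus.params.embedded_del_gene[1] + 400)
    p2 = PrimerPair(
        name="downstream",
        forward=contig[f2_start:f2_start + primer_len],
        reverse=revcomp(contig[down_end - primer_len:down_end]),
        gene_interval=(f2_start, down_end),
    )
    for p in (p1, p2):
        p.validate(locus)
    return [p1, p2]


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def insilico_pcr(
    sample: SampleGenome,
    primers: PrimerPair,
    max_product: int = 8000,
) -> list[Amplicon]:
    """Amplify every site where both primers match exactly in the correct
    orientation within ``max_product`` on the same haplotype."""
    if min(len(primers.forward), len(primers.reverse)) < 15:
        raise PrimerError("primers must be >= 15 nt")
    out: list[Amplicon] = []
    rev_site = revcomp(primers.reverse)
    for h, hap in enumerate(sample.haplotypes):
        f_hits = _find_all(hap, primers.forward)
        r_hits = _find_all(hap, rev_site)
        for f in f_hits:
            for r in r_hits:
                end = r + len(rev_site)
                if f < end and end - f <= max_product:
                    out.append(Amplicon(
                        seq=hap[f:end], hap_index=h, hap_start=f,
                        primer_name=primers.name,
                    ))
    return out


def consensus_genotype(
    amplicons: list[Amplicon],
    locus: LocusModel,
    gene_interval: tuple[int, int],
    max_edits: int = 25,
) -> list[SangerCall]:
    """Align amplicons to the intended gene-copy interval and report every
    disagreement; an allele seen in some but not all amplicons is het.

    Alignment is a lightweight anchored diff (the arm is noise-free): each
    amplicon is compared to the gene reference interval with a single-gap
    model, which covers every variant the simulator can place. Amplicons
    beyond ``max_edits`` differences are skipped with a warning.
    """
    if not amplicons:
        raise PrimerError("no amplicons to genotype")
    contig = locus.contig()
    s, e = gene_interval
    ref = contig[s:e]
    per_amplicon: list[set[tuple[int, str, str]]] = []
    for amp in amplicons:
        diffs = _diff_single_gap(ref, amp.seq)
        if diffs is None or len(diffs) > max_edits:
            warnings.warn(
                f"amplicon from haplotype {amp.hap_index} at {amp.hap_start} "
                "does not align within the edit threshold; skipped",
                stacklevel=2,
            )
            continue
        norm = set()
        for pos, r_allele, a_allele in diffs:
            norm.add(trim_and_left_align(contig, s + pos, r_allele, a_allele))
        per_amplicon.append(norm)
    if not per_amplicon:
        return []
    all_vars = set().union(*per_amplicon)
    calls = []
    for pos, r_allele, a_allele in sorted(all_vars):
        n_with = sum(1 for v in per_amplicon if (pos, r_allele, a_allele) in v)
        zyg = "hom" if n_with == len(per_amplicon) else "het"
        calls.append(SangerCall(pos, r_allele, a_allele, zyg, n_with))
    return calls


def sanger_arm(
    sample: SampleGenome, pairs: list[PrimerPair] | None = None
) -> list[SangerCall]:
    """Run the whole in-silico Sanger pipeline: amplify with every primer
    pair and merge the consensus calls (first pair wins on duplicates)."""
    pairs = pairs if pairs is not None else default_primer_pairs(sample.locus)
    seen: dict[tuple[int, str, str], SangerCall] = {}
    for pair in pairs:
        amps = insilico_pcr(sample, pair)
        if not amps:
            continue
        for call in consensus_genotype(amps, sample.locus, pair.gene_interval):
            seen.setdefault(call.key, call)
    return sorted(seen.values(), key=lambda c: c.key)


def _diff_single_gap(ref: str, alt: str, max_gap: int = 64):
    """Diff two near-identical sequences allowing at most one indel run.

    Returns a list of (ref_pos, ref_allele, alt_allele) raw differences with
    reference-adjacent runs merged into complex alleles, or None if the
    length difference exceeds ``max_gap``.
    """
    shift = len(alt) - len(ref)
    if abs(shift) > max_gap:
        return None
    rc, ac = encode(ref), encode(alt)
    if shift == 0:
        diffs = [(int(i), ref[i], alt[i]) for i in np.flatnonzero(rc != ac)]
        return _merge_adjacent(diffs, ref)
    # one gap: choose the split minimizing prefix + suffix mismatches, the
    # prefix aligned from the left and the suffix from the right
    n = min(len(ref), len(alt))
    pre = np.concatenate(([0], np.cumsum(rc[:n] != ac[:n])))
    mm_r = rc[len(ref) - n:][::-1] != ac[len(alt) - n:][::-1]
    cr = np.concatenate(([0], np.cumsum(mm_r)))
    costs = pre + cr[::-1]          # costs[t] for prefix length t in 0..n
    split = int(np.argmin(costs))
    diffs = [(int(i), ref[i], alt[i]) for i in np.flatnonzero(rc[:split] != ac[:split])]
    if shift < 0:
        diffs.append((split, ref[split:split - shift], ""))
    else:
        diffs.append((split, "", alt[split:split + shift]))
    for k in np.flatnonzero(mm_r[:n - split]):
        i = len(ref) - 1 - int(k)
        diffs.append((i, ref[i], alt[i + shift]))
    diffs.sort(key=lambda d: d[0])
    return _merge_adjacent(diffs, ref)


def _merge_adjacent(diffs, ref: str, bridge: int = 2):
    """Merge near-adjacent raw differences into complex alleles whenever an
    indel is involved, bridging up to ``bridge`` matching reference bases."""
    out: list[tuple[int, str, str]] = []
    for d in sorted(diffs, key=lambda x: x[0]):
        if out:
            p, r, a = out[-1]
            gap = d[0] - (p + len(r))
            is_indel = len(r) != len(a) or len(d[1]) != len(d[2])
            if gap == 0 or (0 < gap <= bridge and is_indel):
                fill = ref[p + len(r):d[0]]
                out[-1] = (p, r + fill + d[1], a + fill + d[2])
                continue
        out.append(d)
    return out
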