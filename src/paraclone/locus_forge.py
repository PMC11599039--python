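"""Synthetic gene/pseudogene locus, reference-build renderings and case samples.

The model emulates a high-identity paralog pair of the *GBA1*/*GBA1LP* kind:
a functional gene whose 3' portion is mirrored by a nearby pseudogene, with a
short core block of perfect identity broken only by a handful of paralogous
sequence variants (PSVs), and a longer flanking tract of ~97.5% identity.
Two reference-build renderings of the same locus differ only in which allele
is *registered* at the pseudogene copy of a subset of PSVs: "buildA" carries
the population-major pseudogene alleles (GRCh37-like), "buildB" carries
gene-like minor alleles at the discordant sites (GRCh38-like). That
registration difference, not any property of the samples, is what drives the
read-misassignment mechanisms downstream.

Coordinates are 0-based half-open internally; emitted VCF/BED/SAM are 1-based
per format convention. Both paralogs sit on the same strand of one synthetic
contig, gene first.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np

from ._seq import random_dna
from ._variants import trim_and_left_align

CONTIG_NAME = "synthctg1"

GENE = "gene"
PSEUDO = "pseudogene"

SCENARIOS = (
    "plain_control",
    "case1_pseudolike_het_snv",
    "case2_control",
    "case3_gene_delins",
    "case4_gene_conversion_sv",
)


class LocusConfigError(ValueError):
    """Invalid locus preset (bad PSV offsets, inconsistent geometry)."""


class ScenarioError(ValueError):
    """Scenario variant collides with a PSV or falls outside the locus."""


@dataclass(frozen=True)
class PsvSite:
    """A fixed gene/pseudogene sequence difference and its build registrations.

    Offsets are 0-based within the gene block and the pseudogene block
    respectively.  ``buildA_registered`` is always the pseudogene major
    allele; ``buildB_registered`` is either the same (build-concordant site)
    or the gene-like minor allele (registration-discordant site).
    ``pop_minor_af`` is carried as metadata only — simulated pseudogene
    haplotypes always carry the major allele unless a scenario says otherwise.
    """

    gene_offset: int
    pseudo_offset: int
    gene_allele: str
    pseudo_major_allele: str
    buildA_registered: str
    buildB_registered: str
    pop_minor_af: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_allele == self.pseudo_major_allele:
            raise LocusConfigError(
                f"PSV at gene offset {self.gene_offset}: gene allele equals pseudogene major"
            )
        if self.buildA_registered != self.pseudo_major_allele:
            raise LocusConfigError(
                f"PSV at gene offset {self.gene_offset}: buildA must register the pseudogene major"
            )
        if self.buildB_registered not in (self.pseudo_major_allele, self.gene_allele):
            raise LocusConfigError(
                f"PSV at gene offset {self.gene_offset}: buildB registration must be "
                "the pseudogene major or the gene allele"
            )

    @property
    def discordant(self) -> bool:
        return self.buildB_registered != self.buildA_registered


@dataclass(frozen=True)
class PsvSpec:
    """Preset-level PSV description (offset within the core block)."""

    core_offset: int
    gene_allele: str
    pseudo_major_allele: str
    discordant: bool
    pop_minor_af: float = 0.0


@dataclass(frozen=True)
class LocusParams:
    """Geometry and site plan for a synthetic paralog pair."""

    gene_len: int = 7600
    core_start: int = 1000          # gene-local start of the perfect-identity block
    core_len: int = 1614
    separation_bp: int = 16000      # gap between gene end and pseudogene start
    flank: int = 1000
    divergence: float = 0.025       # substitution rate outside the core, inside the homologous span
    psvs: tuple[PsvSpec, ...] = ()
    # scenario geometry (gene-local unless noted)
    delins_interval: tuple[int, int] = (1480, 1500)
    delins_insert: str = "TG"
    conversion_start_pseudo: int = 600   # pseudo-local start of the case-4 conversion tract
    embedded_del_gene: tuple[int, int] = (3500, 3503)
    embedded_del_seq: str = "CAC"

    @property
    def pseudo_len(self) -> int:
        # the pseudogene mirrors the gene from the core start to the gene end
        return self.gene_len - self.core_start

    def validate(self) -> None:
        if not (0 <= self.core_start and self.core_start + self.core_len <= self.gene_len):
            raise LocusConfigError("core block does not fit inside the gene")
        seen: set[int] = set()
        for s in self.psvs:
            if not (0 <= s.core_offset < self.core_len):
                raise LocusConfigError(
                    f"PSV at core offset {s.core_offset} lies outside the core block "
                    f"[0, {self.core_len})"
                )
            if s.core_offset in seen:
                raise LocusConfigError(f"duplicate PSV at core offset {s.core_offset}")
            seen.add(s.core_offset)
        if not (0.0 <= self.divergence < 0.25):
            raise LocusConfigError("divergence must be in [0, 0.25)")


# Letters chosen so the diagnostic read triples are internally consistent:
# a variant-carrying gene read scores 0 against the buildB pseudogene copy,
# 1 against the gene copy and 2 against the buildA pseudogene copy across the
# three 3' sites; a pseudogene-derived read with a gene-like base at the
# concordant site scores 2/3/1 respectively.
GBA1_LIKE = LocusParams(
    psvs=(
        PsvSpec(266, "A", "G", True, 0.213),
        PsvSpec(276, "C", "T", True, 0.0108),
        PsvSpec(576, "C", "G", True, 0.0017),
        PsvSpec(590, "C", "G", True, 0.0107),
        PsvSpec(625, "A", "G", False, 0.0),
    ),
)

PRESETS: dict[str, LocusParams] = {"gba1_like": GBA1_LIKE}


@dataclass
class LocusModel:
    """A generated paralog pair on one synthetic contig (buildA truth state)."""

    gene_seq: str
    pseudo_seq: str
    gene_interval: tuple[int, int]
    pseudo_interval: tuple[int, int]
    core_block_len: int
    psv_sites: tuple[PsvSite, ...]
    separation_bp: int
    rng_seed: int
    params: LocusParams
    flank_left: str
    gap_seq: str
    flank_right: str
    contig_name: str = CONTIG_NAME

    @property
    def gene_start(self) -> int:
        return self.gene_interval[0]

    @property
    def pseudo_start(self) -> int:
        return self.pseudo_interval[0]

    @property
    def contig_len(self) -> int:
        return self.pseudo_interval[1] + len(self.flank_right)

    @property
    def displacement(self) -> int:
        """Contig-coordinate shift from a gene-homologous position to its
        pseudogene counterpart (constant: the homologous span has no indels)."""
        return self.pseudo_start - (self.gene_start + self.params.core_start)

    @property
    def concordant_sites(self) -> tuple[PsvSite, ...]:
        return tuple(s for s in self.psv_sites if not s.discordant)

    @property
    def discordant_sites(self) -> tuple[PsvSite, ...]:
        return tuple(s for s in self.psv_sites if s.discordant)

    def contig(self, pseudo_registration: dict[int, str] | None = None) -> str:
        """Assemble the full contig; ``pseudo_registration`` maps
        pseudo-local offsets to override bases in the pseudogene copy."""
        pseudo = self.pseudo_seq
        if pseudo_registration:
            arr = list(pseudo)
            for off, base in pseudo_registration.items():
                arr[off] = base
            pseudo = "".join(arr)
        return self.flank_left + self.gene_seq + self.gap_seq + pseudo + self.flank_right

    def gene_pos(self, gene_local: int) -> int:
        return self.gene_start + gene_local

    def pseudo_pos(self, pseudo_local: int) -> int:
        return self.pseudo_start + pseudo_local


@dataclass
class ReferenceBuild:
    """One rendering of the locus as a reference genome."""

    name: str
    contig_seq: str
    registration: dict[int, str]  # PSV gene_offset -> base registered at the pseudogene copy
    locus: LocusModel

    @property
    def contig_name(self) -> str:
        return self.locus.contig_name


@dataclass
class TruthRecord:
    """A ground-truth variant on a sample haplotype.

    Small-variant positions are 0-based on the carrying haplotype with the
    lift to buildA contig coordinates recorded in ``ref_pos``; ``ref``/``alt``
    are left-normalized against buildA.
    """

    kind: str                     # "snv" | "delins" | "sv_gene_conversion"
    locus_copy: str               # GENE | PSEUDO
    zygosity: str                 # "het" | "hom"
    hap_index: int
    hap_pos: int | None = None
    ref_pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    converted_interval: tuple[int, int] | None = None   # acceptor (pseudogene) interval, buildA coords
    donor_interval: tuple[int, int] | None = None       # gene-derived donor interval, buildA coords
    embedded_deletion: tuple[int, int] | None = None    # deletion inside the donor, buildA gene coords
    cn_gene: int | None = None
    cn_pseudo: int | None = None


@dataclass
class SampleGenome:
    """A diploid individual over the synthetic contig."""

    sample_id: str
    scenario: str
    haplotypes: tuple[str, str]
    truth: list[TruthRecord]
    locus: LocusModel

    def gene_truth(self) -> list[TruthRecord]:
        """Truth records on the functional gene copy — what a gene-targeted
        assay (or a gene-restricted call set) is expected to recover."""
        return [t for t in self.truth if t.locus_copy == GENE]


def build_locus(seed: int, preset: str | LocusParams = "gba1_like") -> LocusModel:
    """Generate the paralog pair deterministically from ``seed``.

    Background sequence is i.i.d. uniform ACGT; the pseudogene mirrors the
    gene from the core start to the gene end, base-for-base inside the core
    block except at PSVs, and with seeded random substitutions at
    ``params.divergence`` outside it.
    """
    params = PRESETS[preset] if isinstance(preset, str) else preset
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC10C]))

    gene = list(random_dna(rng, params.gene_len))
    # fix the embedded-deletion motif so case 4 deletes a literal CAC-like triplet
    ds, de = params.embedded_del_gene
    if de <= params.gene_len and de - ds == len(params.embedded_del_seq):
        gene[ds:de] = list(params.embedded_del_seq)
    # avoid a delins insert that is a prefix of the deleted run (keeps the
    # truth representation unambiguous)
    ins = params.delins_insert
    i0, i1 = params.delins_interval
    if ins and i1 <= params.gene_len and "".join(gene[i0:i0 + len(ins)]) == ins:
        gene[i0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[gene[i0]]

    sites = []
    for s in params.psvs:
        g_off = params.core_start + s.core_offset
        gene[g_off] = s.gene_allele
        sites.append(
            PsvSite(
                gene_offset=g_off,
                pseudo_offset=s.core_offset,
                gene_allele=s.gene_allele,
                pseudo_major_allele=s.pseudo_major_allele,
                buildA_registered=s.pseudo_major_allele,
                buildB_registered=s.gene_allele if s.discordant else s.pseudo_major_allele,
                pop_minor_af=s.pop_minor_af,
            )
        )
    gene = "".join(gene)

    pseudo = list(gene[params.core_start:])
    for s in params.psvs:
        pseudo[s.core_offset] = s.pseudo_major_allele
    # diverged homologous tail outside the core block
    tail_start = params.core_len
    for pos in range(tail_start, len(pseudo)):
        if rng.random() < params.divergence:
            base = pseudo[pos]
            pseudo[pos] = "ACGT"[(("ACGT".index(base)) + int(rng.integers(1, 4))) % 4]
    pseudo = "".join(pseudo)

    flank_left = random_dna(rng, params.flank)
    gap = random_dna(rng, params.separation_bp)
    flank_right = random_dna(rng, params.flank)

    gene_start = params.flank
    pseudo_start = gene_start + params.gene_len + params.separation_bp
    return LocusModel(
        gene_seq=gene,
        pseudo_seq=pseudo,
        gene_interval=(gene_start, gene_start + params.gene_len),
        pseudo_interval=(pseudo_start, pseudo_start + len(pseudo)),
        core_block_len=params.core_len,
        psv_sites=tuple(sorted(sites, key=lambda s: s.gene_offset)),
        separation_bp=params.separation_bp,
        rng_seed=int(seed),
        params=params,
        flank_left=flank_left,
        gap_seq=gap,
        flank_right=flank_right,
    )


def render_reference(
    locus: LocusModel,
    build: str,
    discordant_sites: tuple[PsvSite, ...] | None = None,
) -> ReferenceBuild:
    """Render the locus as a reference build.

    buildA registers the pseudogene major allele at every PSV; buildB
    registers the gene-like allele at each site in ``discordant_sites``
    (default: the preset's registration-discordant PSVs). The gene copy is
    identical across builds.
    """
    if build not in ("buildA", "buildB"):
        raise ValueError(f"unknown build {build!r}")
    if discordant_sites is None:
        discordant_sites = locus.discordant_sites if build == "buildB" else ()
    known = set(locus.psv_sites)
    for s in discordant_sites:
        if s not in known:
            raise ValueError(f"discordant site at gene offset {s.gene_offset} is not in the locus")
    registration = {s.gene_offset: s.pseudo_major_allele for s in locus.psv_sites}
    overrides: dict[int, str] = {}
    if build == "buildB":
        for s in discordant_sites:
            registration[s.gene_offset] = s.gene_allele
            overrides[s.pseudo_offset] = s.gene_allele
    return ReferenceBuild(
        name=build,
        contig_seq=locus.contig(overrides),
        registration=registration,
        locus=locus,
    )


def write_fasta(name: str, seq: str, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def reference_to_fasta(ref: ReferenceBuild, path: str) -> None:
    write_fasta(ref.contig_name, ref.contig_seq, path)


def _apply_snv(contig: str, pos: int, alt: str) -> str:
    return contig[:pos] + alt + contig[pos + 1:]


def make_sample(locus: LocusModel, scenario: str, seed: int) -> SampleGenome:
    """Build a diploid sample for one of the case archetypes.

    Haplotype 0 is always the buildA-like reference haplotype; scenario
    variants are placed heterozygously on haplotype 1. Truth records are
    re-derivable by diffing haplotype 1 against the buildA contig.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    params = locus.params
    ref_contig = locus.contig()
    hap0 = ref_contig
    truth: list[TruthRecord] = []
    psv_gene_positions = {locus.gene_pos(s.gene_offset) for s in locus.psv_sites}

    if scenario == "plain_control":
        hap1 = ref_contig

    elif scenario == "case1_pseudolike_het_snv":
        conc = locus.concordant_sites
        if not conc:
            raise ScenarioError("case1 requires a build-concordant PSV site")
        site = conc[0]
        pos = locus.gene_pos(site.gene_offset)
        alt = site.pseudo_major_allele
        hap1 = _apply_snv(ref_contig, pos, alt)
        truth.append(
            TruthRecord(
                kind="snv", locus_copy=GENE, zygosity="het", hap_index=1,
                hap_pos=pos, ref_pos=pos, ref=site.gene_allele, alt=alt,
            )
        )

    elif scenario == "case2_control":
        conc = locus.concordant_sites
        if not conc:
            raise ScenarioError("case2 requires a build-concordant PSV site")
        site = conc[0]
        pos = locus.pseudo_pos(site.pseudo_offset)
        alt = site.gene_allele  # gene-like minor allele on the pseudogene copy
        hap1 = _apply_snv(ref_contig, pos, alt)
        truth.append(
            TruthRecord(
                kind="snv", locus_copy=PSEUDO, zygosity="het", hap_index=1,
                hap_pos=pos, ref_pos=pos, ref=site.pseudo_major_allele, alt=alt,
            )
        )

    elif scenario == "case3_gene_delins":
        d0, d1 = params.delins_interval
        p0, p1 = locus.gene_pos(d0), locus.gene_pos(d1)
        if any(p0 <= p < p1 for p in psv_gene_positions):
            raise ScenarioError(
                "delins interval overlaps a PSV site; the gene/pseudogene mismatch "
                "arithmetic would be destroyed — move the interval"
            )
        ins = params.delins_insert
        hap1 = ref_contig[:p0] + ins + ref_contig[p1:]
        pos, ref, alt = trim_and_left_align(
            ref_contig, p0 - 1, ref_contig[p0 - 1:p1], ref_contig[p0 - 1] + ins
        )
        truth.append(
            TruthRecord(
                kind="delins", locus_copy=GENE, zygosity="het", hap_index=1,
                hap_pos=pos, ref_pos=pos, ref=ref, alt=alt,
            )
        )

    else:  # case4_gene_conversion_sv
        conv_p = params.conversion_start_pseudo
        acc0 = locus.pseudo_pos(conv_p)
        acc1 = locus.pseudo_interval[1]
        # donor: the gene-homologous interval for the whole converted tract
        don0 = locus.gene_pos(params.core_start + conv_p)
        don1 = locus.gene_interval[1]
        e0, e1 = (locus.gene_pos(p) for p in params.embedded_del_gene)
        if not (don0 <= e0 < e1 <= don1):
            raise ScenarioError("embedded deletion falls outside the conversion donor interval")
        frag_reach = 450  # one fragment length; see read_sim defaults
        if not any(acc0 - frag_reach <= locus.pseudo_pos(s.pseudo_offset) < acc0
                   for s in locus.psv_sites):
            raise ScenarioError(
                "no PSV within one fragment length upstream of the conversion start; "
                "the breakpoint miscalling mechanism needs one"
            )
        donor = ref_contig[don0:e0] + ref_contig[e1:don1]
        hap1 = ref_contig[:acc0] + donor + ref_contig[acc1:]
        truth.append(
            TruthRecord(
                kind="sv_gene_conversion", locus_copy=PSEUDO, zygosity="het", hap_index=1,
                converted_interval=(acc0, acc1),
                donor_interval=(don0, don1),
                embedded_deletion=(e0, e1),
                cn_gene=3, cn_pseudo=1,
            )
        )

    return SampleGenome(
        sample_id=f"{scenario}_s{seed}",
        scenario=scenario,
        haplotypes=(hap0, hap1),
        truth=truth,
        locus=locus,
    )


# ---------------------------------------------------------------------------
# truth serialization

def write_truth(sample: SampleGenome, out_dir: str) -> tuple[str, str]:
    """Emit truth as a small-variant VCF plus a BED of SV/copy-number truth.

    Returns the (vcf_path, bed_path) pair. Small variants are 1-based and
    left-normalized against the buildA contig; the BED carries the reciprocal
    gain/loss intervals with their truth copy numbers.
    """
    os.makedirs(out_dir, exist_ok=True)
    locus = sample.locus
    vcf_path = os.path.join(out_dir, f"{sample.sample_id}.truth.vcf")
    bed_path = os.path.join(out_dir, f"{sample.sample_id}.truth.bed")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={locus.contig_name},length={locus.contig_len}>\n")
        fh.write('##INFO=<ID=LOCUS_COPY,Number=1,Type=String,Description="gene or pseudogene copy">\n')
        fh.write('##INFO=<ID=KIND,Number=1,Type=String,Description="truth variant kind">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample.sample_id}\n")
        small = sorted(
            (t for t in sample.truth if t.kind in ("snv", "delins")),
            key=lambda t: t.ref_pos,
        )
        for t in small:
            gt = "0/1" if t.zygosity == "het" else "1/1"
            fh.write(
                f"{locus.contig_name}\t{t.ref_pos + 1}\t.\t{t.ref}\t{t.alt}\t.\tPASS\t"
                f"LOCUS_COPY={t.locus_copy};KIND={t.kind}\tGT\t{gt}\n"
            )
    with open(bed_path, "w") as fh:
        for t in sample.truth:
            if t.kind != "sv_gene_conversion":
                continue
            fh.write(
                f"{locus.contig_name}\t{t.donor_interval[0]}\t{t.donor_interval[1]}\t"
                f"gain_gene\t{t.cn_gene}\n"
            )
            fh.write(
                f"{locus.contig_name}\t{t.converted_interval[0]}\t{t.converted_interval[1]}\t"
                f"loss_pseudo\t{t.cn_pseudo}\n"
            )
            fh.write(
                f"{locus.contig_name}\t{t.embedded_deletion[0]}\t{t.embedded_deletion[1]}\t"
                f"embedded_deletion\t.\n"
            )
    return vcf_path, bed_path


def read_truth(vcf_path: str, bed_path: str) -> list[TruthRecord]:
    """Round-trip reader for :func:`write_truth` output."""
    records: list[TruthRecord] = []
    with open(vcf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info, _fmt, gt = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=") for kv in info.split(";"))
            records.append(
                TruthRecord(
                    kind=fields["KIND"], locus_copy=fields["LOCUS_COPY"],
                    zygosity="het" if gt == "0/1" else "hom", hap_index=1,
                    hap_pos=int(pos) - 1, ref_pos=int(pos) - 1, ref=ref, alt=alt,
                )
            )
    sv_parts: dict[str, tuple] = {}
    with open(bed_path) as fh:
        for line in fh:
            chrom, start, end, label, cn = line.split()
            sv_parts[label] = (int(start), int(end), cn)
    if sv_parts:
        records.append(
            TruthRecord(
                kind="sv_gene_conversion", locus_copy=PSEUDO, zygosity="het", hap_index=1,
                donor_interval=sv_parts["gain_gene"][:2],
                converted_interval=sv_parts["loss_pseudo"][:2],
                embedded_deletion=sv_parts["embedded_deletion"][:2],
                cn_gene=int(sv_parts["gain_gene"][2]),
                cn_pseudo=int(sv_parts["loss_pseudo"][2]),
            )
        )
    return records
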