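"""MAPQ-filtered pileup genotyping, depth tracks and copy-number ratio scan.

The caller is intentionally simple: reads passing the mapping-quality filter
are piled up CIGAR-aware; positions where an alternate allele reaches 20% of
the allele depth with at least ``min_depth`` passing reads are emitted, with
heterozygous calls flagged when the allele balance is markedly biased
(< 0.3). This is the minimal mechanism that reproduces the call/no-call
behaviour of a GATK-like pipeline at a paralog-confounded locus; no genotype
likelihoods are computed.

Indel events absorb immediately adjacent mismatching bases from the same
read into a single complex (delins) allele before normalization, the way
haplotype-based callers effectively represent them; isolated mismatches
remain SNV evidence.

The copy-number scan deliberately applies no MAPQ filter by default: reads
from gene-conversion products are exactly the ones whose placements are
ambiguous, and their depth is the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._seq import encode, revcomp
from ._variants import trim_and_left_align
from .locus_forge import ReferenceBuild
from .paralog_mapper import AlignmentRecord

_BASES = "ACGT"


class PileupError(ValueError):
    pass


@dataclass(frozen=True)
class CallerThresholds:
    min_depth: int = 8
    het_min_ab: float = 0.2    # alt fraction at/above which a variant is emitted
    hom_min_ab: float = 0.8    # alt fraction at/above which the genotype is hom
    biased_ab: float = 0.3     # het calls below this allele balance are flagged
    mapq_min: int = 20


@dataclass
class PileupColumn:
    ref_pos: int
    ref_base: str
    base_counts: dict[str, int]
    indel_events: dict[tuple[int, str, str], int]
    filtered_depth: int


class PileupColumns:
    """Dense per-position pileup over the whole contig (MAPQ-passing reads)."""

    def __init__(self, refseq: str, mapq_min: int):
        self.refseq = refseq
        self.mapq_min = mapq_min
        n = len(refseq)
        self.base_counts = np.zeros((4, n), dtype=np.int32)
        self.del_span = np.zeros(n, dtype=np.int32)
        self.indel_events: dict[tuple[int, str, str], int] = {}
        self._ref_codes = encode(refseq)

    @property
    def filtered_depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=0) + self.del_span

    def column(self, pos: int) -> PileupColumn:
        counts = {b: int(self.base_counts[i, pos]) for i, b in enumerate(_BASES)}
        events = {k: v for k, v in self.indel_events.items() if k[0] == pos}
        return PileupColumn(
            ref_pos=pos,
            ref_base=self.refseq[pos],
            base_counts=counts,
            indel_events=events,
            filtered_depth=int(self.filtered_depth[pos]),
        )

    def add_read(self, seq: str, ref_start: int, cigar: list[tuple[str, int]]) -> None:
        """Pile one aligned read; ``seq`` is the aligned-orientation sequence."""
        qlen = sum(n for op, n in cigar if op in "MIS")
        if qlen != len(seq):
            raise PileupError(
                f"CIGAR consumes {qlen} query bases but sequence has {len(seq)}"
            )
        codes = encode(seq)
        rpos, qpos = ref_start, 0
        # diffs: (kind, ref_pos, ref_len, query_pos, query_len)
        diffs: list[tuple[str, int, int, int, int]] = []
        for op, n in cigar:
            if op == "M":
                seg_r = self._ref_codes[rpos:rpos + n]
                seg_q = codes[qpos:qpos + n]
                known = np.flatnonzero(seg_q < 4)
                np.add.at(self.base_counts, (seg_q[known], known + rpos), 1)
                for off in np.flatnonzero(seg_r != seg_q):
                    diffs.append(("X", rpos + int(off), 1, qpos + int(off), 1))
                rpos += n
                qpos += n
            elif op == "D":
                self.del_span[rpos:rpos + n] += 1
                diffs.append(("D", rpos, n, qpos, 0))
                rpos += n
            elif op == "I":
                diffs.append(("I", rpos, 0, qpos, n))
                qpos += n
            elif op == "S":
                qpos += n
            else:
                raise PileupError(f"unsupported CIGAR op {op!r}")
        if any(d[0] in "DI" for d in diffs):
            self._register_indel_blocks(diffs, seq, codes)

    def _register_indel_blocks(self, diffs, seq: str, codes: np.ndarray) -> None:
        """Merge runs of reference-adjacent differences containing an indel
        into one complex (delins) event, recorded normalized. Mismatching
        bases absorbed into a complex allele are moved out of the SNV counts
        (they are part of the indel allele, not independent substitutions);
        their depth contribution is kept via the deletion-span track."""
        blocks: list[list[tuple]] = []
        prev_end = None
        bridge = 2  # matched bases allowed inside one complex allele
        for d in diffs:
            r0, r1 = d[1], d[1] + d[2]
            if prev_end is not None and r0 <= prev_end + bridge:
                blocks[-1].append(d)
            else:
                blocks.append([d])
            prev_end = max(prev_end, r1) if prev_end is not None else r1
        for block in blocks:
            if not any(d[0] in "DI" for d in block):
                continue
            r0 = block[0][1]
            r1 = max(d[1] + d[2] for d in block)
            q0 = block[0][3]
            q1 = max(d[3] + d[4] for d in block)
            ref_allele = self.refseq[r0:r1]
            alt_allele = seq[q0:q1]
            if ref_allele == alt_allele:
                continue
            for d in block:
                if d[0] == "X" and codes[d[3]] < 4:
                    self.base_counts[codes[d[3]], d[1]] -= 1
                    self.del_span[d[1]] += 1
            pos, ref, alt = trim_and_left_align(self.refseq, r0, ref_allele, alt_allele)
            key = (pos, ref, alt)
            self.indel_events[key] = self.indel_events.get(key, 0) + 1


def _cigar_tuples(cig: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def build_pileup(
    sam, reference: ReferenceBuild, mapq_min: int = 20
) -> PileupColumns:
    """Pile MAPQ-passing primary alignments from a SAM path or a list of
    in-memory :class:`AlignmentRecord`."""
    cols = PileupColumns(reference.contig_seq, mapq_min)
    for seq, start, cig, mapq in _iter_alignments(sam):
        if mapq < mapq_min:
            continue
        cols.add_read(seq, start, cig)
    return cols


def _iter_alignments(sam):
    if isinstance(sam, str):
        with pysam.AlignmentFile(sam, "r") as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                cig = [(op, n) for n, op in
                       ((n, "MIDNSHP=X"[o]) for o, n in rec.cigartuples)]
                yield rec.query_sequence, rec.reference_start, cig, rec.mapping_quality
    else:
        for rec in sam:
            if rec.unmapped:
                continue
            seq = rec.seq if rec.strand == "+" else revcomp(rec.seq)
            yield seq, rec.ref_start, _cigar_tuples(rec.cigar), rec.mapq


@dataclass
class VariantCall:
    pos: int                   # 0-based internally; +1 on VCF output
    ref: str
    alt: str
    genotype: str              # "het" | "hom"
    ad_ref: int
    ad_alt: int
    filter_flags: frozenset[str] = frozenset()

    @property
    def allele_balance(self) -> float:
        return self.ad_alt / (self.ad_ref + self.ad_alt)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def call_small_variants(
    columns: PileupColumns, thresholds: CallerThresholds | None = None
) -> list[VariantCall]:
    """Genotype SNVs and (complex) indels from the pileup."""
    th = thresholds or CallerThresholds()
    calls: list[VariantCall] = []
    depth = columns.filtered_depth
    refc = columns._ref_codes
    counts = columns.base_counts
    total = counts.sum(axis=0)
    # SNVs: any non-reference base at >= het_min_ab of the allele depth
    nonref = counts.copy()
    idx = np.arange(len(refc))
    valid = refc < 4
    nonref[refc[valid], idx[valid]] = 0
    cand_pos = np.flatnonzero((nonref.max(axis=0) > 0) & (depth > 0))
    for pos in cand_pos:
        ad_ref = int(counts[refc[pos], pos]) if refc[pos] < 4 else 0
        for b in range(4):
            if b == refc[pos]:
                continue
            ad_alt = int(counts[b, pos])
            if ad_alt == 0:
                continue
            ab = ad_alt / (ad_ref + ad_alt)
            if ab < th.het_min_ab or depth[pos] < th.min_depth:
                continue
            calls.append(_make_call(int(pos), columns.refseq[pos], _BASES[b],
                                    ad_ref, ad_alt, int(depth[pos]), th))
    for (pos, ref, alt), n in columns.indel_events.items():
        d = int(depth[pos])
        ad_alt = int(n)
        ad_ref = max(d - ad_alt, 0)
        if d == 0:
            continue
        ab = ad_alt / (ad_ref + ad_alt)
        if ab < th.het_min_ab or d < th.min_depth:
            continue
        calls.append(_make_call(pos, ref, alt, ad_ref, ad_alt, d, th))
    calls.sort(key=lambda c: c.key)
    return calls


def _make_call(pos, ref, alt, ad_ref, ad_alt, depth, th: CallerThresholds) -> VariantCall:
    ab = ad_alt / (ad_ref + ad_alt)
    gt = "hom" if ab >= th.hom_min_ab else "het"
    flags = set()
    if gt == "het" and ab < th.biased_ab:
        flags.add("biased_ab")
    if depth < 8:
        flags.add("low_depth")
    return VariantCall(pos, ref, alt, gt, ad_ref, ad_alt, frozenset(flags))


def write_vcf(calls: list[VariantCall], reference: ReferenceBuild, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.contig_name},length={len(reference.contig_seq)}>\n")
        fh.write('##FILTER=<ID=biased_ab,Description="Het call with allele balance below 0.3">\n')
        fh.write('##FILTER=<ID=low_depth,Description="Filtered depth below 8">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in sorted(calls, key=lambda c: c.key):
            filt = ";".join(sorted(c.filter_flags)) or "PASS"
            gt = "0/1" if c.genotype == "het" else "1/1"
            fh.write(
                f"{reference.contig_name}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\t{filt}\t.\t"
                f"GT:AD\t{gt}:{c.ad_ref},{c.ad_alt}\n"
            )


def read_vcf_calls(path: str) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, filt, _info, _fmt, sample = line.split("\t")
            gt, ad = sample.strip().split(":")
            ad_ref, ad_alt = (int(x) for x in ad.split(","))
            flags = frozenset() if filt == "PASS" else frozenset(filt.split(";"))
            calls.append(VariantCall(int(pos) - 1, ref, alt,
                                     "het" if gt == "0/1" else "hom",
                                     ad_ref, ad_alt, flags))
    return calls


# ---------------------------------------------------------------------------
# depth tracks and copy-number ratio scan

@dataclass
class DepthTrack:
    window_size: int
    means: np.ndarray            # per-window mean depth (or ratio)
    is_ratio: bool = False

    def window_interval(self, i: int) -> tuple[int, int]:
        return (i * self.window_size, (i + 1) * self.window_size)


@dataclass
class CnSegment:
    start: int                   # contig coords, half-open
    end: int
    mean_ratio: float
    cn: int
    kind: str                    # "gain" | "loss"


def depth_track(sam, reference: ReferenceBuild, window_size: int = 100,
                mapq_min: int = 0) -> DepthTrack:
    """Per-window mean depth from primary alignments (MAPQ filter off by
    default — see module docstring)."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = len(reference.contig_seq)
    cov = np.zeros(n + 1, dtype=np.int64)
    for seq, start, cig, mapq in _iter_alignments(sam):
        if mapq < mapq_min:
            continue
        span = sum(ln for op, ln in cig if op in "MD")
        cov[start] += 1
        cov[min(start + span, n)] -= 1
    cov = np.cumsum(cov[:-1])
    n_win = (n + window_size - 1) // window_size
    means = np.array([
        cov[i * window_size:(i + 1) * window_size].mean() for i in range(n_win)
    ])
    return DepthTrack(window_size=window_size, means=means)


def depth_ratio(sample_track: DepthTrack, control_tracks: list[DepthTrack]) -> DepthTrack:
    """Per-window ratio of sample depth to the mean of the control depths.

    Windows where the control mean is zero are undefined (NaN) and skipped
    downstream, with a warning.
    """
    if not control_tracks:
        raise ValueError("at least one control track is required")
    ctrl = np.vstack([t.means for t in control_tracks]).mean(axis=0)
    ratio = np.full_like(sample_track.means, np.nan, dtype=float)
    ok = ctrl > 0
    ratio[ok] = sample_track.means[ok] / ctrl[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} windows with zero control depth skipped",
            stacklevel=2,
        )
    return DepthTrack(window_size=sample_track.window_size, means=ratio, is_ratio=True)


def call_cn_segments(
    ratio_track: DepthTrack,
    gain: float = 1.25,
    loss: float = 0.75,
    min_windows: int = 3,
) -> list[CnSegment]:
    """Maximal runs of consecutive defined windows beyond a threshold.

    Undefined (NaN) windows carry no evidence either way: they do not break a
    run. The copy number of a segment is ``round(2 * mean ratio)`` on a
    diploid baseline.
    """
    means = ratio_track.means
    w = ratio_track.window_size
    segments: list[CnSegment] = []
    state = None   # ("gain"|"loss", [window indices])
    for i, v in enumerate(means):
        if np.isnan(v):
            continue
        label = "gain" if v >= gain else ("loss" if v <= loss else None)
        if state is not None and label == state[0]:
            state[1].append(i)
        else:
            if state is not None:
                segments.append(state)
            state = (label, [i]) if label else None
    if state is not None:
        segments.append(state)
    out = []
    for kind, idxs in segments:
        if len(idxs) < min_windows:
            continue
        vals = means[idxs]
        mean_ratio = float(vals.mean())
        out.append(CnSegment(
            start=idxs[0] * w, end=(idxs[-1] + 1) * w,
            mean_ratio=mean_ratio, cn=int(round(2 * mean_ratio)), kind=kind,
        ))
    return out
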