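"""Read placement against a reference build with paralog-aware MAPQ.

A deliberately small re-implementation of the parts of a short-read aligner
that matter for gene/pseudogene confusion: candidate locations come from
exact k-mer seeds on either strand, the homologous window at the other
paralog is always scored even without a seed hit, candidates are scored by
edit cost (mismatch 1, gap open 2, gap extend 1), and mapping quality is the
phred-scaled posterior that the best placement is wrong, with exact score
ties mapped to MAPQ 0. Reads whose best score exceeds 30% of the read length
are reported unmapped.

Because the simulator introduces substitution errors only, any read carries
at most one indel junction (a sample indel or an SV breakpoint); candidate
scoring therefore uses an exact single-gap search within the band, which for
such reads is equivalent to a full banded alignment under the same costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from ._seq import encode, revcomp
from .locus_forge import ReferenceBuild
from .read_sim import ReadPair


class MapperError(ValueError):
    pass


@dataclass(frozen=True)
class MapperConfig:
    k: int = 21
    eps_map: float = 0.005       # per-base error probability in the MAPQ posterior
    mapq_cap: int = 60
    gap_open: int = 2
    gap_extend: int = 1
    band: int = 32
    unmapped_frac: float = 0.3   # best score above ceil(frac * read_len) -> unmapped
    frag_mean: float = 450.0     # used only for pair concordance tie-breaking
    frag_sd: float = 60.0

    def validate(self) -> None:
        if not (0.0 < self.eps_map < 0.5):
            raise MapperError("eps_map must lie in (0, 0.5)")


@dataclass
class Placement:
    """One candidate gapped alignment of a read."""

    ref_start: int
    cigar: tuple[tuple[str, int], ...]   # ops over {"M","I","D"}; consumes read_len query bases
    n_mismatch: int
    n_gap_open: int
    n_gap_extend: int
    strand: str                          # "+" or "-"

    @property
    def score(self) -> int:
        return self.n_mismatch + 2 * self.n_gap_open + self.n_gap_extend

    @property
    def n_edits(self) -> tuple[int, int, int]:
        return (self.n_mismatch, self.n_gap_open, self.n_gap_extend)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


@dataclass
class AlignmentRecord:
    """A primary alignment (or unmapped record) for one mate."""

    read_id: str
    mate: int                    # 1 or 2
    seq: str
    ref_start: int | None
    cigar: str | None
    mapq: int
    n_edits: int
    strand: str | None
    properly_paired: bool = False
    unmapped: bool = False
    mate_ref_start: int | None = None
    mate_strand: str | None = None
    tlen: int = 0


class ReferenceIndex:
    """Exact k-mer index over the forward reference contig, plus the paralog
    displacement needed to force-score the homologous window."""

    def __init__(self, reference: ReferenceBuild, config: MapperConfig | None = None):
        self.config = config or MapperConfig()
        self.config.validate()
        self.reference = reference
        self.seq = reference.contig_seq
        self.codes = encode(self.seq)
        locus = reference.locus
        g0 = locus.gene_start + locus.params.core_start
        g1 = locus.gene_interval[1]
        p0, p1 = locus.pseudo_interval
        self._gene_span = (g0, g1)
        self._pseudo_span = (p0, p1)
        self._disp = locus.displacement
        k = self.config.k
        index: dict[str, list[int]] = {}
        for i in range(len(self.seq) - k + 1):
            index.setdefault(self.seq[i:i + k], []).append(i)
        self._index = index

    def seed_diagonals(self, read: str) -> set[int]:
        """Distinct candidate start diagonals from every exact k-mer of the read."""
        k = self.config.k
        if len(read) < k:
            raise MapperError(f"read shorter than seed length k={k}")
        diags: set[int] = set()
        for off in range(0, len(read) - k + 1):
            hits = self._index.get(read[off:off + k])
            if hits:
                for pos in hits:
                    diags.add(pos - off)
        return diags

    def paralog_shift(self, start: int, read_len: int) -> int | None:
        mid = start + read_len // 2
        if self._gene_span[0] <= mid < self._gene_span[1]:
            return start + self._disp
        if self._pseudo_span[0] <= mid < self._pseudo_span[1]:
            return start - self._disp
        return None


def _score_diagonal(
    idx: ReferenceIndex, rcodes: np.ndarray, start: int, strand: str
) -> list[Placement]:
    """Score a read against the reference around one start diagonal: the
    ungapped alignment plus the best alignment containing a single gap of
    each size up to the band width."""
    cfg = idx.config
    L = len(rcodes)
    n = len(idx.codes)

    def window(s: int) -> np.ndarray:
        if s >= 0 and s + L <= n:
            return idx.codes[s:s + L]
        w = np.full(L, 4, dtype=np.uint8)  # N pads mismatch everything
        lo, hi = max(s, 0), min(s + L, n)
        if lo < hi:
            w[lo - s:hi - s] = idx.codes[lo:hi]
        return w

    out: list[Placement] = []

    def prefix_mm(shift: int) -> np.ndarray:
        # prefix_mm(s)[i] = mismatches of read[:i] aligned on diagonal start+s
        mm = rcodes != window(start + shift)
        return np.concatenate(([0], np.cumsum(mm)))

    pre0 = prefix_mm(0)
    h0 = int(pre0[-1])
    out.append(Placement(start, (("M", L),), h0, 0, 0, strand))
    if h0 <= cfg.gap_open + cfg.gap_extend:
        return out  # no gapped alignment can do better

    tot0 = pre0[L]
    # best single-gap alignment; each gap is searched with the prefix anchored
    # on this diagonal and, symmetrically, with the suffix anchored on it, so
    # junctions near either read end are found from a single seeded diagonal.
    best = None  # (cost, g, kind_rank, ref_start, split, kind)
    for g in range(1, cfg.band + 1):
        pre_p = prefix_mm(g)
        pre_n = prefix_mm(-g)
        gap_cost = cfg.gap_open + g * cfg.gap_extend
        searches = [
            # deletion: read[:i] then skip g ref bases, suffix shifted right
            ("D", start, pre0[1:L] + (pre_p[L] - pre_p[1:L]), 1),
            ("D", start - g, pre_n[1:L] + (tot0 - pre0[1:L]), 1),
        ]
        if g <= L - 2:
            searches += [
                # insertion: read[i:i+g] unaligned, suffix shifted left
                ("I", start, pre0[1:L - g] + (pre_n[L] - pre_n[1 + g:L]), 1),
                ("I", start + g, pre_p[1:L - g] + (tot0 - pre0[1 + g:L]), 1),
            ]
        for kind, rstart, costs, i0 in searches:
            if len(costs) == 0:
                continue
            i = int(np.argmin(costs))
            cost = int(costs[i]) + gap_cost
            key = (cost, g, 0 if kind == "D" else 1, rstart, i + i0)
            if best is None or key < best[:5]:
                best = (cost, g, 0 if kind == "D" else 1, rstart, i + i0, kind)
    if best is not None and best[0] < h0:
        cost, g, _rank, rstart, i, kind = best
        nm = cost - cfg.gap_open - g * cfg.gap_extend
        if kind == "D":
            cigar = tuple(x for x in (("M", i), ("D", g), ("M", L - i)) if x[1] > 0)
        else:
            cigar = tuple(x for x in (("M", i), ("I", g), ("M", L - i - g)) if x[1] > 0)
        out.append(Placement(rstart, cigar, nm, 1, g, strand))
    return out


def enumerate_placements(
    read_seq: str, reference: ReferenceBuild | ReferenceIndex, config: MapperConfig | None = None
) -> list[Placement]:
    """All scored candidate placements of a read, both strands, with the
    homologous paralog window always included; deduplicated so that at most
    one placement survives within each band-radius neighbourhood."""
    idx = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, config)
    cfg = idx.config
    L = len(read_seq)
    placements: list[Placement] = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        rcodes = encode(seq)
        diags = idx.seed_diagonals(seq)
        for d in list(diags):
            shifted = idx.paralog_shift(d, L)
            if shifted is not None:
                diags.add(shifted)
        for d in sorted(diags):
            placements.extend(_score_diagonal(idx, rcodes, d, strand))
    # keep the best placement within each band-radius cluster of starts
    placements.sort(key=lambda p: (p.ref_start, p.score))
    deduped: list[Placement] = []
    for p in placements:
        if deduped and abs(p.ref_start - deduped[-1].ref_start) <= cfg.band:
            if p.score < deduped[-1].score:
                deduped[-1] = p
        else:
            deduped.append(p)
    threshold = math.ceil(cfg.unmapped_frac * L)
    return [p for p in deduped if p.score <= threshold]


def compute_mapq(placements: list[Placement], config: MapperConfig, read_len: int) -> int:
    """Phred-scaled posterior MAPQ with exact ties mapped to 0.

    With ``eps = eps_map``, placement i has posterior weight
    ``eps**score_i * (1-eps)**(read_len-score_i)``; MAPQ is
    ``round(-10*log10(1 - p_best/sum))`` capped at ``mapq_cap``.
    """
    if not placements:
        raise MapperError("empty placement list")
    scores = sorted(p.score for p in placements)
    if len(scores) >= 2 and scores[0] == scores[1]:
        return 0
    lr = math.log(config.eps_map / (1.0 - config.eps_map))
    weights = [math.exp((s - scores[0]) * lr) for s in scores]
    p_err = sum(weights[1:]) / sum(weights)
    if p_err <= 0.0:
        return config.mapq_cap
    return min(config.mapq_cap, int(round(-10.0 * math.log10(p_err))))


def _choose_primary(
    placements: list[Placement],
    mate_best: list[Placement],
    cfg: MapperConfig,
) -> Placement:
    """Pick the reported placement: best score; ties broken by mate
    concordance (FR orientation, insert within mean +/- 4 sd), then by the
    lowest reference coordinate."""
    best_score = min(p.score for p in placements)
    tied = [p for p in placements if p.score == best_score]
    if len(tied) == 1:
        return tied[0]
    lo = cfg.frag_mean - 4 * cfg.frag_sd
    hi = cfg.frag_mean + 4 * cfg.frag_sd

    def concordant(p: Placement) -> bool:
        for q in mate_best:
            if q.strand == p.strand:
                continue
            if p.strand == "+":
                ins = (q.ref_start + q.ref_span) - p.ref_start
            else:
                ins = (p.ref_start + p.ref_span) - q.ref_start
            if lo <= ins <= hi:
                return True
        return False

    conc = [p for p in tied if concordant(p)]
    pool = conc if conc else tied
    return min(pool, key=lambda p: p.ref_start)


def _soft_clip(
    primary: Placement, oriented_codes: np.ndarray, idx: ReferenceIndex
) -> tuple[int, str, int]:
    """Soft-clip mismatch-dense alignment ends (a read ending inside an
    unmodelled junction otherwise sprays mismatches into the pileup, as a
    local aligner's clipping avoids). Each terminal M run is trimmed at the
    cut maximizing (3*mismatches - matches) over the clipped part, clipping
    only when that score is positive. Returns (ref_start, cigar, n_clipped_mm).
    """
    ops = list(primary.cigar)
    ref_start = primary.ref_start
    clipped_mm = 0

    def end_mm(op_len: int, rpos: int, qpos: int) -> np.ndarray:
        seg_r = idx.codes[max(rpos, 0):rpos + op_len]
        if len(seg_r) < op_len:  # window partially off-contig
            pad = np.full(op_len, 4, dtype=np.uint8)
            if rpos >= 0:
                pad[:len(seg_r)] = seg_r
            seg_r = pad
        return oriented_codes[qpos:qpos + op_len] != seg_r

    def best_cut(mm: np.ndarray) -> tuple[int, int]:
        # mm ordered from the read end inward; returns (cut_len, mm_removed)
        score, best, cut, nmm, bn = 0, 0, 0, 0, 0
        for t, bad in enumerate(mm, 1):
            score += 3 if bad else -1
            nmm += int(bad)
            if score > best:
                best, cut, bn = score, t, nmm
        return (cut, bn) if best > 0 else (0, 0)

    L = int(sum(n for op, n in ops if op in "MI"))
    # leading end
    if ops and ops[0][0] == "M":
        n = ops[0][1]
        mm = end_mm(n, ref_start, 0)
        cut, bn = best_cut(mm)
        cut = min(cut, n - 1)
        if cut > 0:
            ops[0] = ("M", n - cut)
            ops.insert(0, ("S", cut))
            ref_start += cut
            clipped_mm += int(mm[:cut].sum())
    # trailing end
    if ops and ops[-1][0] == "M":
        n = ops[-1][1]
        q_end = L
        r_end = primary.ref_start + primary.ref_span
        mm = end_mm(n, r_end - n, q_end - n)[::-1]
        cut, bn = best_cut(mm)
        cut = min(cut, n - 1)
        if cut > 0:
            ops[-1] = ("M", ops[-1][1] - cut)
            ops.append(("S", cut))
            clipped_mm += int(mm[:cut].sum())
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return ref_start, cigar, clipped_mm


def map_pair(
    pair: ReadPair, idx: ReferenceIndex
) -> tuple[AlignmentRecord, AlignmentRecord]:
    cfg = idx.config
    recs = []
    placement_sets = []
    for mate, seq in ((1, pair.mate1_seq), (2, pair.mate2_seq)):
        placement_sets.append(enumerate_placements(seq, idx))
    for mate, seq, own, other in (
        (1, pair.mate1_seq, placement_sets[0], placement_sets[1]),
        (2, pair.mate2_seq, placement_sets[1], placement_sets[0]),
    ):
        if not own:
            recs.append(AlignmentRecord(
                read_id=pair.name, mate=mate, seq=seq, ref_start=None, cigar=None,
                mapq=0, n_edits=0, strand=None, unmapped=True,
            ))
            continue
        other_best = (
            [p for p in other if p.score == min(q.score for q in other)] if other else []
        )
        primary = _choose_primary(own, other_best, cfg)
        mapq = compute_mapq(own, cfg, len(seq))
        oriented = encode(seq if primary.strand == "+" else revcomp(seq))
        ref_start, cigar, clipped_mm = _soft_clip(primary, oriented, idx)
        recs.append(AlignmentRecord(
            read_id=pair.name, mate=mate, seq=seq, ref_start=ref_start,
            cigar=cigar, mapq=mapq, n_edits=primary.score - clipped_mm,
            strand=primary.strand,
        ))
        recs[-1]._primary = primary  # kept for pairing bookkeeping below
    r1, r2 = recs
    if not (r1.unmapped or r2.unmapped):
        p1, p2 = r1._primary, r2._primary
        r1.mate_ref_start, r1.mate_strand = p2.ref_start, p2.strand
        r2.mate_ref_start, r2.mate_strand = p1.ref_start, p1.strand
        left, right = (p1, p2) if p1.ref_start <= p2.ref_start else (p2, p1)
        ins = right.ref_start + right.ref_span - left.ref_start
        proper = (
            p1.strand != p2.strand
            and left.strand == "+"
            and cfg.frag_mean - 4 * cfg.frag_sd <= ins <= cfg.frag_mean + 4 * cfg.frag_sd
        )
        r1.properly_paired = r2.properly_paired = proper
        sign = 1 if p1.ref_start <= p2.ref_start else -1
        r1.tlen, r2.tlen = sign * ins, -sign * ins
    return r1, r2


def map_reads(
    pairs, reference: ReferenceBuild, config: MapperConfig | None = None
) -> list[AlignmentRecord]:
    """Map a stream of read pairs; returns primary records sorted by position.

    Every mate yields exactly one record (aligned or unmapped).
    """
    idx = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, config)
    records: list[AlignmentRecord] = []
    for pair in pairs:
        records.extend(map_pair(pair, idx))
    records.sort(key=lambda r: (r.unmapped, r.ref_start if r.ref_start is not None else 0))
    return records


def write_sam(records: list[AlignmentRecord], reference: ReferenceBuild, path: str) -> None:
    """Emit plain-text SAM (FLAG, 1-based POS, MAPQ, CIGAR, NM tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference.contig_name, "LN": len(reference.contig_seq)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            flag = 0x1 | (0x40 if r.mate == 1 else 0x80)
            if r.unmapped:
                a.flag = flag | 0x4
                a.query_sequence = r.seq
                out.write(a)
                continue
            if r.strand == "-":
                flag |= 0x10
                a.query_sequence = revcomp(r.seq)
            else:
                a.query_sequence = r.seq
            if r.mate_strand == "-":
                flag |= 0x20
            if r.properly_paired:
                flag |= 0x2
            a.flag = flag
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar
            if r.mate_ref_start is not None:
                a.next_reference_id = 0
                a.next_reference_start = r.mate_ref_start
                a.template_length = r.tlen
            a.set_tag("NM", r.n_edits)
            out.write(a)
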