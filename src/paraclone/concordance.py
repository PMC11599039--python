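"""Cross-pipeline call-set comparison and inconsistency classification.

Mirrors the adjudication table of a gene/pseudogene miscalling study: each
variant seen in truth or in any arm (Sanger, short-read against buildA,
short-read against buildB) gets one record, and every non-concordant record
is assigned the mechanism that explains it — reference-registration
misalignment (missed or spurious), MAPQ dropout, or a structural-variant
artifact. Structural evidence takes precedence: a gene conversion generates
registration-like artifacts that would otherwise be mislabelled, so
reciprocal copy-number segments are checked first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._variants import is_normalized
from .insilico_sanger import SangerCall
from .locus_forge import GENE, LocusModel, TruthRecord
from .pileup_caller import CnSegment, VariantCall

CONCORDANT = "concordant"
REGISTRATION_MISSED = "registration_missed"
REGISTRATION_SPURIOUS = "registration_spurious"
LOW_MAPQ_DROPOUT = "low_mapq_dropout"
SV_ARTIFACT = "structural_variant_artifact"
UNCLASSIFIED = "unclassified"

ARMS = ("sanger", "sr_buildA", "sr_buildB")


@dataclass
class InconsistencyRecord:
    variant_key: tuple[int, str, str]
    called_in: dict[str, bool]
    truth: bool
    category: str | None = None

    @property
    def concordant(self) -> bool:
        return all(self.called_in[a] == self.truth for a in ARMS)


def _keys(calls: Sequence, locus: LocusModel) -> set[tuple[int, str, str]]:
    out = set()
    refseq = locus.contig()
    for c in calls:
        key = c.key if hasattr(c, "key") else (c.ref_pos, c.ref, c.alt)
        if len(key[1]) != len(key[2]) and not is_normalized(refseq, *key):
            raise ValueError(f"unnormalized indel {key}")
        out.add(key)
    return out


def compare_callsets(
    truth: Sequence[TruthRecord],
    sanger_calls: Sequence[SangerCall],
    srA_calls: Sequence[VariantCall],
    srB_calls: Sequence[VariantCall],
    locus: LocusModel,
) -> list[InconsistencyRecord]:
    """One record per variant present in truth or any arm (gene-copy
    coordinates, normalized)."""
    truth_small = [t for t in truth if t.kind in ("snv", "delins") and t.locus_copy == GENE]
    tkeys = _keys(truth_small, locus)
    arm_keys = {
        "sanger": _keys(sanger_calls, locus),
        "sr_buildA": _keys(srA_calls, locus),
        "sr_buildB": _keys(srB_calls, locus),
    }
    all_keys = tkeys | set().union(*arm_keys.values())
    records = []
    for key in sorted(all_keys):
        records.append(InconsistencyRecord(
            variant_key=key,
            called_in={arm: key in arm_keys[arm] for arm in ARMS},
            truth=key in tkeys,
        ))
    return records


def _pseudo_base_at(locus: LocusModel, gene_contig_pos: int) -> str | None:
    """The true pseudogene base homologous to a gene-copy contig position,
    or None outside the homologous span."""
    hom = gene_contig_pos + locus.displacement
    p0, p1 = locus.pseudo_interval
    if p0 <= hom < p1:
        return locus.pseudo_seq[hom - p0]
    return None


def classify_inconsistency(
    record: InconsistencyRecord,
    locus: LocusModel,
    cn_segments: Sequence[CnSegment] = (),
    mapq_stats: Mapping[str, np.ndarray] | None = None,
    min_depth: int = 8,
) -> str:
    """Assign the mechanism category for one record (pure function).

    Rule order: structural-variant evidence first (reciprocal gain/loss
    copy-number segments over the paralogs), then registration-missed, then
    registration-spurious, then MAPQ dropout.
    """
    if record.concordant:
        return CONCORDANT
    pos, ref, alt = record.variant_key
    g0, g1 = locus.gene_interval
    p0, p1 = locus.pseudo_interval

    def overlaps(seg: CnSegment, iv: tuple[int, int]) -> bool:
        return seg.start < iv[1] and iv[0] < seg.end

    has_gain = any(s.kind == "gain" and overlaps(s, (g0, g1)) for s in cn_segments)
    has_loss = any(s.kind == "loss" and overlaps(s, (p0, p1)) for s in cn_segments)
    if has_gain and has_loss:
        return SV_ARTIFACT

    # registration_missed: a real gene variant whose alt is the pseudogene
    # allele at the homologous offset, recovered under buildA but not buildB
    if record.truth and record.called_in["sr_buildA"] and not record.called_in["sr_buildB"]:
        if len(ref) == 1 and len(alt) == 1 and _pseudo_base_at(locus, pos) == alt:
            return REGISTRATION_MISSED

    # registration_spurious: a call with no truth whose alt is a pseudogene
    # major allele at the gene homolog of a registration-discordant PSV
    if not record.truth and record.called_in["sr_buildB"]:
        for site in locus.discordant_sites:
            if pos == locus.gene_pos(site.gene_offset) and alt == site.pseudo_major_allele:
                return REGISTRATION_SPURIOUS

    # low_mapq_dropout: a real variant missed where too few MAPQ-passing
    # reads remained over the site
    if record.truth and mapq_stats is not None:
        for arm in ("sr_buildB", "sr_buildA"):
            if not record.called_in[arm] and arm in mapq_stats:
                span = slice(pos, pos + max(len(ref), 1))
                if float(np.asarray(mapq_stats[arm])[span].mean()) < min_depth:
                    return LOW_MAPQ_DROPOUT
    return UNCLASSIFIED


def classify_all(
    records: Sequence[InconsistencyRecord],
    locus: LocusModel,
    cn_segments: Sequence[CnSegment] = (),
    mapq_stats: Mapping[str, np.ndarray] | None = None,
) -> list[InconsistencyRecord]:
    for r in records:
        r.category = classify_inconsistency(r, locus, cn_segments, mapq_stats)
    return list(records)


def report(records: Sequence[InconsistencyRecord], path: str) -> int:
    """Write the adjudication table as TSV plus a plain-text summary block;
    returns the number of unclassified inconsistencies."""
    rows = []
    for r in sorted(records, key=lambda r: r.variant_key):
        pos, ref, alt = r.variant_key
        rows.append({
            "pos": pos + 1, "ref": ref, "alt": alt,
            "truth": r.truth,
            **{arm: r.called_in[arm] for arm in ARMS},
            "category": r.category or UNCLASSIFIED,
        })
    df = pd.DataFrame(rows, columns=["pos", "ref", "alt", "truth", *ARMS, "category"])
    df.to_csv(path, sep="\t", index=False)
    with open(path + ".summary.txt", "w") as fh:
        fh.write("Inconsistency classification summary\n")
        if rows:
            for cat, n in df["category"].value_counts().items():
                fh.write(f"  {cat}: {n}\n")
        else:
            fh.write("  (no records)\n")
    return int((df["category"] == UNCLASSIFIED).sum()) if rows else 0
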