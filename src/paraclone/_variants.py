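"""VCF-style variant normalization shared by truth writing, calling and comparison."""

from __future__ import annotations


def trim_and_left_align(refseq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize a variant to its minimal, left-most representation.

    ``pos`` is 0-based on ``refseq``; ``ref``/``alt`` are allele strings as in
    a VCF record body. Implements the standard normalization algorithm: while
    both alleles end in the same base, truncate it, extending both alleles one
    reference base to the left whenever one allele would become empty; finally
    trim the shared prefix down to a single anchor base.
    """
    if ref == alt:
        raise ValueError("ref and alt are identical")
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif not ref or not alt:
            if pos == 0:
                # cannot extend further left; re-anchor on the right
                nxt = refseq[len(ref)]
                ref, alt = ref + nxt, alt + nxt
                break
            pos -= 1
            ref, alt = refseq[pos] + ref, refseq[pos] + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def is_normalized(refseq: str, pos: int, ref: str, alt: str) -> bool:
    return trim_and_left_align(refseq, pos, ref, alt) == (pos, ref.upper(), alt.upper())
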