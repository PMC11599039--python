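"""Paired-end short-read simulation from a diploid sample genome.

Fragments are drawn uniformly along each haplotype with truncated-normal
lengths; mate 1 reads the fragment 5' end on the forward strand, mate 2 the
3' end reverse-complemented. Sequencing noise is i.i.d. per-base substitution
at ``err_rate``; base qualities are constant (Q30) and ignored downstream —
the calling behaviour this package studies is driven by mapping quality, not
base quality. Read names carry the fragment's truth origin so every
downstream assignment can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from ._seq import revcomp
from .locus_forge import SampleGenome


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    read_len: int = 150
    target_depth: float = 30.0
    frag_mean: float = 450.0
    frag_sd: float = 60.0
    err_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.read_len < 1:
            raise SimConfigError("read_len must be positive")
        if not (0.0 <= self.err_rate < 1.0):
            raise SimConfigError("err_rate must lie in [0, 1)")
        if self.target_depth <= 0 or self.frag_mean <= 0 or self.frag_sd < 0:
            raise SimConfigError("depth and fragment-length parameters must be positive")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    mate1_seq: str
    mate2_seq: str
    qual: str
    origin: tuple[int, int, int]  # (haplotype index, fragment start, fragment end)

    @property
    def name(self) -> str:
        h, s, e = self.origin
        return f"{self.pair_id}|h{h}|{s}|{e}"


def simulate_reads(sample: SampleGenome, config: SimConfig) -> Iterator[ReadPair]:
    """Yield read pairs at the configured mean depth, deterministically per seed.

    The expected number of pairs is
    ``target_depth * total_haplotype_length / (2 * 2 * read_len)`` (each pair
    contributes two reads, each haplotype carries half the depth); the actual
    count is Poisson-distributed around it.
    """
    config.validate()
    haps = sample.haplotypes
    if min(len(h) for h in haps) <= config.frag_mean:
        raise SimConfigError("haplotypes shorter than the mean fragment length")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD]))
    total = sum(len(h) for h in haps)
    n_pairs = int(rng.poisson(config.target_depth * total / (4.0 * config.read_len)))
    L = config.read_len
    qual = chr(33 + 30) * L
    for i in range(n_pairs):
        hap_i = int(rng.integers(0, len(haps)))
        hap = haps[hap_i]
        flen = int(round(rng.normal(config.frag_mean, config.frag_sd)))
        flen = max(L, min(flen, len(hap)))
        start = int(rng.integers(0, len(hap) - flen + 1))
        frag = hap[start:start + flen]
        m1 = frag[:L]
        m2 = revcomp(frag[-L:])
        if config.err_rate > 0.0:
            m1 = _add_errors(m1, rng, config.err_rate)
            m2 = _add_errors(m2, rng, config.err_rate)
        yield ReadPair(
            pair_id=f"{sample.sample_id}:{i}",
            mate1_seq=m1,
            mate2_seq=m2,
            qual=qual,
            origin=(hap_i, start, start + flen),
        )


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        base = arr[pos]
        if base in "ACGT":
            arr[pos] = "ACGT"[("ACGT".index(base) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def write_fastq(pairs: Iterable[ReadPair], path_r1: str, path_r2: str) -> int:
    """Write mates to a FASTQ pair, preserving order; returns the pair count."""
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.mate1_seq}\n+\n{p.qual}\n")
            f2.write(f"@{p.name}/2\n{p.mate2_seq}\n+\n{p.qual}\n")
            n += 1
    if n == 0:
        raise ValueError("empty read stream")
    return n


def read_fastq(path_r1: str, path_r2: str) -> Iterator[ReadPair]:
    """Round-trip reader for :func:`write_fastq` output (truth tags parsed back)."""
    with open(path_r1) as f1, open(path_r2) as f2:
        while True:
            h1 = f1.readline()
            if not h1:
                break
            s1 = f1.readline().strip()
            f1.readline(); q1 = f1.readline().strip()
            h2 = f2.readline()
            s2 = f2.readline().strip()
            f2.readline(); f2.readline()
            name1 = h1.strip()[1:].rsplit("/", 1)[0]
            name2 = h2.strip()[1:].rsplit("/", 1)[0]
            if name1 != name2:
                raise ValueError(f"mismatched R1/R2 read ids: {name1} vs {name2}")
            pid, h, s, e = name1.rsplit("|", 3)
            yield ReadPair(
                pair_id=pid, mate1_seq=s1, mate2_seq=s2, qual=q1,
                origin=(int(h[1:]), int(s), int(e)),
            )
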