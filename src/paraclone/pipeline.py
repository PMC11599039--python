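"""End-to-end orchestration of the simulation arms.

Convenience functions gluing the modules together the way the study design
does: simulate a case archetype, map it against both reference builds, call
variants, run the in-silico Sanger arm, scan copy number against diploid
controls and adjudicate the call sets. These are what the examples, the
tests and the acceptance script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .concordance import InconsistencyRecord, classify_all, compare_callsets
from .insilico_sanger import SangerCall, sanger_arm
from .locus_forge import LocusModel, ReferenceBuild, SampleGenome, make_sample, render_reference
from .paralog_mapper import AlignmentRecord, MapperConfig, ReferenceIndex, map_reads
from .pileup_caller import (
    CallerThresholds,
    CnSegment,
    DepthTrack,
    VariantCall,
    build_pileup,
    call_cn_segments,
    call_small_variants,
    depth_ratio,
    depth_track,
)
from .read_sim import SimConfig, simulate_reads


def restrict_to_gene(calls: list[VariantCall], locus: LocusModel) -> list[VariantCall]:
    g0, g1 = locus.gene_interval
    return [c for c in calls if g0 <= c.pos < g1]


@dataclass
class ScenarioResult:
    sample: SampleGenome
    sanger_calls: list[SangerCall]
    sr_calls: dict[str, list[VariantCall]]          # per build, gene-restricted
    sr_calls_full: dict[str, list[VariantCall]]     # per build, whole contig
    filtered_depth: dict[str, np.ndarray]           # MAPQ-passing depth per build
    alignments: dict[str, list[AlignmentRecord]]


def run_scenario(
    locus: LocusModel,
    scenario: str,
    seed: int,
    builds: tuple[str, ...] = ("buildA", "buildB"),
    sim: SimConfig | None = None,
    mapper: MapperConfig | None = None,
    thresholds: CallerThresholds | None = None,
    references: dict[str, ReferenceIndex] | None = None,
) -> ScenarioResult:
    """Simulate one sample and run Sanger + short-read arms against each build."""
    sample = make_sample(locus, scenario, seed)
    sim = sim or SimConfig(seed=seed)
    if sim.seed != seed:
        sim = SimConfig(**{**sim.__dict__, "seed": seed})
    pairs = list(simulate_reads(sample, sim))
    th = thresholds or CallerThresholds()
    sr_calls, sr_full, depths, alns = {}, {}, {}, {}
    for build in builds:
        idx = (references or {}).get(build) or ReferenceIndex(
            render_reference(locus, build), mapper
        )
        records = map_reads(pairs, idx.reference, idx.config)
        cols = build_pileup(records, idx.reference, mapq_min=th.mapq_min)
        calls = call_small_variants(cols, th)
        sr_full[build] = calls
        sr_calls[build] = restrict_to_gene(calls, locus)
        depths[build] = cols.filtered_depth
        alns[build] = records
    return ScenarioResult(
        sample=sample,
        sanger_calls=sanger_arm(sample),
        sr_calls=sr_calls,
        sr_calls_full=sr_full,
        filtered_depth=depths,
        alignments=alns,
    )


def build_indices(
    locus: LocusModel,
    builds: tuple[str, ...] = ("buildA", "buildB"),
    mapper: MapperConfig | None = None,
) -> dict[str, ReferenceIndex]:
    """Pre-build the k-mer indices once for a cohort run."""
    return {
        b: ReferenceIndex(render_reference(locus, b), mapper) for b in builds
    }


def cn_scan(
    locus: LocusModel,
    scenario: str,
    seed: int,
    n_controls: int = 5,
    build: str = "buildB",
    window_size: int = 100,
    sim_depth: float = 30.0,
    index: ReferenceIndex | None = None,
    library_normalize: bool = True,
) -> tuple[DepthTrack, list[CnSegment]]:
    """Control-normalized depth-ratio scan for one sample.

    Simulates the sample plus ``n_controls`` diploid controls at the same
    depth, maps everything to one build and returns the per-window ratio
    track with its copy-number segments.

    ``library_normalize`` rescales every track to unit mean coverage first,
    the usual library-size correction in read-depth CN analysis; a
    reciprocal gain/loss event leaves total coverage unchanged, so the
    correction removes sequencing-throughput jitter without biasing the
    ratio signature.
    """
    idx = index or ReferenceIndex(render_reference(locus, build))
    ss = np.random.SeedSequence([int(seed), 0xC2])
    child = ss.generate_state(n_controls + 1, dtype=np.uint32)

    def track_for(scn: str, s: int) -> DepthTrack:
        sample = make_sample(locus, scn, s)
        pairs = simulate_reads(sample, SimConfig(seed=s, target_depth=sim_depth))
        records = map_reads(pairs, idx.reference, idx.config)
        track = depth_track(records, idx.reference, window_size=window_size)
        if library_normalize:
            track.means = track.means / track.means.mean()
        return track

    sample_track = track_for(scenario, int(child[0]) % (2**31))
    controls = [
        track_for("plain_control", int(child[i + 1]) % (2**31))
        for i in range(n_controls)
    ]
    ratio = depth_ratio(sample_track, controls)
    return ratio, call_cn_segments(ratio)


def tract_ratios(
    locus: LocusModel,
    ratio_track: DepthTrack,
    truth_sv,
    margin: int | None = None,
) -> tuple[float, float]:
    """Mean window depth ratio over the locus-assignable portions of a
    gene-conversion tract: (gene side, pseudogene side).

    Inside the perfect-identity core block the two copies cannot be told
    apart at short-read length, so the mapper necessarily pools their depth
    and the ratio is ~1 there by construction; the copy-number signature of
    the conversion lives in the locus-specific remainder of the tract. The
    measurement therefore averages windows of the converted interval that
    lie beyond the core block plus one read length of margin.
    """
    w = ratio_track.window_size
    margin = 150 if margin is None else margin
    core_gene_end = locus.gene_start + locus.params.core_start + locus.core_block_len
    core_pseudo_end = locus.pseudo_start + locus.core_block_len

    def mean_over(a: int, b: int) -> float:
        vals = ratio_track.means[a // w:b // w]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean())

    g0, g1 = truth_sv.donor_interval
    p0, p1 = truth_sv.converted_interval
    gene_ratio = mean_over(max(g0, core_gene_end + margin), g1)
    pseudo_ratio = mean_over(max(p0, core_pseudo_end + margin), p1)
    return gene_ratio, pseudo_ratio


def adjudicate(
    result: ScenarioResult,
    cn_segments: list[CnSegment] = (),
) -> list[InconsistencyRecord]:
    """Compare truth against all arms and classify every inconsistency."""
    locus = result.sample.locus
    records = compare_callsets(
        result.sample.gene_truth(),
        result.sanger_calls,
        result.sr_calls["buildA"],
        result.sr_calls["buildB"],
        locus,
    )
    mapq_stats = {f"sr_{b}": d for b, d in result.filtered_depth.items()}
    return classify_all(records, locus, cn_segments, mapq_stats)
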