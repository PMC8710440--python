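"""End-to-end orchestration of the three coverage analyses.

Ties the stages together in memory: build the reference model and line
karyotypes once, reuse the exact-match indexes across lines and seed
replicates, and expose per-line runs that the CLI, the tests and the
acceptance script all share.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cenh3, cnv, deficiency
from .mapping import (AlignmentSet, ExactMatcher, SubtractiveTally, TrimParams,
                      targets_from, trim_reads)
from .read_sim import DEFAULT_CHIP_FRACTION, ReadBatch, simulate_chip, simulate_wgs
from .synthetic_genome import (BIC1_JUNCTION_MB, DEFAULT_SCALE, LINE_NAMES,
                               Karyotype, ReferenceModel, build_karyotype,
                               build_reference)

DEFAULT_WGS_DEPTH = 30.0
DEFAULT_CHIP_DEPTH = 10.0


@dataclass
class Study:
    """Reference model, karyotypes and shared mapping indexes."""

    reference: ReferenceModel
    karyotypes: dict[str, Karyotype]
    a_matcher: ExactMatcher
    b_matcher: ExactMatcher

    @classmethod
    def build(cls, seed: int, scale_factor: float = DEFAULT_SCALE,
              lines=LINE_NAMES) -> "Study":
        ref = build_reference(seed=seed, scale_factor=scale_factor)
        karyotypes = {line: build_karyotype(line, ref) for line in lines}
        return cls(
            reference=ref,
            karyotypes=karyotypes,
            a_matcher=ExactMatcher(targets_from(ref, ref.a_contigs)),
            b_matcher=ExactMatcher(targets_from(ref, ref.b_contigs)),
        )


@dataclass
class WgsRun:
    """One line's WGS library routed through both mapping branches."""

    line: str
    seed: int
    n_reads: int
    a_alignments: AlignmentSet  # unique 0-mismatch on the A genome
    b_specific: AlignmentSet  # unique B placements of A-unmapped survivors
    tally: SubtractiveTally


def run_wgs(study: Study, line: str, depth: float = DEFAULT_WGS_DEPTH,
            seed: int = 0, error_rate: float = 0.0, trim: bool = True) -> WgsRun:
    batch = simulate_wgs(study.reference, study.karyotypes[line], depth=depth,
                         seed=seed, error_rate=error_rate)
    if trim:
        batch = trim_reads(batch, TrimParams())
    a_res = study.a_matcher.classify(batch)
    a_set = AlignmentSet(batch, np.nonzero(a_res.unique_mask)[0], a_res)
    survivors = batch.subset(~a_res.unique_mask)
    b_res = study.b_matcher.classify(survivors)
    b_set = AlignmentSet(survivors, np.nonzero(b_res.unique_mask)[0], b_res)
    tally = SubtractiveTally(
        input=len(batch),
        a_filtered=int(a_res.unique_mask.sum()),
        b_unique=int(b_res.unique_mask.sum()),
        b_multi=int(b_res.multi_mask.sum()),
        unmapped=int(b_res.unmapped_mask.sum()),
    )
    return WgsRun(line, seed, len(batch), a_set, b_set, tally)


def cnv_ratio_track(study: Study, sample: WgsRun, control: WgsRun,
                    min_ref_count: int = 10) -> cnv.RatioTrack:
    """chr9 gene-window ratio of a sample line over the control line."""
    windows = study.reference.gene_windows
    s_track = cnv.count_windows(sample.a_alignments, windows)
    c_track = cnv.count_windows(control.a_alignments, windows)
    return cnv.compute_ratio(s_track, c_track, min_ref_count=min_ref_count)


def deficiency_tracks(study: Study, sample: WgsRun, control: WgsRun,
                      contig: str = "chrB"):
    s = deficiency.build_deficiency_track(sample.b_specific, contig, study.reference)
    c = deficiency.build_deficiency_track(control.b_specific, contig, study.reference)
    return s, c


def call_deficiency(study: Study, sample: WgsRun, control: WgsRun,
                    contig: str = "chrB") -> deficiency.DeficiencyCall:
    s, c = deficiency_tracks(study, sample, control, contig)
    return deficiency.call_b_breakpoint(s, c, scale_factor=study.reference.scale_factor)


@dataclass
class ChipRun:
    """One line's ChIP/input pair with A-branch (and optional B-branch) coverage."""

    line: str
    seed: int
    a_coverage: cenh3.CoverageTrack
    b_coverage: cenh3.CoverageTrack | None = None
    tallies: dict = field(default_factory=dict)


def run_chip(study: Study, line: str, depth: float = DEFAULT_CHIP_DEPTH,
             chip_fraction: float = DEFAULT_CHIP_FRACTION, seed: int = 0,
             b_branch: bool = False, trim: bool = True) -> ChipRun:
    """Simulate and map one line's CENH3 ChIP and input libraries.

    The A branch maps both libraries uniquely to the A genome and bins
    coverage on the A contigs.  The B branch (on demand) routes both
    libraries through subtractive mapping and bins coverage on the B
    contigs -- the two-stage read routing used for B-centromere occupancy.
    """
    chip, inp = simulate_chip(
        study.reference, study.karyotypes[line],
        chip_fraction=chip_fraction, depth=depth, seed=seed,
    )
    if trim:
        chip = trim_reads(chip, TrimParams())
        inp = trim_reads(inp, TrimParams())
    ref = study.reference
    chip_a = study.a_matcher.classify(chip)
    inp_a = study.a_matcher.classify(inp)
    a_cov = cenh3.build_coverage(
        AlignmentSet(chip, np.nonzero(chip_a.unique_mask)[0], chip_a),
        AlignmentSet(inp, np.nonzero(inp_a.unique_mask)[0], inp_a),
        ref, ref.a_contigs,
    )
    run = ChipRun(line, seed, a_cov)
    run.tallies = {
        "chip_unique": int(chip_a.unique_mask.sum()),
        "input_unique": int(inp_a.unique_mask.sum()),
    }
    if b_branch:
        chip_sub = chip.subset(~chip_a.unique_mask)
        inp_sub = inp.subset(~inp_a.unique_mask)
        chip_b = study.b_matcher.classify(chip_sub)
        inp_b = study.b_matcher.classify(inp_sub)
        run.b_coverage = cenh3.build_coverage(
            AlignmentSet(chip_sub, np.nonzero(chip_b.unique_mask)[0], chip_b),
            AlignmentSet(inp_sub, np.nonzero(inp_b.unique_mask)[0], inp_b),
            ref, ref.b_contigs,
        )
    return run


# ---------------------------------------------------------------------------
# one full seed replicate of the synthetic study
# ---------------------------------------------------------------------------


@dataclass
class ReplicateMetrics:
    """Headline quantities of one seed replicate of the six-line study."""

    ratio_deleted: float
    n_deleted: int
    ratio_distal: float
    n_distal: int
    cnv_point_mb: float | None
    b1104_breakpoint_mb: float | None
    b496_breakpoint_mb: float | None
    b1104_segment_kb: float | None
    b496_domain_kb: float | None


def run_replicate(study: Study, seed: int, wgs_depth: float = DEFAULT_WGS_DEPTH,
                  chip_depth: float = DEFAULT_CHIP_DEPTH,
                  include_chip: bool = True) -> ReplicateMetrics:
    """Simulate, map and analyse one seed replicate of the study lines.

    Runs the heterozygote/mini-line CNV comparison, the B deficiency calls,
    the elevated-segment detection, and (optionally) the six-line ChIP
    comparison yielding mini B496's unique-domain width.
    """
    ref = study.reference
    sf = ref.scale_factor
    junction_bp = ref.mb_to_bp(BIC1_JUNCTION_MB)
    b73 = run_wgs(study, "B73", depth=wgs_depth, seed=seed)
    het = run_wgs(study, "9-Bic-1_het", depth=wgs_depth, seed=seed + 211)
    b1104 = run_wgs(study, "miniB1104", depth=wgs_depth, seed=seed + 433)
    b496 = run_wgs(study, "miniB496", depth=wgs_depth, seed=seed + 677)

    track = cnv_ratio_track(study, het, b73)
    ends, starts = track.window_ends(), track.window_starts()
    deleted = track.unmasked & (ends <= junction_bp)
    distal = track.unmasked & (starts >= junction_bp + ref.mb_to_bp(0.04))
    call = cnv.localize_breakpoint(track, scale_factor=sf)

    def _bp(run):
        dcall = call_deficiency(study, run, b73)
        return dcall.breakpoint.point_paper_mb if dcall.status == "breakpoint" else None

    track1104 = cnv_ratio_track(study, b1104, b73)
    segs = cnv.detect_segments(track1104, "elevated", scale_factor=sf)
    seg_kb = max(segs, key=lambda s: s.length_bp).length_bp / sf * 1000.0 if segs else None

    domain_kb = None
    if include_chip:
        chip_runs = {
            line: run_chip(study, line, depth=chip_depth, seed=seed + 900 + 13 * j)
            for j, line in enumerate(LINE_NAMES)
        }
        controls = [chip_runs[l].a_coverage for l in LINE_NAMES if l != "miniB496"]
        domains = cenh3.call_unique_domains(
            chip_runs["miniB496"].a_coverage, controls, "chr9", scale_factor=sf
        )
        unique = [d for d in domains if d.unique_to_line]
        if unique:
            domain_kb = max(unique, key=lambda d: d.width).width_paper_kb

    return ReplicateMetrics(
        ratio_deleted=float(np.mean(track.ratio[deleted])),
        n_deleted=int(deleted.sum()),
        ratio_distal=float(np.mean(track.ratio[distal])),
        n_distal=int(distal.sum()),
        cnv_point_mb=None if call is None else call.point_paper_mb,
        b1104_breakpoint_mb=_bp(b1104),
        b496_breakpoint_mb=_bp(b496),
        b1104_segment_kb=seg_kb,
        b496_domain_kb=domain_kb,
    )
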