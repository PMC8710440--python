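"""CENH3 ChIP-seq occupancy: coverage tracks, B-centromere classification,
and line-unique de novo centromere domain calling.

Coverage is mean per-base read coverage per bin (1 paper-kb by default),
scaled to reads-per-million (RPM) of the library, separately for ChIP and
input.  Enrichment is (chip_rpm + eps) / (input_rpm + eps) with bins of
very low input coverage masked; by default the enrichment track is divided
by its genome-wide median so that unenriched background sits at 1
regardless of the ChIP efficiency (the fraction of the library drawn from
CENH3-bound chromatin).

Two comparisons mirror the study design: (1) mean scaffold enrichment over
the B centromeric scaffolds classifies each line's B centromere as
active / reduced / absent against positive and negative control lines;
(2) candidate bins of high enrichment on 9S are merged into domains, and a
domain is *unique* to the focal line when every control line is flat over
the same interval -- the signature of a de novo centromere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_genome import ReferenceModel

DEFAULT_EPS = 0.5
DEFAULT_ENRICH_THRESHOLD = 3.0
DEFAULT_CONTROL_CEILING = 1.5
DEFAULT_MIN_WIDTH_KB = 10.0
DEFAULT_MAX_GAP_BINS = 2


@dataclass
class CoverageTrack:
    """Binned ChIP and input coverage (RPM) with derived enrichment."""

    bin_size: int
    contigs: tuple[str, ...]
    chip_rpm: dict[str, np.ndarray]
    input_rpm: dict[str, np.ndarray]
    enrichment: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]  # True => bin excluded (low input)
    median_factor: float = 1.0
    # raw per-bin read-start counts (independent evidence units, unlike the
    # body-coverage RPM values whose neighbouring bins are correlated)
    chip_starts: dict[str, np.ndarray] | None = None
    input_starts: dict[str, np.ndarray] | None = None

    def bins(self, contig: str) -> int:
        return len(self.chip_rpm[contig])


def _binned_coverage(starts: np.ndarray, lengths: np.ndarray, contig_len: int,
                     bin_size: int) -> np.ndarray:
    """Mean per-base coverage per bin from read starts and lengths."""
    n_bins = int(np.ceil(contig_len / bin_size))
    diff = np.zeros(contig_len + 1)
    np.add.at(diff, np.clip(starts, 0, contig_len), 1.0)
    np.add.at(diff, np.clip(starts + lengths, 0, contig_len), -1.0)
    depth = np.cumsum(diff[:-1])
    pad = n_bins * bin_size - contig_len
    if pad:
        depth = np.concatenate([depth, np.zeros(pad)])
    return depth.reshape(n_bins, bin_size).mean(axis=1)


def build_coverage(
    chip_alignments,
    input_alignments,
    reference: ReferenceModel,
    contigs: tuple[str, ...] | list[str],
    bin_paper_kb: float = 1.0,
    eps: float = DEFAULT_EPS,
    mask_percentile: float = 5.0,
    median_normalize: bool = True,
) -> CoverageTrack:
    """Per-bin ChIP/input RPM coverage and input-normalized enrichment.

    Bins whose input RPM falls below the ``mask_percentile`` of the track's
    input bins are masked.  With ``median_normalize`` the enrichment is
    rescaled by its median over unmasked bins (background -> 1).
    """
    if len(input_alignments) == 0:
        raise ValueError("empty input alignment set: enrichment undefined")
    if len(chip_alignments) == 0:
        raise ValueError("empty ChIP alignment set")
    bin_size = max(1, reference.kb_to_bp(bin_paper_kb))
    chip_scale = 1e6 / len(chip_alignments)
    input_scale = 1e6 / len(input_alignments)
    chip_rpm, input_rpm = {}, {}
    chip_starts, input_starts = {}, {}
    for c in contigs:
        clen = reference.contig_length(c)
        n_bins = int(np.ceil(clen / bin_size))
        cs, cl = chip_alignments.on_contig(c)
        ns, nl = input_alignments.on_contig(c)
        chip_rpm[c] = _binned_coverage(cs, cl, clen, bin_size) * chip_scale
        input_rpm[c] = _binned_coverage(ns, nl, clen, bin_size) * input_scale
        chip_starts[c] = np.bincount(cs // bin_size, minlength=n_bins).astype(np.int64)
        input_starts[c] = np.bincount(ns // bin_size, minlength=n_bins).astype(np.int64)
    all_input = np.concatenate([input_rpm[c] for c in contigs])
    cutoff = float(np.percentile(all_input, mask_percentile))
    mask = {c: input_rpm[c] < cutoff for c in contigs}
    enrichment = {
        c: (chip_rpm[c] + eps) / (input_rpm[c] + eps) for c in contigs
    }
    factor = 1.0
    if median_normalize:
        unmasked = np.concatenate([enrichment[c][~mask[c]] for c in contigs])
        if unmasked.size:
            med = float(np.median(unmasked))
            if med > 0:
                factor = med
                for c in contigs:
                    enrichment[c] = enrichment[c] / factor
    return CoverageTrack(
        bin_size=bin_size,
        contigs=tuple(contigs),
        chip_rpm=chip_rpm,
        input_rpm=input_rpm,
        enrichment=enrichment,
        mask=mask,
        median_factor=factor,
        chip_starts=chip_starts,
        input_starts=input_starts,
    )


def chip_vs_chip(focal: CoverageTrack, other: CoverageTrack, eps: float = DEFAULT_EPS) -> dict[str, np.ndarray]:
    """Line-vs-line mode: focal ChIP RPM over another line's ChIP RPM."""
    if focal.contigs != other.contigs or focal.bin_size != other.bin_size:
        raise ValueError("tracks not on the same grid")
    return {c: (focal.chip_rpm[c] + eps) / (other.chip_rpm[c] + eps) for c in focal.contigs}


# ---------------------------------------------------------------------------
# B-centromere occupancy classification
# ---------------------------------------------------------------------------


def occupancy_score(track: CoverageTrack, scaffold_contigs, eps: float = DEFAULT_EPS) -> float:
    """Aggregate ChIP:input mass ratio over the B centromeric scaffolds."""
    for c in scaffold_contigs:
        if c not in track.chip_rpm:
            raise ValueError(f"track lacks scaffold {c}")
    chip = sum(float(track.chip_rpm[c].sum()) for c in scaffold_contigs)
    inp = sum(float(track.input_rpm[c].sum()) for c in scaffold_contigs)
    return (chip + eps) / (inp + eps)


def classify_b_occupancy(
    line_tracks: dict[str, CoverageTrack],
    scaffold_contigs,
    positive_controls,
    negative_controls,
    absent_factor: float = 1.5,
    active_factor: float = 0.5,
) -> dict[str, str]:
    """Label each line's B-centromere CENH3 state: active / reduced / absent.

    A line is ``absent`` when its scaffold occupancy score does not exceed
    ``absent_factor`` times the negative-control score, ``active`` when it
    reaches ``active_factor`` of the positive-control score, and
    ``reduced`` in between.
    """
    if not positive_controls or not negative_controls:
        raise ValueError("need at least one positive and one negative control line")
    scores = {line: occupancy_score(t, scaffold_contigs) for line, t in line_tracks.items()}
    pos = float(np.mean([scores[l] for l in positive_controls]))
    neg = float(np.mean([scores[l] for l in negative_controls]))
    labels = {}
    for line, s in scores.items():
        if s <= neg * absent_factor:
            labels[line] = "absent"
        elif s >= pos * active_factor:
            labels[line] = "active"
        else:
            labels[line] = "reduced"
    return labels


# ---------------------------------------------------------------------------
# de novo domain calling
# ---------------------------------------------------------------------------


@dataclass
class DomainCall:
    contig: str
    start: int
    end: int
    mean_enrichment: float
    unique_to_line: bool | None
    width_paper_kb: float | None = None
    start_paper_mb: float | None = None
    end_paper_mb: float | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


def call_unique_domains(
    focal: CoverageTrack,
    controls: list[CoverageTrack],
    contig: str,
    enrich_threshold: float = DEFAULT_ENRICH_THRESHOLD,
    min_width_paper_kb: float = DEFAULT_MIN_WIDTH_KB,
    max_gap_bins: int = DEFAULT_MAX_GAP_BINS,
    max_masked_gap_bins: int = 15,
    control_ceiling: float = DEFAULT_CONTROL_CEILING,
    z_crit: float = 5.0,
    scale_factor: float | None = None,
) -> list[DomainCall]:
    """CENH3 domains on ``contig`` present in the focal line only.

    Unmasked bins with enrichment >= ``enrich_threshold`` are merged when
    separated by at most ``max_gap_bins`` unmasked sub-threshold bins;
    masked bins carry no evidence either way, so they do not break a
    domain (up to ``max_masked_gap_bins`` total gap span -- the input mask
    removes its percentile of bins even inside true domains).  Merged
    intervals narrower than ``min_width_paper_kb``, or whose *mean*
    enrichment (over all unmasked bins, gaps included) stays below the
    threshold, are dropped -- the mean requirement rejects runs of
    isolated noise bins glued together by gap merging.  A candidate must
    further be significant at ``z_crit`` on its pooled *read-start* counts
    (chip vs input, against the track-wide start ratio): body-coverage
    bins within a read length of each other are correlated, so a single
    excess ChIP fragment over an input dip can clear the enrichment
    threshold but never this test.  A domain is unique
    to the focal line iff every control's mean enrichment over the
    interval stays below ``control_ceiling``; a control with no unmasked
    bins over the interval cannot attest and blocks uniqueness.  Without
    controls, uniqueness is flagged unknown (``None``).
    """
    enr = focal.enrichment[contig]
    ok = ~focal.mask[contig]
    hot = np.nonzero(ok & (enr >= enrich_threshold))[0]
    bs = focal.bin_size
    if scale_factor is not None:
        min_width_bp = min_width_paper_kb * scale_factor / 1000.0
    else:
        min_width_bp = min_width_paper_kb * bs  # bins default to 1 paper-kb
    out: list[DomainCall] = []
    if hot.size == 0:
        return out
    cold_unmasked = np.cumsum(ok & (enr < enrich_threshold))
    run_start = hot[0]
    prev = hot[0]
    runs = []
    for b in hot[1:]:
        n_cold = int(cold_unmasked[b - 1] - cold_unmasked[prev])
        if n_cold > max_gap_bins or b - prev - 1 > max_masked_gap_bins:
            runs.append((run_start, prev))
            run_start = b
        prev = b
    runs.append((run_start, prev))
    for b0, b1 in runs:
        start, end = int(b0 * bs), int((b1 + 1) * bs)
        if end - start < min_width_bp:
            continue
        sel = slice(b0, b1 + 1)
        mean_enr = float(np.mean(enr[sel][ok[sel]])) if ok[sel].any() else 0.0
        if mean_enr < enrich_threshold:
            continue
        if focal.chip_starts is not None and focal.input_starts is not None:
            nc = float(focal.chip_starts[contig][sel].sum()) + 0.5
            ni = float(focal.input_starts[contig][sel].sum()) + 0.5
            gc = sum(float(focal.chip_starts[c].sum()) for c in focal.contigs) + 0.5
            gi = sum(float(focal.input_starts[c].sum()) for c in focal.contigs) + 0.5
            z = np.log((nc / ni) / (gc / gi)) / np.sqrt(1.0 / nc + 1.0 / ni)
            if z < z_crit:
                continue
        if controls:
            unique = True
            for ct in controls:
                c_enr = ct.enrichment[contig][sel]
                c_ok = ~ct.mask[contig][sel]
                # a control with no usable bins cannot attest absence
                c_mean = float(np.mean(c_enr[c_ok])) if c_ok.any() else np.inf
                if c_mean >= control_ceiling:
                    unique = False
                    break
        else:
            unique = None
        width_kb = None
        start_mb = end_mb = None
        if scale_factor is not None:
            width_kb = (end - start) / scale_factor * 1000.0
            start_mb = start / scale_factor
            end_mb = end / scale_factor
        out.append(
            DomainCall(
                contig=contig,
                start=start,
                end=end,
                mean_enrichment=mean_enr,
                unique_to_line=unique,
                width_paper_kb=width_kb,
                start_paper_mb=start_mb,
                end_paper_mb=end_mb,
            )
        )
    return out
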