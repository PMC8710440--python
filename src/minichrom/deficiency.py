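"""B-chromosome deficiency mapping.

B-specific reads (output of two-stage subtractive mapping) are counted in
fixed windows of 1 paper-kb along the B reference.  In a line carrying a
truncated B, windows proximal to the truncation are covered while distal
windows fall to the cross-homology background that shared knob/CentC
repeats produce even in B-less lines.  The truncation point is called as
the exact single change point of the covered/deficient indicator, with
"covered" meaning a window count above the background level estimated from
a negative-control (B-less) line.  The indicator is used instead of the
raw counts because repeat cross-homology makes counts heavy-tailed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cnv import BreakpointCall, _best_split
from .synthetic_genome import ReferenceModel


@dataclass
class DeficiencyTrack:
    contig: str
    window_size: int  # model bp
    counts: np.ndarray
    background_level: float = 0.0

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")

    @property
    def log10_counts(self) -> np.ndarray:
        return np.log10(self.counts + 1.0)

    def window_start(self, i: int) -> int:
        return i * self.window_size


@dataclass
class DeficiencyCall:
    """Outcome of B breakpoint calling.

    ``status`` is one of ``breakpoint`` (a covered-to-deficient change
    point was found), ``no_deficiency`` (covered to the end of the
    reference) or ``no_b_material`` (background only, as in a B-less
    line).
    """

    status: str
    breakpoint: BreakpointCall | None = None
    covered_fraction: float = 0.0


def build_deficiency_track(
    alignments,
    contig: str,
    reference: ReferenceModel | None = None,
    contig_length: int | None = None,
    window_size: int | None = None,
    window_paper_kb: float = 1.0,
) -> DeficiencyTrack:
    """Per-window counts of B-specific alignments along one contig.

    The window is 1 paper-kb by default, converted to model bp through the
    reference scale factor; alignments are assigned by start coordinate.
    """
    if reference is not None:
        contig_length = reference.contig_length(contig)
        if window_size is None:
            window_size = max(1, reference.kb_to_bp(window_paper_kb))
    if contig_length is None or window_size is None:
        raise ValueError("need a reference or explicit contig_length and window_size")
    if window_size > contig_length:
        warnings.warn(
            f"window_size {window_size} exceeds contig length {contig_length}; single window"
        )
        window_size = contig_length
    starts, _ = alignments.on_contig(contig)
    n_win = int(np.ceil(contig_length / window_size))
    counts = np.bincount(starts // window_size, minlength=n_win).astype(np.int64)
    return DeficiencyTrack(contig=contig, window_size=int(window_size), counts=counts)


def estimate_background(control: DeficiencyTrack, percentile: float = 95.0) -> float:
    """Background level: the given percentile of the control's window counts."""
    return float(np.percentile(control.counts, percentile))


def call_b_breakpoint(
    sample: DeficiencyTrack,
    control: DeficiencyTrack,
    covered_level: float = 0.5,
    min_side_windows: int = 25,
    scale_factor: float | None = None,
) -> DeficiencyCall:
    """Call the B truncation point of a sample track against a control.

    Windows with counts above the control's 95th-percentile count are
    classified covered; the change point of the covered indicator is found
    by the same exact SSE scan used for CNV breakpoints.  A breakpoint is
    reported only when exactly one side of the split is covered (indicator
    mean >= ``covered_level``); a track covered on both sides is
    ``no_deficiency`` and one covered on neither (background only, as in a
    B-less line) is ``no_b_material``.  The split must leave at least
    ``min_side_windows`` on each side, so read-length edge effects at the
    very ends of the reference cannot mimic a truncation.
    """
    if sample.contig != control.contig or sample.window_size != control.window_size \
            or len(sample.counts) != len(control.counts):
        raise ValueError("sample and control tracks are not on the same grid")
    bg = estimate_background(control)
    indicator = (sample.counts > bg).astype(float)
    frac = float(indicator.mean())
    k, sse, mean_l, mean_r = _best_split(indicator, min_side=min_side_windows)
    n = len(indicator)
    pooled_sd = np.sqrt(sse / max(n - 2, 1))
    confidence = (
        np.inf if pooled_sd == 0 and mean_l != mean_r
        else (abs(mean_l - mean_r) / pooled_sd if pooled_sd > 0 else 0.0)
    )
    left_cov = mean_l >= covered_level
    right_cov = mean_r >= covered_level
    if not (left_cov and not right_cov):
        # covered on both sides, on neither, or only distally -- the last
        # is the proximal multi-mapping dead zone (ZmBs/satellite arrays),
        # not a truncation, which always removes the distal side.
        status = "no_deficiency" if frac >= covered_level else "no_b_material"
        return DeficiencyCall(status=status, covered_fraction=frac)
    point = float(k * sample.window_size)
    call = BreakpointCall(
        contig=sample.contig,
        left_window_id=f"{sample.contig}:win{k - 1}",
        right_window_id=f"{sample.contig}:win{k}",
        point_bp=point,
        point_paper_mb=None if scale_factor is None else point / scale_factor,
        mean_left=mean_l,
        mean_right=mean_r,
        confidence=float(confidence),
    )
    return DeficiencyCall(status="breakpoint", breakpoint=call, covered_fraction=frac)
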