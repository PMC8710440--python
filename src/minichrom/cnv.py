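"""Per-gene-window counting, CNV ratio tracks, and breakpoint/segment calls.

The copy-number comparison counts uniquely mapped reads per gene window,
normalizes each sample by its total unique mapped read count (library
size), and forms the per-window ratio

    ratio_w = (sample_w / sample_lib) / (reference_w / reference_lib)

so a hemizygous deletion in an otherwise disomic line sits near 0.5 and a
trisomic segment near 1.5.  Breakpoints are localized by an exact
single-change-point scan: the split minimizing the total within-segment sum
of squared deviations of the ratio, evaluated at every boundary (no
heuristic search).  Runs of windows deviating from the track median detect
elevated/depressed segments such as the 9S piece carried by a mini
chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_genome import GeneWindow


@dataclass
class WindowCountTrack:
    contig: str
    windows: list[GeneWindow]
    counts: np.ndarray
    library_size: int
    unassigned: int = 0

    def __post_init__(self):
        if len(self.counts) != len(self.windows):
            raise ValueError("counts and windows differ in length")
        if self.library_size < int(self.counts.sum()):
            raise ValueError("library_size smaller than assigned counts")


@dataclass
class RatioTrack:
    contig: str
    windows: list[GeneWindow]
    ratio: np.ndarray
    log2_ratio: np.ndarray
    mask: np.ndarray  # True => window excluded (low reference coverage)
    sample_counts: np.ndarray | None = None
    ref_counts: np.ndarray | None = None
    sample_lib: int = 0
    ref_lib: int = 0

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def window_starts(self) -> np.ndarray:
        return np.array([w.start for w in self.windows])

    def window_ends(self) -> np.ndarray:
        return np.array([w.end for w in self.windows])


@dataclass
class BreakpointCall:
    contig: str
    left_window_id: str
    right_window_id: str
    point_bp: float
    point_paper_mb: float | None
    mean_left: float
    mean_right: float
    confidence: float


@dataclass
class SegmentCall:
    contig: str
    start_bp: int
    end_bp: int
    n_windows: int
    mean_ratio: float
    direction: str
    start_paper_mb: float | None = None
    end_paper_mb: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def count_windows(alignments, windows: list[GeneWindow], library_size: int | None = None) -> WindowCountTrack:
    """Count alignments per gene window by start coordinate (half-open).

    An alignment is assigned to the window containing its start; starts
    outside every window go to the ``unassigned`` bucket.  ``library_size``
    defaults to the total number of alignments in the set (all contigs),
    which is the library normalizer used for ratio computation.
    """
    if not windows:
        raise ValueError("window list is empty")
    contig = windows[0].contig
    if any(w.contig != contig for w in windows):
        raise ValueError("windows span multiple contigs")
    starts, _lengths = alignments.on_contig(contig)
    wstarts = np.array([w.start for w in windows])
    wends = np.array([w.end for w in windows])
    if (wstarts[1:] < wends[:-1]).any():
        raise ValueError("windows overlap or are unsorted")
    idx = np.searchsorted(wstarts, starts, side="right") - 1
    inside = (idx >= 0) & (starts < wends[np.maximum(idx, 0)])
    counts = np.bincount(idx[inside], minlength=len(windows)).astype(np.int64)
    lib = int(len(alignments)) if library_size is None else int(library_size)
    return WindowCountTrack(
        contig=contig,
        windows=list(windows),
        counts=counts,
        library_size=lib,
        unassigned=int(len(starts) - inside.sum()),
    )


def compute_ratio(sample: WindowCountTrack, reference: WindowCountTrack,
                  min_ref_count: int = 10) -> RatioTrack:
    """Library-normalized sample:reference ratio per window.

    Windows whose reference count falls below ``min_ref_count`` are masked
    (unmappable or undersampled in the control); log2 is defined only on
    unmasked windows with positive ratio.
    """
    if [ (w.id, w.start, w.end) for w in sample.windows ] != \
       [ (w.id, w.start, w.end) for w in reference.windows ]:
        raise ValueError("sample and reference window lists differ")
    if sample.library_size <= 0 or reference.library_size <= 0:
        raise ValueError("empty library")
    mask = reference.counts < min_ref_count
    ratio = np.zeros(len(sample.windows))
    ok = ~mask
    ratio[ok] = (sample.counts[ok] / sample.library_size) / (
        reference.counts[ok] / reference.library_size
    )
    log2 = np.full(len(ratio), np.nan)
    pos = ok & (ratio > 0)
    log2[pos] = np.log2(ratio[pos])
    return RatioTrack(sample.contig, sample.windows, ratio, log2, mask,
                      sample_counts=sample.counts, ref_counts=reference.counts,
                      sample_lib=sample.library_size, ref_lib=reference.library_size)


def _best_split(values: np.ndarray, min_side: int = 1) -> tuple[int, float, float, float]:
    """Exact single change point by total within-segment SSE.

    Returns (split index k, sse, mean_left, mean_right) where the left
    segment is values[:k] and the right values[k:], minimizing
    SSE(left) + SSE(right) over k = min_side..n-min_side.  Ties break to
    the smallest k.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    min_side = max(1, int(min_side))
    if n < 2 * min_side:
        raise ValueError("too few values for the requested split")
    c1 = np.cumsum(v)
    c2 = np.cumsum(v * v)
    k = np.arange(min_side, n - min_side + 1)
    sum_l, sum_r = c1[k - 1], c1[-1] - c1[k - 1]
    ss_l, ss_r = c2[k - 1], c2[-1] - c2[k - 1]
    sse = (ss_l - sum_l**2 / k) + (ss_r - sum_r**2 / (n - k))
    best = int(np.argmin(sse))
    kbest = int(k[best])
    return kbest, float(sse[best]), float(sum_l[best] / kbest), float(sum_r[best] / (n - kbest))


def localize_breakpoint(track: RatioTrack, confidence_threshold: float = 3.0,
                        scale_factor: float | None = None) -> BreakpointCall | None:
    """Single change point of the ratio by exact SSE scan over all splits.

    Returns ``None`` (no breakpoint) when the split is not supported:
    confidence = |mean_left - mean_right| / pooled within-segment s.d.
    must reach ``confidence_threshold``.  The reported point is the
    boundary between the flanking unmasked windows.
    """
    sel = np.nonzero(track.unmasked)[0]
    if len(sel) < 4:
        raise ValueError("need >= 4 unmasked windows")
    vals = track.ratio[sel]
    k, sse, mean_l, mean_r = _best_split(vals)
    n = len(vals)
    pooled_sd = np.sqrt(sse / max(n - 2, 1))
    if pooled_sd == 0:
        confidence = np.inf if mean_l != mean_r else 0.0
    else:
        confidence = abs(mean_l - mean_r) / pooled_sd
    if confidence < confidence_threshold:
        return None
    left_w = track.windows[sel[k - 1]]
    right_w = track.windows[sel[k]]
    point = (left_w.end + right_w.start) / 2.0
    return BreakpointCall(
        contig=track.contig,
        left_window_id=left_w.id,
        right_window_id=right_w.id,
        point_bp=point,
        point_paper_mb=None if scale_factor is None else point / scale_factor,
        mean_left=mean_l,
        mean_right=mean_r,
        confidence=float(confidence),
    )


def detect_segments(track: RatioTrack, direction: str = "elevated",
                    min_windows: int = 3, margin: float = 0.25,
                    z_crit: float = 4.0,
                    scale_factor: float | None = None) -> list[SegmentCall]:
    """Maximal runs of consecutive unmasked windows deviating from the median.

    Two-level rule: a window joins a run when its ratio deviates from the
    track median by more than ``margin / 2`` in the stated direction, and a
    run is reported only if it spans at least ``min_windows`` windows *and*
    its mean ratio deviates by more than the full ``margin``.  The half-
    margin membership keeps short true segments intact despite per-window
    sampling noise, while the run-mean requirement keeps noise-only runs
    out.  When per-window counts are available, a run must additionally be
    significant at ``z_crit`` on its pooled counts (Poisson standard error
    of the log pooled ratio; ~Bonferroni level for a few hundred windows),
    which suppresses chance runs of mildly deviating windows.  Masked
    windows break runs.
    """
    if direction not in ("elevated", "depressed"):
        raise ValueError("direction must be 'elevated' or 'depressed'")
    ok = track.unmasked
    if not ok.any():
        raise ValueError("all windows masked")
    med = float(np.median(track.ratio[ok]))
    sign = 1.0 if direction == "elevated" else -1.0
    dev = sign * (track.ratio - med)
    hit = ok & (dev > margin / 2.0)
    out: list[SegmentCall] = []
    i, n = 0, len(hit)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hit[j + 1]:
            j += 1
        run_mean_dev = float(np.mean(dev[i : j + 1]))
        significant = True
        if track.sample_counts is not None and track.ref_counts is not None \
                and track.sample_lib > 0 and track.ref_lib > 0:
            s_sum = float(track.sample_counts[i : j + 1].sum())
            r_sum = float(track.ref_counts[i : j + 1].sum())
            if s_sum > 0 and r_sum > 0 and med > 0:
                pooled = (s_sum / track.sample_lib) / (r_sum / track.ref_lib)
                se_log = np.sqrt(1.0 / s_sum + 1.0 / r_sum)
                z = sign * np.log(pooled / med) / se_log
                significant = z >= z_crit
            else:
                significant = False
        if j - i + 1 >= min_windows and run_mean_dev > margin and significant:
            start = track.windows[i].start
            end = track.windows[j].end
            out.append(
                SegmentCall(
                    contig=track.contig,
                    start_bp=start,
                    end_bp=end,
                    n_windows=j - i + 1,
                    mean_ratio=float(np.mean(track.ratio[i : j + 1][ok[i : j + 1]])),
                    direction=direction,
                    start_paper_mb=None if scale_factor is None else start / scale_factor,
                    end_paper_mb=None if scale_factor is None else end / scale_factor,
                )
            )
        i = j + 1
    return out
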