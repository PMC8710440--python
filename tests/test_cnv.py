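"""Window counting, ratio normalization, and change-point/segment calls."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from minichrom.cnv import (
    RatioTrack,
    WindowCountTrack,
    _best_split,
    compute_ratio,
    count_windows,
    detect_segments,
    localize_breakpoint,
)
from minichrom.synthetic_genome import GeneWindow


def _windows(n, width=100, gap=0, contig="chr9"):
    out = []
    pos = 0
    for i in range(n):
        out.append(GeneWindow(f"w{i + 1}", contig, pos, pos + width))
        pos += width + gap
    return out


def _track(ratio, mask=None, counts_scale=200):
    """RatioTrack with self-consistent integer counts for the z filter."""
    ratio = np.asarray(ratio, dtype=float)
    n = len(ratio)
    wins = _windows(n)
    mask = np.zeros(n, dtype=bool) if mask is None else np.asarray(mask)
    ref = np.full(n, counts_scale, dtype=np.int64)
    samp = np.round(ratio * counts_scale).astype(np.int64)
    return RatioTrack("chr9", wins, ratio, np.where(ratio > 0, np.log2(np.maximum(ratio, 1e-9)), np.nan),
                      mask, sample_counts=samp, ref_counts=ref,
                      sample_lib=int(samp.sum() * 10), ref_lib=int(ref.sum() * 10))


# ---------------------------------------------------------------------------
# count_windows
# ---------------------------------------------------------------------------


def test_empty_alignments_give_zero_counts(fake_alignments):
    track = count_windows(fake_alignments([]), _windows(5))
    assert (track.counts == 0).all() and track.unassigned == 0


def test_half_open_boundary_assignment(fake_alignments):
    wins = _windows(2, width=100)  # [0,100), [100,200)
    track = count_windows(fake_alignments([("chr9", 0), ("chr9", 99), ("chr9", 100)]), wins)
    assert track.counts.tolist() == [2, 1]


def test_reads_outside_windows_counted_unassigned(fake_alignments):
    wins = [GeneWindow("w1", "chr9", 100, 200)]
    track = count_windows(fake_alignments([("chr9", 50), ("chr9", 150), ("chr9", 250)]), wins)
    assert track.counts.tolist() == [1] and track.unassigned == 2
    assert track.counts.sum() + track.unassigned == 3


def test_counts_match_brute_force_membership(fake_alignments):
    rng = np.random.default_rng(5)
    wins = _windows(20, width=80, gap=20)
    starts = rng.integers(0, 2100, size=500)
    track = count_windows(fake_alignments([("chr9", int(s)) for s in starts]), wins)
    for i, w in enumerate(wins):
        assert track.counts[i] == int(np.sum((starts >= w.start) & (starts < w.end)))


def test_empty_window_list_rejected(fake_alignments):
    with pytest.raises(ValueError, match="empty"):
        count_windows(fake_alignments([]), [])


# ---------------------------------------------------------------------------
# compute_ratio
# ---------------------------------------------------------------------------


def _count_track(counts, lib=None):
    counts = np.asarray(counts, dtype=np.int64)
    return WindowCountTrack("chr9", _windows(len(counts)), counts,
                            int(counts.sum() if lib is None else lib))


def test_identity_ratio_is_one():
    t = _count_track([50, 60, 70, 80])
    r = compute_ratio(t, t, min_ref_count=10)
    assert np.allclose(r.ratio[r.unmasked], 1.0)


def test_low_reference_windows_masked_and_log2_defined():
    s = _count_track([50, 0, 70, 80])
    ref = _count_track([50, 3, 70, 80])
    r = compute_ratio(s, ref, min_ref_count=10)
    assert r.mask.tolist() == [False, True, False, False]
    assert np.isfinite(r.log2_ratio[r.unmasked]).all()


def test_ratio_scale_invariance():
    s = _count_track([50, 60, 70, 80], lib=1000)
    ref = _count_track([40, 80, 60, 90], lib=2000)
    r1 = compute_ratio(s, ref)
    s2 = _count_track([c * 7 for c in [50, 60, 70, 80]], lib=7000)
    r2 = compute_ratio(s2, ref)
    assert np.allclose(r1.ratio, r2.ratio)


def test_mismatched_windows_rejected():
    s = _count_track([50, 60])
    bad = WindowCountTrack("chr9", _windows(2, width=50), np.array([1, 2]), 3)
    with pytest.raises(ValueError, match="differ"):
        compute_ratio(s, bad)


# ---------------------------------------------------------------------------
# localize_breakpoint
# ---------------------------------------------------------------------------


def _brute_force_split(values, min_side=1):
    best = None
    n = len(values)
    for k in range(min_side, n - min_side + 1):
        l, r = values[:k], values[k:]
        sse = np.sum((l - l.mean()) ** 2) + np.sum((r - r.mean()) ** 2)
        if best is None or sse < best[1] - 1e-12:
            best = (k, sse)
    return best


@given(st.lists(st.floats(min_value=0.0, max_value=4.0, allow_nan=False), min_size=4,
                max_size=200))
def test_exact_scan_equals_brute_force_sse(values):
    v = np.asarray(values)
    k, sse, ml, mr = _best_split(v)
    bk, bsse = _brute_force_split(v)
    assert sse == pytest.approx(bsse, abs=1e-8)
    # the chosen split is a minimizer (exact k may differ only under
    # floating-point ties)
    direct = (np.sum((v[:k] - v[:k].mean()) ** 2)
              + np.sum((v[k:] - v[k:].mean()) ** 2))
    assert direct <= bsse + 1e-8
    assert ml == pytest.approx(v[:k].mean()) and mr == pytest.approx(v[k:].mean())


def test_noiseless_step_split_exactly_at_step():
    track = _track([0.5] * 7 + [1.0] * 9)
    call = localize_breakpoint(track, scale_factor=100.0)
    assert call is not None
    assert call.left_window_id == "w7" and call.right_window_id == "w8"
    assert call.point_bp == 700.0 and call.point_paper_mb == 7.0
    assert call.confidence == np.inf


def test_flat_noisy_track_yields_no_breakpoint():
    rng = np.random.default_rng(0)
    track = _track(1.0 + 0.05 * rng.standard_normal(60))
    assert localize_breakpoint(track) is None


def test_masked_windows_excluded_from_scan():
    ratio = np.array([0.5] * 5 + [9.0] + [0.5] * 4 + [1.0] * 10)
    mask = np.zeros(20, dtype=bool)
    mask[5] = True
    call = localize_breakpoint(_track(ratio, mask=mask))
    assert call is not None and call.right_window_id == "w11"


def test_too_few_windows_rejected():
    with pytest.raises(ValueError, match=">= 4"):
        localize_breakpoint(_track([1.0, 1.0], mask=np.array([False, False])))


def test_planted_heterozygote_junction_recovered(study):
    """Change point of simulated 9-Bic-1 het vs B73 within 2 windows of 3.06 Mb."""
    from minichrom.pipeline import cnv_ratio_track, run_wgs

    sf = study.reference.scale_factor
    points = []
    for s in (301, 302, 303):
        b73 = run_wgs(study, "B73", depth=15, seed=s)
        het = run_wgs(study, "9-Bic-1_het", depth=15, seed=s + 7)
        call = localize_breakpoint(cnv_ratio_track(study, het, b73), scale_factor=sf)
        assert call is not None
        points.append(call.point_paper_mb)
    assert all(abs(p - 3.06) <= 0.1 for p in points)


# ---------------------------------------------------------------------------
# detect_segments
# ---------------------------------------------------------------------------


def test_flat_track_has_no_segments():
    rng = np.random.default_rng(1)
    track = _track(1.0 + 0.05 * rng.standard_normal(100))
    assert detect_segments(track, "elevated") == []
    assert detect_segments(track, "depressed") == []


def test_planted_elevated_run_recovered_with_tight_bounds():
    rng = np.random.default_rng(2)
    ratio = 1.0 + 0.06 * rng.standard_normal(120)
    ratio[40:70] += 0.5  # 30-window trisomic segment
    segs = detect_segments(_track(ratio), "elevated", scale_factor=100.0)
    assert len(segs) == 1
    s = segs[0]
    assert abs(s.start_bp - 40 * 100) <= 200 and abs(s.end_bp - 70 * 100) <= 200
    assert s.mean_ratio == pytest.approx(1.5, abs=0.1)


def test_depressed_segment_detected_symmetrically():
    rng = np.random.default_rng(3)
    ratio = 1.0 + 0.06 * rng.standard_normal(120)
    ratio[10:40] -= 0.5
    segs = detect_segments(_track(ratio), "depressed")
    assert len(segs) == 1 and segs[0].n_windows >= 28


def test_short_runs_below_min_windows_dropped():
    ratio = np.ones(60)
    ratio[30:32] = 1.6
    assert detect_segments(_track(ratio), "elevated", min_windows=3) == []


def test_masked_windows_break_runs():
    ratio = np.ones(40)
    ratio[10:20] = 1.6
    mask = np.zeros(40, dtype=bool)
    mask[14:16] = True
    segs = detect_segments(_track(ratio, mask=mask), "elevated", min_windows=3)
    assert len(segs) == 2


def test_copy_state_recovery_within_ten_percent(study):
    """Segment means for planted copy states {1,2,3} land within 10% of c/2."""
    from minichrom.pipeline import cnv_ratio_track, run_wgs

    b73 = run_wgs(study, "B73", depth=20, seed=555)
    b1104 = run_wgs(study, "miniB1104", depth=20, seed=556)
    het = run_wgs(study, "9-Bic-1_het", depth=20, seed=557)
    ref = study.reference
    tr = cnv_ratio_track(study, b1104, b73)
    lo, hi = ref.mb_to_bp(3.11), ref.mb_to_bp(3.49)
    starts, ends = tr.window_starts(), tr.window_ends()
    tri = tr.unmasked & (starts >= lo) & (ends <= hi)
    assert abs(np.mean(tr.ratio[tri]) - 1.5) < 0.15
    tr2 = cnv_ratio_track(study, het, b73)
    mono = tr2.unmasked & (ends <= ref.mb_to_bp(3.0))
    assert abs(np.mean(tr2.ratio[mono]) - 0.5) < 0.05
    di = tr2.unmasked & (starts >= ref.mb_to_bp(3.2))
    assert abs(np.mean(tr2.ratio[di]) - 1.0) < 0.1
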