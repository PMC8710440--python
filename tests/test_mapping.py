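"""Trimming rules, exact unique mapping vs the exhaustive oracle, subtractive routing."""
import numpy as np
import pytest

from minichrom._util import revcomp
from minichrom.mapping import (
    ExactMatcher,
    TrimParams,
    map_unique,
    read_sam,
    subtractive_map,
    targets_from,
    trim_reads,
    write_sam,
)
from minichrom.read_sim import Read, ReadBatch, simulate_wgs
from minichrom.synthetic_genome import Chromosome, SegmentSpec, build_karyotype


def _q(scores):
    return "".join(chr(33 + s) for s in scores)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def test_high_quality_read_unchanged():
    r = Read("r1", "ACGT" * 25, _q([40] * 100))
    out = trim_reads([r], TrimParams())
    assert len(out) == 1 and out.sequence(0) == r.sequence


def test_short_read_dropped_by_min_len():
    r = Read("r1", "ACGTACGTACGTACGTACGT", _q([40] * 20))
    assert len(trim_reads([r], TrimParams())) == 0  # MINLEN 29


def test_sliding_window_clip_matches_hand_computation():
    """12-base example worked by hand: LEADING keeps base 0 (Q40); TRAILING
    ends at the last base >= 29 (index 9); the first 4-base window with mean
    below 30 starts at index 3 (40,35,20,20 -> 28.75), so the read is cut
    there, leaving the first 3 bases."""
    scores = [40, 40, 40, 40, 35, 20, 20, 20, 40, 40, 10, 10]
    r = Read("r1", "ACGTACGTACGT", _q(scores))
    out = trim_reads([r], TrimParams(leading_q=30, trailing_q=29, window_len=4,
                                     window_q=30, min_len=2, avg_q=20))
    assert len(out) == 1
    assert out.sequence(0) == "ACG"
    assert out.quality_string(0) == _q([40, 40, 40])


def test_leading_and_trailing_clipped():
    scores = [10, 10, 40, 40, 40, 40, 40, 40, 20]
    r = Read("r1", "AACGTACGT", _q(scores))
    out = trim_reads([r], TrimParams(leading_q=30, trailing_q=29, window_len=4,
                                     window_q=10, min_len=2, avg_q=0))
    assert out.sequence(0) == "CGTACG"


def test_low_mean_quality_dropped():
    r = Read("r1", "A" * 40, _q([27] * 40))
    assert len(trim_reads([r], TrimParams(leading_q=20, trailing_q=20, window_q=20,
                                          min_len=10, avg_q=28))) == 0


def test_malformed_quality_record_skipped_with_warning(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r1\nACGT\n+\nII\n@r2\nACGT\n+\nIIII\n")
    with pytest.warns(UserWarning, match="malformed"):
        batch = ReadBatch.from_fastq(p)
    assert len(batch) == 1 and batch.read_id(0) == "r2"


# ---------------------------------------------------------------------------
# exact unique mapping
# ---------------------------------------------------------------------------


def test_map_unique_agrees_with_exhaustive_substring_oracle(repeat_ref, oracle):
    """Classification of a simulated library equals brute-force substring search."""
    targets = {c: repeat_ref.sequences[c] for c in repeat_ref.sequences}
    kt = build_karyotype(
        "custom", repeat_ref,
        custom_chromosomes=build_karyotype("B73", repeat_ref).chromosomes
        + [Chromosome("B", [SegmentSpec("chrB", 0, repeat_ref.contig_length("chrB"))])],
    )
    batch = simulate_wgs(repeat_ref, kt, depth=3.0, seed=21)
    matcher = ExactMatcher(targets)
    res = matcher.classify(batch)
    for i in range(len(batch)):
        hits = oracle(batch.sequence(i), targets)
        assert res.n_hits[i] == len(hits), f"read {i}: {batch.truth_of(i)}"
        if len(hits) == 1:
            name, pos, strand = hits[0]
            assert res.contig_names[res.contig_idx[i]] == name
            assert res.pos[i] == pos
            assert ("-" if res.strand[i] else "+") == strand


def test_repeat_read_excluded_as_multi_mapper(repeat_ref):
    """A read copied verbatim at two knob loci is not reported."""
    seq = repeat_ref.sequences["chr9"][12010:12110]  # inside k0, also at 15010
    res = ExactMatcher(targets_from(repeat_ref, ("chr9",))).classify(
        ReadBatch.from_strings([seq]))
    assert res.n_hits[0] >= 2
    aln = map_unique(ReadBatch.from_strings([seq]), {"chr9": repeat_ref.sequences["chr9"]})
    assert len(aln) == 0


def test_b_unique_read_maps_to_truth_position(tiny_ref):
    seq = tiny_ref.sequences["chrB"][500:600]
    aln = map_unique(ReadBatch.from_strings([seq]),
                     {c: tiny_ref.sequences[c] for c in tiny_ref.sequences})
    rec = list(aln)[0]
    assert (rec.contig, rec.start, rec.strand) == ("chrB", 500, "+")
    assert rec.mismatches == 0 and rec.n_hits == 1


def test_reverse_strand_placement(tiny_ref):
    seq = revcomp(tiny_ref.sequences["chr9"][700:800])
    rec = list(map_unique(ReadBatch.from_strings([seq]),
                          {"chr9": tiny_ref.sequences["chr9"]}))[0]
    assert (rec.start, rec.strand) == (700, "-")


def test_reads_with_n_or_too_short_are_unmapped(tiny_ref):
    targets = {"chr9": tiny_ref.sequences["chr9"]}
    seq = tiny_ref.sequences["chr9"][100:200]
    with_n = seq[:50] + "N" + seq[51:]
    short = seq[:20]
    res = ExactMatcher(targets).classify(ReadBatch.from_strings([with_n, short]))
    assert (res.n_hits == 0).all()


def test_strand_symmetry_under_global_reverse_complement(tiny_ref):
    """Reverse-complementing every read keeps positions, flips strands."""
    kt = build_karyotype("B73", tiny_ref)
    batch = simulate_wgs(tiny_ref, kt, depth=1.0, seed=31)
    rc = ReadBatch.from_strings([revcomp(batch.sequence(i)) for i in range(len(batch))])
    matcher = ExactMatcher(targets_from(tiny_ref, tiny_ref.a_contigs))
    fwd, rev = matcher.classify(batch), matcher.classify(rc)
    assert (fwd.n_hits == rev.n_hits).all()
    u = fwd.unique_mask
    assert (fwd.pos[u] == rev.pos[u]).all()
    assert (fwd.strand[u] != rev.strand[u]).all()


# ---------------------------------------------------------------------------
# subtractive mapping
# ---------------------------------------------------------------------------


def test_subtractive_tally_conservation(study):
    from minichrom.pipeline import run_wgs

    run = run_wgs(study, "miniB1104", depth=5.0, seed=77)
    t = run.tally
    assert t.input == t.a_filtered + t.b_unique + t.b_multi + t.unmapped


def test_stage1_removes_exactly_a_reads_without_shared_repeats(tiny_ref):
    kt = build_karyotype("B73+B", tiny_ref)
    batch = simulate_wgs(tiny_ref, kt, depth=3.0, seed=13)
    a_targets = targets_from(tiny_ref, tiny_ref.a_contigs)
    b_targets = targets_from(tiny_ref, tiny_ref.b_contigs)
    a_res = ExactMatcher(a_targets).classify(batch)
    a_names = set(tiny_ref.a_contigs)
    truth_a = np.array([batch.truth_of(i)[0] in a_names for i in range(len(batch))])
    assert (a_res.unique_mask == truth_a).all()
    _b_set, tally = subtractive_map(batch, a_targets, b_targets)
    assert tally.a_filtered == int(truth_a.sum())
    assert tally.b_multi == 0  # no repeats anywhere


def test_shared_single_copy_monomer_read_removed_at_stage1(repeat_ref):
    """CentC c0 sits once on chr9 and once on chrB: its reads are unique on
    the A side and are filtered there, never reaching the B stage."""
    ann = next(a for a in repeat_ref.repeat_annotations
               if a.contig == "chr9" and a.variant == "c0")
    seq = repeat_ref.sequences["chr9"][ann.start : ann.start + 100]
    _b, tally = subtractive_map(
        ReadBatch.from_strings([seq]),
        targets_from(repeat_ref, repeat_ref.a_contigs),
        targets_from(repeat_ref, repeat_ref.b_contigs),
    )
    assert tally.a_filtered == 1 and tally.b_unique == 0


def test_multi_a_monomer_read_survives_to_unique_b_hit(repeat_ref):
    """CentC c1 sits twice on chr9 and once on chrB: multi on A, so it
    survives stage 1 and lands uniquely on chrB (the background mechanism)."""
    ann = next(a for a in repeat_ref.repeat_annotations
               if a.contig == "chrB" and a.variant == "c1")
    seq = repeat_ref.sequences["chrB"][ann.start : ann.start + 100]
    b_set, tally = subtractive_map(
        ReadBatch.from_strings([seq]),
        targets_from(repeat_ref, repeat_ref.a_contigs),
        targets_from(repeat_ref, repeat_ref.b_contigs),
    )
    assert tally.b_unique == 1
    rec = list(b_set)[0]
    assert rec.contig == "chrB" and rec.start == ann.start


def test_overlapping_target_namespaces_rejected(tiny_ref):
    t = {"chr9": tiny_ref.sequences["chr9"]}
    with pytest.raises(ValueError, match="name spaces"):
        subtractive_map(ReadBatch.from_strings(["ACGT" * 25]), t, t)


# ---------------------------------------------------------------------------
# SAM round trip
# ---------------------------------------------------------------------------


def test_sam_round_trip(tiny_ref, tmp_path):
    kt = build_karyotype("B73", tiny_ref)
    batch = simulate_wgs(tiny_ref, kt, depth=0.5, seed=17)
    aln = map_unique(batch, targets_from(tiny_ref, tiny_ref.a_contigs))
    path = tmp_path / "out.sam"
    write_sam(aln, path, seed=17)
    back = read_sam(path)
    assert len(back) == len(aln)
    for contig in tiny_ref.a_contigs:
        s1, l1 = aln.on_contig(contig)
        s2, l2 = back.on_contig(contig)
        assert sorted(s1.tolist()) == sorted(s2.tolist())
        assert (l2 == 100).all()
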