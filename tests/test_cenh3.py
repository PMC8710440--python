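"""CENH3 coverage, B-centromere occupancy labels, unique-domain calls."""
import numpy as np
import pytest

from minichrom.cenh3 import (
    build_coverage,
    call_unique_domains,
    chip_vs_chip,
    classify_b_occupancy,
    occupancy_score,
)
from minichrom.pipeline import run_chip, run_wgs
from minichrom.synthetic_genome import ActiveCentromere, build_karyotype
from minichrom.read_sim import simulate_chip
from minichrom.mapping import AlignmentSet

LINES = ("B73", "B73+B", "TB-9Sb", "9-Bic-1_het", "miniB1104", "miniB496")


@pytest.fixture(scope="module")
def chip_runs(study):
    """One ChIP/input replicate per line, both branches."""
    return {line: run_chip(study, line, depth=10, seed=600 + 7 * i, b_branch=True)
            for i, line in enumerate(LINES)}


def test_chip_equal_to_input_gives_unit_enrichment(study):
    run = run_wgs(study, "B73", depth=10, seed=71)
    cov = build_coverage(run.a_alignments, run.a_alignments, study.reference,
                        ("chr9",))
    ok = ~cov.mask["chr9"]
    assert np.allclose(cov.enrichment["chr9"][ok], 1.0, atol=1e-9)


def test_empty_input_rejected(study, fake_alignments):
    run = run_wgs(study, "B73", depth=5, seed=72)
    with pytest.raises(ValueError, match="input"):
        build_coverage(run.a_alignments, fake_alignments([]), study.reference, ("chr9",))


def test_genome_median_enrichment_near_one_for_every_line(chip_runs):
    for line, run in chip_runs.items():
        enr = np.concatenate([run.a_coverage.enrichment[c][~run.a_coverage.mask[c]]
                              for c in run.a_coverage.contigs])
        assert 0.8 <= float(np.median(enr)) <= 1.2, line


def test_planted_interval_enrichment_matches_mixture_expectation(study):
    """Closed-form two-component mixture expectation, within 15%."""
    ref = study.reference
    kt = build_karyotype("B73", ref)
    lo, hi = ref.mb_to_bp(5.0), ref.mb_to_bp(5.2)  # 2 kb model interval
    kt.active_centromeres = [ActiveCentromere("chr9", lo, hi)]
    f = 0.3
    vals = []
    for s in (81, 82, 83):
        chip, inp = simulate_chip(ref, kt, chip_fraction=f, depth=12, seed=s)
        chip_res = study.a_matcher.classify(chip)
        inp_res = study.a_matcher.classify(inp)
        cov = build_coverage(
            AlignmentSet(chip, np.nonzero(chip_res.unique_mask)[0], chip_res),
            AlignmentSet(inp, np.nonzero(inp_res.unique_mask)[0], inp_res),
            ref, ref.a_contigs, median_normalize=False)
        bins = slice(lo // cov.bin_size, hi // cov.bin_size)
        vals.append(float(np.mean(cov.chip_rpm["chr9"][bins]))
                    / float(np.mean(cov.input_rpm["chr9"][bins])))
    # expectation: chip share in interval = f + (1-f) * 2*Li/Ltot, input = 2*Li/Ltot
    Li, Ltot = hi - lo, kt.total_content_bp()
    expected = (f + (1 - f) * 2 * Li / Ltot) / (2 * Li / Ltot)
    assert np.mean(vals) == pytest.approx(expected, rel=0.15)


def test_occupancy_labels_reproduce_line_pattern(chip_runs, study):
    tracks = {line: r.b_coverage for line, r in chip_runs.items()}
    labels = classify_b_occupancy(tracks, study.reference.b_scaffolds,
                                  positive_controls=["B73+B", "TB-9Sb"],
                                  negative_controls=["B73"])
    assert labels["B73"] == "absent"  # negative control self-consistent
    assert labels["B73+B"] == "active" and labels["TB-9Sb"] == "active"
    assert labels["9-Bic-1_het"] == "absent"  # inactive B centromere
    assert labels["miniB1104"] == "reduced"  # partial re-association
    assert labels["miniB496"] == "absent"


def test_occupancy_monotone_in_planted_enrichment(study):
    """Sweeping the B-centromere weight moves the label absent->reduced->active."""
    ref = study.reference
    order = {"absent": 0, "reduced": 1, "active": 2}
    ranks = []
    pos_run = run_chip(study, "B73+B", depth=8, seed=660, b_branch=True)
    neg_run = run_chip(study, "B73", depth=8, seed=661, b_branch=True)
    for j, w in enumerate((0.02, 0.25, 1.0)):
        kt = build_karyotype("B73+B", ref)
        kt.active_centromeres = [
            ActiveCentromere(a.contig, a.start, a.end,
                             w if a.contig in ref.b_contigs else a.weight)
            for a in kt.active_centromeres
        ]
        import minichrom.pipeline as pl

        study2 = pl.Study(ref, {**study.karyotypes, "sweep": kt},
                          study.a_matcher, study.b_matcher)
        run = pl.run_chip(study2, "sweep", depth=8, seed=662 + j, b_branch=True)
        tracks = {"pos": pos_run.b_coverage, "neg": neg_run.b_coverage,
                  "sweep": run.b_coverage}
        labels = classify_b_occupancy(tracks, ref.b_scaffolds, ["pos"], ["neg"])
        ranks.append(order[labels["sweep"]])
    assert ranks == sorted(ranks)
    assert ranks[0] == 0 and ranks[-1] == 2


def test_missing_scaffold_rejected(chip_runs):
    with pytest.raises(ValueError, match="scaffold"):
        occupancy_score(chip_runs["B73"].a_coverage, ("B_scaf1",))
    with pytest.raises(ValueError, match="control"):
        classify_b_occupancy({}, ("B_scaf1",), [], [])


def test_focal_line_in_controls_yields_no_unique_domain(chip_runs, study):
    focal = chip_runs["miniB496"].a_coverage
    controls = [chip_runs[l].a_coverage for l in LINES if l != "miniB496"] + [focal]
    doms = call_unique_domains(focal, controls, "chr9",
                               scale_factor=study.reference.scale_factor)
    assert [d for d in doms if d.unique_to_line] == []


def test_planted_domain_bounds_recovered_within_two_bins(study):
    sf = study.reference.scale_factor
    for s in (701, 702, 703):
        runs = {line: run_chip(study, line, depth=10, seed=s * 10 + i)
                for i, line in enumerate(LINES)}
        controls = [runs[l].a_coverage for l in LINES if l != "miniB496"]
        doms = [d for d in call_unique_domains(runs["miniB496"].a_coverage, controls,
                                               "chr9", scale_factor=sf)
                if d.unique_to_line]
        assert len(doms) == 1
        d = doms[0]
        assert abs(d.start_paper_mb - 9.51) <= 0.002
        assert abs(d.end_paper_mb - 9.67) <= 0.002


def test_negative_lines_never_unique(chip_runs, study):
    sf = study.reference.scale_factor
    for focal in ("B73", "B73+B", "TB-9Sb", "9-Bic-1_het"):
        controls = [chip_runs[l].a_coverage for l in LINES if l != focal]
        doms = call_unique_domains(chip_runs[focal].a_coverage, controls, "chr9",
                                   scale_factor=sf)
        assert [d for d in doms if d.unique_to_line] == [], focal


def test_uniqueness_monotone_under_added_controls(chip_runs, study):
    """Adding controls can revoke uniqueness but never create it."""
    sf = study.reference.scale_factor
    focal = chip_runs["miniB1104"].a_coverage
    subset = [chip_runs["B73"].a_coverage]
    superset = subset + [chip_runs[l].a_coverage
                         for l in ("B73+B", "TB-9Sb", "miniB496")]
    uniq_small = {(d.start, d.end) for d in
                  call_unique_domains(focal, subset, "chr9", scale_factor=sf)
                  if d.unique_to_line}
    uniq_big = {(d.start, d.end) for d in
                call_unique_domains(focal, superset, "chr9", scale_factor=sf)
                if d.unique_to_line}
    assert uniq_big <= uniq_small
    # and control order is irrelevant
    reordered = {(d.start, d.end) for d in
                 call_unique_domains(focal, superset[::-1], "chr9", scale_factor=sf)
                 if d.unique_to_line}
    assert reordered == uniq_big


def test_no_controls_flags_uniqueness_unknown(chip_runs, study):
    doms = call_unique_domains(chip_runs["miniB496"].a_coverage, [], "chr9",
                               scale_factor=study.reference.scale_factor)
    assert doms and all(d.unique_to_line is None for d in doms)


def test_chip_vs_chip_mode_highlights_the_same_domain(chip_runs, study):
    ref = study.reference
    ratio = chip_vs_chip(chip_runs["miniB496"].a_coverage,
                         chip_runs["B73"].a_coverage)
    lo, hi = ref.mb_to_bp(9.52) // 10, ref.mb_to_bp(9.66) // 10
    inside = float(np.mean(ratio["chr9"][lo:hi]))
    outside = float(np.median(ratio["chr9"]))
    assert inside > 5 * outside
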