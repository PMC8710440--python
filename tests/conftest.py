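"""Shared fixtures: small oracle-friendly reference models and the default study."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from minichrom._util import revcomp
from minichrom.pipeline import Study
from minichrom.synthetic_genome import RepeatPlacement, build_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study() -> Study:
    """The default full-scale six-line study (shared, read-only)."""
    return Study.build(seed=7)


@pytest.fixture(scope="session")
def tiny_ref():
    """Repeat-free ~45 kb model: every B k-mer is absent from A (oracle scale)."""
    return build_reference(
        seed=3,
        sizes_mb={"chr9": 2.0, "chrOther": 1.0, "chrB": 1.5},
        scaffold_kb={"B_scaf1": 50.0},
        layout=[],
    )


@pytest.fixture(scope="session")
def repeat_ref():
    """Tiny model with planted shared repeats for multi-mapping tests.

    CentC c0 occurs once on chr9 and once on chrB (so a read inside it is
    unique on A and removed at subtractive stage 1); CentC c1 occurs twice
    on chr9 and once on chrB (multi on A, survives to a unique B hit);
    knob k0 twice on chr9 only.
    """
    layout = [
        RepeatPlacement("chr9", 3000, "CentC", "c0"),
        RepeatPlacement("chr9", 6000, "CentC", "c1"),
        RepeatPlacement("chr9", 9000, "CentC", "c1"),
        RepeatPlacement("chr9", 12000, "knob180", "k0"),
        RepeatPlacement("chr9", 15000, "knob180", "k0"),
        RepeatPlacement("chrB", 2000, "CentC", "c0"),
        RepeatPlacement("chrB", 5000, "CentC", "c1"),
        RepeatPlacement("chrB", 8000, "knob180", "k0"),
    ]
    return build_reference(
        seed=11,
        sizes_mb={"chr9": 2.0, "chrOther": 0.0, "chrB": 1.5},
        scaffold_kb={},
        layout=layout,
        verify_b_unique=True,
    )


def substring_occurrences(read_seq: str, targets: dict[str, str]):
    """Exhaustive oracle: all 0-mismatch placements of a read over both strands.

    A '-' placement means the reverse complement of the read matches the
    forward target at that position (same convention as the mapper).
    """
    hits = []
    for name, seq in targets.items():
        for strand, q in (("+", read_seq), ("-", revcomp(read_seq))):
            if "N" in q:
                continue
            start = seq.find(q)
            while start != -1:
                hits.append((name, start, strand))
                start = seq.find(q, start + 1)
    return hits


@pytest.fixture
def oracle():
    return substring_occurrences


class FakeAlignments:
    """Minimal alignment container for count/coverage unit tests."""

    def __init__(self, placements, contig_names=("chr9",), read_len=100):
        # placements: list of (contig, start)
        self.contig_names = tuple(contig_names)
        self._by_contig = {c: [] for c in self.contig_names}
        for c, s in placements:
            self._by_contig[c].append(s)
        self.read_len = read_len
        self.n = len(placements)

    def __len__(self):
        return self.n

    def on_contig(self, contig):
        starts = np.asarray(sorted(self._by_contig.get(contig, [])), dtype=np.int64)
        return starts, np.full(len(starts), self.read_len, dtype=np.int64)


@pytest.fixture
def fake_alignments():
    return FakeAlignments
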