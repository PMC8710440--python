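"""Scaled synthetic maize A/B reference models and line karyotypes.

The package analyses derivatives of the maize B chromosome at desk scale.
Instead of the ~2.1 Gb maize genome, a reference *model* is built in which
one paper-megabase (paper-Mb) of chromosome corresponds to ``scale_factor``
model base pairs (default 10 kb).  The model carries:

``chr9``
    the proximal 15 paper-Mb of chromosome 9 (all breakpoints of interest
    fall in the first 10 Mb of 9S), with a CentC/CRM centromere array and a
    knob180 array;
``chrOther``
    an 85 paper-Mb ballast contig standing in for the remainder of the A
    genome, so that library-size normalization behaves as it does genome
    wide;
``chrB``
    the proximal 8 paper-Mb of the B chromosome: a proximal centromere
    region with ZmBs arrays, plus scattered single copies of CentC / CRM /
    knob180 monomers whose identical partners sit in the A-genome arrays
    (the source of the cross-homology background in deficiency mapping);
``B_scaf1..3``
    unplaced B centromeric scaffolds (575 paper-kb total) of B-specific
    sequence with ZmBs arrays.

Repeat monomers of a "shared" family are exact copies across contigs, so
reads simulated from them multi-map exactly as centromeric satellite reads
do; all non-repeat B sequence is random and therefore shares no read-length
k-mer with the A contigs (checked at build time).

Karyotypes describe the six study lines as lists of reference segments with
copy numbers, plus the intervals where CENH3 (the centromeric histone H3
variant) is loaded in that line.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import decode_seq, encode_seq, kmer_hashes, rng_for

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

REPEAT_FAMILIES = ("CentC", "CRM", "knob180", "ZmBs")
#: monomer lengths in model bp; CentC keeps its real 156 bp monomer
MONOMER_LEN = {"CentC": 156, "CRM": 300, "knob180": 180, "ZmBs": 150}
SHARED_WITH_A = {"CentC": True, "CRM": True, "knob180": True, "ZmBs": False}


@dataclass(frozen=True)
class RepeatAnnotation:
    """One placed repeat block: ``n_copies`` tandem copies of one monomer variant."""

    contig: str
    start: int
    end: int
    family: str
    shared_with_A: bool
    variant: str = ""
    n_copies: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"repeat {self.variant}: end <= start")
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")


@dataclass(frozen=True)
class GeneWindow:
    """A gene-region counting window (0-based, half-open)."""

    id: str
    contig: str
    start: int
    end: int


@dataclass(frozen=True)
class SegmentSpec:
    """A reference interval contributing to a (derived) chromosome."""

    source_contig: str
    start: int
    end: int
    copies: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end <= start")
        if self.copies < 0:
            raise ValueError("copies < 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ActiveCentromere:
    """An interval of simulated CENH3 loading.

    ``weight`` scales the share of ChIP enrichment the interval attracts
    relative to a fully active centromere (1.0); the partially re-activated
    B centromere of mini B1104 uses a weight < 1.
    """

    contig: str
    start: int
    end: int
    weight: float = 1.0


@dataclass
class Chromosome:
    """An (optionally derived) chromosome: ordered fusion of reference parts."""

    name: str
    parts: list[SegmentSpec]
    copies: int = 1

    @property
    def length(self) -> int:
        return sum(p.length for p in self.parts)


class ReferenceModel:
    """Synthetic reference sequences plus annotations and the coordinate scale."""

    def __init__(
        self,
        sequences: dict[str, str],
        repeat_annotations: list[RepeatAnnotation],
        gene_windows: list[GeneWindow],
        scale_factor: float,
        a_contigs: tuple[str, ...],
        b_contigs: tuple[str, ...],
    ):
        if scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if len(set(sequences)) != len(sequences):
            raise ValueError("contig names not unique")
        self.sequences = sequences
        self.repeat_annotations = repeat_annotations
        self.gene_windows = gene_windows
        self.scale_factor = float(scale_factor)
        self.a_contigs = tuple(a_contigs)
        self.b_contigs = tuple(b_contigs)
        self.codes: dict[str, np.ndarray] = {
            name: encode_seq(seq) for name, seq in sequences.items()
        }
        self._validate()

    # -- coordinates --------------------------------------------------------
    def mb_to_bp(self, paper_mb: float) -> int:
        """paper-Mb -> model bp (model coordinate = paper_Mb * scale_factor)."""
        return int(round(paper_mb * self.scale_factor))

    def bp_to_mb(self, bp: float) -> float:
        return float(bp) / self.scale_factor

    def kb_to_bp(self, paper_kb: float) -> int:
        return int(round(paper_kb * self.scale_factor / 1000.0))

    def contig_length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def b_scaffolds(self) -> tuple[str, ...]:
        return tuple(c for c in self.b_contigs if c != "chrB")

    def repeat_intervals(self, contig: str) -> list[tuple[int, int]]:
        return [(a.start, a.end) for a in self.repeat_annotations if a.contig == contig]

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for ann in self.repeat_annotations:
            if ann.contig not in self.sequences:
                raise ValueError(f"annotation on unknown contig {ann.contig}")
            if ann.end > self.contig_length(ann.contig):
                raise ValueError(f"repeat {ann.variant} outside contig {ann.contig}")
        prev_end: dict[str, int] = {}
        for w in self.gene_windows:
            if w.contig not in self.sequences or w.end > self.contig_length(w.contig):
                raise ValueError(f"gene window {w.id} outside its contig")
            if w.start < prev_end.get(w.contig, 0) and w.start != 0:
                raise ValueError("gene windows overlap or are unsorted")
            prev_end[w.contig] = w.end
        # shared families must occur verbatim on an A contig and a B contig
        by_variant: dict[str, set[str]] = {}
        for ann in self.repeat_annotations:
            by_variant.setdefault(ann.family, set()).add(
                "A" if ann.contig in self.a_contigs else "B"
            )
        for fam, sides in by_variant.items():
            if SHARED_WITH_A[fam] and sides != {"A", "B"}:
                raise ValueError(f"shared family {fam} not present on both A and B")
            if not SHARED_WITH_A[fam] and "A" in sides:
                raise ValueError(f"B-specific family {fam} placed on an A contig")

    def check_b_background_unique(self, read_len: int) -> None:
        """Verify that no read-length k-mer of non-repeat B sequence occurs on A.

        Uses 64-bit rolling k-mer hashes on both strands of the A contigs;
        a hash hit is re-verified by string comparison, so the check is exact.
        """
        a_hashes = []
        for c in self.a_contigs:
            codes = self.codes[c]
            if len(codes) >= read_len:
                a_hashes.append(kmer_hashes(codes, read_len))
                a_hashes.append(kmer_hashes(codes[::-1].copy(), read_len))
        if not a_hashes:
            return
        a_sorted = np.sort(np.concatenate(a_hashes))
        for c in self.b_contigs:
            codes = self.codes[c]
            if len(codes) < read_len:
                continue
            h = kmer_hashes(codes, read_len)
            # positions overlapping a repeat placement are allowed to recur on A
            mask = np.ones(len(h), dtype=bool)
            for s, e in self.repeat_intervals(c):
                lo = max(0, s - read_len + 1)
                mask[lo:e] = False
            idx = np.searchsorted(a_sorted, h[: len(mask)][mask])
            idx = np.clip(idx, 0, len(a_sorted) - 1)
            hits = a_sorted[idx] == h[mask]
            if hits.any():
                pos = np.nonzero(mask)[0][hits][0]
                raise ValueError(
                    f"B background k-mer at {c}:{pos} also occurs on an A contig"
                )


# ---------------------------------------------------------------------------
# default model layout
# ---------------------------------------------------------------------------

#: contig sizes in paper-Mb (scaffolds in paper-kb below)
DEFAULT_SIZES_MB = {"chr9": 15.0, "chrOther": 85.0, "chrB": 8.0}
DEFAULT_SCAFFOLD_KB = {"B_scaf1": 200.0, "B_scaf2": 190.0, "B_scaf3": 185.0}
DEFAULT_SCALE = 10_000.0  # model bp per paper-Mb
DEFAULT_WINDOW_MB = 0.05  # gene-window width, paper-Mb


@dataclass(frozen=True)
class RepeatPlacement:
    """Layout request: n tandem copies of one monomer variant at a position."""

    contig: str
    start: int  # model bp
    family: str
    variant: str
    n_copies: int = 1


def default_repeat_layout(scale: float = DEFAULT_SCALE) -> list[RepeatPlacement]:
    """Repeat layout of the default model (positions in model bp).

    Every shared monomer variant placed on chrB occurs at >= 2 A-genome
    locations, so reads from it multi-map on A (and survive stage 1 of
    subtractive mapping), while its single B copy is uniquely placeable on
    the B side -- reproducing the knob/CentC cross-homology background.
    """

    def bp(paper_mb: float) -> int:
        return int(round(paper_mb * scale))

    lay: list[RepeatPlacement] = []
    # chr9 centromere: two passes over CentC variants (reversed second pass
    # keeps every monomer junction sequence unique), then two CRM elements.
    pos = bp(12.0)
    for v in [f"c{i}" for i in range(8)] + [f"c{i}" for i in range(7, -1, -1)]:
        lay.append(RepeatPlacement("chr9", pos, "CentC", v))
        pos += MONOMER_LEN["CentC"]
    lay.append(RepeatPlacement("chr9", bp(12.26), "CRM", "r0"))
    lay.append(RepeatPlacement("chr9", bp(12.30), "CRM", "r1"))
    # chr9 knob: shuffled single copies
    pos = bp(14.0)
    for v in [f"k{i}" for i in range(6)]:
        lay.append(RepeatPlacement("chr9", pos, "knob180", v))
        pos += MONOMER_LEN["knob180"]
    # chrOther centromere + knob (one more A copy of every shared variant)
    pos = bp(42.5)
    for v in [f"c{i}" for i in range(8)]:
        lay.append(RepeatPlacement("chrOther", pos, "CentC", v))
        pos += MONOMER_LEN["CentC"]
    lay.append(RepeatPlacement("chrOther", bp(42.64), "CRM", "r0"))
    lay.append(RepeatPlacement("chrOther", bp(42.68), "CRM", "r1"))
    pos = bp(60.0)
    for v in [f"k{i}" for i in range(6)]:
        lay.append(RepeatPlacement("chrOther", pos, "knob180", v))
        pos += MONOMER_LEN["knob180"]
    # chrB proximal centromere region (0 - 0.25 paper-Mb): ZmBs array plus
    # single shared monomers
    lay.append(RepeatPlacement("chrB", bp(0.002), "ZmBs", "z0", n_copies=8))
    lay.append(RepeatPlacement("chrB", bp(0.16), "CentC", "c0"))
    lay.append(RepeatPlacement("chrB", bp(0.19), "CentC", "c1"))
    lay.append(RepeatPlacement("chrB", bp(0.22), "CRM", "r0"))
    # knob monomers along the B arm (the centromeric-knob neighbourhood
    # starts just distal of 2.1 paper-Mb) and further scattered homology
    for mb, v in [(2.15, "k0"), (3.5, "k1"), (4.8, "k2"), (6.1, "k3"), (7.4, "k4")]:
        lay.append(RepeatPlacement("chrB", bp(mb), "knob180", v))
    for mb, v in [(3.0, "c2"), (5.0, "c3"), (6.5, "c4")]:
        lay.append(RepeatPlacement("chrB", bp(mb), "CentC", v))
    lay.append(RepeatPlacement("chrB", bp(5.5), "CRM", "r1"))
    # scaffolds: ZmBs only; their unique background is B-specific sequence
    lay.append(RepeatPlacement("B_scaf1", 100, "ZmBs", "z0", n_copies=3))
    lay.append(RepeatPlacement("B_scaf2", 150, "ZmBs", "z0", n_copies=2))
    lay.append(RepeatPlacement("B_scaf3", 200, "ZmBs", "z0", n_copies=2))
    return lay


def build_reference(
    seed: int,
    scale_factor: float = DEFAULT_SCALE,
    sizes_mb: dict[str, float] | None = None,
    scaffold_kb: dict[str, float] | None = None,
    layout: list[RepeatPlacement] | None = None,
    window_mb: float = DEFAULT_WINDOW_MB,
    read_len: int = 100,
    verify_b_unique: bool = True,
) -> ReferenceModel:
    """Build the synthetic reference model.

    Deterministic for a fixed ``seed``.  ``layout=[]`` builds a repeat-free
    model (useful for oracle tests); ``layout=None`` uses the default.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    sizes_mb = dict(DEFAULT_SIZES_MB if sizes_mb is None else sizes_mb)
    scaffold_kb = dict(DEFAULT_SCAFFOLD_KB if scaffold_kb is None else scaffold_kb)
    lengths = {c: int(round(mb * scale_factor)) for c, mb in sizes_mb.items() if mb > 0}
    for c, kb in scaffold_kb.items():
        if kb > 0:
            lengths[c] = int(round(kb * scale_factor / 1000.0))
    if "chr9" not in lengths or "chrB" not in lengths:
        raise ValueError("model requires at least chr9 and chrB")
    a_contigs = tuple(c for c in ("chr9", "chrOther") if c in lengths)
    b_contigs = tuple(c for c in lengths if c not in a_contigs)
    if layout is None:
        layout = [p for p in default_repeat_layout(scale_factor) if p.contig in lengths]

    # monomer library: deterministic, independent of background draws
    mono_rng = rng_for(seed, 1)
    variants = sorted({(p.family, p.variant) for p in layout})
    monomers = {
        (fam, var): mono_rng.integers(0, 4, size=MONOMER_LEN[fam], dtype=np.uint8)
        for fam, var in variants
    }

    bg_rng = rng_for(seed, 2)
    codes: dict[str, np.ndarray] = {}
    for contig in sorted(lengths):  # fixed order => reproducible
        codes[contig] = bg_rng.integers(0, 4, size=lengths[contig], dtype=np.uint8)

    annotations: list[RepeatAnnotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for p in sorted(layout, key=lambda p: (p.contig, p.start)):
        if p.contig not in lengths:
            raise ValueError(f"placement on unknown contig {p.contig}")
        block = np.tile(monomers[(p.family, p.variant)], p.n_copies)
        end = p.start + len(block)
        if p.start < 0 or end > lengths[p.contig]:
            raise ValueError(
                f"repeat {p.variant} does not fit on {p.contig} "
                f"(scale too small for the requested layout)"
            )
        for s, e in occupied[p.contig]:
            if p.start < e and s < end:
                raise ValueError(f"overlapping repeat layout on {p.contig}")
        occupied[p.contig].append((p.start, end))
        codes[p.contig][p.start:end] = block
        annotations.append(
            RepeatAnnotation(
                contig=p.contig,
                start=p.start,
                end=end,
                family=p.family,
                shared_with_A=SHARED_WITH_A[p.family],
                variant=p.variant,
                n_copies=p.n_copies,
            )
        )

    window_bp = int(round(window_mb * scale_factor))
    if window_bp < 1:
        raise ValueError("scale too small for the requested gene windows")
    gene_windows = [
        GeneWindow(id=f"G9_{i + 1:04d}", contig="chr9", start=s, end=min(s + window_bp, lengths["chr9"]))
        for i, s in enumerate(range(0, lengths["chr9"], window_bp))
        if min(s + window_bp, lengths["chr9"]) - s == window_bp
    ]

    ref = ReferenceModel(
        sequences={c: decode_seq(codes[c]) for c in codes},
        repeat_annotations=annotations,
        gene_windows=gene_windows,
        scale_factor=scale_factor,
        a_contigs=a_contigs,
        b_contigs=b_contigs,
    )
    if verify_b_unique:
        ref.check_b_background_unique(read_len)
    return ref


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

#: breakpoints and intervals of the study lines, paper-Mb
BIC1_JUNCTION_MB = 3.06  # 9S translocation point of 9-Bic-1 (2.94-3.06 interval)
B1104_9S_MB = (3.06, 3.52)  # 9S segment carried by mini B1104 (~500 kb)
B496_9S_MB = (9.51, 9.67)  # interstitial 9S segment on mini B496 (~160 kb)
B_TRUNCATION_MB = {"miniB1104": 2.1, "9-Bic-1": 2.1, "miniB496": 7.5}
CHR9_CEN_MB = (12.0, 12.33)
OTHER_CEN_MB = (42.5, 42.72)
B_CEN_CHRB_MB = (0.0, 0.25)  # proximal B centromere region on the chrB assembly
B1104_DENOVO_MB = (3.10, 3.35)  # de novo CENH3 domain of mini B1104
B496_DENOVO_MB = (9.51, 9.67)  # de novo CENH3 domain of mini B496
B1104_BCEN_WEIGHT = 0.25  # partial CENH3 re-association at the B1104 B centromere

LINE_NAMES = ("B73", "B73+B", "TB-9Sb", "9-Bic-1_het", "miniB1104", "miniB496")


@dataclass
class Karyotype:
    """A line: chromosomes (with copy counts) plus CENH3-loaded intervals."""

    line_name: str
    chromosomes: list[Chromosome]
    active_centromeres: list[ActiveCentromere] = field(default_factory=list)

    @property
    def segments(self) -> list[SegmentSpec]:
        out = []
        for chrom in self.chromosomes:
            for p in chrom.parts:
                out.append(
                    SegmentSpec(p.source_contig, p.start, p.end, copies=chrom.copies * p.copies)
                )
        return out

    def total_content_bp(self) -> int:
        return sum(c.length * c.copies for c in self.chromosomes)

    def copy_number(self, contig: str, reference: ReferenceModel) -> np.ndarray:
        """Per-base copy number of reference ``contig`` in this line."""
        n = reference.contig_length(contig)
        diff = np.zeros(n + 1, dtype=np.int64)
        for seg in self.segments:
            if seg.source_contig == contig:
                diff[seg.start] += seg.copies
                diff[seg.end] -= seg.copies
        return np.cumsum(diff[:-1])

    def emit_haplotypes(self, reference: ReferenceModel):
        """Yield (name, sequence) for every physical chromosome copy."""
        for chrom in self.chromosomes:
            seq = "".join(
                reference.sequences[p.source_contig][p.start : p.end] for p in chrom.parts
            )
            for i in range(chrom.copies):
                yield f"{self.line_name}|{chrom.name}|{i + 1}", seq

    def validate(self, reference: ReferenceModel) -> None:
        for chrom in self.chromosomes:
            for p in chrom.parts:
                if p.source_contig not in reference.sequences:
                    raise ValueError(f"segment on unknown contig {p.source_contig}")
                if p.end > reference.contig_length(p.source_contig):
                    raise ValueError(f"segment beyond end of {p.source_contig}")
        for ac in self.active_centromeres:
            cn = self.copy_number(ac.contig, reference)
            if not (cn[ac.start : ac.end] >= 1).all():
                raise ValueError(
                    f"active centromere {ac.contig}:{ac.start}-{ac.end} "
                    f"not fully covered in {self.line_name}"
                )


def _scaffold_parts(reference: ReferenceModel) -> list[SegmentSpec]:
    return [SegmentSpec(s, 0, reference.contig_length(s)) for s in reference.b_scaffolds]


def _b_cen_intervals(reference: ReferenceModel, weight: float = 1.0) -> list[ActiveCentromere]:
    out = [
        ActiveCentromere("chrB", reference.mb_to_bp(B_CEN_CHRB_MB[0]),
                         reference.mb_to_bp(B_CEN_CHRB_MB[1]), weight)
    ]
    for s in reference.b_scaffolds:
        out.append(ActiveCentromere(s, 0, reference.contig_length(s), weight))
    return out


def build_karyotype(
    line_name: str,
    reference: ReferenceModel,
    custom_chromosomes: list[Chromosome] | None = None,
    custom_active: list[ActiveCentromere] | None = None,
) -> Karyotype:
    """Karyotype of one of the six study lines (or ``custom``).

    Lines: B73 (diploid, no B), B73+B and TB-9Sb (active B centromere),
    9-Bic-1_het (one chr9 plus one 9-Bic-1: distal 9S fused to the
    proximal 2.1 paper-Mb of the B, B centromere inactive), miniB1104
    (2x chr9 plus the mini combining 9S 3.06-3.52 Mb with B 0-2.1 Mb,
    de novo centromere at 3.10-3.35 Mb) and miniB496 (2x chr9 plus the
    mini combining B 0-7.5 Mb with 9S 9.51-9.67 Mb, de novo centromere
    on that 9S piece).
    """
    mb = reference.mb_to_bp
    chr9_len = reference.contig_length("chr9")
    have_other = "chrOther" in reference.sequences

    def base_diploid() -> list[Chromosome]:
        out = [Chromosome("chr9", [SegmentSpec("chr9", 0, chr9_len)], copies=2)]
        if have_other:
            out.append(
                Chromosome(
                    "chrOther",
                    [SegmentSpec("chrOther", 0, reference.contig_length("chrOther"))],
                    copies=2,
                )
            )
        return out

    def a_cen() -> list[ActiveCentromere]:
        out = []
        if mb(CHR9_CEN_MB[1]) <= chr9_len:
            out.append(ActiveCentromere("chr9", mb(CHR9_CEN_MB[0]), mb(CHR9_CEN_MB[1])))
        if have_other:
            out.append(ActiveCentromere("chrOther", mb(OTHER_CEN_MB[0]), mb(OTHER_CEN_MB[1])))
        return out

    def full_b() -> Chromosome:
        return Chromosome(
            "B",
            [SegmentSpec("chrB", 0, reference.contig_length("chrB"))] + _scaffold_parts(reference),
        )

    if line_name == "custom":
        if not custom_chromosomes:
            raise ValueError("custom karyotype requires custom_chromosomes")
        kt = Karyotype(line_name, custom_chromosomes, custom_active or [])
    elif line_name == "B73":
        kt = Karyotype(line_name, base_diploid(), a_cen())
    elif line_name in ("B73+B", "TB-9Sb"):
        # TB-9Sb is modelled with the same content as B73+B: what the three
        # analyses see is an active B centromere on B sequence.
        kt = Karyotype(line_name, base_diploid() + [full_b()], a_cen() + _b_cen_intervals(reference))
    elif line_name == "9-Bic-1_het":
        derived = Chromosome(
            "9-Bic-1",
            [SegmentSpec("chr9", mb(BIC1_JUNCTION_MB), chr9_len),
             SegmentSpec("chrB", 0, mb(B_TRUNCATION_MB["9-Bic-1"]))]
            + _scaffold_parts(reference),
        )
        chroms = [Chromosome("chr9", [SegmentSpec("chr9", 0, chr9_len)], copies=1), derived]
        if have_other:
            chroms.append(
                Chromosome(
                    "chrOther",
                    [SegmentSpec("chrOther", 0, reference.contig_length("chrOther"))],
                    copies=2,
                )
            )
        kt = Karyotype(line_name, chroms, a_cen())  # B centromere inactive
    elif line_name == "miniB1104":
        mini = Chromosome(
            "miniB1104",
            [SegmentSpec("chr9", mb(B1104_9S_MB[0]), mb(B1104_9S_MB[1])),
             SegmentSpec("chrB", 0, mb(B_TRUNCATION_MB["miniB1104"]))]
            + _scaffold_parts(reference),
        )
        active = a_cen() + [
            ActiveCentromere("chr9", mb(B1104_DENOVO_MB[0]), mb(B1104_DENOVO_MB[1]))
        ] + _b_cen_intervals(reference, weight=B1104_BCEN_WEIGHT)
        kt = Karyotype(line_name, base_diploid() + [mini], active)
    elif line_name == "miniB496":
        mini = Chromosome(
            "miniB496",
            [SegmentSpec("chrB", 0, mb(B_TRUNCATION_MB["miniB496"])),
             SegmentSpec("chr9", mb(B496_9S_MB[0]), mb(B496_9S_MB[1]))]
            + _scaffold_parts(reference),
        )
        active = a_cen() + [
            ActiveCentromere("chr9", mb(B496_DENOVO_MB[0]), mb(B496_DENOVO_MB[1]))
        ]
        kt = Karyotype(line_name, base_diploid() + [mini], active)
    else:
        raise ValueError(f"unknown line {line_name!r}; use one of {LINE_NAMES} or 'custom'")

    kt.validate(reference)
    return kt
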