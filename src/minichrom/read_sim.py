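"""WGS and CENH3 ChIP/input read simulation from a karyotype.

Reads are held in a :class:`ReadBatch`, a column-oriented container (base
codes, lengths, Phred qualities, truth provenance) that the trimmer and the
mapper operate on vectorised; individual :class:`Read` views are available
for inspection and FASTQ round trips.  Truth provenance (source contig,
position, strand) is carried for testing and sidecar output only -- the
analysis modules never read it.

WGS read starts are uniform over the concatenated chromosome copies, so the
expected per-base coverage at a locus of copy number ``c`` is
``depth * c / 2`` (depth is expressed relative to a disomic locus).  ChIP
reads follow a two-component mixture: with probability ``chip_fraction`` a
fragment is drawn from the line's CENH3-loaded intervals (chosen with
probability proportional to interval length x weight, start uniform with
the whole fragment inside the interval), otherwise from the genome-wide
background.  Input libraries are WGS-like.  Paired reads come from a fixed
300 bp fragment; qualities are constant Q35 with an optional low-quality
tail so that trimming has work to do.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import decode_seq, encode_seq, rng_for
from .synthetic_genome import Karyotype, ReferenceModel

PHRED_OFFSET = 33
DEFAULT_READ_LEN = 100
DEFAULT_INSERT = 300
DEFAULT_BASE_Q = 35
DEFAULT_CHIP_FRACTION = 0.3
DEFAULT_CHIP_DEPTH = 10.0


@dataclass
class Read:
    """A single read (materialised view of one ReadBatch row)."""

    id: str
    sequence: str
    qualities: str  # Phred+33
    truth: tuple[str, int, str] | None = None  # (contig, start, strand)


class ReadBatch:
    """Column-oriented read container.

    ``codes`` is an (n, max_len) uint8 matrix (A=0..T=3, 4=N); rows are
    left-aligned and padded; ``lengths`` gives per-read length.  ``qual``
    holds Phred scores (not ASCII).  Truth arrays are optional.
    """

    def __init__(
        self,
        codes: np.ndarray,
        lengths: np.ndarray,
        qual: np.ndarray,
        id_prefix: str = "rd",
        truth_contig: np.ndarray | None = None,
        truth_pos: np.ndarray | None = None,
        truth_strand: np.ndarray | None = None,
        truth_names: tuple[str, ...] = (),
        ids: list[str] | None = None,
    ):
        self.codes = codes
        self.lengths = lengths.astype(np.int32)
        self.qual = qual
        self.id_prefix = id_prefix
        self.truth_contig = truth_contig
        self.truth_pos = truth_pos
        self.truth_strand = truth_strand
        self.truth_names = tuple(truth_names)
        self._ids = ids
        if len(self.lengths) != len(codes) or qual.shape != codes.shape:
            raise ValueError("inconsistent batch shapes")

    def __len__(self) -> int:
        return len(self.lengths)

    def read_id(self, i: int) -> str:
        if self._ids is not None:
            return self._ids[i]
        if self.truth_contig is not None:
            return (
                f"{self.id_prefix}{i}|{self.truth_names[self.truth_contig[i]]}"
                f"|{self.truth_pos[i]}|{'-' if self.truth_strand[i] else '+'}"
            )
        return f"{self.id_prefix}{i}"

    def sequence(self, i: int) -> str:
        return decode_seq(self.codes[i, : self.lengths[i]])

    def quality_string(self, i: int) -> str:
        return (self.qual[i, : self.lengths[i]] + PHRED_OFFSET).tobytes().decode("ascii")

    def truth_of(self, i: int) -> tuple[str, int, str] | None:
        if self.truth_contig is None:
            return None
        return (
            self.truth_names[self.truth_contig[i]],
            int(self.truth_pos[i]),
            "-" if self.truth_strand[i] else "+",
        )

    def read(self, i: int) -> Read:
        return Read(self.read_id(i), self.sequence(i), self.quality_string(i), self.truth_of(i))

    def __iter__(self):
        return (self.read(i) for i in range(len(self)))

    def subset(self, index: np.ndarray) -> "ReadBatch":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return ReadBatch(
            self.codes[index],
            self.lengths[index],
            self.qual[index],
            self.id_prefix,
            None if self.truth_contig is None else self.truth_contig[index],
            None if self.truth_pos is None else self.truth_pos[index],
            None if self.truth_strand is None else self.truth_strand[index],
            self.truth_names,
            None if self._ids is None else [self._ids[i] for i in index],
        )

    # -- FASTQ --------------------------------------------------------------
    def to_fastq(self, path) -> None:
        """Write Sanger FASTQ; read ids carry truth provenance after '|'."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.read_id(i)}\n{self.sequence(i)}\n+\n{self.quality_string(i)}\n")

    @classmethod
    def from_fastq(cls, path) -> "ReadBatch":
        """Read Sanger FASTQ; malformed records are skipped with a warning."""
        import warnings

        ids, seqs, quals = [], [], []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                if not header.startswith("@") or len(seq) != len(qual) or not seq:
                    warnings.warn(f"skipping malformed FASTQ record near {header.strip()!r}")
                    continue
                ids.append(header[1:].strip())
                seqs.append(seq)
                quals.append(qual)
        return cls.from_strings(seqs, quals, ids)

    @classmethod
    def from_strings(cls, seqs, quals=None, ids=None, id_prefix="rd") -> "ReadBatch":
        n = len(seqs)
        max_len = max((len(s) for s in seqs), default=0)
        codes = np.full((n, max_len), 4, dtype=np.uint8)
        qual = np.zeros((n, max_len), dtype=np.uint8)
        lengths = np.zeros(n, dtype=np.int32)
        for i, s in enumerate(seqs):
            lengths[i] = len(s)
            codes[i, : len(s)] = encode_seq(s)
            if quals is not None:
                q = np.frombuffer(quals[i].encode("ascii"), dtype=np.uint8)
                if (q < PHRED_OFFSET).any():
                    raise ValueError(f"malformed quality string for read {i}")
                qual[i, : len(s)] = q - PHRED_OFFSET
            else:
                qual[i, : len(s)] = DEFAULT_BASE_Q
        return cls(codes, lengths, qual, id_prefix, ids=list(ids) if ids else None)

    @classmethod
    def from_reads(cls, reads) -> "ReadBatch":
        reads = list(reads)
        return cls.from_strings(
            [r.sequence for r in reads], [r.qualities for r in reads], [r.id for r in reads]
        )


# ---------------------------------------------------------------------------
# haplotype assembly
# ---------------------------------------------------------------------------


class _HaplotypeSet:
    """Concatenated chromosome sequences of a karyotype with truth lookup.

    Each chromosome appears once in the concatenation; its copy number
    enters through sampling weights, never through duplicated sequence.
    """

    def __init__(self, reference: ReferenceModel, karyotype: Karyotype):
        self.contig_names = tuple(reference.sequences)
        name_idx = {c: i for i, c in enumerate(self.contig_names)}
        chunks, unit_bounds, part_starts, part_src, part_off, copies = [], [0], [], [], [], []
        pos = 0
        for chrom in karyotype.chromosomes:
            if chrom.copies == 0:
                continue
            for p in chrom.parts:
                chunks.append(reference.codes[p.source_contig][p.start : p.end])
                part_starts.append(pos)
                part_src.append(name_idx[p.source_contig])
                part_off.append(p.start)
                pos += p.length
            unit_bounds.append(pos)
            copies.append(chrom.copies)
        if pos == 0:
            raise ValueError("empty karyotype: no chromosome content")
        self.codes = np.concatenate(chunks)
        self.unit_start = np.asarray(unit_bounds[:-1], dtype=np.int64)
        self.unit_end = np.asarray(unit_bounds[1:], dtype=np.int64)
        self.unit_copies = np.asarray(copies, dtype=np.int64)
        self.part_start = np.asarray(part_starts, dtype=np.int64)
        self.part_src = np.asarray(part_src, dtype=np.int64)
        self.part_off = np.asarray(part_off, dtype=np.int64)
        self.total_content = int(np.sum((self.unit_end - self.unit_start) * self.unit_copies))

    def sample_starts(self, n: int, span: int, rng: np.random.Generator) -> np.ndarray:
        """n fragment starts uniform over all copies, fragments inside units."""
        allowed = np.maximum(self.unit_end - self.unit_start - span + 1, 0)
        weights = allowed * self.unit_copies
        total = int(weights.sum())
        if total <= 0:
            raise ValueError(f"no chromosome long enough for span {span}")
        r = rng.integers(0, total, size=n)
        cum = np.cumsum(weights)
        unit = np.searchsorted(cum, r, side="right")
        prev = cum[unit] - weights[unit]
        offset = (r - prev) % np.maximum(allowed[unit], 1)
        return self.unit_start[unit] + offset

    def truth(self, starts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        j = np.searchsorted(self.part_start, starts, side="right") - 1
        return self.part_src[j], starts - self.part_start[j] + self.part_off[j]


def _apply_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    sub = (codes + shift) % 4
    codes[mask] = sub[mask]


def _qualities(n: int, read_len: int, base_q: int, low_q_tail_frac: float,
               tail_q: int, rng: np.random.Generator) -> np.ndarray:
    qual = np.full((n, read_len), base_q, dtype=np.uint8)
    if low_q_tail_frac > 0 and n:
        hit = rng.random(n) < low_q_tail_frac
        tail_len = rng.integers(5, max(6, read_len // 3), size=n)
        cols = np.arange(read_len)
        tail_mask = hit[:, None] & (cols[None, :] >= (read_len - tail_len)[:, None])
        qual[tail_mask] = tail_q
    return qual


def _gather_reads(src: np.ndarray, starts: np.ndarray, read_len: int) -> np.ndarray:
    return src[starts[:, None] + np.arange(read_len)[None, :]]


def _orient(codes: np.ndarray, minus: np.ndarray) -> np.ndarray:
    out = codes.copy()
    rc = 3 - codes[minus][:, ::-1]
    out[minus] = rc
    return out


def simulate_wgs(
    reference: ReferenceModel,
    karyotype: Karyotype,
    depth: float,
    read_len: int = DEFAULT_READ_LEN,
    paired: bool = False,
    error_rate: float = 0.0,
    seed: int = 0,
    insert: int = DEFAULT_INSERT,
    base_q: int = DEFAULT_BASE_Q,
    low_q_tail_frac: float = 0.0,
    tail_q: int = 10,
) -> ReadBatch:
    """Simulate whole-genome shotgun reads from a line.

    ``depth`` is fold coverage at a disomic locus; a locus at copy number c
    receives ``depth * c / 2``.  Deterministic for a fixed seed.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    hap = _HaplotypeSet(reference, karyotype)
    rng = rng_for(seed, 11)
    span = insert if paired else read_len
    n_frag = int(round(depth * hap.total_content / (2.0 * read_len * (2 if paired else 1))))
    if n_frag == 0:
        return _empty_batch(read_len, hap)
    starts = hap.sample_starts(n_frag, span, rng)
    minus = rng.integers(0, 2, size=n_frag).astype(bool)
    if paired:
        batch = _emit_pairs(hap, starts, minus, read_len, insert, rng, error_rate,
                            base_q, low_q_tail_frac, tail_q, "wgs")
    else:
        codes = _orient(_gather_reads(hap.codes, starts, read_len), minus)
        _apply_errors(codes, error_rate, rng)
        src, pos = hap.truth(starts)
        batch = ReadBatch(
            codes,
            np.full(n_frag, read_len, dtype=np.int32),
            _qualities(n_frag, read_len, base_q, low_q_tail_frac, tail_q, rng),
            "wgs",
            src.astype(np.int16),
            pos,
            minus.astype(np.int8),
            tuple(reference.sequences),
        )
    return batch


def _empty_batch(read_len: int, hap: _HaplotypeSet) -> ReadBatch:
    z = np.zeros((0, read_len), dtype=np.uint8)
    return ReadBatch(z, np.zeros(0, dtype=np.int32), z.copy(), "wgs",
                     np.zeros(0, dtype=np.int16), np.zeros(0, dtype=np.int64),
                     np.zeros(0, dtype=np.int8), hap.contig_names)


def _emit_pairs(hap, frag_starts, frag_minus, read_len, insert, rng, error_rate,
                base_q, low_q_tail_frac, tail_q, prefix) -> ReadBatch:
    """Two mates per fragment: 5' read forward, 3' read reverse-complemented."""
    n = len(frag_starts)
    left = _gather_reads(hap.codes, frag_starts, read_len)
    right_start = frag_starts + insert - read_len
    right = _gather_reads(hap.codes, right_start, read_len)
    codes = np.empty((2 * n, read_len), dtype=np.uint8)
    pos = np.empty(2 * n, dtype=np.int64)
    strand = np.empty(2 * n, dtype=np.int8)
    # mate 1 at even rows, mate 2 at odd rows
    plus = ~frag_minus
    codes[0::2][plus] = left[plus]
    codes[0::2][frag_minus] = 3 - right[frag_minus][:, ::-1]
    codes[1::2][plus] = 3 - right[plus][:, ::-1]
    codes[1::2][frag_minus] = left[frag_minus]
    pos[0::2] = np.where(plus, frag_starts, right_start)
    pos[1::2] = np.where(plus, right_start, frag_starts)
    strand[0::2] = frag_minus.astype(np.int8)
    strand[1::2] = (~frag_minus).astype(np.int8)
    _apply_errors(codes, error_rate, rng)
    src1, p1 = hap.truth(pos[0::2])
    src2, p2 = hap.truth(pos[1::2])
    src = np.empty(2 * n, dtype=np.int16)
    src[0::2], src[1::2] = src1, src2
    tpos = np.empty(2 * n, dtype=np.int64)
    tpos[0::2], tpos[1::2] = p1, p2
    return ReadBatch(
        codes,
        np.full(2 * n, read_len, dtype=np.int32),
        _qualities(2 * n, read_len, base_q, low_q_tail_frac, tail_q, rng),
        prefix,
        src,
        tpos,
        strand,
        hap.contig_names,
    )


def simulate_chip(
    reference: ReferenceModel,
    karyotype: Karyotype,
    enrichment_intervals=None,
    chip_fraction: float = DEFAULT_CHIP_FRACTION,
    depth: float = DEFAULT_CHIP_DEPTH,
    read_len: int = DEFAULT_READ_LEN,
    paired: bool = True,
    insert: int = DEFAULT_INSERT,
    error_rate: float = 0.0,
    seed: int = 0,
    base_q: int = DEFAULT_BASE_Q,
    low_q_tail_frac: float = 0.0,
    tail_q: int = 10,
) -> tuple[ReadBatch, ReadBatch]:
    """Simulate a CENH3 ChIP library and its matched input.

    ChIP fragments come from a two-component mixture: with probability
    ``chip_fraction`` from the karyotype's active-centromere intervals
    (interval chosen proportional to length x weight, fragment uniform and
    wholly inside), otherwise genome-wide.  Returns (chip, input) batches.
    """
    if not 0.0 <= chip_fraction <= 1.0:
        raise ValueError("chip_fraction must be in [0, 1]")
    intervals = karyotype.active_centromeres if enrichment_intervals is None else enrichment_intervals
    if chip_fraction > 0 and not intervals:
        raise ValueError("no active centromere intervals but chip_fraction > 0")
    hap = _HaplotypeSet(reference, karyotype)
    name_idx = {c: i for i, c in enumerate(hap.contig_names)}
    span = insert if paired else read_len
    for ac in intervals:
        cn = karyotype.copy_number(ac.contig, reference)
        if not (cn[ac.start : ac.end] >= 1).all():
            raise ValueError(f"active interval {ac.contig}:{ac.start}-{ac.end} not in a retained segment")
        if ac.end - ac.start < span:
            raise ValueError(f"active interval {ac.contig}:{ac.start}-{ac.end} shorter than fragment")
    rng = rng_for(seed, 13)
    n_frag = int(round(depth * hap.total_content / (2.0 * read_len * (2 if paired else 1))))

    # -- ChIP fragment positions: sampled in *reference* coordinates for the
    # enriched component (every physical copy carries identical sequence)
    enriched = rng.random(n_frag) < chip_fraction
    n_enr = int(enriched.sum())
    frag_contig = np.full(n_frag, -1, dtype=np.int64)  # -1 => background (haplotype coords)
    frag_pos = np.empty(n_frag, dtype=np.int64)
    if n_enr:
        w = np.array([max(ac.end - ac.start - span + 1, 0) * ac.weight for ac in intervals])
        if w.sum() <= 0:
            raise ValueError("active intervals too short for the fragment length")
        which = rng.choice(len(intervals), size=n_enr, p=w / w.sum())
        offs = rng.random(n_enr)
        for i, ac in enumerate(intervals):
            sel = which == i
            lo, hi = ac.start, ac.end - span + 1
            frag_pos[np.nonzero(enriched)[0][sel]] = lo + (offs[sel] * (hi - lo)).astype(np.int64)
            frag_contig[np.nonzero(enriched)[0][sel]] = name_idx[ac.contig]
    n_bg = n_frag - n_enr
    if n_bg:
        frag_pos[~enriched] = hap.sample_starts(n_bg, span, rng)
    minus = rng.integers(0, 2, size=n_frag).astype(bool)

    chip = _emit_mixture(reference, hap, frag_contig, frag_pos, minus, read_len, insert,
                         paired, rng, error_rate, base_q, low_q_tail_frac, tail_q)
    input_ = simulate_wgs(reference, karyotype, depth, read_len, paired, error_rate,
                          seed=seed + 1, insert=insert, base_q=base_q,
                          low_q_tail_frac=low_q_tail_frac, tail_q=tail_q)
    input_.id_prefix = "inp"
    return chip, input_


def _emit_mixture(reference, hap, frag_contig, frag_pos, minus, read_len, insert,
                  paired, rng, error_rate, base_q, low_q_tail_frac, tail_q) -> ReadBatch:
    """Emit ChIP reads; enriched fragments are sliced from reference contigs,
    background fragments from the haplotype concatenation."""
    bg = frag_contig < 0
    # translate background haplotype positions to reference coordinates; the
    # read *sequence* is still taken from the haplotype (junction fidelity)
    n = len(frag_pos)
    span = insert if paired else read_len

    def slice_at(starts, which_bg, length_offset=0, length=read_len):
        out = np.empty((len(starts), length), dtype=np.uint8)
        if which_bg.any():
            out[which_bg] = _gather_reads(hap.codes, starts[which_bg] + length_offset, length)
        fg = ~which_bg
        if fg.any():
            idx = starts[fg] + length_offset
            cont = frag_contig[fg]
            for ci in np.unique(cont):
                m = cont == ci
                out_rows = np.nonzero(fg)[0][m]
                out[out_rows] = _gather_reads(
                    reference.codes[hap.contig_names[ci]], idx[m], length
                )
        return out

    def truth_at(starts):
        src = np.empty(n, dtype=np.int64)
        pos = np.empty(n, dtype=np.int64)
        if bg.any():
            s, p = hap.truth(starts[bg])
            src[bg], pos[bg] = s, p
        fg = ~bg
        src[fg], pos[fg] = frag_contig[fg], starts[fg]
        return src.astype(np.int16), pos

    if not paired:
        codes = _orient(slice_at(frag_pos, bg), minus)
        _apply_errors(codes, error_rate, rng)
        src, pos = truth_at(frag_pos)
        return ReadBatch(codes, np.full(n, read_len, dtype=np.int32),
                         _qualities(n, read_len, base_q, low_q_tail_frac, tail_q, rng),
                         "chip", src, pos, minus.astype(np.int8), hap.contig_names)

    left = slice_at(frag_pos, bg, 0)
    right = slice_at(frag_pos, bg, insert - read_len)
    right_start = frag_pos + insert - read_len
    codes = np.empty((2 * n, read_len), dtype=np.uint8)
    pos_arr = np.empty(2 * n, dtype=np.int64)
    strand = np.empty(2 * n, dtype=np.int8)
    plus = ~minus
    codes[0::2][plus] = left[plus]
    codes[0::2][minus] = 3 - right[minus][:, ::-1]
    codes[1::2][plus] = 3 - right[plus][:, ::-1]
    codes[1::2][minus] = left[minus]
    pos_arr[0::2] = np.where(plus, frag_pos, right_start)
    pos_arr[1::2] = np.where(plus, right_start, frag_pos)
    strand[0::2] = minus.astype(np.int8)
    strand[1::2] = plus.astype(np.int8)
    _apply_errors(codes, error_rate, rng)
    src1, p1 = truth_at(pos_arr[0::2])
    src2, p2 = truth_at(pos_arr[1::2])
    src = np.empty(2 * n, dtype=np.int16)
    src[0::2], src[1::2] = src1, src2
    tpos = np.empty(2 * n, dtype=np.int64)
    tpos[0::2], tpos[1::2] = p1, p2
    return ReadBatch(codes, np.full(2 * n, read_len, dtype=np.int32),
                     _qualities(2 * n, read_len, base_q, low_q_tail_frac, tail_q, rng),
                     "chip", src, tpos, strand, hap.contig_names)
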