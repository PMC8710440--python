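"""Quality trimming, exact unique read placement, and subtractive mapping.

The study's pipeline maps reads with an external aligner and then filters
the SAM to 0-mismatch, uniquely-mapped records.  In the filtered limit that
contract is exact-match unique search, which is what the built-in
:class:`ExactMatcher` implements: a read is reported iff it matches exactly
one location, on either strand, across the whole target set, with zero
mismatches.  Any object with the same ``classify`` signature can be
substituted (the adapter seam for wrapping a real aligner); the internal
matcher is the tested default.

Subtractive ("deficiency") mapping routes a read set through two stages:

1. reads that place *uniquely* with 0 mismatches on the A-genome targets
   are regarded as A-chromosome reads and removed; multi-mapping reads
   (e.g. from CentC/knob arrays) survive this stage, which is why shared
   repeats produce a background on the B side even in B-less lines;
2. survivors are matched against the B targets and only unique placements
   are kept.

Counts are conserved: input = A-filtered + B-unique + B-multi + unmapped.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from ._util import encode_seq, header_lines
from .read_sim import PHRED_OFFSET, Read, ReadBatch

DEFAULT_SEED_LEN = 29  # = the MINLEN threshold; 29 bases pack exactly into 58 bits


# ---------------------------------------------------------------------------
# trimming (Trimmomatic-style steps, applied in the order LEADING, TRAILING,
# SLIDINGWINDOW, MINLEN, AVGQUAL)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrimParams:
    leading_q: int = 30
    trailing_q: int = 29
    window_len: int = 4
    window_q: int = 30
    min_len: int = 29
    avg_q: int = 28


def trim_reads(batch: ReadBatch | Iterable[Read], params: TrimParams | None = None, **kw) -> ReadBatch:
    """Quality-trim a read batch.

    Leading/trailing bases below their thresholds are removed; the read is
    then truncated at the start of the first ``window_len`` window whose
    mean quality falls below ``window_q``; reads shorter than ``min_len``
    or with mean quality below ``avg_q`` are dropped.  Mates are treated as
    singletons: if one mate is dropped the other is retained.
    """
    p = params or TrimParams(**kw)
    if min(p.leading_q, p.trailing_q, p.window_q, p.avg_q) < 0 or p.window_len < 1:
        raise ValueError("trim thresholds must be non-negative")
    if not isinstance(batch, ReadBatch):
        batch = ReadBatch.from_reads(batch)
    n, max_len = batch.codes.shape
    if n == 0:
        return batch
    L = batch.lengths.astype(np.int64)
    uniform = bool((batch.lengths == max_len).all())
    top = max(p.leading_q, p.trailing_q, p.window_q, p.avg_q)
    if int(L.min()) >= p.min_len:
        qmin = int(batch.qual.min()) if uniform else None
        if qmin is not None and qmin >= top:
            return batch  # nothing to trim at these thresholds
    Q = batch.qual.astype(np.int64)
    cols = np.arange(max_len)
    valid = cols[None, :] < L[:, None]
    if not uniform:
        if int(Q[valid].min()) >= top and int(L.min()) >= p.min_len:
            return batch

    ok_lead = (Q >= p.leading_q) & valid
    start = np.argmax(ok_lead, axis=1)
    start[~ok_lead.any(axis=1)] = L[~ok_lead.any(axis=1)]  # fully trimmed
    ok_trail = (Q >= p.trailing_q) & valid
    end = max_len - np.argmax(ok_trail[:, ::-1], axis=1)
    end[~ok_trail.any(axis=1)] = 0
    end = np.minimum(end, L)

    # sliding window: cut at the first window (inside [start, end)) whose
    # mean quality is below window_q
    w = p.window_len
    C = np.zeros((n, max_len + 1), dtype=np.int64)
    np.cumsum(np.where(valid, Q, 0), axis=1, out=C[:, 1:])
    if max_len >= w:
        winsum = C[:, w:] - C[:, :-w]  # window starting at col j, j <= max_len - w
        pcols = np.arange(max_len - w + 1)
        in_range = (pcols[None, :] >= start[:, None]) & (pcols[None, :] <= (end - w)[:, None])
        bad = (winsum < w * p.window_q) & in_range
        first_bad = np.argmax(bad, axis=1)
        has_bad = bad.any(axis=1)
        end = np.where(has_bad, first_bad, end)
    end = np.maximum(end, start)

    new_len = end - start
    mean_q = np.zeros(n)
    nz = new_len > 0
    mean_q[nz] = (C[np.arange(n), end][nz] - C[np.arange(n), start][nz]) / new_len[nz]
    keep = (new_len >= p.min_len) & (mean_q >= p.avg_q)

    idx = np.nonzero(keep)[0]
    out_max = int(new_len[keep].max()) if idx.size else 0
    gcols = start[keep, None] + np.arange(out_max)[None, :]
    gcols = np.minimum(gcols, max_len - 1)
    sub = batch.subset(idx)
    codes = sub.codes[np.arange(len(idx))[:, None], gcols] if idx.size else np.zeros((0, 0), np.uint8)
    qual = sub.qual[np.arange(len(idx))[:, None], gcols] if idx.size else np.zeros((0, 0), np.uint8)
    pad = np.arange(out_max)[None, :] >= new_len[keep, None]
    if idx.size:
        codes = codes.copy()
        qual = qual.copy()
        codes[pad] = 4
        qual[pad] = 0
    return ReadBatch(
        codes, new_len[keep].astype(np.int32), qual, sub.id_prefix,
        sub.truth_contig, sub.truth_pos, sub.truth_strand, sub.truth_names, sub._ids,
    )


# ---------------------------------------------------------------------------
# exact unique matcher
# ---------------------------------------------------------------------------


class AlignmentRecord(NamedTuple):
    """A unique 0-mismatch read placement."""

    read_id: str
    contig: str
    start: int
    strand: str
    mismatches: int = 0
    n_hits: int = 1


class MapResult:
    """Per-read classification against a target set.

    ``n_hits`` counts verified 0-mismatch placements over both strands of
    all targets; ``contig_idx``/``pos``/``strand`` are valid where
    ``n_hits == 1`` (and -1/-1/0 elsewhere).
    """

    def __init__(self, contig_names, n_hits, contig_idx, pos, strand):
        self.contig_names = tuple(contig_names)
        self.n_hits = n_hits
        self.contig_idx = contig_idx
        self.pos = pos
        self.strand = strand

    @property
    def unique_mask(self) -> np.ndarray:
        return self.n_hits == 1

    @property
    def multi_mask(self) -> np.ndarray:
        return self.n_hits > 1

    @property
    def unmapped_mask(self) -> np.ndarray:
        return self.n_hits == 0


class AlignmentSet:
    """Unique alignments of a batch: array-backed, iterable as records."""

    def __init__(self, batch: ReadBatch, rows: np.ndarray, result: MapResult):
        self.batch = batch
        self.rows = rows  # row indices into batch
        self.contig_names = result.contig_names
        self.contig_idx = result.contig_idx[rows]
        self.pos = result.pos[rows]
        self.strand = result.strand[rows]
        self.lengths = batch.lengths[rows].astype(np.int64)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        for i in range(len(self)):
            yield AlignmentRecord(
                self.batch.read_id(int(self.rows[i])),
                self.contig_names[self.contig_idx[i]],
                int(self.pos[i]),
                "-" if self.strand[i] else "+",
            )

    def on_contig(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, lengths) of alignments on one contig."""
        ci = self.contig_names.index(contig)
        m = self.contig_idx == ci
        return self.pos[m], self.lengths[m]


def _pack_seeds(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit packing of every k-mer (k <= 31); N-containing => invalid."""
    vals = np.zeros(len(codes) - k + 1, dtype=np.uint64)
    bad = np.zeros(len(vals), dtype=bool)
    for i in range(k):
        c = codes[i : i + len(vals)]
        vals = (vals << np.uint64(2)) | (np.minimum(c, 3)).astype(np.uint64)
        bad |= c > 3
    vals[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return vals


class ExactMatcher:
    """Exact-match unique mapper over both strands of a target set.

    Seeds the first ``seed_len`` bases of a query (2-bit exact packing) in a
    sorted index of the forward target strands, verifies every candidate by
    direct base comparison, and counts placements of the query and of its
    reverse complement.  No heuristics: the report equals an exhaustive
    substring scan.
    """

    PAD = 1024  # sentinel gap between contigs; also max supported query length

    def __init__(self, targets: Mapping[str, str] | Mapping[str, np.ndarray],
                 seed_len: int = DEFAULT_SEED_LEN):
        if not 1 <= seed_len <= 31:
            raise ValueError("seed_len must be in 1..31")
        self.seed_len = seed_len
        self.contig_names = tuple(targets)
        chunks, offsets = [], []
        pos = 0
        for name in self.contig_names:
            t = targets[name]
            codes = t if isinstance(t, np.ndarray) else encode_seq(t)
            offsets.append(pos)
            chunks.append(codes)
            chunks.append(np.full(self.PAD, 4, dtype=np.uint8))
            pos += len(codes) + self.PAD
        self.genome = np.concatenate(chunks) if chunks else np.zeros(0, np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.contig_lengths = {n: len(targets[n]) for n in self.contig_names}
        seed_vals, seed_gpos = [], []
        for name, off in zip(self.contig_names, self.offsets):
            ln = self.contig_lengths[name]
            if ln >= seed_len:
                v = _pack_seeds(self.genome[off : off + ln], seed_len)
                keep = v != np.uint64(0xFFFFFFFFFFFFFFFF)
                seed_vals.append(v[keep])
                seed_gpos.append(np.nonzero(keep)[0] + off)
        if seed_vals:
            vals = np.concatenate(seed_vals)
            gpos = np.concatenate(seed_gpos)
            order = np.argsort(vals, kind="stable")
            self.sorted_vals = vals[order]
            self.sorted_gpos = gpos[order]
        else:
            self.sorted_vals = np.zeros(0, dtype=np.uint64)
            self.sorted_gpos = np.zeros(0, dtype=np.int64)

    # -- queries ------------------------------------------------------------
    def _contig_of(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci, gpos - self.offsets[ci]

    def classify(self, batch: ReadBatch | Iterable[Read]) -> MapResult:
        if not isinstance(batch, ReadBatch):
            batch = ReadBatch.from_reads(list(batch))
        n, max_len = batch.codes.shape
        k = self.seed_len
        n_hits = np.zeros(n, dtype=np.int32)
        contig_idx = np.full(n, -1, dtype=np.int32)
        pos = np.full(n, -1, dtype=np.int64)
        strand = np.zeros(n, dtype=np.int8)
        if n == 0 or len(self.sorted_vals) == 0:
            return MapResult(self.contig_names, n_hits, contig_idx, pos, strand)
        L = batch.lengths.astype(np.int64)
        if (batch.lengths == max_len).all():
            has_n = (batch.codes > 3).any(axis=1)
        else:
            cols = np.arange(max_len)
            valid_cols = cols[None, :] < L[:, None]
            has_n = ((batch.codes > 3) & valid_cols).any(axis=1)
        eligible = (L >= k) & (L <= self.PAD) & ~has_n

        # forward seed: first k bases; reverse seed: complement of the last
        # k bases, reversed (= first k of the reverse-complemented read)
        fwd_seed = np.zeros(n, dtype=np.uint64)
        rev_seed = np.zeros(n, dtype=np.uint64)
        idx_rows = np.nonzero(eligible)[0]
        if idx_rows.size == 0:
            return MapResult(self.contig_names, n_hits, contig_idx, pos, strand)
        sub_codes = batch.codes[idx_rows]
        subL = L[idx_rows]
        back = sub_codes[
            np.arange(len(idx_rows))[:, None], subL[:, None] - 1 - np.arange(k)[None, :]
        ]
        f = np.zeros(len(idx_rows), dtype=np.uint64)
        r = np.zeros(len(idx_rows), dtype=np.uint64)
        two = np.uint64(2)
        for i in range(k):
            f = (f << two) | sub_codes[:, i].astype(np.uint64)
            r = (r << two) | (3 - back[:, i]).astype(np.uint64)
        fwd_seed[idx_rows], rev_seed[idx_rows] = f, r

        lo_f = np.searchsorted(self.sorted_vals, fwd_seed, side="left")
        hi_f = np.searchsorted(self.sorted_vals, fwd_seed, side="right")
        lo_r = np.searchsorted(self.sorted_vals, rev_seed, side="left")
        hi_r = np.searchsorted(self.sorted_vals, rev_seed, side="right")
        cf = np.where(eligible, hi_f - lo_f, 0)
        cr = np.where(eligible, hi_r - lo_r, 0)
        tc = cf + cr

        # single-candidate fast path, fully vectorised
        single = tc == 1
        if single.any():
            srows = np.nonzero(single)[0]
            is_f = cf[srows] == 1
            top = len(self.sorted_gpos) - 1
            gpos = np.where(is_f,
                            self.sorted_gpos[np.minimum(lo_f[srows], top)],
                            self.sorted_gpos[np.minimum(lo_r[srows], top)])
            sL = L[srows]
            qmax = int(sL.max())
            # query codes: the read itself (forward) or its reverse complement
            q = np.full((len(srows), qmax), 4, dtype=np.uint8)
            fsel = np.nonzero(is_f)[0]
            rsel = np.nonzero(~is_f)[0]
            if fsel.size:
                q[fsel, :] = batch.codes[srows[fsel], :qmax]
            if rsel.size:
                rr = srows[rsel]
                gidx = np.maximum(L[rr][:, None] - 1 - np.arange(qmax)[None, :], 0)
                rcod = batch.codes[rr[:, None], gidx]
                rcod = np.where(rcod <= 3, 3 - rcod, rcod)
                q[rsel, :] = rcod
            # contig padding (PAD sentinels) guarantees gpos + qmax stays in range
            ref = self.genome[gpos[:, None] + np.arange(qmax)[None, :]]
            if (sL == qmax).all():
                match = (ref == q).all(axis=1)
            else:
                in_len = np.arange(qmax)[None, :] < sL[:, None]
                match = ((ref == q) | ~in_len).all(axis=1)
            ok = srows[match]
            n_hits[ok] = 1
            ci, local = self._contig_of(gpos[match])
            contig_idx[ok] = ci
            pos[ok] = local
            strand[ok] = (~is_f[match]).astype(np.int8)

        # multi-candidate rows: verify each candidate
        multi_rows = np.nonzero(tc >= 2)[0]
        genome = self.genome
        for row in multi_rows:
            ln = int(L[row])
            fq = batch.codes[row, :ln]
            rq = 3 - fq[::-1]
            placements = []
            for q, lo, hi, st in ((fq, lo_f[row], hi_f[row], 0), (rq, lo_r[row], hi_r[row], 1)):
                for j in range(int(lo), int(hi)):
                    g = int(self.sorted_gpos[j])
                    if np.array_equal(genome[g : g + ln], q):
                        placements.append((g, st))
                        if len(placements) > 2:
                            break
            n_hits[row] = len(placements)
            if len(placements) == 1:
                g, st = placements[0]
                ci, local = self._contig_of(np.array([g]))
                contig_idx[row] = ci[0]
                pos[row] = local[0]
                strand[row] = st
        return MapResult(self.contig_names, n_hits, contig_idx, pos, strand)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def map_unique(reads, targets: Mapping[str, str] | ExactMatcher) -> AlignmentSet:
    """Alignments of reads matching exactly one 0-mismatch location.

    ``targets`` is a contig-name -> sequence mapping (or a prebuilt
    matcher).  Multi-hit and unmatched reads are excluded but countable via
    the matcher's :meth:`ExactMatcher.classify`.
    """
    matcher = targets if isinstance(targets, ExactMatcher) else ExactMatcher(targets)
    if not isinstance(reads, ReadBatch):
        reads = ReadBatch.from_reads(list(reads))
    res = matcher.classify(reads)
    return AlignmentSet(reads, np.nonzero(res.unique_mask)[0], res)


@dataclass(frozen=True)
class SubtractiveTally:
    """Read routing tallies of subtractive mapping (counts are conserved)."""

    input: int
    a_filtered: int
    b_unique: int
    b_multi: int
    unmapped: int

    def __post_init__(self):
        if self.input != self.a_filtered + self.b_unique + self.b_multi + self.unmapped:
            raise ValueError("subtractive tally does not conserve read counts")


def subtractive_map(
    reads,
    a_targets: Mapping[str, str] | ExactMatcher,
    b_targets: Mapping[str, str] | ExactMatcher,
) -> tuple[AlignmentSet, SubtractiveTally]:
    """Two-stage A-then-B routing yielding B-specific unique alignments.

    Stage 1 removes reads placing uniquely (0 mismatches) on the A targets;
    stage 2 keeps survivors placing uniquely on the B targets.
    """
    a_matcher = a_targets if isinstance(a_targets, ExactMatcher) else ExactMatcher(a_targets)
    b_matcher = b_targets if isinstance(b_targets, ExactMatcher) else ExactMatcher(b_targets)
    if set(a_matcher.contig_names) & set(b_matcher.contig_names):
        raise ValueError("A and B target name spaces overlap")
    if not isinstance(reads, ReadBatch):
        reads = ReadBatch.from_reads(list(reads))
    a_res = a_matcher.classify(reads)
    survivors = np.nonzero(~a_res.unique_mask)[0]
    sub = reads.subset(survivors)
    b_res = b_matcher.classify(sub)
    b_set = AlignmentSet(sub, np.nonzero(b_res.unique_mask)[0], b_res)
    tally = SubtractiveTally(
        input=len(reads),
        a_filtered=int(a_res.unique_mask.sum()),
        b_unique=int(b_res.unique_mask.sum()),
        b_multi=int(b_res.multi_mask.sum()),
        unmapped=int(b_res.unmapped_mask.sum()),
    )
    return b_set, tally


# ---------------------------------------------------------------------------
# SAM input/output (plain text dialect via pysam)
# ---------------------------------------------------------------------------


def write_sam(alignments: AlignmentSet, path, seed=0, params: dict | None = None) -> None:
    """Write unique alignments as plain SAM with NM (mismatches) and NH tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": int(length)}
            for name, length in _sq_lengths(alignments).items()
        ],
        "CO": [line.lstrip("# ") for line in header_lines(seed, params)],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(len(alignments)):
            row = int(alignments.rows[i])
            a = pysam.AlignedSegment(out.header)
            a.query_name = alignments.batch.read_id(row).split("|")[0]
            a.query_sequence = alignments.batch.sequence(row)
            a.query_qualities = pysam.qualitystring_to_array(
                alignments.batch.quality_string(row)
            )
            a.flag = 16 if alignments.strand[i] else 0
            a.reference_id = int(alignments.contig_idx[i])
            a.reference_start = int(alignments.pos[i])
            a.mapping_quality = 60
            a.cigarstring = f"{int(alignments.lengths[i])}M"
            a.set_tag("NM", 0)
            a.set_tag("NH", 1)
            out.write(a)


def _sq_lengths(alignments: AlignmentSet) -> dict[str, int]:
    # minimal @SQ lengths: far enough to contain every alignment
    out = {}
    for name in alignments.contig_names:
        ci = alignments.contig_names.index(name)
        m = alignments.contig_idx == ci
        end = int((alignments.pos[m] + alignments.lengths[m]).max()) if m.any() else 1
        out[name] = end
    return out


class SamAlignments:
    """Minimal alignment view read back from a SAM file (for stage handoff)."""

    def __init__(self, contig_names, contig_idx, pos, lengths, strand):
        self.contig_names = tuple(contig_names)
        self.contig_idx = contig_idx
        self.pos = pos
        self.lengths = lengths
        self.strand = strand

    def __len__(self):
        return len(self.pos)

    def on_contig(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        ci = self.contig_names.index(contig)
        m = self.contig_idx == ci
        return self.pos[m], self.lengths[m]


def read_sam(path) -> SamAlignments:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        names = list(fh.references)
        ci, pos, ln, st = [], [], [], []
        for rec in fh:
            if rec.is_unmapped:
                continue
            ci.append(rec.reference_id)
            pos.append(rec.reference_start)
            ln.append(rec.query_length or rec.infer_query_length() or 0)
            st.append(1 if rec.is_reverse else 0)
    return SamAlignments(
        names,
        np.asarray(ci, dtype=np.int32),
        np.asarray(pos, dtype=np.int64),
        np.asarray(ln, dtype=np.int64),
        np.asarray(st, dtype=np.int8),
    )


def targets_from(reference, names: Iterable[str]) -> dict[str, np.ndarray]:
    """Target mapping (name -> codes) for a subset of reference contigs."""
    return {n: reference.codes[n] for n in names}
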