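"""Small shared helpers: base coding, rounding, seeds, output headers."""
from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__version__ = "0.1.0"

BASES = "ACGT"
# code 0..3 for ACGT, 4 for anything else (N etc.)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode_seq(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on code arrays; code 4 (N) maps to itself."""
    out = codes[..., ::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)  # odd => invertible mod 2^64


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """64-bit polynomial rolling hashes of every k-mer of a code array.

    H[p] = sum_i codes[p+i] * m^(k-1-i) (mod 2^64), computed without a
    Python loop via prefix sums in the inverse-multiplier basis.  Distinct
    k-mers collide with probability ~2^-64; callers needing exactness must
    re-verify hits by direct comparison.
    """
    L = len(codes)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    with np.errstate(over="ignore"):
        m = _HASH_MULT
        minv = np.uint64(pow(int(m), -1, 1 << 64))
        # inv_pows[i] = minv^i (mod 2^64)
        inv_pows = np.concatenate(
            ([np.uint64(1)], np.multiply.accumulate(np.full(L - 1, minv, dtype=np.uint64)))
        )
        q = np.zeros(L + 1, dtype=np.uint64)
        np.cumsum(codes.astype(np.uint64) * inv_pows, out=q[1:])
        # pows[p] = m^(k-1+p)
        base = np.uint64(pow(int(m), k - 1, 1 << 64))
        pows = base * np.concatenate(
            ([np.uint64(1)], np.multiply.accumulate(np.full(n - 1, m, dtype=np.uint64)))
        )
        return (q[k : k + n] - q[:n]) * pows


def rng_for(seed: int, *tags: int) -> np.random.Generator:
    """Independent generator for (seed, tags); stable across runs."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(t) & 0x7FFFFFFF for t in tags]])


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_step(x: float, step: float) -> float:
    """Round to the nearest multiple of `step`, halves away from zero."""
    return step * round_half_up(x / step, 0)


def config_hash(params: dict) -> str:
    text = repr(sorted((str(k), str(v)) for k, v in params.items()))
    return hashlib.sha1(text.encode()).hexdigest()[:10]


def header_lines(seed, params: dict | None = None, prefix: str = "#") -> list[str]:
    """Provenance header embedded in every text output."""
    params = params or {}
    return [
        f"{prefix} minichrom v{__version__}",
        f"{prefix} seed={seed} config_hash={config_hash(params)}",
    ]
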