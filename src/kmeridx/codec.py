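"""Two-bit k-mer codec, sliding-window enumeration and Hamming neighborhoods.

A k-mer over {A, C, G, T} is packed two bits per base into a 64-bit unsigned
integer with A=0, C=1, G=2, T=3 and the 5'-most base in the most significant
pair.  Alphabetical base order makes integer order match lexicographic order.
k is capped at 31 so a code occupies at most 62 bits, leaving the top bits of
a machine word free for tags elsewhere in the package.
"""
from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterator

import numpy as np

from .errors import AmbiguousBaseError, LengthError, RangeError

MAX_K = 31
BASES = "ACGT"

_BASE_TO_BITS = {b: i for i, b in enumerate(BASES)}

# byte value -> 2-bit base value, -1 for anything that is not ACGT/acgt
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise LengthError(f"k must be in [1, {MAX_K}], got {k}")


def _check_code(code: int, k: int) -> None:
    _check_k(k)
    if not 0 <= code < 4**k:
        raise RangeError(f"code {code} out of range for k={k}")


def encode_kmer(seq: str, k: int) -> int:
    """Pack a k-base ACGT string into its integer code."""
    _check_k(k)
    if len(seq) != k:
        raise LengthError(f"expected a {k}-mer, got {len(seq)} bases")
    code = 0
    for ch in seq.upper():
        try:
            code = (code << 2) | _BASE_TO_BITS[ch]
        except KeyError:
            raise AmbiguousBaseError(f"non-ACGT base {ch!r} in k-mer") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_code(code, k)
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Code of the reverse complement (an involution)."""
    _check_code(code, k)
    out = 0
    for _ in range(k):
        out = (out << 2) | ((code & 3) ^ 3)
        code >>= 2
    return out


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised :func:`revcomp_code` over a uint64 array."""
    _check_k(k)
    codes = codes.astype(np.uint64, copy=True)
    out = np.zeros_like(codes)
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        out = (out << two) | ((codes & three) ^ three)
        codes >>= two
    return out


def hamming(code_a: int, code_b: int, k: int) -> tuple[int, list[int]]:
    """Hamming distance and 1-based mismatch positions (from the 5' end)."""
    _check_code(code_a, k)
    _check_code(code_b, k)
    positions = []
    for p in range(k):
        shift = 2 * (k - 1 - p)
        if (code_a >> shift) & 3 != (code_b >> shift) & 3:
            positions.append(p + 1)
    return len(positions), positions


def window_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-windows of ``seq`` as (offsets, codes) arrays.

    Windows containing any non-ACGT character are skipped; lower-case bases
    are treated as their upper-case equivalents.  Offsets are 0-based and
    ascending.
    """
    _check_k(k)
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(raw) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    vals = _LUT[raw]
    invalid = vals < 0
    # window i is bad iff it covers any invalid base
    csum = np.concatenate(([0], np.cumsum(invalid)))
    bad = (csum[k:] - csum[:-k]) > 0
    v = np.where(invalid, 0, vals).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes |= v[j : j + n] << np.uint64(2 * (k - 1 - j))
    offsets = np.flatnonzero(~bad).astype(np.int64)
    return offsets, codes[offsets]


def enumerate_windows(seq: str, k: int) -> list[tuple[int, int]]:
    """Sliding-window decomposition as a list of (offset, code) pairs."""
    offs, codes = window_codes(seq, k)
    return [(int(o), int(c)) for o, c in zip(offs, codes)]


@lru_cache(maxsize=None)
def _neighbor_plan(k: int, d: int):
    """Precomputed substitution plan for all distance-d neighbors.

    Returns (shifts, deltas, positions): for each of the C(k,d)*3^d rows,
    ``shifts[r, j]`` is the bit shift of the j-th substituted base,
    ``deltas[r, j]`` in {1,2,3} is added (mod 4) to the original base value,
    and ``positions[r]`` is the tuple of 1-based substituted positions.
    """
    pos_combos = list(itertools.combinations(range(k), d))
    alt_combos = list(itertools.product((1, 2, 3), repeat=d))
    n_pos, n_alt = len(pos_combos), len(alt_combos)
    shifts = np.empty((n_pos * n_alt, d), dtype=np.uint64)
    deltas = np.empty((n_pos * n_alt, d), dtype=np.uint64)
    positions = []
    row = 0
    for combo in pos_combos:
        sh = tuple(2 * (k - 1 - p) for p in combo)
        pos1 = tuple(p + 1 for p in combo)
        for alts in alt_combos:
            shifts[row] = sh
            deltas[row] = alts
            positions.append(pos1)
            row += 1
    return shifts, deltas, tuple(positions)


def neighbor_codes(
    code: int, k: int, d_min: int, d_max: int
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, ...]]]:
    """All codes at Hamming distance in [d_min, d_max] from ``code``.

    Returns (codes, distances, mismatch position tuples), grouped by
    ascending distance; each neighbor appears exactly once and the original
    code is included iff d_min == 0.
    """
    _check_code(code, k)
    if not 0 <= d_min <= d_max <= k:
        raise RangeError(f"invalid distance bounds [{d_min}, {d_max}] for k={k}")
    chunks_c, chunks_d, positions = [], [], []
    c64 = np.uint64(code)
    for d in range(d_min, d_max + 1):
        if d == 0:
            chunks_c.append(np.array([code], dtype=np.uint64))
            chunks_d.append(np.zeros(1, dtype=np.uint8))
            positions.append(())
            continue
        shifts, deltas, pos = _neighbor_plan(k, d)
        orig = (c64 >> shifts) & np.uint64(3)
        newb = (orig + deltas) & np.uint64(3)
        # uint64 arithmetic wraps mod 2^64, so subtract-then-add is exact
        diff = ((newb << shifts) - (orig << shifts)).sum(axis=1, dtype=np.uint64)
        chunks_c.append(c64 + diff)
        chunks_d.append(np.full(len(diff), d, dtype=np.uint8))
        positions.extend(pos)
    if not chunks_c:
        return np.empty(0, np.uint64), np.empty(0, np.uint8), []
    return np.concatenate(chunks_c), np.concatenate(chunks_d), positions


def hamming_neighbors(
    code: int, k: int, d_min: int, d_max: int
) -> Iterator[tuple[int, int]]:
    """Yield (neighbor code, distance) for every code within the band."""
    codes, dists, _ = neighbor_codes(code, k, d_min, d_max)
    for c, d in zip(codes, dists):
        yield int(c), int(d)


def neighborhood_size(k: int, d_min: int, d_max: int) -> int:
    """Number of codes at distance in [d_min, d_max]: sum of 3^d * C(k, d)."""
    from math import comb

    return sum(3**d * comb(k, d) for d in range(d_min, d_max + 1))
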