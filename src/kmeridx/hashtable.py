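"""Open-addressing hash table with an invertible Fibonacci hash.

Keys are hashed by multiplication with the odd 64-bit constant nearest
2^64/phi.  An odd multiplier is a bijection modulo 2^64, so the hash can be
inverted with the multiplier's modular inverse, and a slot never needs to
store its key: the home bucket is the top b bits of the hash, the slot
stores only the remaining 64-b bits (the remainder) plus the displacement
from the home bucket under linear probing.  Occupied flag (1 bit) +
displacement (8 bits) + remainder (64-b bits) is the full per-slot
metadata; keys are reconstructed, never stored.

Tables are build-once/query-many: insertion and growth are supported,
deletion is not.
"""
from __future__ import annotations

import numpy as np

from .errors import CapacityError, RangeError

_U64_MASK = (1 << 64) - 1

#: the odd integer nearest 2^64 / phi — the canonical Fibonacci multiplier
MULTIPLIER = 0x9E3779B97F4A7C15
#: modular inverse of MULTIPLIER mod 2^64 (exists because MULTIPLIER is odd)
MULTIPLIER_INVERSE = pow(MULTIPLIER, -1, 1 << 64)

_MULT = np.uint64(MULTIPLIER)
_MULT_INV = np.uint64(MULTIPLIER_INVERSE)

MAX_DISPLACEMENT = 254
MAX_B = 62


def fib_mix(x: int) -> int:
    """Multiplicative (Fibonacci) hash: (x * MULTIPLIER) mod 2^64."""
    return (x * MULTIPLIER) & _U64_MASK


def fib_unmix(h: int) -> int:
    """Inverse hash: (h * MULTIPLIER_INVERSE) mod 2^64."""
    return (h * MULTIPLIER_INVERSE) & _U64_MASK


def fib_mix_array(x: np.ndarray) -> np.ndarray:
    """Vectorised fib_mix over a uint64 array (wraps mod 2^64)."""
    return x.astype(np.uint64, copy=False) * _MULT


def fib_unmix_array(h: np.ndarray) -> np.ndarray:
    return h.astype(np.uint64, copy=False) * _MULT_INV


class FibHashTable:
    """Associative array keyed by integers < 2^63 with 64-bit payloads.

    Parameters
    ----------
    b : int
        log2 of the initial slot capacity.
    max_load : float
        Occupancy fraction above which the table doubles.
    """

    def __init__(self, b: int = 16, max_load: float = 0.7):
        if not 1 <= b <= MAX_B:
            raise CapacityError(f"b must be in [1, {MAX_B}], got {b}")
        if not 0.0 < max_load <= 0.95:
            raise ValueError("max_load must be in (0, 0.95]")
        self.max_load = max_load
        self._n = 0
        # instrumentation: keys asked and slots inspected
        self.lookups = 0
        self.probes = 0
        self._alloc(b)

    def _alloc(self, b: int) -> None:
        cap = 1 << b
        self._b = b
        self._occ = np.zeros(cap, dtype=bool)
        self._disp = np.zeros(cap, dtype=np.uint8)
        self._rem = np.zeros(cap, dtype=np.uint64)
        self._val = np.zeros(cap, dtype=np.uint64)

    # -- basic properties -------------------------------------------------
    @property
    def b(self) -> int:
        return self._b

    @property
    def capacity(self) -> int:
        return 1 << self._b

    @property
    def n_keys(self) -> int:
        return self._n

    @property
    def load_factor(self) -> float:
        return self._n / self.capacity

    @property
    def slot_metadata_bits(self) -> int:
        """Bits of metadata per slot: 1 (occupied) + 8 (displacement) + 64-b."""
        return 1 + 8 + (64 - self._b)

    def __len__(self) -> int:
        return self._n

    def __contains__(self, key: int) -> bool:
        return self.lookup(key) is not None

    # -- insertion --------------------------------------------------------
    def _try_insert(self, key: int, value: int) -> bool:
        """Insert without growing; False if the table must double first."""
        b = self._b
        cap_mask = (1 << b) - 1
        h = fib_mix(key)
        home = h >> (64 - b)
        rem = h & ((1 << (64 - b)) - 1)
        occ, disp, rema = self._occ, self._disp, self._rem
        i, d = home, 0
        while occ[i]:
            if disp[i] == d and rema[i] == rem:
                self._val[i] = value  # re-insert replaces the payload
                return True
            i = (i + 1) & cap_mask
            d += 1
            if d > MAX_DISPLACEMENT:
                return False
        if self._n + 1 > self.max_load * (cap_mask + 1):
            return False
        occ[i] = True
        disp[i] = d
        rema[i] = rem
        self._val[i] = value
        self._n += 1
        return True

    def insert(self, key: int, value: int) -> None:
        """Insert or replace; grows the table when load or probing demand it."""
        if not 0 <= key < 1 << 63:
            raise RangeError("keys must be unsigned and < 2^63 (top bit reserved)")
        if not 0 <= value < 1 << 64:
            raise RangeError("values must fit in 64 bits")
        while not self._try_insert(key, value):
            self._grow()

    def _grow(self) -> None:
        keys, vals = self._contents()
        b = self._b
        while True:
            b += 1
            if b > MAX_B:
                raise CapacityError("table cannot grow beyond 2^62 slots")
            self._alloc(b)
            self._n = 0
            if all(
                self._try_insert(int(k), int(v))
                for k, v in zip(keys.tolist(), vals.tolist())
            ):
                return

    # -- lookup -----------------------------------------------------------
    def lookup(self, key: int):
        """Payload for ``key`` or None if absent."""
        self.lookups += 1
        b = self._b
        cap_mask = (1 << b) - 1
        h = fib_mix(key)
        home = h >> (64 - b)
        rem = h & ((1 << (64 - b)) - 1)
        occ, disp, rema = self._occ, self._disp, self._rem
        i, d = home, 0
        while occ[i]:
            self.probes += 1
            if disp[i] == d and rema[i] == rem:
                return int(self._val[i])
            i = (i + 1) & cap_mask
            d += 1
            if d > cap_mask:  # guard against a full table
                return None
        self.probes += 1  # the terminating empty slot
        return None

    def lookup_many(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched lookup: (found mask, values) aligned with ``keys``."""
        keys = np.ascontiguousarray(keys, dtype=np.uint64)
        n = len(keys)
        self.lookups += n
        b = self._b
        cap_mask = np.uint64((1 << b) - 1)
        h = keys * _MULT
        home_shift = np.uint64(64 - b)
        rem_mask = np.uint64(((1 << (64 - b)) - 1))
        rem = h & rem_mask
        idx = (h >> home_shift).astype(np.int64)
        found = np.zeros(n, dtype=bool)
        values = np.zeros(n, dtype=np.uint64)
        active = np.arange(n)
        d = 0
        cap = 1 << b
        while active.size:
            cur = idx[active]
            self.probes += active.size
            occ = self._occ[cur]
            hit = occ & (self._disp[cur] == d) & (self._rem[cur] == rem[active])
            if hit.any():
                ai = active[hit]
                found[ai] = True
                values[ai] = self._val[cur[hit]]
            resolved = hit | ~occ
            active = active[~resolved]
            if active.size:
                idx[active] = (idx[active] + 1) & int(cap_mask)
                d += 1
                if d > cap:
                    break
        return found, values

    # -- iteration / reconstruction --------------------------------------
    def _contents(self) -> tuple[np.ndarray, np.ndarray]:
        """Reconstruct every (key, value): keys are never stored verbatim."""
        idx = np.flatnonzero(self._occ)
        if idx.size == 0:
            return np.empty(0, np.uint64), np.empty(0, np.uint64)
        cap = self.capacity
        home = (idx - self._disp[idx].astype(np.int64)) % cap
        h = (home.astype(np.uint64) << np.uint64(64 - self._b)) | self._rem[idx]
        keys = h * _MULT_INV
        return keys, self._val[idx].copy()

    def iterate_keys(self):
        """Yield every inserted (key, value) pair, each exactly once."""
        keys, vals = self._contents()
        for k, v in zip(keys.tolist(), vals.tolist()):
            yield k, v

    # -- bitpacked serialisation ------------------------------------------
    def to_state(self) -> dict:
        """Serialisable state with slot metadata at 9 + (64-b) bits/slot."""
        meta = (self._occ.astype(np.uint64) << np.uint64(8)) | self._disp.astype(
            np.uint64
        )
        return {
            "b": self._b,
            "n_keys": self._n,
            "max_load": self.max_load,
            "meta": pack_bits(meta, 9),
            "rem": pack_bits(self._rem, 64 - self._b),
            "values": self._val[self._occ].tobytes(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "FibHashTable":
        b = state["b"]
        table = cls(b=b, max_load=state["max_load"])
        cap = 1 << b
        meta = unpack_bits(state["meta"], 9, cap)
        table._occ = ((meta >> np.uint64(8)) & np.uint64(1)).astype(bool)
        table._disp = (meta & np.uint64(0xFF)).astype(np.uint8)
        table._rem = unpack_bits(state["rem"], 64 - b, cap)
        vals = np.frombuffer(state["values"], dtype=np.uint64)
        table._val = np.zeros(cap, dtype=np.uint64)
        table._val[table._occ] = vals
        table._n = int(table._occ.sum())
        if table._n != state["n_keys"]:
            from .errors import FormatError

            raise FormatError("slot bitstream occupancy disagrees with header")
        return table


def pack_bits(values: np.ndarray, width: int) -> bytes:
    """Pack the low ``width`` bits of each uint64 into a contiguous bitstream."""
    if width == 0:
        return b""
    shifts = np.arange(width - 1, -1, -1, dtype=np.uint64)
    bits = ((values[:, None] >> shifts[None, :]) & np.uint64(1)).astype(np.uint8)
    return np.packbits(bits.ravel()).tobytes()


def unpack_bits(data: bytes, width: int, count: int) -> np.ndarray:
    """Inverse of :func:`pack_bits` for ``count`` values."""
    if width == 0:
        return np.zeros(count, dtype=np.uint64)
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8), count=count * width)
    bits = bits.reshape(count, width).astype(np.uint64)
    out = np.zeros(count, dtype=np.uint64)
    one = np.uint64(1)
    for j in range(width):
        out = (out << one) | bits[:, j]
    return out
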