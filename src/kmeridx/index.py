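"""Genome k-mer index: k-mer code -> (count, locations) over a FASTA assembly.

Every ACGT window of every contig is a key.  The 64-bit table payload uses
one tag bit: tag 0 means the payload is a single packed location inline;
tag 1 means the low bits are an offset into the posting arena, whose entry
is a count followed by that many packed locations.  A location packs
(contig ordinal: 16 bits, 0-based offset: 46 bits, strand: 1 bit) into 63
bits, leaving the tag bit free.
"""
from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import codec
from .errors import ChecksumError, EmptyInputError, FormatError, RangeError
from .fastaio import contig_table_checksum, read_fasta
from .hashtable import FibHashTable

MAGIC = b"KMKY"
FORMAT_VERSION = 1
KIND_GENOME = 1
KIND_VARIANTS = 2

TAG_ARENA = 1 << 63
_LOC_MASK = (1 << 63) - 1

MAX_CONTIGS = 1 << 16
MAX_OFFSET = 1 << 46


@dataclass(frozen=True)
class Location:
    """One occurrence of a k-mer: contig name, 0-based offset, strand."""

    contig: str
    offset: int
    strand: str  # '+' or '-'


def pack_location(contig_ord: int, offset: int, minus: bool = False) -> int:
    if contig_ord >= MAX_CONTIGS or offset >= MAX_OFFSET:
        raise RangeError("location exceeds packing limits")
    return (contig_ord << 47) | (offset << 1) | int(minus)


def unpack_location(packed: int) -> tuple[int, int, bool]:
    packed &= _LOC_MASK
    return packed >> 47, (packed >> 1) & (MAX_OFFSET - 1), bool(packed & 1)


class GenomeIndex:
    """K-mer index over an assembly, answering exact lookups in O(1).

    Parameters are normally supplied by :meth:`build` or :meth:`load`.
    """

    def __init__(
        self,
        k: int,
        strand_mode: str,
        contigs: list[tuple[str, int]],
        table: FibHashTable,
        arena: np.ndarray,
        n_windows: int,
    ):
        if strand_mode not in ("forward", "both"):
            raise ValueError("strand_mode must be 'forward' or 'both'")
        self.k = k
        self.strand_mode = strand_mode
        self.contigs = contigs
        self.table = table
        self.arena = arena
        self.n_windows = n_windows
        self.contig_checksum = contig_table_checksum(contigs)

    # ------------------------------------------------------------------
    @classmethod
    def build(cls, source, k: int, strand_mode: str = "forward", b: int | None = None):
        """Index every valid k-window of a FASTA source (path or dict).

        Locations always record the window as written in the FASTA (strand
        '+'); ``strand_mode='both'`` enables reverse-complement matching at
        query time instead of doubling the index.
        """
        contig_seqs = read_fasta(source)
        if len(contig_seqs) > MAX_CONTIGS:
            raise RangeError("too many contigs for 16-bit ordinals")
        codes_parts, locs_parts = [], []
        contigs = []
        for ordinal, (name, seq) in enumerate(contig_seqs.items()):
            contigs.append((name, len(seq)))
            offs, codes = codec.window_codes(seq, k)
            if offs.size:
                locs = (np.uint64(ordinal << 47)) | (offs.astype(np.uint64) << np.uint64(1))
                codes_parts.append(codes)
                locs_parts.append(locs)
        if codes_parts:
            all_codes = np.concatenate(codes_parts)
            all_locs = np.concatenate(locs_parts)
        else:
            all_codes = np.empty(0, np.uint64)
            all_locs = np.empty(0, np.uint64)
        n_windows = int(all_codes.size)

        order = np.argsort(all_codes, kind="stable")
        sc = all_codes[order]
        sl = all_locs[order]
        if sc.size:
            starts = np.concatenate(([0], np.flatnonzero(sc[1:] != sc[:-1]) + 1))
            ends = np.concatenate((starts[1:], [sc.size]))
        else:
            starts = ends = np.empty(0, np.int64)
        counts = ends - starts
        n_distinct = starts.size

        if b is None:
            b = 4
            while (1 << b) * 0.65 < max(n_distinct, 1):
                b += 1
        table = FibHashTable(b=b)

        arena_size = int((counts[counts >= 2] + 1).sum())
        arena = np.zeros(arena_size, dtype=np.uint64)
        apos = 0
        sc_l = sc.tolist()
        for gi in range(n_distinct):
            s, e = int(starts[gi]), int(ends[gi])
            code = sc_l[s]
            if e - s == 1:
                table.insert(code, int(sl[s]))
            else:
                arena[apos] = e - s
                arena[apos + 1 : apos + 1 + (e - s)] = sl[s:e]
                table.insert(code, TAG_ARENA | apos)
                apos += 1 + (e - s)
        return cls(k, strand_mode, contigs, table, arena, n_windows)

    # ------------------------------------------------------------------
    def _packed_locations(self, value: int) -> list[int]:
        if value & TAG_ARENA:
            pos = value & _LOC_MASK
            count = int(self.arena[pos])
            return self.arena[pos + 1 : pos + 1 + count].tolist()
        return [value]

    def _to_location(self, packed: int, minus: bool = False) -> Location:
        ordinal, offset, stored_minus = unpack_location(packed)
        strand = "-" if (minus ^ stored_minus) else "+"
        return Location(self.contigs[ordinal][0], offset, strand)

    def _forward_hits(self, code: int) -> list[int]:
        value = self.table.lookup(code)
        if value is None:
            return []
        return self._packed_locations(value)

    def exact_query(self, code: int) -> tuple[int, list[Location]]:
        """Count and locations of a k-mer; (0, []) when absent.

        In strand mode 'both', occurrences whose forward window equals the
        reverse complement of the query are reported with strand '-'.
        """
        if not 0 <= code < 4**self.k:
            raise RangeError(f"code {code} out of range for k={self.k}")
        locs = [self._to_location(p) for p in self._forward_hits(code)]
        if self.strand_mode == "both":
            rc = codec.revcomp_code(code, self.k)
            if rc != code:
                locs += [self._to_location(p, minus=True) for p in self._forward_hits(rc)]
        return len(locs), locs

    def counts_many(self, codes: np.ndarray) -> np.ndarray:
        """Forward-strand occurrence count for each code (vectorised)."""
        found, vals = self.table.lookup_many(codes)
        counts = found.astype(np.int64)
        arena_hits = found & (vals >> np.uint64(63) == 1)
        if arena_hits.any():
            pos = (vals[arena_hits] & np.uint64(_LOC_MASK)).astype(np.int64)
            counts[arena_hits] = self.arena[pos].astype(np.int64)
        return counts

    def occurrence_counts(self, codes: np.ndarray) -> np.ndarray:
        """Counts under the index's strand mode."""
        counts = self.counts_many(codes)
        if self.strand_mode == "both":
            rc = codec.revcomp_codes(codes, self.k)
            not_pal = rc != codes.astype(np.uint64)
            if not_pal.any():
                counts[not_pal] += self.counts_many(rc[not_pal])
        return counts

    @property
    def n_distinct(self) -> int:
        return self.table.n_keys

    def stats(self) -> dict:
        return {
            "k": self.k,
            "strand_mode": self.strand_mode,
            "contigs": len(self.contigs),
            "total_length": sum(length for _, length in self.contigs),
            "distinct_kmers": self.n_distinct,
            "total_windows": self.n_windows,
            "capacity": self.table.capacity,
            "load_factor": self.table.load_factor,
        }

    # -- serialisation --------------------------------------------------
    def save(self, path) -> None:
        sections = _genome_sections(self)
        write_container(path, KIND_GENOME, sections)

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        kind, sections = read_container(path)
        if kind != KIND_GENOME:
            raise FormatError("not a genome index file")
        return _genome_from_sections(sections)


# ----------------------------------------------------------------------
# "KMKY" container: magic, version, kind, then length-prefixed sections,
# closed by a CRC32 of everything before it.  Little-endian throughout.
# ----------------------------------------------------------------------


def write_container(path, kind: int, sections: list[bytes]) -> None:
    buf = bytearray()
    buf += MAGIC
    buf += struct.pack("<HB", FORMAT_VERSION, kind)
    buf += struct.pack("<I", len(sections))
    for sec in sections:
        buf += struct.pack("<Q", len(sec))
        buf += sec
    buf += struct.pack("<I", zlib.crc32(bytes(buf)))
    with open(path, "wb") as fh:
        fh.write(bytes(buf))


def read_container(path) -> tuple[int, list[bytes]]:
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 15 or data[:4] != MAGIC:
        raise FormatError("bad magic: not a KMKY index file")
    version, kind = struct.unpack_from("<HB", data, 4)
    if version != FORMAT_VERSION:
        raise FormatError(f"unsupported format version {version}")
    stored_crc = struct.unpack_from("<I", data, len(data) - 4)[0]
    if zlib.crc32(data[:-4]) != stored_crc:
        raise ChecksumError("index file is corrupt (CRC mismatch)")
    (n_sections,) = struct.unpack_from("<I", data, 7)
    sections = []
    pos = 11
    try:
        for _ in range(n_sections):
            (length,) = struct.unpack_from("<Q", data, pos)
            pos += 8
            if pos + length > len(data) - 4:
                raise FormatError("truncated index file")
            sections.append(data[pos : pos + length])
            pos += length
    except struct.error as exc:
        raise FormatError("truncated index file") from exc
    return kind, sections


def _pack_contig_table(contigs: list[tuple[str, int]]) -> bytes:
    out = bytearray(struct.pack("<H", len(contigs)))
    for name, length in contigs:
        raw = name.encode()
        out += struct.pack("<H", len(raw)) + raw + struct.pack("<Q", length)
    return bytes(out)


def _unpack_contig_table(data: bytes) -> list[tuple[str, int]]:
    (n,) = struct.unpack_from("<H", data, 0)
    pos = 2
    contigs = []
    for _ in range(n):
        (ln,) = struct.unpack_from("<H", data, pos)
        pos += 2
        name = data[pos : pos + ln].decode()
        pos += ln
        (length,) = struct.unpack_from("<Q", data, pos)
        pos += 8
        contigs.append((name, length))
    return contigs


def _genome_sections(index: GenomeIndex) -> list[bytes]:
    state = index.table.to_state()
    header = struct.pack(
        "<BBBQQdI",
        index.k,
        0 if index.strand_mode == "forward" else 1,
        state["b"],
        state["n_keys"],
        index.n_windows,
        state["max_load"],
        index.contig_checksum,
    )
    return [
        header,
        _pack_contig_table(index.contigs),
        state["meta"],
        state["rem"],
        state["values"],
        index.arena.tobytes(),
    ]


def _genome_from_sections(sections: list[bytes]) -> GenomeIndex:
    try:
        k, strand, b, n_keys, n_windows, max_load, crc = struct.unpack(
            "<BBBQQdI", sections[0]
        )
        contigs = _unpack_contig_table(sections[1])
        table = FibHashTable.from_state(
            {
                "b": b,
                "n_keys": n_keys,
                "max_load": max_load,
                "meta": sections[2],
                "rem": sections[3],
                "values": sections[4],
            }
        )
        arena = np.frombuffer(sections[5], dtype=np.uint64).copy()
    except (IndexError, struct.error) as exc:
        raise FormatError("malformed genome index sections") from exc
    index = GenomeIndex(
        k, "forward" if strand == 0 else "both", contigs, table, arena, n_windows
    )
    if index.contig_checksum != crc:
        raise ChecksumError("contig table checksum mismatch")
    return index
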