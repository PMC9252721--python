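"""FASTA input and coordinate-based sequence retrieval.

Assemblies here are desk-scale, so contigs are held in memory as plain
strings.  Gzipped files are detected by magic bytes rather than suffix.
"""
from __future__ import annotations

import gzip
import io
import zlib
from pathlib import Path

from Bio import SeqIO

from .errors import (
    DuplicateContigNameError,
    EmptyInputError,
    OutOfBoundsError,
    UnknownContigError,
)


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(source) -> dict[str, str]:
    """Load a (possibly gzipped, multi-contig, wrapped) FASTA into a dict.

    A dict passed in is returned unchanged, which lets every consumer accept
    either a path or an already-loaded assembly.
    """
    if isinstance(source, dict):
        if not source:
            raise EmptyInputError("assembly has no contigs")
        return source
    contigs: dict[str, str] = {}
    with _open_text(source) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise DuplicateContigNameError(f"duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise EmptyInputError(f"no FASTA records in {source}")
    return contigs


def write_fasta(contigs: dict[str, str], path, wrap: int = 60, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            header = f">{name} {description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def fetch_region(source, contig: str, start: int, end: int) -> str:
    """Subsequence of ``contig`` over the 0-based half-open [start, end).

    The result is upper-cased, matching how windows are indexed.
    """
    contigs = read_fasta(source)
    if contig not in contigs:
        raise UnknownContigError(f"contig {contig!r} not in assembly")
    seq = contigs[contig]
    if not 0 <= start < end <= len(seq):
        raise OutOfBoundsError(
            f"[{start}, {end}) outside contig {contig!r} of length {len(seq)}"
        )
    return seq[start:end].upper()


def contig_table_checksum(contigs) -> int:
    """CRC32 over (name, length) pairs; ties an index file to its assembly.

    Accepts either a {name: sequence} dict or a list of (name, length).
    """
    if isinstance(contigs, dict):
        items = [(name, len(seq)) for name, seq in contigs.items()]
    else:
        items = list(contigs)
    payload = "\x00".join(f"{name}\x01{length}" for name, length in items)
    return zlib.crc32(payload.encode())
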