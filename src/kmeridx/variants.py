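"""K-mer representation of variants and the bipartite k-mer -> variant index.

A variant is represented by the set of k-mers of its alternate haplotype
that overlap the altered bases (substitutions, insertions) or span the
deletion junction.  With full reference context a variant with L altered
bases generates L + k - 1 k-mers (SNV: k, deletion: k - 1, insertion of
length L: L + k - 1); fewer near contig edges.  A catalogue of variants
then forms a bipartite graph between k-mer keys and variant records —
several variants may share a k-mer, and one variant always has several
k-mers — indexed in the same hash-table schema as an assembly.
"""
from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field

import numpy as np

from . import codec
from .errors import (
    FormatError,
    RangeError,
    ReferenceMismatchError,
)
from .fastaio import read_fasta
from .hashtable import FibHashTable
from .index import (
    KIND_VARIANTS,
    GenomeIndex,
    read_container,
    write_container,
)

logger = logging.getLogger("kmeridx")

#: default allele-frequency INFO keys, mirroring gnomAD-style population fields
DEFAULT_AF_KEYS = (
    "AF",
    "AF_afr",
    "AF_amr",
    "AF_asj",
    "AF_eas",
    "AF_fin",
    "AF_nfe",
    "AF_oth",
    "AF_sas",
    "AF_popmax",
)


@dataclass
class VariantRecord:
    """One normalized variant (one ALT allele) with its AF metadata."""

    contig: str
    pos: int  # 1-based VCF position
    ref: str
    alt: str
    vtype: str  # SNV / MNV / INS / DEL
    af_values: tuple = ()
    variant_id: int = -1

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open reference interval replaced by the ALT core."""
        pos0 = self.pos - 1
        if len(self.ref) == len(self.alt):
            return pos0, pos0 + len(self.ref)
        return pos0 + 1, pos0 + len(self.ref)


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def _split_alleles(variant: VariantRecord) -> tuple[int, str, str]:
    """(anchor length, ref core, alt core) under VCF left-anchoring.

    For length-changing variants REF and ALT share a leading anchor base that
    is not itself altered; same-length substitutions have no anchor.
    """
    ref, alt = variant.ref, variant.alt
    if len(ref) == len(alt):
        return 0, ref, alt
    if not ref or not alt or ref[0] != alt[0]:
        raise RangeError(
            f"indel at {variant.contig}:{variant.pos} is not left-anchored "
            f"(REF {ref!r}, ALT {alt!r})"
        )
    return 1, ref[1:], alt[1:]


def alt_window(reference, variant: VariantRecord, k: int) -> tuple[str, tuple[int, int]]:
    """Alternate-haplotype window of a variant with (k-1)-base context.

    Returns the alt sequence spanning up to k-1 reference bases on each side
    of the altered bases (clipped at contig edges) and the 0-based half-open
    interval of the altered bases within it — zero-length at the junction
    for a pure deletion.
    """
    contigs = read_fasta(reference)
    if variant.contig not in contigs:
        raise ReferenceMismatchError(f"unknown contig {variant.contig!r}")
    seq = contigs[variant.contig].upper()
    pos0 = variant.pos - 1
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if seq[pos0 : pos0 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} does not match reference at {variant.contig}:{variant.pos}"
        )
    _anchor, _ref_core, alt_core = _split_alleles(variant)
    span_start, span_end = variant.ref_span
    left = seq[max(0, span_start - (k - 1)) : span_start]
    right = seq[span_end : span_end + (k - 1)]
    alt_seq = left + alt_core.upper() + right
    return alt_seq, (len(left), len(left) + len(alt_core))


def variant_kmers(reference, variant: VariantRecord, k: int) -> list[tuple[int, int]]:
    """(code, offset-in-alt-haplotype) for every k-mer the variant generates.

    K-mers must overlap at least one altered base, or for a pure deletion
    contain both bases adjacent to the junction.  Windows containing
    non-ACGT characters are skipped.
    """
    alt_seq, (a, b) = alt_window(reference, variant, k)
    offs, codes = codec.window_codes(alt_seq, k)
    out = []
    for off, code in zip(offs.tolist(), codes.tolist()):
        if a < b:  # substituted/inserted bases present
            if off < b and off + k > a:
                out.append((code, off))
        else:  # zero-length deletion junction at a
            if off <= a - 1 and off + k >= a + 1:
                out.append((code, off))
    return out


@dataclass
class VariantHit:
    """A variant matched by one query window, with its metadata."""

    variant: VariantRecord
    offset_in_alt: int
    in_reference: bool = False


@dataclass
class WindowVariantHits:
    window_index: int  # 1-based
    offset: int
    kmer: str
    hits: list[VariantHit] = field(default_factory=list)


class VariantIndex:
    """Bipartite k-mer -> variant index, queryable like an assembly index."""

    def __init__(
        self,
        k: int,
        af_keys: tuple[str, ...],
        records: list[VariantRecord],
        table: FibHashTable,
        arena: np.ndarray,
        flagged_codes: set[int] | None = None,
        n_skipped: int = 0,
        n_dropped_codes: int = 0,
    ):
        self.k = k
        self.af_keys = tuple(af_keys)
        self.records = records
        self.table = table
        self.arena = arena  # entry: n, then n packed (variant_id << 16 | offset)
        self.flagged_codes = flagged_codes or set()
        self.n_skipped = n_skipped
        self.n_dropped_codes = n_dropped_codes

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def n_distinct_kmers(self) -> int:
        return self.table.n_keys

    # ------------------------------------------------------------------
    @classmethod
    def build(
        cls,
        records: list[VariantRecord],
        reference,
        k: int,
        af_keys: tuple[str, ...] = DEFAULT_AF_KEYS,
        drop_reference_kmers: bool = False,
        assembly_index: GenomeIndex | None = None,
    ) -> "VariantIndex":
        """Build from normalized records; order-independent result.

        Records failing REF verification are logged, counted and skipped.
        K-mers also present in the supplied assembly index are flagged; they
        are removed from the table only when ``drop_reference_kmers`` is set.
        """
        reference = read_fasta(reference)
        # canonical ordering makes the index independent of VCF record order
        ordered = sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt))
        kept: list[VariantRecord] = []
        postings: dict[int, list[int]] = {}
        n_skipped = 0
        for rec in ordered:
            try:
                kmers = variant_kmers(reference, rec, k)
            except ReferenceMismatchError as exc:
                logger.warning("skipping variant: %s", exc)
                n_skipped += 1
                continue
            vid = len(kept)
            rec.variant_id = vid
            kept.append(rec)
            for code, off in kmers:
                postings.setdefault(code, []).append((vid << 16) | off)

        flagged: set[int] = set()
        n_dropped = 0
        if assembly_index is not None:
            if assembly_index.k != k:
                raise RangeError("assembly index k differs from variant k")
            codes = np.fromiter(postings.keys(), dtype=np.uint64, count=len(postings))
            found, _ = assembly_index.table.lookup_many(codes)
            flagged = {int(c) for c in codes[found]}
            if drop_reference_kmers:
                for code in flagged:
                    del postings[code]
                n_dropped = len(flagged)

        n_distinct = len(postings)
        b = 4
        while (1 << b) * 0.65 < max(n_distinct, 1):
            b += 1
        table = FibHashTable(b=b)
        arena_size = sum(len(v) + 1 for v in postings.values())
        arena = np.zeros(arena_size, dtype=np.uint64)
        apos = 0
        for code in sorted(postings):
            entries = postings[code]
            arena[apos] = len(entries)
            arena[apos + 1 : apos + 1 + len(entries)] = entries
            table.insert(code, apos)
            apos += 1 + len(entries)
        return cls(k, af_keys, kept, table, arena, flagged, n_skipped, n_dropped)

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        reference,
        k: int,
        af_keys: tuple[str, ...] = DEFAULT_AF_KEYS,
        drop_reference_kmers: bool = False,
        assembly_index: GenomeIndex | None = None,
    ) -> "VariantIndex":
        records = read_vcf_records(vcf_path, af_keys)
        return cls.build(
            records, reference, k, af_keys, drop_reference_kmers, assembly_index
        )

    # ------------------------------------------------------------------
    def _hits_for_code(self, code: int) -> list[VariantHit]:
        pos = self.table.lookup(code)
        if pos is None:
            return []
        n = int(self.arena[pos])
        out = []
        for packed in self.arena[pos + 1 : pos + 1 + n].tolist():
            vid, off = packed >> 16, packed & 0xFFFF
            out.append(
                VariantHit(self.records[vid], off, in_reference=code in self.flagged_codes)
            )
        return out

    def query(self, seq: str) -> list[WindowVariantHits]:
        """Variants whose k-mer set contains each k-window of ``seq``."""
        offs, codes = codec.window_codes(seq.upper(), self.k)
        seq = seq.upper()
        out = []
        for off, code in zip(offs.tolist(), codes.tolist()):
            out.append(
                WindowVariantHits(
                    window_index=off + 1,
                    offset=off,
                    kmer=seq[off : off + self.k],
                    hits=self._hits_for_code(code),
                )
            )
        return out

    # ------------------------------------------------------------------
    def to_bed(self, path) -> None:
        """Export variants as BED (0-based half-open) with AF columns."""
        with open(path, "w") as fh:
            fh.write(
                "#contig\tstart\tend\tref\talt\tvtype\t"
                + "\t".join(self.af_keys)
                + "\n"
            )
            for rec in self.records:
                start = rec.pos - 1
                end = start + len(rec.ref)
                afs = "\t".join(
                    "." if v is None else f"{v:g}" for v in rec.af_values
                )
                fh.write(
                    f"{rec.contig}\t{start}\t{end}\t{rec.ref}\t{rec.alt}\t"
                    f"{rec.vtype}\t{afs}\n"
                )

    def save(self, path) -> None:
        state = self.table.to_state()
        header = struct.pack(
            "<BBQd", self.k, state["b"], state["n_keys"], state["max_load"]
        )
        meta = json.dumps(
            {
                "af_keys": list(self.af_keys),
                "n_skipped": self.n_skipped,
                "n_dropped_codes": self.n_dropped_codes,
                "flagged_codes": sorted(self.flagged_codes),
                "records": [
                    [r.contig, r.pos, r.ref, r.alt, r.vtype, list(r.af_values)]
                    for r in self.records
                ],
            }
        ).encode()
        write_container(
            path,
            KIND_VARIANTS,
            [header, meta, state["meta"], state["rem"], state["values"],
             self.arena.tobytes()],
        )

    @classmethod
    def load(cls, path) -> "VariantIndex":
        kind, sections = read_container(path)
        if kind != KIND_VARIANTS:
            raise FormatError("not a variant index file")
        try:
            k, b, n_keys, max_load = struct.unpack("<BBQd", sections[0])
            meta = json.loads(sections[1].decode())
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
        except (IndexError, struct.error, json.JSONDecodeError) as exc:
            raise FormatError("malformed variant index sections") from exc
        records = [
            VariantRecord(c, p, r, a, t, tuple(afs), variant_id=i)
            for i, (c, p, r, a, t, afs) in enumerate(meta["records"])
        ]
        return cls(
            k,
            tuple(meta["af_keys"]),
            records,
            table,
            arena,
            set(meta["flagged_codes"]),
            meta["n_skipped"],
            meta["n_dropped_codes"],
        )


def read_vcf_records(
    vcf_path, af_keys: tuple[str, ...] = DEFAULT_AF_KEYS
) -> list[VariantRecord]:
    """Read and split a VCF into per-ALT normalized records.

    Multi-allelic records are split one VariantRecord per ALT; AF INFO keys
    declared with Number=A are matched to their ALT.  Missing AF keys are
    recorded as None rather than raised.
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(vcf_path))
    for v in vcf:
        alts = v.ALT or []
        for ai, alt in enumerate(alts):
            afs = []
            for key in af_keys:
                val = v.INFO.get(key)
                if val is None:
                    afs.append(None)
                elif isinstance(val, (tuple, list, np.ndarray)):
                    afs.append(float(val[ai]) if ai < len(val) else None)
                else:
                    afs.append(float(val))
            records.append(
                VariantRecord(
                    contig=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    vtype=classify_variant(v.REF, alt),
                    af_values=tuple(afs),
                )
            )
    vcf.close()
    return records
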