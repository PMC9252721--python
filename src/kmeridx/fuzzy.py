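"""Fuzzy (Hamming-neighborhood) queries and per-window summaries.

A fuzzy query enumerates every code within the allowed mismatch band of the
query k-mer and performs one exact table lookup per neighbor — exactly
sum over d of 3^d * C(k, d) lookups, each O(1), independent of the size of
the indexed genome.  Summary rows count genome *locations* per distance;
detail rows expose the distinct neighbor sequences with their locations and
a dot-notation rendering of the mismatches.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codec
from .errors import LengthError, RangeError
from .index import GenomeIndex, Location


@dataclass
class FuzzyMatch:
    """One indexed neighbor of a query k-mer."""

    query_code: int
    match_code: int
    distance: int
    mismatch_positions: tuple[int, ...]
    count: int
    locations: list[Location] = field(default_factory=list)


@dataclass
class SummaryRow:
    """Per-window location counts grouped by mismatch distance."""

    window_index: int  # 1-based position of the window in the query
    kmer: str
    n_exact: int
    n_mm1: int
    n_mm2: int
    ambiguous: bool = False


@dataclass
class DetailRow:
    """One matched neighbor of one query window."""

    window_index: int
    query_kmer: str
    match_kmer: str
    distance: int
    rendered: str
    count: int
    locations: list[Location]
    mismatch_positions: tuple[int, ...]


def dot_notation(query_kmer: str, match_kmer: str) -> str:
    """Render a match against its query: '.' where equal, else the match base."""
    if len(query_kmer) != len(match_kmer):
        raise LengthError("query and match k-mers differ in length")
    return "".join(
        "." if q == m else m for q, m in zip(query_kmer.upper(), match_kmer.upper())
    )


def fuzzy_query(
    index: GenomeIndex, code: int, d_min: int = 0, d_max: int = 2
) -> list[FuzzyMatch]:
    """All indexed neighbors of ``code`` at distance in [d_min, d_max].

    Results are sorted by (distance, match code).  Under strand mode 'both'
    each neighbor is also matched against reverse-complement occurrences.
    """
    k = index.k
    if not 0 <= d_min <= d_max <= k:
        raise RangeError(f"invalid distance band [{d_min}, {d_max}]")
    codes, dists, positions = codec.neighbor_codes(code, k, d_min, d_max)
    found, vals = index.table.lookup_many(codes)
    both = index.strand_mode == "both"
    if both:
        rc = codec.revcomp_codes(codes, k)
        not_pal = rc != codes
        rc_found = np.zeros_like(found)
        rc_vals = np.zeros_like(vals)
        if not_pal.any():
            f2, v2 = index.table.lookup_many(rc[not_pal])
            rc_found[not_pal] = f2
            rc_vals[not_pal] = v2
    matches = []
    for i in np.flatnonzero(found | (rc_found if both else found)):
        locs: list[Location] = []
        if found[i]:
            locs += [index._to_location(p) for p in index._packed_locations(int(vals[i]))]
        if both and rc_found[i]:
            locs += [
                index._to_location(p, minus=True)
                for p in index._packed_locations(int(rc_vals[i]))
            ]
        if not locs:
            continue
        matches.append(
            FuzzyMatch(
                query_code=code,
                match_code=int(codes[i]),
                distance=int(dists[i]),
                mismatch_positions=tuple(positions[i]),
                count=len(locs),
                locations=locs,
            )
        )
    matches.sort(key=lambda m: (m.distance, m.match_code))
    return matches


def _iter_windows(seq: str, k: int):
    """(window_index, offset, kmer string, code or None) for every window."""
    seq = seq.upper()
    offs, codes = codec.window_codes(seq, k)
    valid = dict(zip(offs.tolist(), codes.tolist()))
    for off in range(len(seq) - k + 1):
        yield off + 1, off, seq[off : off + k], valid.get(off)


def summarize_windows(index: GenomeIndex, seq: str, d_max: int = 2) -> list[SummaryRow]:
    """One row per k-window of ``seq`` with location counts per distance.

    Windows containing non-ACGT characters are kept, flagged ambiguous, so
    window indices stay aligned with query coordinates.
    """
    k = index.k
    rows = []
    for wi, _off, kmer, code in _iter_windows(seq, k):
        if code is None:
            rows.append(SummaryRow(wi, kmer, 0, 0, 0, ambiguous=True))
            continue
        codes, dists, _ = codec.neighbor_codes(code, k, 0, d_max)
        counts = index.occurrence_counts(codes)
        by_d = [0, 0, 0]
        for d in range(min(d_max, 2) + 1):
            by_d[d] = int(counts[dists == d].sum())
        rows.append(SummaryRow(wi, kmer, by_d[0], by_d[1], by_d[2]))
    return rows


def detail_windows(
    index: GenomeIndex, seq: str, d_min: int = 0, d_max: int = 2
) -> list[DetailRow]:
    """Per-match rows for every window, ordered by (window, distance, code)."""
    k = index.k
    rows = []
    for wi, _off, kmer, code in _iter_windows(seq, k):
        if code is None:
            continue
        for m in fuzzy_query(index, code, d_min, d_max):
            match_kmer = codec.decode_kmer(m.match_code, k)
            rows.append(
                DetailRow(
                    window_index=wi,
                    query_kmer=kmer,
                    match_kmer=match_kmer,
                    distance=m.distance,
                    rendered=dot_notation(kmer, match_kmer),
                    count=m.count,
                    locations=m.locations,
                    mismatch_positions=m.mismatch_positions,
                )
            )
    return rows
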