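"""Coordinate parsing and TSV report rendering.

User-facing coordinates are 1-based inclusive (UCSC style, e.g.
``chr17:7671806-7671856``); everything internal is 0-based half-open.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .errors import InvertedIntervalError, LengthError, ParseError
from .fuzzy import DetailRow, SummaryRow
from .index import Location

logger = logging.getLogger("kmeridx")

# ASCII hyphen or Unicode en-dash between the two coordinates
_REGION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<start>\d+)[-–](?P<end>\d+)$")


@dataclass(frozen=True)
class RegionSpec:
    """A parsed region; ``start``/``end`` are 0-based half-open."""

    contig: str
    start: int
    end: int

    @property
    def user_start(self) -> int:
        return self.start + 1

    @property
    def user_end(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start


def parse_region(text: str) -> RegionSpec:
    """Parse ``contig:start-end`` (1-based inclusive) into a RegionSpec."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ParseError(
            f"cannot parse region {text!r}; expected contig:start-end "
            "(no thousands separators)"
        )
    start, end = int(m.group("start")), int(m.group("end"))
    if start < 1:
        raise ParseError("coordinates are 1-based; start must be >= 1")
    if start > end:
        raise InvertedIntervalError(f"region start {start} > end {end}")
    return RegionSpec(m.group("contig"), start - 1, end)


def render_region(spec: RegionSpec) -> str:
    return f"{spec.contig}:{spec.user_start}-{spec.user_end}"


def render_location(loc: Location, k: int) -> str:
    """1-based inclusive rendering, e.g. ``c1:1-4:+`` for offset 0, k=4."""
    return f"{loc.contig}:{loc.offset + 1}-{loc.offset + k}:{loc.strand}"


@dataclass
class ReportConfig:
    d_min: int = 0
    d_max: int = 2
    max_detail_rows: int = 1000
    summary_path: str | None = None
    detail_path: str | None = None

    def __post_init__(self):
        if self.max_detail_rows < 1:
            raise ValueError("max_detail_rows must be >= 1")


SUMMARY_COLUMNS = ("window_index", "kmer", "n_exact", "n_mm1", "n_mm2", "flag")
DETAIL_COLUMNS = (
    "window_index",
    "query_kmer",
    "distance",
    "match_rendered",
    "count",
    "locations",
    "mismatch_positions",
)


def _summary_line(row: SummaryRow) -> str:
    flag = "ambiguous" if row.ambiguous else "."
    return f"{row.window_index}\t{row.kmer}\t{row.n_exact}\t{row.n_mm1}\t{row.n_mm2}\t{flag}"


def _detail_line(row: DetailRow, k: int) -> str:
    locs = ";".join(render_location(l, k) for l in row.locations)
    pos = ",".join(map(str, row.mismatch_positions))
    return (
        f"{row.window_index}\t{row.query_kmer}\t{row.distance}\t"
        f"{row.rendered}\t{row.count}\t{locs}\t{pos}"
    )


def write_report_tables(
    summary_rows: list[SummaryRow],
    detail_rows: list[DetailRow],
    config: ReportConfig,
    k: int,
) -> dict:
    """Write the summary and detail TSVs, truncating the detail table.

    Detail rows beyond ``max_detail_rows`` go to a sidecar overflow file
    next to the main detail file.  Summary counts are computed upstream of
    truncation and are never affected by it.
    """
    stats = {"summary_rows": len(summary_rows), "detail_rows": len(detail_rows),
             "truncated_rows": 0}
    if config.summary_path:
        with open(config.summary_path, "w") as fh:
            fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
            for row in summary_rows:
                fh.write(_summary_line(row) + "\n")
    if config.detail_path:
        head = detail_rows[: config.max_detail_rows]
        tail = detail_rows[config.max_detail_rows :]
        with open(config.detail_path, "w") as fh:
            fh.write("\t".join(DETAIL_COLUMNS) + "\n")
            for row in head:
                fh.write(_detail_line(row, k) + "\n")
        if tail:
            overflow = str(config.detail_path) + ".overflow"
            with open(overflow, "w") as fh:
                fh.write("\t".join(DETAIL_COLUMNS) + "\n")
                for row in tail:
                    fh.write(_detail_line(row, k) + "\n")
            stats["truncated_rows"] = len(tail)
            stats["overflow_path"] = overflow
            logger.info(
                "detail output truncated to %d rows; %d more written to %s",
                config.max_detail_rows, len(tail), overflow,
            )
    return stats


def rows_to_json(summary_rows, detail_rows, k: int) -> dict:
    """Structured equivalent of the TSV reports."""
    return {
        "summary": [
            {
                "window_index": r.window_index,
                "kmer": r.kmer,
                "n_exact": r.n_exact,
                "n_mm1": r.n_mm1,
                "n_mm2": r.n_mm2,
                "ambiguous": r.ambiguous,
            }
            for r in summary_rows
        ],
        "detail": [
            {
                "window_index": r.window_index,
                "query_kmer": r.query_kmer,
                "distance": r.distance,
                "match_rendered": r.rendered,
                "count": r.count,
                "locations": [render_location(l, k) for l in r.locations],
                "mismatch_positions": list(r.mismatch_positions),
            }
            for r in detail_rows
        ],
    }
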