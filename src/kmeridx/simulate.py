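"""Seeded synthetic genomes, variant sets and the brute-force search oracle.

The generator produces the study substrate for every search test: random
assemblies with repeats planted at known Hamming distances, and SNV/indel
sets placed with full k-mer context so truth counting is unambiguous.  The
oracle, :func:`naive_fuzzy_scan`, compares raw characters at every genome
offset and deliberately shares no code with the codec or hash modules, so
agreement with the index is a meaningful check.

All outputs are deterministic functions of their seed; FASTA descriptions
and VCF headers record the seed used.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Planting:
    """A repeat copied from ``source`` to ``target`` with planted mismatches."""

    contig: str
    source_offset: int
    length: int
    target_offset: int
    mutated_positions: tuple[int, ...]  # 1-based within the repeat
    distance: int


@dataclass
class SimulatedGenome:
    seed: int
    contigs: dict[str, str]
    truth: list[Planting] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    return rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])


def simulate_genome(
    seed: int,
    n_contigs: int = 1,
    lengths: tuple[int, ...] = (10_000,),
    gc: float = 0.41,
    plantings: tuple[dict, ...] = (),
) -> SimulatedGenome:
    """Random assembly with optional planted fuzzy repeats.

    Each planting is a dict with keys ``contig`` (ordinal), ``source``
    (0-based offset), ``length``, and ``targets``: a list of
    (target offset, tuple of 1-based positions to mutate).  Planted regions
    must not overlap one another or their source.
    """
    if len(lengths) == 1 and n_contigs > 1:
        lengths = lengths * n_contigs
    if len(lengths) != n_contigs:
        raise ConfigError("need one length per contig")
    if not 0.0 <= gc <= 1.0:
        raise ConfigError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arrays = [_random_sequence(rng, ln, gc) for ln in lengths]
    names = [f"c{i + 1}" for i in range(n_contigs)]
    truth: list[Planting] = []
    reserved: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_contigs)}

    def _reserve(ci: int, start: int, end: int) -> None:
        if start < 0 or end > lengths[ci]:
            raise ConfigError(f"planting [{start}, {end}) outside contig {ci}")
        for s, e in reserved[ci]:
            if start < e and s < end:
                raise ConfigError("plantings overlap")
        reserved[ci].append((start, end))

    for spec in plantings:
        ci = spec.get("contig", 0)
        src, ln = spec["source"], spec["length"]
        _reserve(ci, src, src + ln)
        for tgt, positions in spec["targets"]:
            _reserve(ci, tgt, tgt + ln)
            copy = arrays[ci][src : src + ln].copy()
            for pos in positions:
                if not 1 <= pos <= ln:
                    raise ConfigError(f"mutation position {pos} outside repeat")
                old = copy[pos - 1]
                choices = _BASES[_BASES != old]
                copy[pos - 1] = rng.choice(choices)
            arrays[ci][tgt : tgt + ln] = copy
            truth.append(
                Planting(
                    contig=names[ci],
                    source_offset=src,
                    length=ln,
                    target_offset=tgt,
                    mutated_positions=tuple(sorted(positions)),
                    distance=len(positions),
                )
            )
    contigs = {
        name: arr.tobytes().decode("ascii") for name, arr in zip(names, arrays)
    }
    return SimulatedGenome(seed=seed, contigs=contigs, truth=truth)


def write_genome_fasta(genome: SimulatedGenome, path, wrap: int = 60) -> None:
    from .fastaio import write_fasta

    write_fasta(genome.contigs, path, wrap=wrap, description=f"simulated seed={genome.seed}")


def write_truth_table(genome: SimulatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# simulated seed={genome.seed}\n")
        fh.write("contig\tsource_offset\tlength\ttarget_offset\tpositions\tdistance\n")
        for p in genome.truth:
            pos = ",".join(map(str, p.mutated_positions))
            fh.write(
                f"{p.contig}\t{p.source_offset}\t{p.length}\t{p.target_offset}\t"
                f"{pos}\t{p.distance}\n"
            )


# ----------------------------------------------------------------------
# variant simulation
# ----------------------------------------------------------------------


@dataclass
class SimulatedVariant:
    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    vtype: str
    af_values: tuple[float, ...]


@dataclass
class SimulatedVariantSet:
    seed: int
    variants: list[SimulatedVariant]
    af_keys: tuple[str, ...]


def simulate_variants(
    contigs: dict[str, str],
    seed: int,
    n_snv: int = 10,
    n_ins: int = 0,
    n_del: int = 0,
    len_range: tuple[int, int] = (1, 3),
    af_keys: tuple[str, ...] = ("AF",),
    k: int = 31,
) -> SimulatedVariantSet:
    """Plant non-overlapping SNVs and indels with full k-mer context.

    Variants are placed at least k + max indel length apart and at least k
    bases from contig edges, on ACGT-only loci, so each variant's k-mer set
    is unambiguous.  REF alleles are taken from (and hence match) the genome.
    Placements whose alternate k-mers occur verbatim anywhere in the genome
    (e.g. insertions duplicating a homopolymer run) are redrawn, so alt
    k-mers are genuinely novel and truth sets are exact.
    """
    rng = np.random.default_rng(seed)
    lo, hi = len_range
    if not 1 <= lo <= hi:
        raise ConfigError("len_range must satisfy 1 <= lo <= hi")
    min_gap = k + hi + 1
    names = list(contigs)
    taken: dict[str, list[int]] = {n: [] for n in names}

    def _place(span: int) -> tuple[str, int] | None:
        for _ in range(2000):
            name = names[int(rng.integers(len(names)))]
            seq = contigs[name]
            if len(seq) < 2 * k + span + 2:
                continue
            pos0 = int(rng.integers(k, len(seq) - k - span))
            if any(abs(pos0 - q) < min_gap for q in taken[name]):
                continue
            region = seq[pos0 - k : pos0 + span + k].upper()
            if any(c not in "ACGT" for c in region):
                continue
            return name, pos0
        return None

    def _alt_kmers_are_novel(name: str, pos0: int, ref: str, alt: str) -> bool:
        """True iff no k-window of the alt haplotype that covers the altered
        bases occurs anywhere in the genome (plain substring search)."""
        seq = contigs[name].upper()
        core = alt if len(ref) == len(alt) else alt[1:]
        span_start = pos0 if len(ref) == len(alt) else pos0 + 1
        span_end = pos0 + len(ref)
        left = seq[max(0, span_start - (k - 1)) : span_start]
        alt_hap = left + core + seq[span_end : span_end + (k - 1)]
        a, b = len(left), len(left) + len(core)
        for off in range(len(alt_hap) - k + 1):
            covers = (
                (off < b and off + k > a)
                if a < b
                else (off <= a - 1 and off + k - 1 >= a)
            )
            if not covers:
                continue
            kmer = alt_hap[off : off + k]
            if any(kmer in contigs[n].upper() for n in names):
                return False
        return True

    def _afs() -> tuple[float, ...]:
        return tuple(round(float(x), 5) for x in rng.uniform(0, 1, size=len(af_keys)))

    variants: list[SimulatedVariant] = []
    plan = ["SNV"] * n_snv + ["INS"] * n_ins + ["DEL"] * n_del
    for vtype in plan:
        length = int(rng.integers(lo, hi + 1)) if vtype != "SNV" else 1
        span = 1 + (length if vtype == "DEL" else 0)
        for _attempt in range(200):
            placed = _place(span)
            if placed is None:
                raise ConfigError("genome too small for the requested variant count")
            name, pos0 = placed
            seq = contigs[name].upper()
            if vtype == "SNV":
                ref = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif vtype == "INS":
                ref = seq[pos0]
                alt = ref + "".join(
                    str(x) for x in rng.choice(list("ACGT"), size=length)
                )
            else:  # DEL: anchor base + `length` deleted bases
                ref = seq[pos0 : pos0 + 1 + length]
                alt = ref[0]
            if _alt_kmers_are_novel(name, pos0, ref, alt):
                taken[name].append(pos0)
                break
        else:
            raise ConfigError("could not place a variant with novel alt k-mers")
        variants.append(
            SimulatedVariant(name, pos0 + 1, ref, alt, vtype, _afs())
        )
    variants.sort(key=lambda v: (v.contig, v.pos))
    return SimulatedVariantSet(seed=seed, variants=variants, af_keys=tuple(af_keys))


def write_variants_vcf(
    vset: SimulatedVariantSet, contigs: dict[str, str], path
) -> None:
    """Deterministic VCF with AF INFO fields and the seed in the header."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=kmeridx-simulate seed={vset.seed}\n")
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for key in vset.af_keys:
            fh.write(
                f'##INFO=<ID={key},Number=A,Type=Float,Description="Simulated allele frequency">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in vset.variants:
            info = ";".join(
                f"{key}={val:g}" for key, val in zip(vset.af_keys, v.af_values)
            )
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


# ----------------------------------------------------------------------
# brute-force oracle
# ----------------------------------------------------------------------


def naive_fuzzy_scan(
    contigs: dict[str, str], query: str, d_max: int
) -> list[tuple[str, int, int, tuple[int, ...]]]:
    """Hamming scan of ``query`` against every genome window.

    Ground-truth oracle: direct character comparison at every offset of
    every contig — no k-mer packing, no hashing.  Windows containing any
    non-ACGT character are excluded (they are never indexed either).
    Returns (contig, 0-based offset, distance, 1-based mismatch positions),
    sorted by (contig, offset).
    """
    query = query.upper()
    k = len(query)
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    hits = []
    for name in sorted(contigs):
        seq = contigs[name].upper()
        if len(seq) < k:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, k)
        acgt = np.isin(arr, _BASES)
        valid = np.lib.stride_tricks.sliding_window_view(acgt, k).all(axis=1)
        mism = windows != q
        dist = mism.sum(axis=1)
        for off in np.flatnonzero(valid & (dist <= d_max)).tolist():
            positions = tuple((np.flatnonzero(mism[off]) + 1).tolist())
            hits.append((name, off, int(dist[off]), positions))
    return hits
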