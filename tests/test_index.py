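"""Genome index: build, exact query, location metadata, serialisation."""
import numpy as np
import pytest

from kmeridx import codec
from kmeridx.errors import (
    ChecksumError,
    EmptyInputError,
    FormatError,
    OutOfBoundsError,
    RangeError,
    UnknownContigError,
)
from kmeridx.fastaio import fetch_region, read_fasta, write_fasta
from kmeridx.index import GenomeIndex, Location, pack_location, unpack_location
from kmeridx.simulate import naive_fuzzy_scan, simulate_genome

from conftest import random_dna


def _counts(index):
    return {
        codec.decode_kmer(key, index.k): index.exact_query(key)[0]
        for key, _ in index.table.iterate_keys()
    }


def test_build_counts_toy(toy_index):
    assert _counts(toy_index) == {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
    assert toy_index.n_windows == 5


def test_build_skips_ambiguous_windows():
    index = GenomeIndex.build({"c1": "ACGNACGT"}, 3)
    assert _counts(index) == {"ACG": 2, "CGT": 1}


def test_build_multi_contig_locations():
    index = GenomeIndex.build({"c1": "AAAA", "c2": "AAAA"}, 4)
    count, locs = index.exact_query(codec.encode_kmer("AAAA", 4))
    assert count == 2
    assert locs == [Location("c1", 0, "+"), Location("c2", 0, "+")]


def test_build_empty_input():
    with pytest.raises(EmptyInputError):
        GenomeIndex.build({}, 4)


def test_exact_query_hits_and_misses(toy_index):
    count, locs = toy_index.exact_query(codec.encode_kmer("ACGT", 4))
    assert count == 2
    assert locs == [Location("c1", 0, "+"), Location("c1", 4, "+")]
    assert toy_index.exact_query(codec.encode_kmer("AAAA", 4)) == (0, [])
    with pytest.raises(RangeError):
        toy_index.exact_query(4**4)


def test_strand_both_reports_reverse_complement_hits():
    index = GenomeIndex.build({"c1": "TACG"}, 4, strand_mode="both")
    count, locs = index.exact_query(codec.encode_kmer("CGTA", 4))
    assert count == 1
    assert locs == [Location("c1", 0, "-")]
    # forward-only index does not see it
    fwd = GenomeIndex.build({"c1": "TACG"}, 4)
    assert fwd.exact_query(codec.encode_kmer("CGTA", 4)) == (0, [])


def test_location_packing_round_trip():
    rng = np.random.default_rng(5)
    for _ in range(1000):
        c = int(rng.integers(0, 1 << 16))
        o = int(rng.integers(0, 1 << 46))
        m = bool(rng.integers(0, 2))
        packed = pack_location(c, o, m)
        assert packed < 1 << 63
        assert unpack_location(packed) == (c, o, m)


def test_save_load_round_trip(toy_index, tmp_path):
    path = tmp_path / "toy.idx"
    toy_index.save(path)
    loaded = GenomeIndex.load(path)
    for code in range(256):
        assert loaded.exact_query(code) == toy_index.exact_query(code)
    assert loaded.contigs == toy_index.contigs
    assert loaded.n_windows == toy_index.n_windows


def test_load_rejects_bad_magic(tmp_path):
    path = tmp_path / "bad.idx"
    path.write_bytes(b"NOPE" + b"\x00" * 40)
    with pytest.raises(FormatError):
        GenomeIndex.load(path)


def test_load_rejects_bad_version(toy_index, tmp_path):
    path = tmp_path / "v.idx"
    toy_index.save(path)
    data = bytearray(path.read_bytes())
    data[4] = 99  # version word
    path.write_bytes(bytes(data))
    with pytest.raises((FormatError, ChecksumError)):
        GenomeIndex.load(path)


def test_load_rejects_truncation(toy_index, tmp_path):
    path = tmp_path / "t.idx"
    toy_index.save(path)
    data = path.read_bytes()
    path.write_bytes(data[: len(data) // 2])
    with pytest.raises((FormatError, ChecksumError)):
        GenomeIndex.load(path)


def test_load_detects_corruption(toy_index, tmp_path):
    path = tmp_path / "c.idx"
    toy_index.save(path)
    data = bytearray(path.read_bytes())
    data[len(data) // 2] ^= 0xFF
    path.write_bytes(bytes(data))
    with pytest.raises((ChecksumError, FormatError)):
        GenomeIndex.load(path)


def test_fetch_region():
    contigs = {"c1": "ACGTACGT"}
    assert fetch_region(contigs, "c1", 1, 5) == "CGTA"
    assert fetch_region(contigs, "c1", 0, 8) == "ACGTACGT"
    with pytest.raises(OutOfBoundsError):
        fetch_region(contigs, "c1", 5, 12)
    with pytest.raises(UnknownContigError):
        fetch_region(contigs, "c2", 0, 4)


def test_fasta_round_trip_gzip_and_wrapping(tmp_path):
    import gzip

    contigs = {"a": "ACGT" * 50, "b": "TTTTGGGG"}
    plain = tmp_path / "x.fa"
    write_fasta(contigs, plain, wrap=13)
    assert read_fasta(plain) == contigs
    gz = tmp_path / "x.fa.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(plain.read_text())
    assert read_fasta(gz) == contigs


def test_soft_masked_bases_are_indexed_uppercase():
    index = GenomeIndex.build({"c1": "acgtACGT"}, 4)
    assert index.exact_query(codec.encode_kmer("ACGT", 4))[0] == 2


@pytest.mark.parametrize("seed,k", [(1, 5), (2, 11), (3, 25)])
def test_count_conservation_and_oracle_spotcheck(seed, k):
    rng = np.random.default_rng(seed)
    genome = simulate_genome(seed, n_contigs=2, lengths=(2000, 1500)).contigs
    index = GenomeIndex.build(genome, k)
    total = sum(count for _, count in
                ((key, index.exact_query(key)[0]) for key, _ in index.table.iterate_keys()))
    n_windows = sum(len(s) - k + 1 for s in genome.values())
    assert total == n_windows == index.n_windows
    # exact queries agree with a naive scan for present and absent k-mers
    for _ in range(30):
        if rng.random() < 0.7:
            name = rng.choice(list(genome))
            off = int(rng.integers(0, len(genome[name]) - k + 1))
            q = genome[name][off : off + k]
        else:
            q = random_dna(rng, k)
        count, locs = index.exact_query(codec.encode_kmer(q, k))
        truth = naive_fuzzy_scan(genome, q, 0)
        assert count == len(truth)
        assert sorted((l.contig, l.offset) for l in locs) == [
            (c, o) for c, o, _, _ in truth
        ]


def test_every_location_window_reencodes_to_its_key():
    genome = simulate_genome(9, lengths=(3000,)).contigs
    k = 9
    index = GenomeIndex.build(genome, k)
    rng = np.random.default_rng(9)
    keys = [key for key, _ in index.table.iterate_keys()]
    for key in rng.choice(len(keys), size=100, replace=False):
        key = keys[int(key)]
        _, locs = index.exact_query(key)
        for loc in locs:
            window = genome[loc.contig][loc.offset : loc.offset + k]
            assert codec.encode_kmer(window, k) == key
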