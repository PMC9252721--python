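"""Variant k-mer representation and the bipartite k-mer -> variant index."""
import numpy as np
import pytest

from kmeridx import codec
from kmeridx.errors import ReferenceMismatchError
from kmeridx.index import GenomeIndex
from kmeridx.simulate import (
    simulate_genome,
    simulate_variants,
    write_genome_fasta,
    write_variants_vcf,
)
from kmeridx.variants import (
    VariantIndex,
    VariantRecord,
    alt_window,
    classify_variant,
    read_vcf_records,
    variant_kmers,
)


def _kmer_strings(reference, variant, k):
    return [codec.decode_kmer(c, k) for c, _ in variant_kmers(reference, variant, k)]


def test_alt_window_snv():
    ref = {"c1": "AAAAACCCCC"}
    v = VariantRecord("c1", 5, "A", "G", "SNV")
    alt_seq, interval = alt_window(ref, v, 3)
    assert alt_seq == "AAGCC"
    assert interval == (2, 3)
    assert _kmer_strings(ref, v, 3) == ["AAG", "AGC", "GCC"]


def test_alt_window_deletion_junction():
    ref = {"c1": "ACGTACGT"}
    v = VariantRecord("c1", 3, "GTA", "G", "DEL")
    alt_seq, (a, b) = alt_window(ref, v, 3)
    assert a == b == 2  # zero-length junction
    assert alt_seq[:2] == "CG" and alt_seq[2:4] == "CG"
    # k-mers spanning the junction: exactly k - 1 of them
    assert _kmer_strings(ref, v, 3) == ["CGC", "GCG"]


def test_alt_window_insertion():
    ref = {"c1": "AAATTT"}
    v = VariantRecord("c1", 3, "A", "AGG", "INS")
    alt_seq, interval = alt_window(ref, v, 3)
    assert alt_seq == "AAGGTT"
    assert interval == (2, 4)  # the two inserted Gs
    assert _kmer_strings(ref, v, 3) == ["AAG", "AGG", "GGT", "GTT"]


def test_alt_window_clipped_at_contig_edge():
    ref = {"c1": "ACGTAC"}
    v = VariantRecord("c1", 1, "A", "T", "SNV")
    alt_seq, interval = alt_window(ref, v, 4)
    assert alt_seq == "TCGT"  # no left context available
    assert interval == (0, 1)
    assert len(variant_kmers(ref, v, 4)) == 1


def test_reference_mismatch_raises():
    ref = {"c1": "AAAAACCCCC"}
    with pytest.raises(ReferenceMismatchError):
        alt_window(ref, VariantRecord("c1", 5, "G", "T", "SNV"), 3)
    with pytest.raises(ReferenceMismatchError):
        alt_window(ref, VariantRecord("c9", 1, "A", "T", "SNV"), 3)


@pytest.mark.parametrize("k", [11, 21, 31])
def test_variant_kmer_count_law(k):
    """With full context: SNV -> k, DEL -> k-1, INS(L) -> L+k-1 k-mers."""
    genome = simulate_genome(41, lengths=(30_000,)).contigs
    vset = simulate_variants(
        genome, 42, n_snv=20, n_ins=20, n_del=20, len_range=(1, 4), k=k
    )
    for v in vset.variants:
        rec = VariantRecord(v.contig, v.pos, v.ref, v.alt, v.vtype)
        n = len(variant_kmers(genome, rec, k))
        l_alt = {"SNV": 1, "INS": len(v.alt) - 1, "DEL": 0}[v.vtype]
        assert n == l_alt + k - 1


def test_alt_kmers_differ_from_reference_window_at_same_offset():
    genome = simulate_genome(43, lengths=(20_000,)).contigs
    k = 15
    vset = simulate_variants(genome, 44, n_snv=10, n_ins=5, n_del=5, k=k)
    for v in vset.variants:
        rec = VariantRecord(v.contig, v.pos, v.ref, v.alt, v.vtype)
        alt_seq, (a, _b) = alt_window(genome, rec, k)
        # reference haplotype over the same span
        span_start, span_end = rec.ref_span
        left = max(0, span_start - (k - 1))
        ref_hap = genome[v.contig][left : span_end + (k - 1)].upper()
        for code, off in variant_kmers(genome, rec, k):
            if off + k <= len(ref_hap):
                assert codec.decode_kmer(code, k) != ref_hap[off : off + k]


def _write_vcf(path, rows, contigs):
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="AF">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines += rows
    path.write_text("\n".join(lines) + "\n")


def test_build_variant_index_toy(tmp_path):
    ref = {"c1": "ACGTACGTTTTTTGCATGCA"}
    rows = [
        "c1\t3\t.\tG\tA\t.\tPASS\tAF=0.5",
        "c1\t15\t.\tC\tG\t.\tPASS\tAF=0.25",
    ]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    vi = VariantIndex.from_vcf(vcf, ref, 3, af_keys=("AF",))
    assert vi.n_variants == 2
    assert vi.n_distinct_kmers == 6  # 3 per SNV, all distinct
    for code, _ in vi.table.iterate_keys():
        hits = vi._hits_for_code(code)
        assert len(hits) == 1


def test_shared_kmer_maps_to_both_variants(tmp_path):
    # two SNVs on identical contexts generate identical alt k-mers
    ref = {"c1": "AAACAAATTTAAACAAA"}
    rows = [
        "c1\t4\t.\tC\tG\t.\tPASS\tAF=0.5",
        "c1\t14\t.\tC\tG\t.\tPASS\tAF=0.5",
    ]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    vi = VariantIndex.from_vcf(vcf, ref, 3, af_keys=("AF",))
    code = codec.encode_kmer("AGA", 3)
    hits = vi._hits_for_code(code)
    assert sorted(h.variant.pos for h in hits) == [4, 14]  # bipartite many-to-many


def test_empty_vcf(tmp_path):
    ref = {"c1": "ACGTACGT"}
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, [], ref)
    vi = VariantIndex.from_vcf(vcf, ref, 3)
    assert vi.n_variants == 0
    assert vi.n_distinct_kmers == 0
    assert all(not w.hits for w in vi.query("ACGTACGT"))


def test_multiallelic_split_and_af_per_alt(tmp_path):
    ref = {"c1": "AAACAAAT" + "G" * 10}
    rows = ["c1\t4\t.\tC\tG,T\t.\tPASS\tAF=0.5,0.125"]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    records = read_vcf_records(vcf, ("AF",))
    assert [(r.alt, r.af_values) for r in records] == [("G", (0.5,)), ("T", (0.125,))]


def test_ref_mismatch_records_skipped_and_counted(tmp_path):
    ref = {"c1": "AAACAAATTTTTTTTT"}
    rows = [
        "c1\t4\t.\tC\tG\t.\tPASS\tAF=0.5",
        "c1\t8\t.\tG\tA\t.\tPASS\tAF=0.5",  # REF is actually T
    ]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    vi = VariantIndex.from_vcf(vcf, ref, 3, af_keys=("AF",))
    assert vi.n_variants == 1
    assert vi.n_skipped == 1


def test_missing_af_key_recorded_as_none(tmp_path):
    ref = {"c1": "AAACAAATTT"}
    rows = ["c1\t4\t.\tC\tG\t.\tPASS\tAF=0.5"]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    records = read_vcf_records(vcf, ("AF", "AF_nfe"))
    assert records[0].af_values == (0.5, None)


def test_build_is_order_independent(tmp_path):
    genome = simulate_genome(50, lengths=(8000,)).contigs
    vset = simulate_variants(genome, 51, n_snv=6, n_ins=3, n_del=3, k=11)
    recs = [
        VariantRecord(v.contig, v.pos, v.ref, v.alt, v.vtype, v.af_values)
        for v in vset.variants
    ]
    vi1 = VariantIndex.build(recs, genome, 11)
    rng = np.random.default_rng(0)
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    vi2 = VariantIndex.build(shuffled, genome, 11)
    probe = genome["c1"][:2000]
    as_tuples = lambda vi: [
        (w.offset, sorted((h.variant.pos, h.variant.alt) for h in w.hits))
        for w in vi.query(probe)
    ]
    assert as_tuples(vi1) == as_tuples(vi2)


def test_reference_shared_kmers_flagged_or_dropped(tmp_path):
    # insertion duplicating the following bases: its alt k-mers exist in ref
    ref = {"c1": "TTTACGACGGGG" + "C" * 8}
    rows = ["c1\t3\t.\tT\tTACG\t.\tPASS\tAF=0.5"]
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, rows, ref)
    asm = GenomeIndex.build(ref, 4)
    flagged = VariantIndex.from_vcf(vcf, ref, 4, assembly_index=asm)
    assert flagged.flagged_codes  # present in reference -> flagged, kept
    assert flagged.n_dropped_codes == 0
    dropped = VariantIndex.from_vcf(
        vcf, ref, 4, assembly_index=asm, drop_reference_kmers=True
    )
    assert dropped.n_dropped_codes == len(flagged.flagged_codes)
    assert dropped.n_distinct_kmers < flagged.n_distinct_kmers


def test_alt_read_recovery_exact():
    """Reads from alt haplotypes recover exactly the planted variant."""
    k = 31
    genome = simulate_genome(60, lengths=(30_000,)).contigs
    vset = simulate_variants(genome, 61, n_snv=10, n_ins=5, n_del=5, k=k)
    recs = [
        VariantRecord(v.contig, v.pos, v.ref, v.alt, v.vtype, v.af_values)
        for v in vset.variants
    ]
    vi = VariantIndex.build(recs, genome, k)
    rng = np.random.default_rng(62)
    for rec in recs:
        alt_seq, (a, b) = alt_window(genome, rec, k)
        # a read overlapping the altered interval (or spanning the junction)
        read = alt_seq
        found = {
            (h.variant.contig, h.variant.pos, h.variant.alt)
            for w in vi.query(read)
            for h in w.hits
        }
        assert found == {(rec.contig, rec.pos, rec.alt)}
    # pure reference reads report nothing
    for _ in range(20):
        off = int(rng.integers(0, len(genome["c1"]) - 200))
        ref_read = genome["c1"][off : off + 200]
        assert all(not w.hits for w in vi.query(ref_read))


def test_query_shorter_than_k(tmp_path):
    ref = {"c1": "AAACAAATTT"}
    vcf = tmp_path / "v.vcf"
    _write_vcf(vcf, ["c1\t4\t.\tC\tG\t.\tPASS\tAF=0.5"], ref)
    vi = VariantIndex.from_vcf(vcf, ref, 5)
    assert vi.query("ACG") == []


def test_variant_index_save_load(tmp_path):
    genome = simulate_genome(70, lengths=(6000,)).contigs
    vset = simulate_variants(genome, 71, n_snv=5, n_ins=2, n_del=2, k=13)
    recs = [
        VariantRecord(v.contig, v.pos, v.ref, v.alt, v.vtype, v.af_values)
        for v in vset.variants
    ]
    vi = VariantIndex.build(recs, genome, 13)
    path = tmp_path / "v.idx"
    vi.save(path)
    back = VariantIndex.load(path)
    assert back.k == 13 and back.af_keys == vi.af_keys
    probe = genome["c1"][:1500]
    dump = lambda v: [
        (w.offset, sorted((h.variant.pos, h.variant.alt, h.variant.af_values)
                          for h in w.hits))
        for w in v.query(probe)
    ]
    assert dump(back) == dump(vi)


def test_classify_variant():
    assert classify_variant("A", "G") == "SNV"
    assert classify_variant("AT", "GC") == "MNV"
    assert classify_variant("A", "ATT") == "INS"
    assert classify_variant("ATT", "A") == "DEL"


def test_mnv_counts_like_multibase_substitution():
    ref = {"c1": "AAAAACCCCCGGGGG"}
    v = VariantRecord("c1", 6, "CC", "TT", "MNV")
    assert len(variant_kmers(ref, v, 5)) == 2 + 5 - 1
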