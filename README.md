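# kmeridx

K-mer indexing of genome assemblies on an invertible Fibonacci-hash table,
with exact and fuzzy (Hamming distance ≤ 2) queries and a k-mer
representation of variant catalogues.

## What problem this solves

Many sequence-analysis questions — is this primer binding site unique? does
this CRISPR target have near-identical off-target sites? does a read carry a
catalogued variant? — reduce to asking, for every k-mer of a query sequence,
*how often and where does this k-mer (or a close neighbor of it) occur in an
assembly or variant set?* BWT-based aligners answer substring queries in
O(m log n); `kmeridx` instead indexes **all** k-mers of an assembly in a hash
table so that a single k-mer lookup is O(1), independent of the indexed
genome's length, and a fuzzy query is a fixed number of such lookups.

The package is for bioinformaticians who want a library (and a small CLI)
that:

- indexes every k-mer (k ≤ 31) of a FASTA assembly with its count and all
  its locations;
- answers fuzzy queries up to two mismatches, reporting neighbor k-mers,
  their locations and mismatch positions in dot notation;
- represents SNVs and indels as the set of alt-haplotype k-mers overlapping
  the altered bases, so a VCF catalogue becomes a bipartite k-mer → variant
  index queryable with raw sequence.

## The data structure

A k-mer is packed 2 bits/base (A=0, C=1, G=2, T=3, 5′-most base most
significant) into a word `x < 4^k`. The table hashes with the multiplicative
(Fibonacci) hash

    h(x) = (x · M) mod 2^64,   M = 0x9E3779B97F4A7C15 (odd, ≈ 2^64/φ)

Because M is odd, h is a bijection of 64-bit words and is inverted by the
modular inverse M⁻¹. For a table of 2^b slots, the **home bucket** is the
top b bits of h(x) and only the remaining 64−b bits (the *remainder*) are
stored, together with a 1-bit occupancy flag and an 8-bit displacement under
linear probing — a quotient-filter-style packing of 9 + (64−b) bits per slot.
Keys are never stored: they are reconstructed as x = h⁻¹(home ≪ (64−b) | rem),
which is also how the table doubles and serialises itself. A probe matches
exactly when displacement and remainder match, since b + (64−b) bits
determine the full (bijective) hash.

The 64-bit payload packs a single genomic location (contig ordinal, offset,
strand — 63 bits) inline, or points into a posting arena holding
`count, loc₁ … loc_count` for repeated k-mers.

A fuzzy query at distance band d ∈ [0,2] enumerates all
`1 + 3k + 9·C(k,2)` neighbor codes (≤ 4278 at k = 31) and performs exactly
one O(1) lookup per neighbor.

A variant with L altered bases contributes the k-windows of its
alt haplotype that overlap the altered interval (or, for a deletion, span
the junction): L + k − 1 k-mers with full context (SNV → k, deletion → k−1,
insertion of length L → L + k − 1).

## Worked example

```bash
# a deterministic 3 kb toy assembly
kmeridx simulate genome --seed 1 --lengths 3000 --out toy.fa
kmeridx build --fasta toy.fa --k 11 --out toy.idx
kmeridx query-region --index toy.idx --fasta toy.fa --region c1:100-160 \
    --summary summary.tsv --detail detail.tsv
head -3 summary.tsv detail.tsv
```

prints (output of the commands above):

```
==> summary.tsv <==
window_index	kmer	n_exact	n_mm1	n_mm2	flag
1	TGCTGTCGATA	1	0	2	.
2	GCTGTCGATAA	1	1	0	.

==> detail.tsv <==
window_index	query_kmer	distance	match_rendered	count	locations	mismatch_positions
1	TGCTGTCGATA	0	...........	1	c1:100-110:+	
1	TGCTGTCGATA	2	A.....T....	1	c1:200-210:+	1,7
```

Reading this: the first 11-mer of region `c1:100-160` occurs exactly once in
the assembly (`n_exact = 1`) and has two neighbors at two mismatches
(`n_mm2 = 2`); the detail table shows one of them at `c1:200-210`, differing
at positions 1 and 7 (`A.....T....` — dots mark identical bases, letters
show the *matched* k-mer's bases). Summary counts tally genome **locations**
per distance; detail rows list each distinct neighbor sequence with all its
locations. Detail output is truncated at 1000 rows by default, the remainder
going to a `.overflow` sidecar; the summary is computed before truncation.

Variant catalogues work the same way:

```bash
kmeridx simulate variants --fasta toy.fa --seed 3 --n-snv 3 --n-del 1 \
    --k 11 --out toy.vcf
kmeridx build-variants --vcf toy.vcf --fasta toy.fa --k 11 \
    --af-fields AF --out toy.var.idx
kmeridx query-variants --index toy.var.idx --seq <alt-haplotype sequence>
```

which reports, per query window, the catalogued variants (coordinate, REF,
ALT, type, allele frequencies) whose k-mer set contains that window.

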