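# Methods

## Scope and model

`kmeridx` implements an exhaustive k-mer index: every length-k window of an
assembly (k ≤ 31) is a key associated with its occurrence count and all its
genomic locations, and fuzzy search is neighborhood enumeration over that
index. The design optimises query time over build time and memory — indices
are built once and queried many times — so a lookup is constant expected
time in both k and the indexed length, at the cost of storing every k-mer
rather than a compressed suffix structure.

## K-mer codec

Bases map A→0, C→1, G→2, T→3 (alphabetical, so integer order equals
lexicographic order), 5′-most base in the most significant bit pair. k is
capped at 31 so codes fit 62 bits, leaving room for a tag bit in table
payloads. Lower-case (soft-masked) bases are upper-cased; any other
character (N, IUPAC codes) invalidates the windows covering it rather than
erroring the whole sequence, and such windows are reported as flagged
"ambiguous" rows so window numbering stays aligned with query coordinates.
Mismatch positions are 1-based from the 5′ end. Distances are
substitution-only (Hamming): fuzzy search finds mismatches, not indels.

## Hash table

- Multiplier M = 0x9E3779B97F4A7C15, the canonical Fibonacci-hashing
  constant (odd integer nearest 2^64/φ). Odd ⇒ bijective mod 2^64 ⇒
  invertible via M⁻¹ = M^(−1) mod 2^64.
- Home bucket = top b bits of the hash (the well-mixed bits of a
  multiplicative hash); slot stores the low 64−b bits (remainder), an
  occupancy bit and an 8-bit displacement from the home bucket.
- Collision resolution: linear probing without deletion. A probe matches
  iff displacement and remainder both match — exact, because (home,
  remainder) determine the full hash and the hash is a bijection.
- Growth: displacement > 254 or load factor > 0.7 triggers doubling; the
  table reconstructs its keys by inverting the hash and re-inserts them.
  Keys are reserved to 63 bits (top bit free for callers' tags).
- Builders pre-size b so that the expected load is ≈ 0.65, avoiding
  repeated doubling during bulk construction; the default standalone table
  starts at 2^16 slots.
- Serialisation packs slot metadata at exactly 1 + 8 + (64−b) bits per slot
  (two packed bitstreams: 9-bit occupancy+displacement words and (64−b)-bit
  remainders) plus 64-bit payloads for occupied slots only.

## Genome index

Payload tag bit 0 ⇒ the payload is one packed location (16-bit contig
ordinal, 46-bit offset, 1-bit strand = 63 bits); tag 1 ⇒ offset into an
append-only posting arena storing `count, loc₁…loc_count`, so counts are
unbounded. Indexing is forward-strand by default: locations are the
positions of the k-mer as written in the FASTA. `strand_mode="both"`
matches reverse complements at query time (reported with strand '−',
palindromic k-mers counted once) instead of doubling the index. The index
file ("KMKY" magic, versioned, CRC32-closed) records a checksum of the
contig (name, length) table so coordinate queries can verify that the
FASTA supplied at query time matches the index.

## Fuzzy search

Full neighbor enumeration: for a band d ∈ [d_min, d_max] the query performs
exactly Σ 3^d·C(k,d) lookups (1 + 93 + 4185 = 4279 at k = 31, d ≤ 2), each
O(1) — chosen over seed-partition schemes because the hash table makes
per-neighbor lookups cheap and the budget is independent of genome size.
The CLI caps d_max at 2 (the combinatorics explode beyond that); the
library accepts any d_max ≤ k. Summary rows count *locations* per distance;
detail rows expose the distinct-sequence view with dot-notation renderings
('.' = identical, otherwise the matched k-mer's base).

## Variant representation

VCF-style left-anchored alleles: for indels REF and ALT share a leading
anchor base that is not itself altered; same-length substitutions (SNV/MNV)
have no anchor. The alt haplotype window is the altered bases plus up to
k−1 reference bases of context on each side (clipped at contig edges); a
variant's k-mers are the windows overlapping at least one altered base, or
— for pure deletions, whose altered interval is a zero-length junction —
the windows containing both junction-adjacent bases. This yields the count
law L_alt + k − 1 (SNV → k, deletion → k − 1, insertion of length L →
L + k − 1) with full context. Overlapping catalogue variants are treated
independently, one alt haplotype per record; multi-allelic VCF rows are
split per ALT, with Number=A INFO fields matched to their allele. Records
whose REF disagrees with the reference are logged, counted and skipped.
Allele-frequency metadata is a configurable ordered list of INFO keys
(default mirrors gnomAD-style population AF fields); missing keys are
stored as missing, not errors. Variant k-mers that also occur in the
assembly are *flagged* (dropping them is opt-in) so the bipartite k-mer ↔
variant graph stays faithful to the catalogue. Building is
order-independent: records are canonically sorted before id assignment.

## Synthetic data and the oracle

The simulator emulates the study substrate at desk scale: uniform-ish
random contigs (default GC 0.41, the human genome-wide fraction; default
10 kb), optional repeats copied to non-overlapping target sites with
mutations planted at chosen 1-based positions (so planted Hamming distances
and positions are known exactly), and variant sets placed with ≥ k bases of
clean ACGT context, pairwise separation > k + indel length, and alt k-mers
that are verified novel by plain substring search — insertions duplicating
a homopolymer run, say, are redrawn, because their alt haplotype locally
equals the reference and would make truth sets ambiguous. Everything is a
deterministic function of the seed, which is recorded in FASTA headers and
VCF comments.

What the generator does **not** emulate: real repeat families and satellite
structure, GC heterogeneity, sequencing errors, soft-masking, overlapping
or clustered variants, and genome-scale k-mer multiplicity distributions.
Passing tests therefore demonstrate algorithmic correctness (agreement with
the brute-force definition of every query), not performance or robustness
claims on real whole-genome data.

The oracle `naive_fuzzy_scan` computes Hamming distance of a query against
every genome window by direct character comparison (numpy byte equality on
the raw sequence); it shares no code with the codec, hash table or index,
so index/oracle agreement is a meaningful two-route check.

## Numerical and design choices

- Coordinates: user-facing 1-based inclusive (`contig:start-end`, ASCII
  hyphen or en-dash); internal 0-based half-open everywhere. Locations
  render as `contig:start-end:strand`.
- Detail reports truncate at 1000 rows by default; the remainder goes to a
  `.overflow` sidecar file and the summary is computed before truncation.
- TSV is the primary report format (diffable); `--json` emits the
  structured equivalent.
- Ties: fuzzy matches sort by (distance, match code), i.e. lexicographic
  within a distance class; locations keep FASTA order.
- Degenerate inputs: queries shorter than k yield empty results; empty
  FASTA/VCF raise or yield empty indices as documented per operation.

## Problem sizes used in the checks

The test suite and acceptance script run the oracle-equivalence check on
20 seeded 10 kb genomes with planted repeats, 200 queries per genome split
over k ∈ {11, 19, 25, 31}; hash checks use 10^5 random keys; the variant
count law uses ~10^3 planted variants over k ∈ {11, 21, 31} on 150 kb
genomes; size-independence of the lookup budget is demonstrated at 2 kb vs
100 kb and of probe counts at matched load across a 16-fold capacity span.
These sizes exercise every code path (inline vs arena payloads, table
growth, repeats at both fuzzy distances) while keeping the whole suite in
tens of seconds on one CPU.

## Known limitations

- k ≤ 31, one word per code; no spaced seeds or minimizers.
- Fuzzy search is substitution-only; indel-tolerant queries are out of
  scope.
- No deletion from tables; indices are immutable once built.
- Whole-human-genome builds are supported in principle by the layout
  (2^16 contigs × 2^46 offsets) but are not exercised here; contigs are
  held in memory as strings, which is the simplest correct choice at desk
  scale.
- Variants are represented independently; nearby variants are not phased
  into joint haplotypes.
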