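# Methods

## Problem and approach

Given reads over {A,C,G,T,N} and a length k (10 < k ≤ 256), the task is the
exact multiset of occurrence counts of all canonical k-mers — where the
canonical form of a k-mer is the lexicographically smaller of itself and its
reverse complement — optionally weighted by base-call quality. The
implementation is an external-memory distribution sort: partition the k-mer
stream into on-disk bins keyed by a short prefix, then sort each bin
independently in memory and concatenate the results in prefix order.
Correctness rests on two structural facts: (a) the 2-bit packing A=0, C=1,
G=2, T=3 with the first base most significant makes integer order equal
lexicographic order, so radix sort and binary search operate directly on the
packed words; (b) bin ids follow lexicographic prefix order of a prefix-free
table, so per-bin sorted output concatenated by ascending bin id is globally
sorted.

k-mer windows containing any non-ACGT symbol are skipped entirely (the read
is kept; its clean windows still count). Lowercase (soft-masked) bases are
accepted and upper-cased.

## Prefix table and bin balancing

Canonical k-mers start with A, C, G, T in exact proportions 7/16, 5/16,
3/16, 1/16 (for odd k; the package's enumeration tests verify this exactly),
while later positions are nearly uniform for k well above the prefix length.
A fixed-length prefix table therefore produces bins whose expected
occupancies differ by a factor of 7. The table starts from all 4^p1_min
prefixes (p1_min ∈ {3,4,5}, chosen from the input size: < 1 GiB → 3,
< 20 GiB → 4, else 5) and splits every prefix whose modeled mass
w(first base)·4^−(len−1) exceeds 0.5× the mean bin mass 4^−p1_min, up to two
times. With the exact start distribution this splits A-, C- and G-start
prefixes one symbol deeper and leaves T-start prefixes short (208 bins for
p1_min = 3). The 0.5 threshold was set from the model itself: it is the
largest threshold that splits every heavy start letter, and splitting A/C/G
but not T minimizes the realized max/mean occupancy ratio (≈1.42 versus 1.75
for any fixed-length table); higher thresholds that leave some A-start
prefix unsplit can only increase the ratio, because splitting adds bins
(lowering the mean) without lowering the maximum. A test measures the ratio
on 10^5 random canonical 25-mers against a fixed 4-symbol table.

## Two-stage prefix removal and the temporary format

Within a bin, a second prefix of p2 bases is removed before anything touches
disk: a full bin buffer (capacity 2^15 entries, shrunk if the memory budget
requires, so every group count fits 2 bytes) is counting-sorted by the p2
bases, which are then replaced by 4^p2 two-byte group counts. p2 is chosen
per bin, subject to k − p1 − p2 ≡ 0 (mod 4) so suffixes pack into whole
bytes, by exhaustively minimizing the worst-case disk formula

    n_k (k − p1 − p2 + e) / 4  +  2 · 4^p2 · n_k / 2^15   bytes,

with e = 0 for classic counters and e = 16 for quality-weighted mode (a
4-byte float weight per entry); the formula is linear in n_k, so the argmin
is size-independent, and ties break toward smaller p2. After compaction a
chunk may strip 4 further bases into the count block; the criterion is
purely byte-arithmetic: strip iff m > 2·(4^(p2+4) − 4^p2) for m entries.

Chunk records are self-delimiting: an 8-byte header (entry count, effective
p2, strip flag, suffix width, weight flag), the little-endian u16 count
block, the packed suffix block, and in quake mode a float32 weight block.
The run report tracks actual bytes written and a *documented overhead
allowance*: 8 bytes per chunk plus, for each final partial chunk, one full
count block (the worst-case formula prorates count blocks per 2^15 entries,
which a partially filled end-of-input chunk cannot achieve). Tests assert
written bytes ≤ formula + allowance on every run.

## Sorting, counting, thresholds

Phase 2 expands each chunk back to full packed k-mers and sorts each bin
with a least-significant-digit radix sort over the bytes of the big-endian
packed representation; constant byte columns (packing pad, shared bin
prefix) are skipped, and each digit pass is a stable 256-bucket counting
sort (numpy's stable integer argsort). Runs of equal k-mers become counts:
run length in classic mode, double-precision sum of the occurrence weights
in quake mode. Thresholding keeps min ≤ count ≤ max (defaults 2 / 2.0 and
unbounded, the convention that discards unique k-mers). Classic counters
saturate at 2^32 − 1 in the fixed-width output record. Bins whose expanded
form exceeds the sorting memory budget are processed in sub-chunks whose
per-sub-chunk counts are re-sorted and merged — an equivalent, purely
fallback path exercised by a dedicated test with an artificially small
budget.

## Quality weights and numeric reproducibility

The weight of one k-mer occurrence is the product over its bases of the
correctness probability 1 − 10^(−q/10) (Phred q, +33 ASCII encoding by
default, +64 selectable). This product is orientation-independent, so window
qualities are taken from the original read orientation even when
canonicalization flips the k-mer. Weights are evaluated per read via prefix
sums of log-probabilities (bases with q = 0 are tracked separately and force
weight 0, keeping the sums finite), rounded to float32 — the width of the
temporary and final storage — and accumulated in float64 in encounter order.
Because the naive oracle applies the same per-occurrence rounding and the
pipeline preserves encounter order end to end (stable counting sorts, stable
radix, sequential segment sums), classic counts match the oracle exactly and
quake counts match to the last bit in practice; the equivalence tests allow
1e-9 relative slack.

## Determinism and parallelism

The final database is a pure function of the input records and the
configuration: bins are mutually independent, and the completer re-emits
results strictly by ascending bin id regardless of completion order. Tests
assert byte-identical databases across worker counts (thread-pool bin
sorting), shuffled bin processing orders, gzip/plain input and 1-versus-6
file splits of the same records.

## Database format

`<name>.kdb` holds fixed-width records: the packed suffix of k − p1_min
bases (left-aligned, 4 bases/byte, so byte order equals lexicographic order)
plus a 4-byte counter (u32 classic, f32 quake). `<name>.kdb.idx` holds a
header (magic, version, k, mode, p1_min, thresholds, total) and, for each of
the 4^p1_min fixed-length prefixes, a u64 record offset and count. Lookup
canonicalizes the query, slices by prefix, and binary-searches the suffix;
iteration streams records in order. The index prefix length is fixed at
p1_min even though bins used variable-length prefixes — sorted order is
unaffected and the search is simpler. The format is this package's own; it
is documented here rather than byte-compatible with any other tool.

## Synthetic data generator

`SyntheticSpec` defaults define the study conditions used throughout the
tests: genome 100 kb (uniform random), 30× coverage, 100 bp reads drawn
uniformly from both strands, 1% substitutions, 0.1% N calls, and a two-level
quality model (q = 40 everywhere, q = 3 at substituted positions) chosen so
that quality weighting visibly separates error k-mers from true k-mers —
a constant-quality model would make quake mode a scaled copy of classic mode
and hide weighting bugs. The generator emulates neither indels, quality
decay along the read, GC bias nor repeat structure; passing equivalence
tests therefore demonstrates algorithmic correctness of the counting
machinery on realistic volumes, not robustness to every artifact of real
sequencers (the counting path itself never assumes anything about those
artifacts beyond the FASTQ contract). Equivalence is checked against
`oracle_count`, an independent hash-table counter operating on strings.

## Problem sizes

Integration and acceptance tests run the full matrix k ∈ {11, 25, 31, 33,
55} × {classic, quake} × {plain, gzip} × {1, 6 files} at the 100 kb / 30×
study scale (≈2.28 million k-mers per run), which completes in a couple of
minutes on one CPU; unit tests use smaller deterministic fixtures. These
sizes were chosen as the smallest at which every mechanism (multiple chunk
flushes per bin, extra-strip decisions, multi-word k-mers for k > 32) is
actually exercised.

## Known limitations

- bzip2 input, paired-end awareness and quality trimming are out of scope.
- Multi-line FASTQ is not supported (multi-line FASTA is).
- The per-bin memory fallback merges sub-chunk count vectors in memory; a
  bin whose *distinct* k-mer set alone exceeded RAM would still fail.
- Parallelism is thread-based over bins in phase 2 only; phase 1 is
  sequential. The design contract is determinism, not speed.
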