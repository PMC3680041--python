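# kmerdisk

Exact, disk-based counting of canonical k-mers in sequencing reads.

Counting how often every length-k substring (k-mer) occurs in a read set is
the first step of genome assemblers, k-mer-spectrum error correctors and many
alignment-free analyses. For real datasets the k-mer multiset is far larger
than RAM, so `kmerdisk` follows the external-memory *distribution sort*
paradigm instead of a giant hash table:

1. **Distribution phase.** Reads are streamed (FASTQ/FASTA, plain or gzip,
   any number of files); every window of k bases containing only A/C/G/T is
   replaced by its *canonical* form — the lexicographic minimum of the k-mer
   and its reverse complement, merging the two DNA strands — and routed to
   one of a few hundred disk bins by a variable-length prefix p1. Because
   canonical k-mers start with A, C, G, T in proportions 7/16, 5/16, 3/16,
   1/16, heavy prefixes get one extra symbol so bin sizes stay balanced.
   Before a full bin buffer is flushed, a counting sort groups its entries by
   the next p2 bases; those bases are deleted and replaced by a block of
   4^p2 two-byte group counts, and only the byte-aligned (k−p1−p2)-base
   suffixes are written. p2 is chosen per bin to minimise the worst-case
   temporary disk usage n_k(k−p1−p2)/4 + 2·4^p2·n_k/2^15 bytes (n_k = number
   of k-mers); a compactor strips 4 further bases whenever the enlarged
   count block still saves space.
2. **Sorting phase.** Each bin is reloaded, its k-mers are reconstructed
   from prefix + group id + suffix, sorted by a least-significant-digit
   radix sort over 8-bit digits of the 2-bit-packed representation,
   aggregated into per-k-mer counts, and filtered by count thresholds (by
   default count ≥ 2, discarding the unique k-mers that are almost always
   sequencing errors). Emitting bins in ascending bin id yields a globally
   sorted on-disk dictionary supporting sequential iteration and
   binary-search lookup.

Counters are either classic integers or quality-weighted "Quake-compatible"
decimals, where each occurrence contributes the product over its bases of
the correctness probability 1 − 10^(−q/10) from the Phred scores.

Supported parameters: 10 < k ≤ 256, read length up to 10240.

## Worked example

Generate a small synthetic dataset (20 kb genome, 10× coverage, 100 bp
reads) and count 25-mers:

```sh
python -c "from kmerdisk.simulate import SyntheticSpec, generate_reads; \
           generate_reads(SyntheticSpec(genome_length=20000, coverage=10, seed=3), '.')"
kmerdisk count -k 25 -o demo reads_0.fastq
```

```
[distribute] reads=2000 kmers=148385 bins=208 chunks=208 tmp_bytes=1119492
[sort] prefilter_total=148385 peak_buffered_bytes=2374160
[complete] total=116260 distinct=19743 singletons=0 non_singletons=19743 -> demo.kdb
```

2000 reads of 100 bp give exactly 2000·(100−25+1) = 152000 windows, of which
148385 are free of N; the default threshold (count ≥ 2) then keeps 19743
distinct 25-mers covering 116260 occurrences (no singletons survive the
filter, so `singletons=0`). Inspect the result:

```sh
$ kmerdisk stats demo
k       25
mode    classic
total   116260
distinct        19743
...
$ kmerdisk dump demo | head -3
AAAAAAGATCTTCAAATTGGCGATA       7
AAAAAAGATTTGTAACGGCGTCTAA       7
AAAAAATCATATTTACGTGAGTAGT       8
$ kmerdisk lookup demo GGGGGGGGGGGGGGGGGGGGGGGGG
GGGGGGGGGGGGGGGGGGGGGGGGG       absent
```

`dump` streams the dictionary in sorted order; `lookup` canonicalizes its
query first, so a k-mer and its reverse complement report the same count.
Add `--quake` to `count` for quality-weighted counters, `-t N` for parallel
bin sorting, `-p {3,4,5}` to force the minimum bin-prefix length.

The same functionality is available as a library: `kmerdisk.pipeline.run`,
`kmerdisk.database.KmerDatabase`, `kmerdisk.simulate.generate_reads` /
`oracle_count`.

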