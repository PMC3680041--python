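"""Phase 2: rebuild, radix-sort and count the k-mers of each bin.

Each temporary bin file is expanded back to full packed k-mers (the p1 bin
prefix and the p2 group parts are re-attached), sorted with an LSD radix sort
over 8-bit digits of the packed representation, aggregated into per-k-mer
counts (run lengths, or summed quality weights in Quake mode), filtered by
count thresholds, and finally emitted in ascending bin-id order, which yields
a globally sorted stream because bin ids follow lexicographic prefix order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from kmerdisk import kmer_core
from kmerdisk.distribution import CompactedChunk

COUNTER_MAX = (1 << 32) - 1  # classic counters saturate at the 4-byte limit


@dataclass(frozen=True)
class CountedKmer:
    """A canonical k-mer with its aggregated count (int or Quake decimal)."""

    kmer: kmer_core.PackedKmer
    count: float


def expand_chunk(
    chunk: CompactedChunk, bin_prefix: str
) -> tuple[np.ndarray, np.ndarray | None]:
    """Reconstruct the full packed k-mers of a compacted chunk.

    Group j of the count block contributes ``prefix_counts[j]`` k-mers
    ``bin_prefix + base4(j, p2_effective) + suffix``.  Inverse (as a
    multiset) of ``compact_chunk`` / ``maybe_strip_extra``.
    """
    k = chunk.k
    p1_len = len(bin_prefix)
    if p1_len != chunk.p1_len:
        raise ValueError("bin prefix length does not match chunk")
    p2 = chunk.p2_effective
    if p1_len + p2 + 4 * chunk.sbytes != k:
        raise ValueError("corrupt chunk: prefix/suffix lengths do not add up to k")
    m = chunk.m
    w = kmer_core.nwords(k)
    byts = np.zeros((m, 8 * w), dtype=np.uint8)
    if chunk.sbytes:
        byts[:, 8 * w - chunk.sbytes :] = chunk.suffixes
    words = kmer_core.bytes_to_words(byts)
    pad = 32 * w - k
    ids = np.repeat(np.arange(len(chunk.prefix_counts), dtype=np.uint64), chunk.prefix_counts)
    prefix_val = kmer_core.encode_prefix_value(bin_prefix)
    for t in range(p1_len + p2):
        if t < p1_len:
            digit = np.uint64((prefix_val >> (2 * (p1_len - 1 - t))) & 3)
        else:
            digit = (ids >> np.uint64(2 * (p2 - 1 - (t - p1_len)))) & np.uint64(3)
        p = pad + t
        words[:, p >> 5] |= digit << np.uint64(2 * (31 - (p & 31)))
    weights = chunk.weights.astype(np.float64) if chunk.weights is not None else None
    return words, weights


def radix_sort(
    kmers: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """LSD radix sort of packed k-mers, 8-bit digits, stable.

    Digits are the bytes of the big-endian packed representation, processed
    least significant first; each pass is a stable counting sort over 256
    buckets.  Byte columns that are constant over the input (the zero pad of
    the packed layout, shared prefixes) are skipped.
    """
    n = len(kmers)
    if n <= 1:
        return kmers, weights
    byts = kmer_core.words_to_bytes(kmers)
    order = np.arange(n, dtype=np.int64)
    for col in range(byts.shape[1] - 1, -1, -1):
        column = byts[:, col]
        if column.min() == column.max():
            continue
        # stable integer argsort over uint8 keys == one counting-sort pass
        order = order[np.argsort(column[order], kind="stable")]
    out = np.ascontiguousarray(kmers[order])
    return out, (weights[order] if weights is not None else None)


def _check_sorted(kmers: np.ndarray) -> None:
    if len(kmers) < 2:
        return
    a, b = kmers[:-1], kmers[1:]
    gt = np.zeros(len(a), dtype=bool)
    decided = np.zeros(len(a), dtype=bool)
    for j in range(kmers.shape[1]):
        gt |= ~decided & (a[:, j] > b[:, j])
        decided |= a[:, j] != b[:, j]
    if gt.any():
        raise ValueError("input is not sorted")


def count_runs(
    kmers: np.ndarray, weights: np.ndarray | None, mode: str = "classic"
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a sorted k-mer array into (distinct k-mers, counts).

    Classic counts are run lengths; Quake counts are the double-precision
    sums of the run's quality weights.  Raises on unsorted input.
    """
    _check_sorted(kmers)
    n = len(kmers)
    if n == 0:
        counts = np.empty(0, dtype=np.float64 if mode == "quake" else np.int64)
        return kmers, counts
    new_run = np.ones(n, dtype=bool)
    new_run[1:] = (kmers[1:] != kmers[:-1]).any(axis=1)
    starts = np.flatnonzero(new_run)
    uniq = np.ascontiguousarray(kmers[starts])
    if mode == "quake":
        if weights is None:
            raise ValueError("quake mode requires weights")
        counts = np.add.reduceat(weights, starts)
    else:
        counts = np.diff(np.append(starts, n)).astype(np.int64)
    return uniq, counts


def quake_weight(window_qualities: Iterable[int]) -> float:
    """Quality weight of one k-mer occurrence: the product over its bases of
    the base-call correctness probability 1 - 10^(-q/10)."""
    w = 1.0
    for q in window_qualities:
        if q < 0:
            raise ValueError("negative Phred score")
        w *= 1.0 - 10.0 ** (-q / 10.0)
    return w


def filter_counts(
    kmers: np.ndarray, counts: np.ndarray, min_t: float, max_t: float = math.inf
) -> tuple[np.ndarray, np.ndarray]:
    """Keep exactly the k-mers with min_t <= count <= max_t, order preserved.

    The defaults elsewhere follow the convention of discarding unique
    k-mers (count below 2), which are overwhelmingly sequencing errors.
    """
    if min_t > max_t:
        raise ValueError("min threshold exceeds max threshold")
    mask = (counts >= min_t) & (counts <= max_t)
    return kmers[mask], counts[mask]


def merge_bins_in_order(
    per_bin: Iterable[tuple[int, np.ndarray, np.ndarray]],
) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Re-emit per-bin sorted results in ascending bin id (the completer).

    Bins may arrive in any completion order; the output is the unique
    bin-id-ascending sequence, hence globally sorted and independent of the
    arrival permutation.  Duplicate bin ids are an error.
    """
    staged: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    seen: set[int] = set()
    for bin_id, kmers, counts in per_bin:
        if bin_id in seen:
            raise ValueError(f"duplicate bin id {bin_id}")
        seen.add(bin_id)
        staged[bin_id] = (kmers, counts)
    for bin_id in sorted(staged):
        kmers, counts = staged.pop(bin_id)
        yield bin_id, kmers, counts
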