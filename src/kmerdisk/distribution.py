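"""Phase 1: distribute canonical k-mers into prefix-defined disk bins.

Each canonical k-mer is routed to a bin by a variable-length prefix p1 drawn
from a :class:`PrefixTable`.  Bin buffers of bounded capacity are compacted on
flush: a counting sort groups entries by the next p2 bases, those p2 bases are
dropped and replaced by a block of 4^p2 two-byte group counts, and the
remaining k-p1-p2 bases (always a multiple of 4, i.e. whole bytes) are written
packed.  A compactor may strip 4 further bases when the enlarged count block
still saves space.  The temporary format is little-endian and byte-exact
round-trippable.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from kmerdisk import kmer_core

#: exact fraction of canonical k-mers starting with A, C, G, T (odd k)
CANONICAL_START_MASS = {"A": 7 / 16, "C": 5 / 16, "G": 3 / 16, "T": 1 / 16}

BIN_CAPACITY = 1 << 15  # max entries per buffer, keeps group counts < 2^16

#: expansion threshold as a fraction of the mean bin mass; prefixes whose
#: modeled canonical-k-mer mass exceeds this are split one symbol deeper
EXPANSION_THRESHOLD = 0.5

MAX_EXPANSIONS = 2

CHUNK_HEADER = struct.Struct("<IBBBB")  # m, p2_effective, stripped, sbytes, has_weights


@dataclass(frozen=True)
class PrefixTable:
    """Prefix-free set of variable-length p1 prefixes in lexicographic order.

    Every canonical k-mer matches exactly one entry; bin ids follow
    lexicographic prefix order, so concatenating sorted bins in bin-id order
    yields a globally sorted k-mer stream.
    """

    p1_min: int
    entries: tuple[tuple[str, int], ...]  # (prefix, bin_id), sorted

    @property
    def n_bins(self) -> int:
        return len(self.entries)

    @property
    def max_len(self) -> int:
        return max(len(p) for p, _ in self.entries)

    def prefix_of(self, bin_id: int) -> str:
        return self.entries[bin_id][0]

    def match(self, kmer: str) -> tuple[str, int]:
        """The unique table entry whose prefix starts ``kmer``."""
        for ln in range(self.p1_min, self.max_len + 1):
            hit = self._by_prefix.get(kmer[:ln])
            if hit is not None:
                return kmer[:ln], hit
        raise ValueError(f"no covering prefix for {kmer[: self.max_len]!r}")

    @property
    def _by_prefix(self) -> dict[str, int]:
        d = self.__dict__.get("_by_prefix_cache")
        if d is None:
            d = {p: b for p, b in self.entries}
            self.__dict__["_by_prefix_cache"] = d
        return d

    def lookup_array(self) -> np.ndarray:
        """bin_id indexed by the base-4 value of the first max_len bases."""
        a = self.__dict__.get("_lookup_cache")
        if a is None:
            m = self.max_len
            a = np.empty(4 ** m, dtype=np.int32)
            for prefix, bin_id in self.entries:
                v = kmer_core.encode_prefix_value(prefix)
                span = 4 ** (m - len(prefix))
                a[v * span : (v + 1) * span] = bin_id
            self.__dict__["_lookup_cache"] = a
        return a


def _modeled_mass(prefix: str) -> float:
    """Expected fraction of canonical k-mers carrying this prefix.

    First-base probabilities are the exact canonical-start distribution
    7/16, 5/16, 3/16, 1/16; later positions are modeled uniform, which is
    what the realized distribution looks like for k well above the prefix
    length.
    """
    return CANONICAL_START_MASS[prefix[0]] * 0.25 ** (len(prefix) - 1)


def build_prefix_table(p1_min: int) -> PrefixTable:
    """Build the variable-length prefix table for a minimum prefix length.

    Starts from all 4^p1_min prefixes and repeatedly (at most twice) splits
    any prefix whose modeled canonical mass exceeds ``EXPANSION_THRESHOLD``
    times the mean mass of the initial table.  With the exact 7/16..1/16
    start distribution this splits A-, C- and G-start prefixes one symbol
    deeper and leaves the light T-start prefixes short, flattening realized
    bin occupancies relative to a fixed-length table.  Deterministic for a
    given p1_min.
    """
    if p1_min not in (3, 4, 5):
        raise ValueError(f"p1_min must be 3, 4 or 5, got {p1_min}")
    mean_mass = 4.0 ** -p1_min
    threshold = EXPANSION_THRESHOLD * mean_mass

    def expand(prefix: str, depth: int) -> list[str]:
        if depth < MAX_EXPANSIONS and _modeled_mass(prefix) > threshold:
            out: list[str] = []
            for b in kmer_core.BASES:
                out.extend(expand(prefix + b, depth + 1))
            return out
        return [prefix]

    prefixes: list[str] = []
    for v in range(4 ** p1_min):
        s = "".join(
            kmer_core.BASES[(v >> (2 * (p1_min - 1 - i))) & 3] for i in range(p1_min)
        )
        prefixes.extend(expand(s, 0))
    # lexicographic order of a prefix-free set is unambiguous
    prefixes.sort()
    return PrefixTable(p1_min, tuple((p, i) for i, p in enumerate(prefixes)))


def assign_bin(x: kmer_core.PackedKmer, table: PrefixTable) -> int:
    """Bin id of a canonical k-mer (scalar convenience over ``match``)."""
    return table.match(x.decode())[1]


def assign_bins_batch(words: np.ndarray, k: int, table: PrefixTable) -> np.ndarray:
    """Vectorized bin assignment for a batch of packed canonical k-mers."""
    key = kmer_core.extract_bases(words, k, 0, table.max_len)
    return table.lookup_array()[key.astype(np.int64)]


def estimate_disk_usage(n_k: int, k: int, p1_len: int, p2: int, mode: str) -> float:
    """Worst-case temporary disk bytes for n_k k-mers.

    Classic counters: n_k(k-p1-p2)/4 + 2*4^p2*n_k/2^15.  Quake-compatible
    counters carry a 4-byte weight per k-mer, adding 16 quarter-bytes:
    n_k(k-p1-p2+16)/4 + 2*4^p2*n_k/2^15.
    """
    if (k - p1_len - p2) % 4 != 0 or k - p1_len - p2 < 0:
        raise ValueError("k - p1 - p2 must be a non-negative multiple of 4")
    extra = 16 if mode == "quake" else 0
    return n_k * (k - p1_len - p2 + extra) / 4 + 2 * 4 ** p2 * n_k / 2 ** 15


def choose_p2(k: int, p1_len: int, mode: str = "classic") -> int:
    """Per-bin p2 minimizing the worst-case temporary disk usage.

    Feasible p2 keep k-p1-p2 a non-negative multiple of 4 (byte-aligned
    suffixes).  The worst-case formula is linear in n_k, so the argmin does
    not depend on the dataset size; ties break toward smaller p2.
    """
    if k <= p1_len:
        raise ValueError(f"no feasible p2 for k={k}, p1_len={p1_len}")
    base = (k - p1_len) % 4
    candidates = range(base, k - p1_len + 1, 4)
    ref_nk = 1 << 15
    return min(candidates, key=lambda p2: (estimate_disk_usage(ref_nk, k, p1_len, p2, mode), p2))


@dataclass
class BinBuffer:
    """In-memory accumulator for one bin; flushed when full."""

    bin_id: int
    prefix: str
    k: int
    p2: int
    capacity: int = BIN_CAPACITY
    _words: list[np.ndarray] = field(default_factory=list)
    _weights: list[np.ndarray] = field(default_factory=list)
    count: int = 0

    def room(self) -> int:
        return self.capacity - self.count

    def add(self, words: np.ndarray, weights: np.ndarray | None) -> None:
        if len(words) > self.room():
            raise ValueError("bin buffer overflow; caller must flush first")
        self._words.append(words)
        if weights is not None:
            self._weights.append(weights)
        self.count += len(words)

    def take(self) -> tuple[np.ndarray, np.ndarray | None]:
        words = np.concatenate(self._words) if self._words else np.empty(
            (0, kmer_core.nwords(self.k)), dtype=np.uint64
        )
        weights = np.concatenate(self._weights) if self._weights else None
        self._words.clear()
        self._weights.clear()
        self.count = 0
        return words, weights

    def nbytes(self) -> int:
        return self.count * (8 * kmer_core.nwords(self.k) + 8)


@dataclass
class CompactedChunk:
    """A flushed bin buffer: p2-group count block + packed k-mer suffixes.

    ``prefix_counts[j]`` is the number of entries whose p2_effective-base
    middle part has value j; suffixes are grouped by ascending j, stable in
    arrival order.  Counts stay below 2^16 because a chunk holds at most
    2^15 entries.
    """

    bin_id: int
    k: int
    p1_len: int
    p2_effective: int
    stripped: bool
    prefix_counts: np.ndarray  # int64, length 4^p2_effective
    suffixes: np.ndarray  # (m, sbytes) uint8, 4 bases per byte, left-aligned
    weights: np.ndarray | None = None  # float32, Quake mode only

    @property
    def m(self) -> int:
        return len(self.suffixes)

    @property
    def sbytes(self) -> int:
        return self.suffixes.shape[1]


def compact_chunk(buffer: BinBuffer, p2: int) -> CompactedChunk:
    """Counting-sort a full bin buffer by its p2-base middle part and strip
    that part, recording per-group counts for later recovery."""
    words, weights = buffer.take()
    if len(words) == 0:
        raise ValueError("cannot compact an empty buffer")
    k, p1_len = buffer.k, len(buffer.prefix)
    slen = k - p1_len - p2
    if slen < 0 or slen % 4:
        raise ValueError("k - p1 - p2 must be a non-negative multiple of 4")
    p2_id = kmer_core.extract_bases(words, k, p1_len, p2).astype(np.int64)
    order = np.argsort(p2_id, kind="stable")  # counting sort: 4^p2 buckets
    counts = np.bincount(p2_id, minlength=4 ** p2)
    sbytes = slen // 4
    byts = kmer_core.words_to_bytes(words)
    suffixes = (
        byts[:, byts.shape[1] - sbytes :][order]
        if sbytes
        else np.empty((len(words), 0), dtype=np.uint8)
    )
    w = weights[order].astype(np.float32) if weights is not None else None
    return CompactedChunk(
        bin_id=buffer.bin_id,
        k=k,
        p1_len=p1_len,
        p2_effective=p2,
        stripped=False,
        prefix_counts=counts,
        suffixes=np.ascontiguousarray(suffixes),
        weights=w,
    )


def maybe_strip_extra(chunk: CompactedChunk) -> CompactedChunk:
    """Strip 4 further bases into the count block when that saves space.

    Moving 4 bases (1 byte) per entry out of the suffix block saves m bytes
    but grows the two-byte count block from 4^p2 to 4^(p2+4) groups; the
    strip is applied only when m > 2*(4^(p2+4) - 4^p2).
    """
    if chunk.stripped or chunk.sbytes < 1:
        return chunk
    p2 = chunk.p2_effective
    growth = 2 * (4 ** (p2 + 4) - 4 ** p2)
    if chunk.m <= growth:
        return chunk
    old_ids = np.repeat(
        np.arange(len(chunk.prefix_counts), dtype=np.int64), chunk.prefix_counts
    )
    new_ids = old_ids * 256 + chunk.suffixes[:, 0].astype(np.int64)
    order = np.argsort(new_ids, kind="stable")
    counts = np.bincount(new_ids, minlength=4 ** (p2 + 4))
    return CompactedChunk(
        bin_id=chunk.bin_id,
        k=chunk.k,
        p1_len=chunk.p1_len,
        p2_effective=p2 + 4,
        stripped=True,
        prefix_counts=counts,
        suffixes=np.ascontiguousarray(chunk.suffixes[order][:, 1:]),
        weights=chunk.weights[order] if chunk.weights is not None else None,
    )


def write_bin_chunk(chunk: CompactedChunk, sink) -> int:
    """Append one self-delimiting chunk record to an open binary sink.

    Layout: header (entry count u32, p2_effective u8, strip flag u8, suffix
    bytes per entry u8, weight flag u8), count block (u16 little-endian per
    group), packed suffix block, then the float32 weight block in Quake
    mode.  Returns the number of bytes appended.
    """
    if chunk.prefix_counts.max(initial=0) >= 1 << 16:
        raise ValueError("group count overflows 2 bytes")
    header = CHUNK_HEADER.pack(
        chunk.m,
        chunk.p2_effective,
        int(chunk.stripped),
        chunk.sbytes,
        int(chunk.weights is not None),
    )
    counts = chunk.prefix_counts.astype("<u2").tobytes()
    body = chunk.suffixes.tobytes()
    wbytes = chunk.weights.astype("<f4").tobytes() if chunk.weights is not None else b""
    data = header + counts + body + wbytes
    sink.write(data)
    return len(data)


def read_bin_chunks(path: str | Path, bin_id: int, k: int, p1_len: int):
    """Yield the :class:`CompactedChunk` records appended to one bin file."""
    with open(path, "rb") as fh:
        while True:
            head = fh.read(CHUNK_HEADER.size)
            if not head:
                return
            if len(head) < CHUNK_HEADER.size:
                raise ValueError(f"{path}: truncated chunk header")
            m, p2_eff, stripped, sbytes, has_w = CHUNK_HEADER.unpack(head)
            n_groups = 4 ** p2_eff
            counts = np.frombuffer(fh.read(2 * n_groups), dtype="<u2").astype(np.int64)
            if len(counts) != n_groups or counts.sum() != m:
                raise ValueError(f"{path}: corrupt count block")
            raw = fh.read(m * sbytes)
            if len(raw) != m * sbytes:
                raise ValueError(f"{path}: truncated suffix block")
            suffixes = np.frombuffer(raw, dtype=np.uint8).reshape(m, sbytes)
            weights = None
            if has_w:
                wraw = fh.read(4 * m)
                if len(wraw) != 4 * m:
                    raise ValueError(f"{path}: truncated weight block")
                weights = np.frombuffer(wraw, dtype="<f4").astype(np.float32)
            yield CompactedChunk(
                bin_id=bin_id,
                k=k,
                p1_len=p1_len,
                p2_effective=p2_eff,
                stripped=bool(stripped),
                prefix_counts=counts,
                suffixes=suffixes,
                weights=weights,
            )
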