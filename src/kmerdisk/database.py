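"""Sorted on-disk k-mer dictionary: writer, iterator, binary-search lookup.

Two files make a database: ``<name>.kdb`` holds fixed-width records (packed
suffix of k - p1_min bases, 4 bases per byte left-aligned, followed by a
4-byte counter), and ``<name>.kdb.idx`` holds the header plus a prefix index:
for each of the 4^p1_min fixed-length prefixes, the starting record offset
and record count.  Records are sorted ascending by full k-mer, so a lookup
canonicalizes its query, jumps to the prefix slice via the index and binary
searches the packed suffix; the whole file can also be read sequentially in
sorted order.  The index always uses fixed-length p1_min prefixes even when
the distribution phase used longer bin prefixes; sorted order is unaffected.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from kmerdisk import kmer_core

MAGIC = b"KDBX"
VERSION = 1

_HEADER = struct.Struct("<4sHHBBHddQ")
# magic, version, k, mode(0 classic/1 quake), p1_min, reserved, min_t, max_t, total

_MODES = {"classic": 0, "quake": 1}
_MODE_NAMES = {v: m for m, v in _MODES.items()}


def _suffix_bytes(k: int, p1_min: int) -> int:
    return (k - p1_min + 3) // 4


def _pack_left(words: np.ndarray, k: int, start: int, length: int) -> np.ndarray:
    """Pack bases [start, start+length) left-aligned, 4 per byte.

    Left alignment (first base in the high bits, zero-padded at the tail)
    makes byte-wise comparison of equal-length suffixes lexicographic.
    """
    n = len(words)
    nb = (length + 3) // 4
    out = np.zeros((n, nb), dtype=np.uint8)
    for j in range(nb):
        take = min(4, length - 4 * j)
        v = kmer_core.extract_bases(words, k, start + 4 * j, take)
        out[:, j] = (v << np.uint64(2 * (4 - take))).astype(np.uint8)
    return out


class DatabaseWriter:
    """Streams globally sorted, distinct (k-mer, count) batches to disk."""

    def __init__(
        self,
        name: str | Path,
        k: int,
        p1_min: int,
        mode: str,
        min_threshold: float,
        max_threshold: float,
    ) -> None:
        self.path = Path(str(name) if str(name).endswith(".kdb") else f"{name}.kdb")
        self.k = k
        self.p1_min = p1_min
        self.mode = mode
        self.min_threshold = min_threshold
        self.max_threshold = max_threshold
        self._counts = np.zeros(4 ** p1_min, dtype=np.int64)
        self._total = 0
        self._last: bytes | None = None
        self._sb = _suffix_bytes(k, p1_min)
        self._fh = open(self.path, "wb")

    def append(self, kmers: np.ndarray, counts: np.ndarray) -> None:
        """Append a sorted, distinct batch that follows all previous ones."""
        if len(kmers) == 0:
            return
        prefix_vals = kmer_core.extract_bases(kmers, self.k, 0, self.p1_min)
        full = np.concatenate(
            [
                prefix_vals.astype(">u8").view(np.uint8).reshape(len(kmers), 8)[:, -2:],
                _pack_left(kmers, self.k, self.p1_min, self.k - self.p1_min),
            ],
            axis=1,
        )
        if len(full) > 1:
            a, b = full[:-1], full[1:]
            less = np.zeros(len(a), dtype=bool)
            decided = np.zeros(len(a), dtype=bool)
            for j in range(full.shape[1]):
                less |= ~decided & (a[:, j] < b[:, j])
                decided |= a[:, j] != b[:, j]
            if not less.all():
                raise ValueError("database input batch not sorted/distinct")
        first = full[0].tobytes()
        if self._last is not None and first <= self._last:
            raise ValueError("database batches out of order")
        self._last = full[-1].tobytes()
        self._counts += np.bincount(
            prefix_vals.astype(np.int64), minlength=4 ** self.p1_min
        )
        self._total += len(kmers)
        if self.mode == "quake":
            cbytes = counts.astype("<f4").view(np.uint8).reshape(len(kmers), 4)
        else:
            cbytes = (
                np.minimum(counts, (1 << 32) - 1)
                .astype("<u4")
                .view(np.uint8)
                .reshape(len(kmers), 4)
            )
        rec = np.concatenate([full[:, 2:], cbytes], axis=1)
        self._fh.write(np.ascontiguousarray(rec).tobytes())

    def close(self) -> "KmerDatabase":
        self._fh.close()
        offsets = np.concatenate(([0], np.cumsum(self._counts)[:-1]))
        with open(self.path.with_suffix(".kdb.idx"), "wb") as fh:
            fh.write(
                _HEADER.pack(
                    MAGIC,
                    VERSION,
                    self.k,
                    _MODES[self.mode],
                    self.p1_min,
                    0,
                    float(self.min_threshold),
                    float(self.max_threshold),
                    self._total,
                )
            )
            fh.write(offsets.astype("<u8").tobytes())
            fh.write(self._counts.astype("<u8").tobytes())
        return KmerDatabase(self.path)


def write_database(
    stream,
    name: str | Path,
    k: int,
    p1_min: int,
    mode: str = "classic",
    min_threshold: float = 1,
    max_threshold: float = float("inf"),
) -> "KmerDatabase":
    """Persist a globally sorted stream of (kmers, counts) array batches."""
    writer = DatabaseWriter(name, k, p1_min, mode, min_threshold, max_threshold)
    try:
        for kmers, counts in stream:
            writer.append(kmers, counts)
    except Exception:
        writer._fh.close()
        raise
    return writer.close()


# 4-base string spelled by each byte value, used to decode packed suffixes
_BYTE_TO_4MER = np.array(
    [
        "".join(kmer_core.BASES[(b >> (2 * (3 - i))) & 3] for i in range(4))
        for b in range(256)
    ],
    dtype="S4",
)


@dataclass
class KmerDatabase:
    """Read-only view of a written database."""

    path: Path

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.path.suffix != ".kdb":
            self.path = self.path.with_name(self.path.name + ".kdb")
        with open(self.path.with_suffix(".kdb.idx"), "rb") as fh:
            head = fh.read(_HEADER.size)
            magic, version, k, mode, p1_min, _res, min_t, max_t, total = _HEADER.unpack(head)
            if magic != MAGIC or version != VERSION:
                raise ValueError(f"{self.path}: not a kmerdisk database")
            self.k = k
            self.mode = _MODE_NAMES[mode]
            self.p1_min = p1_min
            self.min_threshold = min_t
            self.max_threshold = max_t
            self.total_records = total
            n_pref = 4 ** p1_min
            raw = fh.read(16 * n_pref)
            if len(raw) != 16 * n_pref:
                raise ValueError(f"{self.path}: corrupt prefix index")
            self.prefix_offsets = np.frombuffer(raw[: 8 * n_pref], dtype="<u8").astype(np.int64)
            self.prefix_counts = np.frombuffer(raw[8 * n_pref :], dtype="<u8").astype(np.int64)
        if self.prefix_counts.sum() != total:
            raise ValueError(f"{self.path}: index does not partition the records")
        if np.any(np.diff(self.prefix_offsets) < 0):
            raise ValueError(f"{self.path}: index offsets not monotone")
        self._sb = _suffix_bytes(self.k, self.p1_min)
        self._rec = self._sb + 4

    # -- record access ------------------------------------------------------

    def _read_records(self, offset: int, count: int) -> np.ndarray:
        with open(self.path, "rb") as fh:
            fh.seek(offset * self._rec)
            raw = fh.read(count * self._rec)
        if len(raw) != count * self._rec:
            raise ValueError(f"{self.path}: truncated records file")
        return np.frombuffer(raw, dtype=np.uint8).reshape(count, self._rec)

    def _decode_counts(self, rec: np.ndarray) -> np.ndarray:
        cbytes = np.ascontiguousarray(rec[:, self._sb :])
        if self.mode == "quake":
            return cbytes.view("<f4").ravel().astype(np.float64)
        return cbytes.view("<u4").ravel().astype(np.int64)

    def counts_array(self) -> np.ndarray:
        """All stored counters in record (sorted) order."""
        rec = self._read_records(0, self.total_records)
        return self._decode_counts(rec)

    def iterate_batches(self) -> Iterator[tuple[list[str], np.ndarray]]:
        """Sequential scan as (k-mer strings, counts) batches per prefix."""
        for pv in range(4 ** self.p1_min):
            cnt = int(self.prefix_counts[pv])
            if cnt == 0:
                continue
            rec = self._read_records(int(self.prefix_offsets[pv]), cnt)
            prefix = "".join(
                kmer_core.BASES[(pv >> (2 * (self.p1_min - 1 - i))) & 3]
                for i in range(self.p1_min)
            )
            slen = self.k - self.p1_min
            quads = _BYTE_TO_4MER[rec[:, : self._sb]]
            tails = quads.view(f"S{4 * self._sb}").ravel().astype(str)
            strings = [prefix + t[:slen] for t in tails]
            yield strings, self._decode_counts(rec)

    def iterate(self) -> Iterator[tuple[str, float]]:
        """Yield (k-mer string, count) in ascending canonical order."""
        for strings, counts in self.iterate_batches():
            yield from zip(strings, counts.tolist())

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for strings, counts in self.iterate_batches():
            out.update(zip(strings, counts.tolist()))
        return out

    # -- lookup -------------------------------------------------------------

    def lookup(self, query: str):
        """Count of one k-mer, or None if absent (or the query contains N).

        The query is canonicalized first, so ``lookup(x) == lookup(rc(x))``.
        """
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != k={self.k}")
        try:
            x = kmer_core.canonical(kmer_core.encode(query))
        except kmer_core.InvalidBaseError:
            return None
        pv = x.value >> (2 * (self.k - self.p1_min))
        cnt = int(self.prefix_counts[pv])
        if cnt == 0:
            return None
        slen = self.k - self.p1_min
        target = (
            (x.value & ((1 << (2 * slen)) - 1)) << (2 * (4 * self._sb - slen))
        ).to_bytes(self._sb, "big")
        rec = self._read_records(int(self.prefix_offsets[pv]), cnt)
        lo, hi = 0, cnt  # standard binary search over the prefix slice
        while lo < hi:
            mid = (lo + hi) // 2
            if rec[mid, : self._sb].tobytes() < target:
                lo = mid + 1
            else:
                hi = mid
        i = lo
        if i == cnt or rec[i, : self._sb].tobytes() != target:
            return None
        count = self._decode_counts(rec[i : i + 1])[0]
        return float(count) if self.mode == "quake" else int(count)

    # -- statistics ---------------------------------------------------------

    def spectrum_stats(self) -> dict[str, float]:
        """Spectrum categories: total, distinct, singletons, non-singletons.

        total sums all stored counters; distinct is the record count;
        singletons are records with count == 1 (classic) or count < 2.0
        (quake, where fractional counts make exact equality meaningless);
        distinct non-singletons is the complement within distinct.
        """
        counts = self.counts_array()
        distinct = len(counts)
        if self.mode == "quake":
            singles = int((counts < 2.0).sum())
            total = float(counts.sum())
        else:
            singles = int((counts == 1).sum())
            total = int(counts.sum())
        return {
            "total": total,
            "distinct": distinct,
            "singletons": singles,
            "distinct_non_singletons": distinct - singles,
        }


def spectrum_stats(db: KmerDatabase) -> dict[str, float]:
    return db.spectrum_stats()


def lookup(db: KmerDatabase, query: str):
    return db.lookup(query)


def iterate(db: KmerDatabase) -> Iterator[tuple[str, float]]:
    return db.iterate()
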