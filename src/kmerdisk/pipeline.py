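"""Orchestration of the two-phase disk-based counting run.

``run`` streams reads, distributes canonical k-mers into temporary bin files
(phase 1), then sorts and counts each bin and writes the final sorted
database (phase 2).  Bins are independent: any processing order and any
worker count produce a byte-identical database, because the completer emits
results strictly in ascending bin id.  A sequential execution is therefore a
valid (and the default) schedule; ``worker_count > 1`` sorts bins in a thread
pool.
"""

from __future__ import annotations

import math
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from kmerdisk import distribution, kmer_core, seq_io, sorting
from kmerdisk.database import DatabaseWriter, KmerDatabase

#: input-size thresholds for automatic minimum prefix length selection:
#: small collections get -p3, middle-sized -p4, large -p5
P1_AUTO_THRESHOLDS = ((1 << 30, 3), (20 << 30, 4))

DEFAULT_MEMORY_LIMIT = 512 << 20
MIN_BIN_CAPACITY = 64

_BATCH_READS = 8192  # reads per extraction batch in phase 1


@dataclass
class Config:
    """Resolved run parameters; ``auto_tune`` fills the None fields."""

    k: int
    output: str | Path = "kmers"
    p1_min: int | None = None
    memory_limit: int = DEFAULT_MEMORY_LIMIT
    tmp_dir: str | Path | None = None
    worker_count: int = 1
    counter_mode: str = "classic"
    min_threshold: float | None = None
    max_threshold: float = math.inf
    quality_offset: int = 33
    keep_tmp: bool = False
    bin_capacity: int | None = None

    def __post_init__(self) -> None:
        if not kmer_core.K_MIN <= self.k <= kmer_core.K_MAX:
            raise ValueError(f"k must satisfy 10 < k <= 256, got {self.k}")
        if self.counter_mode not in ("classic", "quake"):
            raise ValueError(f"unknown counter mode {self.counter_mode!r}")
        if self.min_threshold is not None and self.min_threshold > self.max_threshold:
            raise ValueError("min_threshold exceeds max_threshold")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")

    @property
    def resolved_min_threshold(self) -> float:
        if self.min_threshold is not None:
            return self.min_threshold
        return 2 if self.counter_mode == "classic" else 2.0


@dataclass
class RunReport:
    """Statistics of one counting run."""

    n_reads: int = 0
    n_kmers: int = 0  # valid k-mers extracted (pre-filter total count)
    prefilter_total: int = 0  # sum of classic counts before thresholding
    n_bins: int = 0
    n_chunks: int = 0
    temp_bytes_written: int = 0
    header_overhead_bytes: int = 0  # chunk headers + partial-chunk count blocks
    peak_buffered_bytes: int = 0
    worst_case_disk_bytes: float = 0.0
    spectrum: dict = field(default_factory=dict)


def auto_tune(config: Config, input_bytes: int) -> Config:
    """Fill unset parameters from the dataset size and memory budget.

    p1_min follows the small/middle/large input rule unless user-set; the
    per-bin buffer capacity is shrunk below the 2^15 default when the full
    set of buffers would not fit the memory limit.
    """
    p1_min = config.p1_min
    if p1_min is None:
        p1_min = 5
        for limit, value in P1_AUTO_THRESHOLDS:
            if input_bytes < limit:
                p1_min = value
                break
    table = distribution.build_prefix_table(p1_min)
    entry_bytes = 8 * kmer_core.nwords(config.k) + 8
    capacity = config.bin_capacity
    if capacity is None:
        capacity = min(
            distribution.BIN_CAPACITY,
            max(config.memory_limit // (table.n_bins * entry_bytes), 0),
        )
    if capacity < MIN_BIN_CAPACITY:
        floor = table.n_bins * entry_bytes * MIN_BIN_CAPACITY
        raise ValueError(
            f"memory_limit {config.memory_limit} below the floor {floor} "
            f"for {table.n_bins} bins"
        )
    return replace(config, p1_min=p1_min, bin_capacity=capacity)


def _input_size(paths: Sequence[str | Path]) -> int:
    return sum(os.path.getsize(p) for p in paths)


def _tmp_path(tmp_dir: Path, bin_id: int) -> Path:
    return tmp_dir / f"kmerdisk_bin_{bin_id}.bin"


def _batches(records: Iterable[seq_io.ReadRecord], size: int):
    batch: list[seq_io.ReadRecord] = []
    for rec in records:
        batch.append(rec)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


class _Phase1:
    """Distributes extracted k-mers into temporary bin files."""

    def __init__(self, config: Config, table: distribution.PrefixTable, tmp_dir: Path):
        self.config = config
        self.table = table
        self.tmp_dir = tmp_dir
        k = config.k
        self.p2_by_bin = [
            distribution.choose_p2(k, len(p), config.counter_mode)
            for p, _ in table.entries
        ]
        self.buffers = [
            distribution.BinBuffer(
                bin_id=b,
                prefix=table.prefix_of(b),
                k=k,
                p2=self.p2_by_bin[b],
                capacity=config.bin_capacity,
            )
            for b in range(table.n_bins)
        ]
        self.handles: dict[int, object] = {}
        self.report = RunReport(n_bins=table.n_bins)

    def _flush(self, bin_id: int) -> None:
        buf = self.buffers[bin_id]
        if buf.count == 0:
            return
        partial = buf.count < buf.capacity
        chunk = distribution.compact_chunk(buf, self.p2_by_bin[bin_id])
        chunk = distribution.maybe_strip_extra(chunk)
        fh = self.handles.get(bin_id)
        if fh is None:
            fh = open(_tmp_path(self.tmp_dir, bin_id), "wb")
            self.handles[bin_id] = fh
        nbytes = distribution.write_bin_chunk(chunk, fh)
        self.report.n_chunks += 1
        self.report.temp_bytes_written += nbytes
        overhead = distribution.CHUNK_HEADER.size
        if partial:
            overhead += 2 * 4 ** chunk.p2_effective
        self.report.header_overhead_bytes += overhead

    def add_batch(self, records: list[seq_io.ReadRecord]) -> None:
        cfg = self.config
        words, weights = seq_io.batch_canonical_kmers(
            records, cfg.k, with_weights=cfg.counter_mode == "quake"
        )
        self.report.n_reads += len(records)
        self.report.n_kmers += len(words)
        if len(words) == 0:
            return
        bins = distribution.assign_bins_batch(words, cfg.k, self.table)
        order = np.argsort(bins, kind="stable")
        sorted_bins = bins[order]
        uniq, starts = np.unique(sorted_bins, return_index=True)
        ends = np.append(starts[1:], len(sorted_bins))
        for b, s, e in zip(uniq.tolist(), starts.tolist(), ends.tolist()):
            idx = order[s:e]
            seg_words = words[idx]
            seg_weights = weights[idx] if weights is not None else None
            pos = 0
            buf = self.buffers[b]
            while pos < len(seg_words):
                take = min(buf.room(), len(seg_words) - pos)
                buf.add(
                    seg_words[pos : pos + take],
                    seg_weights[pos : pos + take] if seg_weights is not None else None,
                )
                pos += take
                if buf.room() == 0:
                    self._flush(b)
        buffered = sum(buf.nbytes() for buf in self.buffers)
        self.report.peak_buffered_bytes = max(self.report.peak_buffered_bytes, buffered)

    def finish(self) -> None:
        for b in range(len(self.buffers)):
            self._flush(b)
        for fh in self.handles.values():
            fh.close()


def _count_bin(
    words: np.ndarray, weights: np.ndarray | None, mode: str, max_rows: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sort-and-count one bin, splitting into sub-chunks when it exceeds
    the in-memory sorting budget (results are identical either way)."""
    if len(words) <= max_rows:
        s_words, s_weights = sorting.radix_sort(words, weights)
        return sorting.count_runs(s_words, s_weights, mode)
    parts_k: list[np.ndarray] = []
    parts_c: list[np.ndarray] = []
    for start in range(0, len(words), max_rows):
        sw, swt = sorting.radix_sort(
            words[start : start + max_rows],
            weights[start : start + max_rows] if weights is not None else None,
        )
        uk, uc = sorting.count_runs(sw, swt, mode)
        parts_k.append(uk)
        parts_c.append(uc)
    merged = np.concatenate(parts_k)
    mcounts = np.concatenate(parts_c).astype(np.float64 if mode == "quake" else np.int64)
    s_words, s_counts = sorting.radix_sort(merged, mcounts)
    new_run = np.ones(len(s_words), dtype=bool)
    new_run[1:] = (s_words[1:] != s_words[:-1]).any(axis=1)
    starts = np.flatnonzero(new_run)
    return np.ascontiguousarray(s_words[starts]), np.add.reduceat(s_counts, starts)


def run(
    config: Config,
    inputs: Sequence[str | Path],
    bin_order: Sequence[int] | None = None,
) -> tuple[KmerDatabase, RunReport]:
    """Execute the full two-phase counting pipeline.

    ``bin_order`` overrides the phase-2 processing order (for testing bin
    independence); the final database does not depend on it, nor on
    ``worker_count``.
    """
    if not inputs:
        raise ValueError("no input files")
    config = auto_tune(config, _input_size(inputs))
    table = distribution.build_prefix_table(config.p1_min)
    tmp_dir = Path(config.tmp_dir) if config.tmp_dir else Path(config.output).parent
    tmp_dir.mkdir(parents=True, exist_ok=True)
    for b in range(table.n_bins):  # drop stale bin files from earlier runs
        _tmp_path(tmp_dir, b).unlink(missing_ok=True)

    phase1 = _Phase1(config, table, tmp_dir)
    try:
        records = seq_io.open_sequence_stream(inputs, quality_offset=config.quality_offset)
        for batch in _batches(records, _BATCH_READS):
            phase1.add_batch(batch)
        phase1.finish()
        report = phase1.report

        p2_min = distribution.choose_p2(config.k, config.p1_min, config.counter_mode)
        report.worst_case_disk_bytes = distribution.estimate_disk_usage(
            report.n_kmers, config.k, config.p1_min, p2_min, config.counter_mode
        )

        mode = config.counter_mode
        min_t = config.resolved_min_threshold
        max_t = config.max_threshold
        row_bytes = 8 * kmer_core.nwords(config.k) * 4 + 16
        max_rows = max(config.memory_limit // row_bytes, 1 << 16)

        def process_bin(bin_id: int) -> tuple[int, np.ndarray, np.ndarray, int]:
            prefix = table.prefix_of(bin_id)
            path = _tmp_path(tmp_dir, bin_id)
            w = kmer_core.nwords(config.k)
            if not path.exists():
                empty = np.empty((0, w), dtype=np.uint64)
                return bin_id, empty, np.empty(0), 0
            parts = [
                sorting.expand_chunk(c, prefix)
                for c in distribution.read_bin_chunks(path, bin_id, config.k, len(prefix))
            ]
            words = np.concatenate([p[0] for p in parts])
            weights = (
                np.concatenate([p[1] for p in parts]) if mode == "quake" else None
            )
            kmers, counts = _count_bin(words, weights, mode, max_rows)
            kmers, counts = sorting.filter_counts(kmers, counts, min_t, max_t)
            return bin_id, kmers, counts, len(words)

        order = list(bin_order) if bin_order is not None else list(range(table.n_bins))
        if sorted(order) != list(range(table.n_bins)):
            raise ValueError("bin_order must be a permutation of all bin ids")

        if config.worker_count == 1:
            completed = (process_bin(b) for b in order)
        else:
            pool = ThreadPoolExecutor(max_workers=config.worker_count)
            completed = pool.map(process_bin, order)

        writer = DatabaseWriter(
            config.output,
            config.k,
            config.p1_min,
            mode,
            min_t,
            max_t,
        )
        results = []
        for bin_id, kmers, counts, n_entries in completed:
            report.prefilter_total += n_entries
            results.append((bin_id, kmers, counts))
        if config.worker_count > 1:
            pool.shutdown()
        for _bin_id, kmers, counts in sorting.merge_bins_in_order(results):
            writer.append(kmers, counts)
        db = writer.close()
        report.spectrum = db.spectrum_stats()
        return db, report
    finally:
        if not config.keep_tmp:
            for b in range(table.n_bins):
                _tmp_path(tmp_dir, b).unlink(missing_ok=True)
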