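"""Synthetic read sets with known k-mer spectra, and the naive oracle counter.

The generator emulates a shotgun sequencing experiment at desk scale: reads
are drawn uniformly from both strands of a random genome, with per-base
substitution errors, occasional N calls, and a two-level quality model (high
quality everywhere, low quality at error positions) so that quality-weighted
counts differ measurably from classic counts.  The oracle is an independent
in-memory hash-table counter with the same canonicalization, N-skipping,
weighting and threshold semantics as the disk-based pipeline; it is the
ground truth every equivalence test compares against.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

HIGH_Q = 40  # Phred score of a clean base call
LOW_Q = 3  # Phred score at injected error positions

_COMP = str.maketrans("ACGTN", "TGCAN")
_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic read set.

    Defaults model a small high-coverage experiment: a 100 kb genome read to
    30-fold coverage with 100 bp reads, 1% substitution errors and 0.1% N
    calls — enough depth that true k-mers are well separated from singleton
    errors.
    """

    genome_length: int = 100_000
    coverage: float = 30.0
    read_length: int = 100
    substitution_rate: float = 0.01
    n_rate: float = 0.001
    quality_model: str = "two-level"  # or "constant"
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.n_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.quality_model not in ("two-level", "constant"):
            raise ValueError(f"unknown quality model {self.quality_model!r}")

    @property
    def n_reads(self) -> int:
        return int(round(self.genome_length * self.coverage / self.read_length))


def _phred_char(q: int) -> str:
    return chr(q + 33)


def generate_reads(
    spec: SyntheticSpec,
    out_dir: str | Path,
    n_files: int = 1,
    compress: bool = False,
    basename: str = "reads",
) -> list[Path]:
    """Write a deterministic synthetic FASTQ dataset; returns the paths.

    Reads are split contiguously over ``n_files`` (emulating multi-file
    datasets); ``compress`` writes gzip members instead of plain text.  The
    record stream is byte-identical for a fixed spec regardless of splitting
    or compression.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = rng.integers(0, 4, size=spec.genome_length, dtype=np.uint8)
    r = spec.read_length
    n = spec.n_reads
    starts = rng.integers(0, spec.genome_length - r + 1, size=n)
    strands = rng.integers(0, 2, size=n)

    records: list[str] = []
    for i in range(n):
        codes = genome[starts[i] : starts[i] + r].copy()
        if strands[i]:
            codes = 3 - codes[::-1]
        err = rng.random(r) < spec.substitution_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            codes[err] = (codes[err] + shift) % 4
        seq = bases[codes].tobytes().decode("ascii")
        if spec.quality_model == "constant":
            qual = _phred_char(HIGH_Q) * r
        else:
            q = np.full(r, HIGH_Q + 33, dtype=np.uint8)
            q[err] = LOW_Q + 33
            qual = q.tobytes().decode("ascii")
        ns = rng.random(r) < spec.n_rate
        if ns.any():
            s = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            s[ns] = ord("N")
            seq = s.tobytes().decode("ascii")
        records.append(f"@read_{i}\n{seq}\n+\n{qual}\n")

    per_file = math.ceil(n / n_files) if n else 0
    paths: list[Path] = []
    for f in range(n_files):
        chunk = records[f * per_file : (f + 1) * per_file]
        suffix = ".fastq.gz" if compress else ".fastq"
        path = out_dir / f"{basename}_{f}{suffix}"
        payload = "".join(chunk).encode("ascii")
        if compress:
            with gzip.GzipFile(path, "wb", mtime=0) as fh:
                fh.write(payload)
        else:
            path.write_bytes(payload)
        paths.append(path)
    return paths


def oracle_count(
    paths,
    k: int,
    mode: str = "classic",
    min_threshold: float | None = None,
    max_threshold: float = math.inf,
    quality_offset: int = 33,
) -> dict[str, float]:
    """Naive in-memory canonical k-mer counter (the ground-truth baseline).

    A plain hash table keyed by the canonical k-mer string; windows with a
    non-ACGT base are skipped; Quake mode accumulates the product-of-
    correctness-probability weight of each occurrence, rounded per occurrence
    to 4-byte float precision (the precision at which any single occurrence
    weight is representable) and summed in double precision in encounter
    order.  ``min_threshold`` defaults to 1 (classic) / 0.0 (quake), i.e. no
    filtering.
    """
    from kmerdisk.seq_io import open_sequence_stream, window_weights

    if min_threshold is None:
        min_threshold = 1 if mode == "classic" else 0.0
    counts: dict[str, float] = {}
    for rec in open_sequence_stream(paths, quality_offset=quality_offset):
        seq = rec.bases.upper()
        r = len(seq)
        if r < k:
            continue
        rc = seq.translate(_COMP)[::-1]
        bad_positions = [m.start() for m in _NON_ACGT.finditer(seq)]
        bad_iter = iter(bad_positions + [r + k])
        next_bad = next(bad_iter)
        if mode == "quake":
            q = rec.qualities if rec.qualities is not None else np.zeros(r, dtype=np.int16)
            wts = window_weights(q, k).astype(np.float32)
        for i in range(r - k + 1):
            while next_bad < i:
                next_bad = next(bad_iter)
            if next_bad < i + k:
                continue
            fwd = seq[i : i + k]
            rev = rc[r - i - k : r - i]
            canon = fwd if fwd <= rev else rev
            if mode == "quake":
                counts[canon] = counts.get(canon, 0.0) + float(wts[i])
            else:
                counts[canon] = counts.get(canon, 0) + 1
    kept = {s: c for s, c in counts.items() if min_threshold <= c <= max_threshold}
    if mode == "quake":
        # report at the 4-byte precision the on-disk dictionary stores,
        # after thresholding on the full double-precision sums
        kept = {s: float(np.float32(c)) for s, c in kept.items()}
    return kept
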