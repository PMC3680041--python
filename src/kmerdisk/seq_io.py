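"""Streaming FASTQ/FASTA input and canonical k-mer extraction.

Input files may be plain or gzip-compressed (sniffed from the magic bytes);
the format is detected from the first record leader ('@' FASTQ, '>' FASTA).
Multiple files are concatenated in the given order.  Windows containing any
non-ACGT symbol (N, IUPAC ambiguity codes) yield no k-mer; the read itself is
kept and its clean windows are still counted.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from kmerdisk import kmer_core
from kmerdisk.kmer_core import INVALID_CODE, PackedKmer, codes_from_sequence

R_MAX = 10240  # longest supported read

DEFAULT_QUALITY_OFFSET = 33  # Phred+33, the modern FASTQ dialect


class SequenceFormatError(ValueError):
    """Malformed FASTQ/FASTA input; message names the file and record."""


@dataclass
class ReadRecord:
    """One sequencing read: id, bases, and optional Phred qualities.

    ``qualities`` is None for FASTA input; when present it aligns one-to-one
    with ``bases``.
    """

    id: str
    bases: str
    qualities: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.bases)


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def _sniff_format(handle: io.TextIOBase, path) -> str:
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            raise SequenceFormatError(f"{path}: empty sequence file")
        if line.strip():
            handle.seek(pos)
            break
    lead = line[0]
    if lead == "@":
        return "fastq"
    if lead == ">":
        return "fasta"
    raise SequenceFormatError(f"{path}: unrecognized format (leader {lead!r})")


def open_sequence_stream(
    paths: Sequence[str | Path], quality_offset: int = DEFAULT_QUALITY_OFFSET
) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from FASTQ/FASTA files, plain or gzipped.

    Records appear in file order then record order; FASTA records carry no
    qualities.  Malformed records raise :class:`SequenceFormatError` naming
    the file and the record index.
    """
    for path in paths:
        handle = _open_maybe_gzip(path)
        fmt = _sniff_format(handle, path)
        index = -1
        try:
            if fmt == "fastq":
                for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                    if len(seq) != len(qual):
                        raise SequenceFormatError(
                            f"{path}: record {index}: sequence/quality length mismatch"
                        )
                    if len(seq) > R_MAX:
                        raise SequenceFormatError(
                            f"{path}: record {index}: read longer than {R_MAX}"
                        )
                    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                        np.int16
                    ) - quality_offset
                    if q.size and q.min() < 0:
                        raise SequenceFormatError(
                            f"{path}: record {index}: negative Phred score "
                            f"(wrong --quality-offset?)"
                        )
                    yield ReadRecord(title.split()[0] if title else "", seq, q)
            else:
                for index, (title, seq) in enumerate(SimpleFastaParser(handle)):
                    if len(seq) > R_MAX:
                        raise SequenceFormatError(
                            f"{path}: record {index}: sequence longer than {R_MAX}"
                        )
                    yield ReadRecord(title.split()[0] if title else "", seq, None)
        except ValueError as exc:
            if isinstance(exc, SequenceFormatError):
                raise
            raise SequenceFormatError(
                f"{path}: record {index + 1}: {exc}"
            ) from exc
        finally:
            handle.close()


def extract_kmers(
    read: ReadRecord, k: int
) -> Iterator[tuple[PackedKmer, np.ndarray | None]]:
    """Canonical k-mers of one read with their window qualities.

    Yields one item per window position whose bases are all A/C/G/T; window
    qualities are the scores of the window in the ORIGINAL read orientation,
    kept even when the canonical form is the reverse complement (the quality
    weight is a product over bases, hence orientation-independent).  A read
    shorter than k yields nothing; an N-free read yields exactly r-k+1 items.
    """
    codes = codes_from_sequence(read.bases)
    words, starts = kmer_core.canonical_windows(codes, k)
    for row, s in zip(words, starts):
        qual = read.qualities[s : s + k] if read.qualities is not None else None
        yield PackedKmer.from_words(row, k), qual


# ---------------------------------------------------------------------------
# batch extraction used by the pipeline and the oracle
# ---------------------------------------------------------------------------

def concat_records(records: Iterable[ReadRecord]) -> tuple[np.ndarray, np.ndarray | None]:
    """Concatenate reads into one code array with invalid-code separators.

    A single separator between consecutive reads suffices: any window that
    crosses a read boundary contains the separator and is therefore skipped
    by the validity mask.  Qualities (where present) are concatenated with a
    zero at separator positions; reads without qualities get zeros, which is
    only meaningful in classic mode.
    """
    code_parts: list[np.ndarray] = []
    qual_parts: list[np.ndarray] = []
    sep = np.array([INVALID_CODE], dtype=np.uint8)
    qsep = np.zeros(1, dtype=np.int16)
    any_qual = False
    for rec in records:
        code_parts.append(codes_from_sequence(rec.bases))
        code_parts.append(sep)
        if rec.qualities is not None:
            any_qual = True
            qual_parts.append(rec.qualities.astype(np.int16))
        else:
            qual_parts.append(np.zeros(len(rec.bases), dtype=np.int16))
        qual_parts.append(qsep)
    if not code_parts:
        return np.empty(0, dtype=np.uint8), None
    codes = np.concatenate(code_parts)
    quals = np.concatenate(qual_parts) if any_qual else None
    return codes, quals


def batch_canonical_kmers(
    records: Iterable[ReadRecord], k: int, with_weights: bool = False
) -> tuple[np.ndarray, np.ndarray | None]:
    """Canonical packed k-mers (and optionally quality weights) for a batch
    of reads.  Returns ``(words (m, nwords), weights (m,) float64 or None)``.

    Weights are computed per read (not over the concatenated batch) so the
    value of a window's weight does not depend on how reads are batched.
    """
    records = list(records)
    codes, _ = concat_records(records)
    words, starts = kmer_core.canonical_windows(codes, k)
    if not with_weights:
        return words, None
    per_pos = np.zeros(max(len(codes), 1), dtype=np.float64)
    offset = 0
    for rec in records:
        r = len(rec.bases)
        if r >= k:
            q = (
                rec.qualities
                if rec.qualities is not None
                else np.zeros(r, dtype=np.int16)
            )
            per_pos[offset : offset + r - k + 1] = window_weights(q, k)
        offset += r + 1  # separator
    return words, per_pos[starts]


def window_weights(qualities: np.ndarray, k: int) -> np.ndarray:
    """Quality weight of every length-k window: the product over bases of
    the correctness probability 1 - 10^(-q/10).

    Computed via prefix sums of log-probabilities; bases with q = 0 have
    correctness probability exactly 0 and force the window weight to 0
    (tracked separately so the log prefix sums stay finite).
    """
    q = qualities.astype(np.float64)
    if np.any(q < 0):
        raise ValueError("negative Phred score")
    p_corr = 1.0 - np.power(10.0, -q / 10.0)
    zero = p_corr <= 0.0
    safe = np.where(zero, 1.0, p_corr)
    logs = np.concatenate(([0.0], np.cumsum(np.log(safe))))
    zcount = np.concatenate(([0], np.cumsum(zero.astype(np.int64))))
    n = len(q) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.float64)
    w = np.exp(logs[k:] - logs[:-k])
    w[(zcount[k:] - zcount[:-k]) > 0] = 0.0
    return w
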