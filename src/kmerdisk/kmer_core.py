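"""k-mer encoding, reverse complement, canonicalization and prefix arithmetic.

A k-mer is packed two bits per base (A=0, C=1, G=2, T=3) with the first base
most significant, so integer order on the packed value equals lexicographic
order on the DNA string.  Counting is done on *canonical* k-mers: the
lexicographically smaller of a k-mer and its reverse complement, which merges
the two strands of double-stranded DNA into one key.

Two representations coexist:

* :class:`PackedKmer` — a scalar value object (arbitrary k up to 256) used by
  the public API and for hand-verifiable arithmetic.
* numpy batches — ``(n, nwords)`` arrays of ``uint64`` words, big-endian word
  order, left-zero-padded so the last base occupies the least significant two
  bits.  Row-wise word comparison equals lexicographic comparison for equal k.
  All hot paths (window extraction, canonicalization, radix sort) run on this
  layout.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

K_MIN = 11  # smallest supported k (constraint 10 < k)
K_MAX = 256

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: byte -> 2-bit code; 255 marks anything that is not A/C/G/T (N, IUPAC codes,
#: gaps...).  Lowercase soft-masked bases are accepted.
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i

INVALID_CODE = np.uint8(255)


class InvalidBaseError(ValueError):
    """A sequence contained a symbol outside {A, C, G, T}."""


def nwords(k: int) -> int:
    """Number of 64-bit words needed to pack a k-mer."""
    return (k + 31) // 32


@functools.total_ordering
@dataclass(frozen=True)
class PackedKmer:
    """An immutable 2-bit-packed k-mer.

    ``value`` holds the base-4 digits of the sequence as one integer, first
    base most significant, so ``value`` comparison of equal-length k-mers is
    lexicographic string comparison.
    """

    k: int
    value: int

    def __post_init__(self) -> None:
        if not K_MIN <= self.k <= K_MAX:
            raise ValueError(f"k={self.k} outside supported range ({K_MIN}..{K_MAX})")
        if not 0 <= self.value < (1 << (2 * self.k)):
            raise ValueError("packed value out of range for k")

    def decode(self) -> str:
        v = self.value
        out = []
        for _ in range(self.k):
            out.append(BASES[v & 3])
            v >>= 2
        return "".join(reversed(out))

    def __lt__(self, other: "PackedKmer") -> bool:
        if self.k == other.k:
            return self.value < other.value
        return self.decode() < other.decode()

    def __str__(self) -> str:
        return self.decode()

    def to_words(self) -> np.ndarray:
        """Big-endian uint64 word vector (left-zero-padded)."""
        w = nwords(self.k)
        out = np.empty(w, dtype=np.uint64)
        for j in range(w):
            out[j] = (self.value >> (64 * (w - 1 - j))) & 0xFFFFFFFFFFFFFFFF
        return out

    @classmethod
    def from_words(cls, words: np.ndarray, k: int) -> "PackedKmer":
        v = 0
        for x in words:
            v = (v << 64) | int(x)
        return cls(k, v)


def encode(sequence: str) -> PackedKmer:
    """Pack a DNA string into a :class:`PackedKmer`.

    Raises :class:`InvalidBaseError` on any symbol outside {A,C,G,T}
    (including N); callers that slide windows over reads skip such k-mers.
    """
    k = len(sequence)
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k-mer length {k} outside supported range ({K_MIN}..{K_MAX})")
    v = 0
    for ch in sequence:
        c = BASE_CODES[ord(ch)] if ord(ch) < 256 else 255
        if c == 255:
            raise InvalidBaseError(f"invalid base {ch!r} in k-mer")
        v = (v << 2) | int(c)
    return PackedKmer(k, v)


def reverse_complement(x: PackedKmer) -> PackedKmer:
    v = x.value
    out = 0
    for _ in range(x.k):
        out = (out << 2) | (3 - (v & 3))
        v >>= 2
    return PackedKmer(x.k, out)


def canonical(x: PackedKmer) -> PackedKmer:
    """min(x, reverse_complement(x)); idempotent and strand-symmetric."""
    r = reverse_complement(x)
    return x if x.value <= r.value else r


@dataclass(frozen=True)
class PrefixSplit:
    """A k-mer decomposed as bin prefix (p1) + counted middle (p2) + suffix.

    ``suffix`` is the packed byte string of the remaining k-p1-p2 bases,
    4 bases per byte, first base in the high bits of the first byte.
    """

    p1_id: int
    p1_prefix: str
    p2_id: int
    suffix: bytes
    k: int

    def reassemble(self) -> PackedKmer:
        p2 = _p2_len_from(self.k, len(self.p1_prefix), self.suffix)
        v = encode_prefix_value(self.p1_prefix)
        v = (v << (2 * p2)) | self.p2_id
        for b in self.suffix:
            v = (v << 8) | b
        return PackedKmer(self.k, v)


def _p2_len_from(k: int, p1_len: int, suffix: bytes) -> int:
    return k - p1_len - 4 * len(suffix)


def encode_prefix_value(prefix: str) -> int:
    """Base-4 integer value of a short prefix string (no length cap)."""
    v = 0
    for ch in prefix:
        c = BASE_CODES[ord(ch)]
        if c == 255:
            raise InvalidBaseError(f"invalid base {ch!r} in prefix")
        v = (v << 2) | int(c)
    return v


def split_prefix(x: PackedKmer, table, p2: int) -> PrefixSplit:
    """Two-stage prefix removal: strip the bin prefix p1 and the counted
    p2-base middle part, leaving a byte-aligned packed suffix.

    ``table`` is any object with ``match(kmer_string) -> (prefix, bin_id)``
    (normally a :class:`kmerdisk.distribution.PrefixTable`).  Requires
    ``(k - len(p1) - p2) % 4 == 0`` so the suffix packs into whole bytes.
    """
    s = x.decode()
    prefix, bin_id = table.match(s)
    p1_len = len(prefix)
    slen = x.k - p1_len - p2
    if slen < 0 or slen % 4 != 0:
        raise ValueError(f"k - p1 - p2 = {slen} must be a non-negative multiple of 4")
    v = x.value
    sbytes = slen // 4
    suffix = int(v & ((1 << (2 * slen)) - 1)).to_bytes(sbytes, "big") if sbytes else b""
    p2_id = (v >> (2 * slen)) & ((1 << (2 * p2)) - 1)
    return PrefixSplit(p1_id=bin_id, p1_prefix=prefix, p2_id=int(p2_id), suffix=suffix, k=x.k)


# ---------------------------------------------------------------------------
# numpy batch layer
# ---------------------------------------------------------------------------

def codes_from_sequence(bases: str | bytes) -> np.ndarray:
    """Map a sequence to uint8 2-bit codes; non-ACGT symbols become 255."""
    if isinstance(bases, str):
        bases = bases.encode("ascii", errors="replace")
    return BASE_CODES[np.frombuffer(bases, dtype=np.uint8)]


def pack_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every length-k window of a code array.

    Returns an ``(L-k+1, nwords)`` uint64 array; the caller is responsible
    for masking windows that contain invalid codes (values > 3 are clipped
    to keep the arithmetic in range, so unmasked rows are garbage, not
    errors).
    """
    L = len(codes)
    n = L - k + 1
    w = nwords(k)
    if n <= 0:
        return np.empty((0, w), dtype=np.uint64)
    c = np.where(codes > 3, 0, codes).astype(np.uint64)
    pad = 32 * w - k
    words = np.zeros((n, w), dtype=np.uint64)
    for b in range(k):
        p = pad + b
        shift = np.uint64(2 * (31 - (p & 31)))
        words[:, p >> 5] |= c[b : b + n] << shift
    return words


def rows_select_min(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise minimum of two equally shaped word matrices under
    lexicographic (most-significant-word-first) order."""
    n, w = a.shape
    use_a = np.ones(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)
    for j in range(w):
        gt = (a[:, j] > b[:, j]) & ~decided
        decided |= (a[:, j] != b[:, j])
        use_a[gt] = False
        if decided.all():
            break
    return np.where(use_a[:, None], a, b)


def canonical_windows(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical packed k-mers of all valid windows of a code array.

    A window is valid when it contains only A/C/G/T codes.  Returns
    ``(words, starts)``: the ``(m, nwords)`` canonical forms and the window
    start positions they came from (original orientation).
    """
    L = len(codes)
    if L < k:
        return np.empty((0, nwords(k)), dtype=np.uint64), np.empty(0, dtype=np.int64)
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    fwd = pack_windows(codes, k)
    rc_codes = (3 - np.where(codes > 3, np.uint8(3), codes))[::-1]
    rev = pack_windows(rc_codes, k)[::-1]
    canon = rows_select_min(fwd, rev)
    starts = np.flatnonzero(valid)
    return np.ascontiguousarray(canon[valid]), starts


def extract_bases(words: np.ndarray, k: int, start: int, length: int) -> np.ndarray:
    """Base-4 integer value of bases [start, start+length) of each row.

    ``length`` must be at most 32 so the result fits a uint64.
    """
    if length > 32:
        raise ValueError("can extract at most 32 bases at once")
    n, w = words.shape
    pad = 32 * w - k
    out = np.zeros(n, dtype=np.uint64)
    for t in range(length):
        p = pad + start + t
        shift = np.uint64(2 * (31 - (p & 31)))
        out = (out << np.uint64(2)) | ((words[:, p >> 5] >> shift) & np.uint64(3))
    return out


def words_to_bytes(words: np.ndarray) -> np.ndarray:
    """Big-endian byte matrix view ``(n, 8*nwords)`` of packed rows."""
    a = np.ascontiguousarray(words)
    return a.byteswap().view(np.uint8).reshape(a.shape[0], 8 * a.shape[1])


def bytes_to_words(byts: np.ndarray) -> np.ndarray:
    """Inverse of :func:`words_to_bytes`; column count must be 8*w."""
    a = np.ascontiguousarray(byts)
    n, m = a.shape
    return a.view(np.dtype(">u8")).reshape(n, m // 8).astype(np.uint64)


def words_row_to_string(row: np.ndarray, k: int) -> str:
    """Decode one packed row back to a DNA string (test/debug helper)."""
    return PackedKmer.from_words(row, k).decode()
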