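"""Prefix table, bin routing, p2 selection, compaction and the temp format."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kmerdisk import distribution as dist
from kmerdisk import kmer_core as kc


@pytest.fixture(scope="module", params=[3, 4, 5])
def table(request):
    return dist.build_prefix_table(request.param)


def test_table_is_prefix_free(table):
    prefixes = [p for p, _ in table.entries]
    for i, a in enumerate(prefixes):
        for b in prefixes[i + 1 :]:
            assert not b.startswith(a) and not a.startswith(b)


def test_bin_ids_follow_lexicographic_prefix_order(table):
    prefixes = [p for p, _ in table.entries]
    assert prefixes == sorted(prefixes)
    assert [b for _, b in table.entries] == list(range(len(prefixes)))


def test_light_t_prefixes_stay_short():
    """Canonical k-mers rarely start with T (mass 1/16), so T prefixes are
    never expanded: every TTT... k-mer maps to the single prefix 'TTT'."""
    t = dist.build_prefix_table(3)
    prefix, _ = t.match("TTT" + "A" * 22)
    assert prefix == "TTT"
    assert t.match("TTTTTTTTT")[0] == "TTT"


def test_invalid_p1_min_rejected():
    with pytest.raises(ValueError):
        dist.build_prefix_table(6)


def _random_canonical(rng, n, k):
    codes = rng.integers(0, 4, size=n + k - 1).astype(np.uint8)
    words, _ = kc.canonical_windows(codes, k)
    return words


def test_variable_table_balances_bins_better_than_fixed(rng):
    """Occupancy spread of 1e5 random canonical 25-mers: the variable-length
    table must beat a fixed 4-symbol table on max/mean."""
    words = _random_canonical(np.random.default_rng(1), 100_000, 25)
    var = dist.build_prefix_table(4)
    fixed_prefixes = sorted(
        "".join(kc.BASES[(v >> (2 * (4 - 1 - i))) & 3] for i in range(4))
        for v in range(256)
    )
    fixed = dist.PrefixTable(4, tuple((p, i) for i, p in enumerate(fixed_prefixes)))

    def max_over_mean(t):
        occ = np.bincount(dist.assign_bins_batch(words, 25, t), minlength=t.n_bins)
        return occ.max() / occ.mean()

    assert max_over_mean(var) < max_over_mean(fixed)


def test_assign_bin_consistency_and_monotonicity(rng, table):
    words = _random_canonical(rng, 2000, 25)
    bins = dist.assign_bins_batch(words, 25, table)
    strings = [kc.words_row_to_string(w, 25) for w in words]
    for s, b in zip(strings, bins):
        assert s.startswith(table.prefix_of(int(b)))
    # monotonicity: packed order and bin order agree across different bins
    order = np.array(sorted(range(len(strings)), key=lambda i: strings[i]))
    sorted_bins = bins[order]
    assert (np.diff(sorted_bins) >= 0).all()


def test_choose_p2_matches_exhaustive_argmin():
    for k in (25, 31, 33, 55):
        for p1_len in (3, 4, 5, 6):
            p2 = dist.choose_p2(k, p1_len)
            assert (k - p1_len - p2) % 4 == 0
            feasible = range((k - p1_len) % 4, k - p1_len + 1, 4)
            best = min(
                feasible, key=lambda q: dist.estimate_disk_usage(1000, k, p1_len, q, "classic")
            )
            assert p2 == best


def test_choose_p2_example_k25_p4():
    assert dist.choose_p2(25, 4) == 5


def test_choose_p2_infeasible():
    with pytest.raises(ValueError):
        dist.choose_p2(11, 11)


def test_estimate_disk_usage_printed_values():
    assert dist.estimate_disk_usage(2 ** 15, 25, 4, 5, "classic") == 133120
    assert dist.estimate_disk_usage(2 ** 15, 25, 4, 5, "quake") == 264192
    assert dist.estimate_disk_usage(0, 25, 4, 5, "classic") == 0


def _buffer_from_strings(strings, prefix="AAA", p2=2):
    k = len(strings[0])
    buf = dist.BinBuffer(bin_id=0, prefix=prefix, k=k, p2=p2)
    words = np.stack([kc.encode(s).to_words() for s in strings])
    buf.add(words, None)
    return buf


def test_compact_chunk_counting_sort_hand_trace():
    """Entries with p2 groups [3,0,3,1] compact to counts {0:1, 1:1, 3:2}
    with suffixes grouped ascending, stable in arrival order."""
    mid = ["TA", "AA", "TA", "AC"]  # p2 group values 12, 0, 12, 1
    sufs = ["ACGTACGT", "CCCCGGGG", "TTTTAAAA", "GGGGCCCC"]
    strings = ["AAA" + m + s for m, s in zip(mid, sufs)]
    chunk = dist.compact_chunk(_buffer_from_strings(strings), 2)
    counts = chunk.prefix_counts
    assert counts[0] == 1 and counts[1] == 1 and counts[12] == 2
    assert counts.sum() == 4
    got = [bytes(row) for row in chunk.suffixes]
    enc = lambda s: bytes([kc.encode_prefix_value(s[i : i + 4]) for i in (0, 4)])
    assert got == [enc("CCCCGGGG"), enc("GGGGCCCC"), enc("ACGTACGT"), enc("TTTTAAAA")]


def test_compact_single_entry():
    chunk = dist.compact_chunk(_buffer_from_strings(["AAATAACGTACGT"[:13]]), 2)
    assert (chunk.prefix_counts > 0).sum() == 1


def test_strip_criterion_arithmetic():
    """m=2^15 at p2=0 saves 32768 bytes vs 510 of counter growth -> strip;
    m=100 at p2=5 saves 100 vs ~500k -> keep."""
    rng = np.random.default_rng(0)

    def chunk_with(m, p2, sbytes):
        counts = np.zeros(4 ** p2, dtype=np.int64)
        counts[0] = m
        sufs = rng.integers(0, 256, size=(m, sbytes)).astype(np.uint8)
        return dist.CompactedChunk(0, 3 + p2 + 4 * sbytes, 3, p2, False, counts, sufs)

    big = chunk_with(2 ** 15, 0, 4)
    stripped = dist.maybe_strip_extra(big)
    assert stripped.stripped and stripped.p2_effective == 4
    assert stripped.sbytes == 3
    assert stripped.prefix_counts.sum() == 2 ** 15

    small = chunk_with(100, 5, 4)
    assert dist.maybe_strip_extra(small) is small


@given(
    st.lists(
        st.tuples(st.integers(0, 4 ** 2 - 1), st.integers(0, 4 ** 8 - 1)),
        min_size=1,
        max_size=300,
    )
)
def test_compact_strip_expand_roundtrip(entries):
    """expand o maybe_strip_extra o compact preserves the k-mer multiset."""
    from kmerdisk import sorting

    k, prefix, p2 = 13, "AAA", 2
    values = [
        (kc.encode_prefix_value(prefix) << 20) | (mid << 16) | suf
        for mid, suf in entries
    ]
    strings = [kc.PackedKmer(k, v).decode() for v in values]
    buf = _buffer_from_strings(strings, prefix, p2)
    chunk = dist.maybe_strip_extra(dist.compact_chunk(buf, p2))
    words, _ = sorting.expand_chunk(chunk, prefix)
    got = sorted(kc.words_row_to_string(w, k) for w in words)
    assert got == sorted(strings)


def test_chunk_write_read_roundtrip_and_size():
    rng = np.random.default_rng(2)
    strings = [
        "AAA" + "".join("ACGT"[c] for c in rng.integers(0, 4, size=10))
        for _ in range(50)
    ]
    chunk = dist.compact_chunk(_buffer_from_strings(strings), 2)
    sink = io.BytesIO()
    n1 = dist.write_bin_chunk(chunk, sink)
    n2 = dist.write_bin_chunk(chunk, sink)
    # size formula: header + 2*4^p2_eff + m*sbytes (classic mode)
    assert n1 == n2 == dist.CHUNK_HEADER.size + 2 * 4 ** 2 + 50 * 2
    sink.seek(0)
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "bin0.bin"
        p.write_bytes(sink.getvalue())
        chunks = list(dist.read_bin_chunks(p, 0, 13, 3))
    assert len(chunks) == 2
    for c in chunks:
        assert c.p2_effective == chunk.p2_effective
        assert np.array_equal(c.prefix_counts, chunk.prefix_counts)
        assert np.array_equal(c.suffixes, chunk.suffixes)


def test_buffer_overflow_rejected():
    buf = dist.BinBuffer(bin_id=0, prefix="AAA", k=13, p2=2, capacity=2)
    with pytest.raises(ValueError):
        buf.add(np.zeros((3, 1), dtype=np.uint64), None)
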