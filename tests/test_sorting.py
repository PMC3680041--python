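"""Radix sort, run counting, quality weights, thresholds, bin merging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kmerdisk import distribution as dist
from kmerdisk import kmer_core as kc
from kmerdisk import sorting


def _random_words(rng, n, k):
    codes = rng.integers(0, 4, size=n + k - 1).astype(np.uint8)
    return kc.pack_windows(codes, k)


@pytest.mark.parametrize("k", [11, 25, 33, 55])
def test_radix_sort_matches_comparison_oracle(rng, k):
    words = _random_words(rng, 10_000, k)
    got, _ = sorting.radix_sort(words)
    oracle = sorted(kc.words_row_to_string(w, k) for w in words)
    assert [kc.words_row_to_string(w, k) for w in got[:100]] == oracle[:100]
    assert [kc.words_row_to_string(w, k) for w in got[-100:]] == oracle[-100:]
    # full equality via tuple comparison, cheap
    assert [tuple(r) for r in got] == sorted(tuple(r) for r in words)


def test_radix_sort_sorted_input_unchanged(rng):
    words, _ = sorting.radix_sort(_random_words(rng, 500, 25))
    again, _ = sorting.radix_sort(words)
    assert np.array_equal(words, again)


def test_radix_sort_stability_on_equal_keys():
    words = np.zeros((5, 1), dtype=np.uint64)
    weights = np.arange(5, dtype=np.float64)
    s_words, s_weights = sorting.radix_sort(words, weights)
    assert np.array_equal(s_weights, weights)


def test_count_runs_direct_tally():
    a = kc.encode("ACGACGACGAC").to_words()
    b = kc.encode("CCAACCAACCA").to_words()
    words = np.stack([a, a, a, b])
    uniq, counts = sorting.count_runs(words, None)
    assert counts.tolist() == [3, 1]
    assert kc.words_row_to_string(uniq[0], 11) == "ACGACGACGAC"


def test_count_runs_empty_and_conservation(rng):
    uniq, counts = sorting.count_runs(np.empty((0, 1), dtype=np.uint64), None)
    assert len(uniq) == 0 and len(counts) == 0
    words, _ = sorting.radix_sort(_random_words(rng, 3000, 11))
    _, counts = sorting.count_runs(words, None)
    assert counts.sum() == 3000


def test_count_runs_rejects_unsorted():
    a = kc.encode("TTTTTTTTTTT").to_words()
    b = kc.encode("AAAAAAAAAAA").to_words()
    with pytest.raises(ValueError):
        sorting.count_runs(np.stack([a, b]), None)


def test_count_runs_quake_sums_weights():
    a = kc.encode("ACGACGACGAC").to_words()
    words = np.stack([a, a])
    uniq, counts = sorting.count_runs(words, np.array([0.5, 0.25]), "quake")
    assert counts.tolist() == [0.75]


def test_quake_weight_closed_form_and_monotonicity():
    assert sorting.quake_weight([40] * 25) == pytest.approx((1 - 1e-4) ** 25, rel=1e-12)
    assert sorting.quake_weight([40, 0, 40]) == 0.0
    lo = sorting.quake_weight([10, 20, 30])
    hi = sorting.quake_weight([20, 20, 30])
    assert lo <= hi
    with pytest.raises(ValueError):
        sorting.quake_weight([40, -1])


def test_filter_counts():
    kmers = np.arange(3, dtype=np.uint64).reshape(3, 1)
    counts = np.array([1, 2, 5])
    fk, fc = sorting.filter_counts(kmers, counts, 2)
    assert fc.tolist() == [2, 5] and fk.ravel().tolist() == [1, 2]
    _, all_c = sorting.filter_counts(kmers, counts, 1)
    assert all_c.tolist() == [1, 2, 5]
    _, none_c = sorting.filter_counts(kmers, counts, 6)
    assert len(none_c) == 0
    with pytest.raises(ValueError):
        sorting.filter_counts(kmers, counts, 3, 2)


def test_expand_chunk_hand_built():
    """Bin 'AAA', p2=2, one group with two suffixes: reconstruction equals
    manual string reassembly."""
    counts = np.zeros(16, dtype=np.int64)
    counts[6] = 2  # group 'CG'
    sufs = np.stack(
        [
            np.frombuffer(bytes([kc.encode_prefix_value("GGGG"), kc.encode_prefix_value("TTTT")]), dtype=np.uint8),
            np.frombuffer(bytes([kc.encode_prefix_value("ACGT"), kc.encode_prefix_value("ACGT")]), dtype=np.uint8),
        ]
    )
    chunk = dist.CompactedChunk(0, 13, 3, 2, False, counts, sufs)
    words, _ = sorting.expand_chunk(chunk, "AAA")
    got = [kc.words_row_to_string(w, 13) for w in words]
    assert got == ["AAACGGGGGTTTT", "AAACGACGTACGT"]


def test_merge_bins_order_and_duplicate_detection(rng):
    w = _random_words(rng, 10, 11)
    results = [(2, w[:3], np.ones(3)), (0, w[3:5], np.ones(2)), (1, w[5:], np.ones(5))]
    out = list(sorting.merge_bins_in_order(results))
    assert [b for b, _, _ in out] == [0, 1, 2]
    perm = list(sorting.merge_bins_in_order(results[::-1]))
    for (b1, k1, c1), (b2, k2, c2) in zip(out, perm):
        assert b1 == b2 and np.array_equal(k1, k2) and np.array_equal(c1, c2)
    with pytest.raises(ValueError):
        list(sorting.merge_bins_in_order([(0, w, np.ones(10)), (0, w, np.ones(10))]))


@given(st.lists(st.integers(0, 4 ** 11 - 1), min_size=0, max_size=200))
def test_global_sortedness_matches_full_sort_oracle(values):
    """Per-bin sort + ascending-bin concatenation equals sorting everything."""
    k = 11
    words = np.array(values, dtype=np.uint64).reshape(-1, 1)
    table = dist.build_prefix_table(3)
    # canonicalize so bin routing is defined
    strings = [kc.canonical(kc.PackedKmer(k, int(v))).decode() for v in words.ravel()]
    words = np.stack([kc.encode(s).to_words() for s in strings]) if strings else np.empty((0, 1), dtype=np.uint64)
    if len(words) == 0:
        return
    bins = dist.assign_bins_batch(words, k, table)
    per_bin = []
    for b in np.unique(bins):
        sub = words[bins == b]
        s, _ = sorting.radix_sort(sub)
        u, c = sorting.count_runs(s, None)
        per_bin.append((int(b), u, c))
    merged = np.concatenate([u for _, u, _ in sorting.merge_bins_in_order(per_bin)])
    oracle = np.array(sorted(set(int(w[0]) for w in words)), dtype=np.uint64)
    assert merged.ravel().tolist() == oracle.tolist()
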