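"""Counting Bloom filter behaviour and the analytic capacity model."""

import io
import math

import numpy as np
import pytest

import speckfix as sf
from speckfix.counting_bloom import COUNTER_MAX


def test_insert_then_query_never_false_negative(rng):
    filt = sf.CountingBloomFilter(1 << 16)
    codes = rng.integers(0, 4**21, size=2000)
    filt.insert_many(codes)
    assert (filt.query_many(codes) >= 1).all()


def test_counters_saturate_at_15():
    filt = sf.CountingBloomFilter(1 << 12)
    for _ in range(20):
        filt.insert(12345)
    assert filt.query(12345) == COUNTER_MAX
    assert filt.buckets.max() <= COUNTER_MAX


def test_empty_filter_queries_zero():
    filt = sf.CountingBloomFilter(1 << 10)
    assert filt.query(999) == 0


def test_query_upper_bounds_exact_count(rng):
    """Bloom estimates overcount but never undercount an exact tally."""
    filt = sf.CountingBloomFilter(1 << 10, n_hashes=4)  # deliberately crowded
    exact: dict[int, int] = {}
    for code in rng.integers(0, 4**15, size=500):
        filt.insert(int(code))
        exact[int(code)] = exact.get(int(code), 0) + 1
    for code, count in exact.items():
        assert filt.query(code) >= min(count, COUNTER_MAX)


def test_uncrowded_filter_counts_exactly(rng):
    filt = sf.CountingBloomFilter(1 << 20)
    code = 424242
    for m in range(1, 10):
        filt.insert(code)
        assert filt.query(code) == m


def test_query_monotone_under_inserts(rng):
    filt = sf.CountingBloomFilter(1 << 12)
    probe = np.array([7, 77, 777])
    last = filt.query_many(probe).astype(int)
    for chunk in rng.integers(0, 4**21, size=(20, 100)):
        filt.insert_many(chunk)
        now = filt.query_many(probe).astype(int)
        assert (now >= last).all()
        last = now


def test_rejects_bad_geometry():
    with pytest.raises(ValueError):
        sf.CountingBloomFilter(1000)  # not a power of two
    with pytest.raises(ValueError):
        sf.CountingBloomFilter(1 << 10, n_hashes=0)


def test_dump_load_roundtrip(rng):
    filt = sf.CountingBloomFilter(1 << 12, n_hashes=6)
    filt.insert_many(rng.integers(0, 4**21, size=300))
    buf = io.BytesIO()
    filt.dump(buf)
    buf.seek(0)
    back = sf.CountingBloomFilter.load(buf)
    assert back.n_hashes == 6 and back.n_buckets == 1 << 12
    assert back.n_inserted == filt.n_inserted
    assert (back.buckets == filt.buckets).all()


# -- analytic model ------------------------------------------------------


@pytest.mark.parametrize(
    "alpha,expected",
    [(1.0, 2.5e-2), (0.5, 5.7e-4), (0.25, 5.7e-6), (0.125, 3.6e-8)],
)
def test_fpp_model(alpha, expected):
    """(1-e^-alpha)^8 at the four representative load factors."""
    assert sf.fpp(alpha, 8) == pytest.approx(expected, rel=0.05)


@pytest.mark.parametrize(
    "alpha,expected",
    [(1.0, 536870912), (0.5, 268435456), (0.25, 134217728), (0.125, 67108864)],
)
def test_max_elements(alpha, expected):
    assert sf.max_elements(alpha, 2**32, 8) == expected


def test_expected_multiplicity():
    assert sf.expected_multiplicity(75, 36, 21) == pytest.approx(75 * 16 / 36)
    assert sf.expected_multiplicity(50, 36, 1) == pytest.approx(50)  # C when k=1
    assert sf.expected_multiplicity(50, 36, 36) == pytest.approx(50 / 36)  # k=L


def test_max_reads_capacity_examples():
    """~2.24e9 reads at alpha=0.25 and ~4.47e9 at alpha=0.5 for 8 partitions."""
    n25 = sf.max_reads(0.25, 2**32, 8, n_partitions=8, coverage=75, read_length=36, k=21)
    n50 = sf.max_reads(0.5, 2**32, 8, n_partitions=8, coverage=75, read_length=36, k=21)
    assert n25 == pytest.approx(2.24e9, rel=0.01)
    assert n50 == pytest.approx(4.47e9, rel=0.01)
    # linear in the partition count
    n1 = sf.max_reads(0.25, 2**32, 8, n_partitions=1, coverage=75, read_length=36, k=21)
    assert n25 == pytest.approx(8 * n1)


def test_plan_capacity_bundles_consistently():
    plan = sf.plan_capacity(alpha=0.25, n_partitions=8)
    assert plan.fpp == sf.fpp(0.25, 8)
    assert plan.max_bases == pytest.approx(plan.max_reads * 36)
    assert math.isclose(
        plan.max_reads,
        plan.max_elements * 8 * plan.expected_multiplicity / (36 - 21 + 1),
    )
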