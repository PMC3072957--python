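"""Counting Bloom filter with 4-bit saturating counters, plus capacity math.

The filter keeps one counter per bucket, capped at 15 (a 4-bit nibble's
range).  Inserting an element increments, with saturation, the ``h`` buckets
selected by its hash values; querying returns the minimum of those buckets,
which is an upper bound on the element's true multiplicity and never a lower
bound (no false negatives).

The false-positive probability follows the classical Bloom model

    FPP = (1 - exp(-alpha))**h,   alpha = h * N_E / N_B,

with N_B buckets and N_E distinct elements; a counting filter has the same
FPP as the bit filter with the same geometry.  The capacity planner inverts
this model: given a load factor alpha it bounds the number of distinct
k-mers per filter, and — via the expected multiplicity m = C*(L-k+1)/L of a
genomic k-mer at coverage C and read length L — the number of reads a
partitioned spectrum of ``n_partitions`` filters can absorb:

    N_R = max_elements * n_partitions * m / (L - k + 1)
        = alpha * N_B * n_partitions * C / (h * L).

Hashing is double hashing g_i(x) = h1(x) + i*h2(x) (mod N_B) over two
fixed-seed 64-bit mixing hashes, which preserves the classical FPP model
while needing only two hash evaluations per element.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from math import exp, floor

import numpy as np

__all__ = [
    "CapacityPlan",
    "CountingBloomFilter",
    "expected_multiplicity",
    "fpp",
    "max_elements",
    "max_reads",
    "plan_capacity",
]

COUNTER_MAX = 15  # 4-bit bucket

_U64 = np.uint64
_SEED1 = _U64(0x9E3779B97F4A7C15)
_SEED2 = _U64(0xC2B2AE3D27D4EB4F)


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer; uint64 in, uint64 out (vectorised)."""
    x = x + _U64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


class CountingBloomFilter:
    """Saturating multiset sketch over packed k-mer codes.

    Parameters
    ----------
    n_buckets:
        Number of counters; must be a power of two (bucket selection masks
        the hash) and at most 2**32.
    n_hashes:
        Number of hash functions h (default 8).
    """

    def __init__(self, n_buckets: int, n_hashes: int = 8):
        if n_buckets <= 0 or n_buckets & (n_buckets - 1):
            raise ValueError("n_buckets must be a positive power of two")
        if n_buckets > 2**32:
            raise ValueError("n_buckets must be <= 2**32")
        if n_hashes < 1:
            raise ValueError("n_hashes must be >= 1")
        self.n_buckets = int(n_buckets)
        self.n_hashes = int(n_hashes)
        self.buckets = np.zeros(self.n_buckets, dtype=np.uint8)
        self.n_inserted = 0  # insert calls, i.e. k-mer occurrences, not distinct

    # -- hashing ---------------------------------------------------------

    def _bucket_indices(self, codes: np.ndarray) -> np.ndarray:
        """(n_hashes, n) bucket indices for an array of codes."""
        x = np.ascontiguousarray(codes, dtype=np.int64).view(np.uint64)
        x = np.atleast_1d(x)
        h1 = _mix64(x ^ _SEED1)
        h2 = _mix64(x ^ _SEED2) | _U64(1)
        i = np.arange(self.n_hashes, dtype=np.uint64)[:, None]
        mask = _U64(self.n_buckets - 1)
        return ((h1[None, :] + i * h2[None, :]) & mask).astype(np.int64)

    # -- mutation --------------------------------------------------------

    def insert_many(self, codes: np.ndarray) -> None:
        """Insert every code (duplicates allowed), saturating counters at 15."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            return
        idx = self._bucket_indices(codes).ravel()
        uniq, counts = np.unique(idx, return_counts=True)
        merged = self.buckets[uniq].astype(np.int64) + counts
        self.buckets[uniq] = np.minimum(merged, COUNTER_MAX).astype(np.uint8)
        self.n_inserted += int(codes.size)

    def insert(self, code: int) -> None:
        self.insert_many(np.array([code], dtype=np.int64))

    # -- queries ---------------------------------------------------------

    def query_many(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity estimates: min bucket value per code (uint8 array)."""
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            return np.zeros(0, dtype=np.uint8)
        out = np.empty(codes.size, dtype=np.uint8)
        chunk = 1 << 21
        flat = codes.ravel()
        for s in range(0, flat.size, chunk):
            idx = self._bucket_indices(flat[s : s + chunk])
            out[s : s + chunk] = self.buckets[idx].min(axis=0)
        return out.reshape(codes.shape)

    def query(self, code: int) -> int:
        return int(self.query_many(np.array([code], dtype=np.int64))[0])

    @property
    def alpha(self) -> float:
        """Load factor h*N_E/N_B taking insert calls as the element count."""
        return self.n_hashes * self.n_inserted / self.n_buckets

    # -- persistence -----------------------------------------------------

    _MAGIC = b"SPKFCBF1"

    def dump(self, fh) -> None:
        """Write filter state (magic, h, N_B, packed nibbles) to a binary file."""
        fh.write(self._MAGIC)
        fh.write(struct.pack("<IQQ", self.n_hashes, self.n_buckets, self.n_inserted))
        packed = (self.buckets[0::2] << 4) | self.buckets[1::2]
        fh.write(packed.tobytes())

    @classmethod
    def load(cls, fh) -> "CountingBloomFilter":
        magic = fh.read(8)
        if magic != cls._MAGIC:
            raise ValueError("not a counting-Bloom-filter dump")
        n_hashes, n_buckets, n_inserted = struct.unpack("<IQQ", fh.read(20))
        filt = cls(n_buckets, n_hashes)
        packed = np.frombuffer(fh.read(n_buckets // 2), dtype=np.uint8)
        filt.buckets[0::2] = packed >> 4
        filt.buckets[1::2] = packed & 0x0F
        filt.n_inserted = n_inserted
        return filt


# -- analytic capacity model --------------------------------------------


def fpp(alpha: float, n_hashes: int = 8) -> float:
    """False-positive probability (1 - e**-alpha)**h of a Bloom filter."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if n_hashes < 1:
        raise ValueError("n_hashes must be >= 1")
    return (1.0 - exp(-alpha)) ** n_hashes


def max_elements(alpha: float, n_buckets: int = 2**32, n_hashes: int = 8) -> int:
    """Largest distinct-element count N_E sustaining load factor alpha."""
    if n_buckets > 2**32:
        raise ValueError("n_buckets must be <= 2**32")
    return floor(alpha * n_buckets / n_hashes)


def expected_multiplicity(coverage: float, read_length: int, k: int) -> float:
    """Expected observations m = C*(L-k+1)/L of a unique genomic k-mer."""
    if read_length < k:
        raise ValueError("read_length must be >= k")
    return coverage * (read_length - k + 1) / read_length


def max_reads(
    alpha: float,
    n_buckets: int = 2**32,
    n_hashes: int = 8,
    n_partitions: int = 1,
    coverage: float = 75,
    read_length: int = 36,
    k: int = 21,
) -> float:
    """Reads processable at fixed FPP by ``n_partitions`` filters.

    Scales linearly with the partition count: each partition owns an equal
    share of the distinct k-mers, so the dataset grows proportionally.
    """
    m = expected_multiplicity(coverage, read_length, k)
    per_read_kmers = read_length - k + 1
    return max_elements(alpha, n_buckets, n_hashes) * n_partitions * m / per_read_kmers


@dataclass(frozen=True)
class CapacityPlan:
    """Bundle of the Bloom capacity analytics for one configuration."""

    alpha: float
    n_buckets: int
    n_hashes: int
    n_partitions: int
    coverage: float
    read_length: int
    k: int
    fpp: float
    max_elements: int
    expected_multiplicity: float
    max_reads: float

    @property
    def max_bases(self) -> float:
        return self.max_reads * self.read_length


def plan_capacity(
    alpha: float = 0.25,
    n_buckets: int = 2**32,
    n_hashes: int = 8,
    n_partitions: int = 1,
    coverage: float = 75,
    read_length: int = 36,
    k: int = 21,
) -> CapacityPlan:
    """Evaluate the FPP/capacity model for one spectrum configuration."""
    return CapacityPlan(
        alpha=alpha,
        n_buckets=n_buckets,
        n_hashes=n_hashes,
        n_partitions=n_partitions,
        coverage=coverage,
        read_length=read_length,
        k=k,
        fpp=fpp(alpha, n_hashes),
        max_elements=max_elements(alpha, n_buckets, n_hashes),
        expected_multiplicity=expected_multiplicity(coverage, read_length, k),
        max_reads=max_reads(
            alpha, n_buckets, n_hashes, n_partitions, coverage, read_length, k
        ),
    )
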