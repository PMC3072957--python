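"""Partitioned k-mer spectrum built on counting Bloom filters.

The spectrum T(G) of a read set is the multiset of k-mers of all reads,
inserted together with their reverse complements.  It is split into
``n_partitions`` local spectra: a k-mer with packed code c belongs to
partition ``c % n_partitions``, so the local spectra are pairwise disjoint
and their union covers every possible k-mer.  Because a k-mer lives in
exactly one partition, a multiplicity query is routed to the owning
partition only; with both strands inserted at build time a forward-code
lookup already sees both-strand support.

A k-mer is *solid* when its multiplicity estimate reaches the threshold M
and *weak* otherwise.  k-mers overlapping ambiguous bases are never
inserted and are always weak.
"""

from __future__ import annotations

import json
import logging
import struct
from typing import Iterable, Sequence

import numpy as np

from speckfix.counting_bloom import COUNTER_MAX, CountingBloomFilter
from speckfix.io_formats import ReadRecord
from speckfix.kmer_codec import (
    digits_of,
    encode,
    kmer_code_matrix,
    revcomp_code_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["ExactKmerCounter", "PartitionedSpectrum"]

DEFAULT_K = 21
DEFAULT_THRESHOLD = 6
DEFAULT_ALPHA = 0.25
DEFAULT_BATCH_SIZE = 65536


class ExactKmerCounter:
    """Exact hash-table multiplicity counter with the Bloom filter's API.

    Used as a drop-in spectrum backend for small problems and as the
    collision-free oracle against which the Bloom-backed spectrum is checked.
    Query results saturate at the same 4-bit ceiling as the Bloom filter so
    the two backends report on the same scale.
    """

    def __init__(self):
        self._codes = np.zeros(0, dtype=np.int64)
        self._counts = np.zeros(0, dtype=np.int64)
        self._pending: list[np.ndarray] = []
        self.n_inserted = 0

    def insert_many(self, codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            return
        self._pending.append(codes.ravel().copy())
        self.n_inserted += int(codes.size)

    def insert(self, code: int) -> None:
        self.insert_many(np.array([code], dtype=np.int64))

    def _finalize(self) -> None:
        if not self._pending:
            return
        new = np.concatenate(self._pending)
        self._pending.clear()
        uniq, counts = np.unique(new, return_counts=True)
        codes = np.concatenate([self._codes, uniq])
        cnts = np.concatenate([self._counts, counts])
        order = np.argsort(codes, kind="stable")
        codes, cnts = codes[order], cnts[order]
        merged_codes, start = np.unique(codes, return_index=True)
        merged = np.add.reduceat(cnts, start) if codes.size else cnts
        self._codes, self._counts = merged_codes, merged

    def exact_count(self, code: int) -> int:
        """True multiplicity without the 4-bit saturation."""
        self._finalize()
        i = np.searchsorted(self._codes, code)
        if i < self._codes.size and self._codes[i] == code:
            return int(self._counts[i])
        return 0

    def query_many(self, codes: np.ndarray) -> np.ndarray:
        self._finalize()
        codes = np.asarray(codes, dtype=np.int64)
        flat = codes.ravel()
        if self._codes.size == 0:
            return np.zeros(codes.shape, dtype=np.uint8)
        idx = np.minimum(np.searchsorted(self._codes, flat), self._codes.size - 1)
        hit = self._codes[idx] == flat
        counts = np.where(hit, self._counts[idx], 0)
        return np.minimum(counts, COUNTER_MAX).astype(np.uint8).reshape(codes.shape)

    def query(self, code: int) -> int:
        return int(self.query_many(np.array([code], dtype=np.int64))[0])


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


class PartitionedSpectrum:
    """The set of per-partition k-mer filters plus partition routing."""

    def __init__(
        self,
        k: int = DEFAULT_K,
        threshold: int = DEFAULT_THRESHOLD,
        n_partitions: int = 1,
        partitions: Sequence | None = None,
        n_buckets: int | None = None,
        n_hashes: int = 8,
        backend: str = "bloom",
    ):
        if n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        self.k = int(k)
        self.threshold = int(threshold)
        self.n_partitions = int(n_partitions)
        self.n_hashes = int(n_hashes)
        self.backend = backend
        if partitions is not None:
            self.partitions = list(partitions)
        elif backend == "exact":
            self.partitions = [ExactKmerCounter() for _ in range(n_partitions)]
        elif backend == "bloom":
            if n_buckets is None:
                raise ValueError("bloom backend needs n_buckets (or use build())")
            self.partitions = [
                CountingBloomFilter(n_buckets, n_hashes) for _ in range(n_partitions)
            ]
        else:
            raise ValueError(f"unknown backend {backend!r}")

    # -- construction ----------------------------------------------------

    @classmethod
    def build(
        cls,
        reads: Iterable[str | ReadRecord],
        k: int = DEFAULT_K,
        threshold: int = DEFAULT_THRESHOLD,
        n_partitions: int = 1,
        n_buckets: int | None = None,
        n_hashes: int = 8,
        backend: str = "bloom",
        alpha: float = DEFAULT_ALPHA,
        batch_size: int = DEFAULT_BATCH_SIZE,
    ) -> "PartitionedSpectrum":
        """Build the spectrum from reads, inserting both strands of every k-mer.

        Each unambiguous k-mer occurrence contributes two inserts — its own
        code and its reverse complement's code — each routed to the partition
        the code selects.  When ``n_buckets`` is not given, each partition's
        filter is sized from the capacity model at load factor ``alpha``
        using the total k-mer occurrence count as a (generous) stand-in for
        the distinct-element count, which keeps the realised FPP comfortably
        below the planned one.
        """
        seqs = [r.sequence if isinstance(r, ReadRecord) else r for r in reads]
        if not seqs:
            logger.warning("building spectrum from empty read set")
        if backend == "bloom" and n_buckets is None:
            occurrences = 2 * sum(max(len(s) - k + 1, 0) for s in seqs)
            per_part = max(occurrences // n_partitions, 1)
            n_buckets = _next_pow2(max(int(n_hashes * per_part / alpha), 1024))
            n_buckets = min(n_buckets, 2**32)
        spec = cls(
            k=k,
            threshold=threshold,
            n_partitions=n_partitions,
            n_buckets=n_buckets,
            n_hashes=n_hashes,
            backend=backend,
        )
        for start in range(0, len(seqs), batch_size):
            spec.insert_reads(seqs[start : start + batch_size])
        return spec

    def insert_reads(self, seqs: Sequence[str]) -> None:
        """Insert every unambiguous k-mer (both strands) of a batch of reads."""
        by_len: dict[int, list[str]] = {}
        for s in seqs:
            by_len.setdefault(len(s), []).append(s)
        for length, group in by_len.items():
            if length < self.k:
                continue
            digits = np.vstack([digits_of(s) for s in group])
            fwd, valid = kmer_code_matrix(digits, self.k)
            rc = revcomp_code_matrix(digits, self.k)
            codes = np.concatenate([fwd[valid], rc[valid]])
            self.insert_codes(codes)

    def insert_codes(self, codes: np.ndarray) -> None:
        """Route packed codes to their owning partitions and insert."""
        codes = np.asarray(codes, dtype=np.int64)
        if self.n_partitions == 1:
            self.partitions[0].insert_many(codes)
            return
        owner = codes % self.n_partitions
        for i, part in enumerate(self.partitions):
            part.insert_many(codes[owner == i])

    # -- queries ---------------------------------------------------------

    def counts_of(self, codes: np.ndarray) -> np.ndarray:
        """Multiplicity estimates for an array of packed codes (owner lookup)."""
        codes = np.asarray(codes, dtype=np.int64)
        if self.n_partitions == 1:
            return self.partitions[0].query_many(codes)
        flat = codes.ravel()
        owner = flat % self.n_partitions
        out = np.zeros(flat.size, dtype=np.uint8)
        for i, part in enumerate(self.partitions):
            sel = owner == i
            if sel.any():
                out[sel] = part.query_many(flat[sel])
        return out.reshape(codes.shape)

    def solid_mask(self, codes: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
        """Boolean solidity per code; invalid (ambiguous) slots are weak."""
        solid = self.counts_of(codes) >= self.threshold
        if valid is not None:
            solid &= valid
        return solid

    def multiplicity(self, kmer: int | str) -> int:
        """Multiplicity estimate of one k-mer (packed code or string)."""
        code = encode(kmer) if isinstance(kmer, str) else int(kmer)
        return self.partitions[code % self.n_partitions].query(code)

    def is_solid(self, kmer: int | str) -> bool:
        """Whether the k-mer's multiplicity reaches the solidity threshold M."""
        return self.multiplicity(kmer) >= self.threshold

    # -- persistence -----------------------------------------------------

    _MAGIC = b"SPKFSPC1"

    def save(self, path) -> None:
        """Write the spectrum (header + per-partition filter dumps) to disk."""
        if self.backend != "bloom":
            raise ValueError("only Bloom-backed spectra can be saved")
        header = json.dumps(
            {"k": self.k, "threshold": self.threshold, "n_partitions": self.n_partitions}
        ).encode()
        with open(path, "wb") as fh:
            fh.write(self._MAGIC)
            fh.write(struct.pack("<I", len(header)))
            fh.write(header)
            for part in self.partitions:
                part.dump(fh)

    @classmethod
    def load(cls, path) -> "PartitionedSpectrum":
        with open(path, "rb") as fh:
            if fh.read(8) != cls._MAGIC:
                raise ValueError("not a spectrum file")
            (hlen,) = struct.unpack("<I", fh.read(4))
            meta = json.loads(fh.read(hlen))
            parts = [
                CountingBloomFilter.load(fh) for _ in range(meta["n_partitions"])
            ]
        return cls(
            k=meta["k"],
            threshold=meta["threshold"],
            n_partitions=meta["n_partitions"],
            partitions=parts,
        )
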