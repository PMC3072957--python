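"""2-bit k-mer codes, reverse complements and partition routing.

A k-mer over {A, C, G, T} is packed into an integer by mapping the bases to
the digits {0, 1, 2, 3} and reading the k-mer as a base-4 number with the
leftmost base most significant, so numeric order coincides with lexicographic
order.  The packed code is the unit of spectrum membership: it is hashed into
the counting Bloom filters and routed to a spectrum partition as
``code % n_partitions``.

Ambiguous bases (N and the other IUPAC degeneracy codes) cannot be
represented in two bits; k-mer windows overlapping them are marked with the
:data:`AMBIGUOUS` sentinel and are treated as weak, never-inserted k-mers by
the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "AMBIGUOUS",
    "AmbiguousBaseError",
    "KmerScan",
    "decode",
    "encode",
    "partition_of",
    "reverse_complement",
    "reverse_complement_code",
    "scan_read",
]

_BASES = "ACGT"
_BASE_TO_DIGIT = {b: i for i, b in enumerate(_BASES)}
_BASE_TO_DIGIT.update({b.lower(): i for i, b in enumerate(_BASES)})

# IUPAC nucleotide complements (DNA); lowercase handled by upper-casing input.
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

_IUPAC = set("ACGTRYSWKMBDHVN")

# Byte-level lookup: ASCII code -> 2-bit digit, -1 for anything ambiguous.
_DIGIT_LUT = np.full(256, -1, dtype=np.int8)
for _b, _d in _BASE_TO_DIGIT.items():
    _DIGIT_LUT[ord(_b)] = _d
_ASCII_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


class _Ambiguous:
    """Singleton marker for k-mer slots overlapping an ambiguous base."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "AMBIGUOUS"


AMBIGUOUS = _Ambiguous()


class AmbiguousBaseError(ValueError):
    """Raised when a sequence that must be unambiguous contains N/IUPAC codes."""


def encode(seq: str) -> int:
    """Pack a DNA string into its 2-bit integer code.

    Bases map A->0, C->1, G->2, T->3; the leftmost base is the most
    significant base-4 digit.  Case-insensitive.  Raises
    :class:`AmbiguousBaseError` for N or other IUPAC degeneracy codes and
    ``ValueError`` for anything that is not a nucleotide code (including U:
    the codec is DNA-only).
    """
    code = 0
    for ch in seq:
        d = _BASE_TO_DIGIT.get(ch)
        if d is None:
            up = ch.upper()
            if up in _IUPAC:
                raise AmbiguousBaseError(f"ambiguous base {ch!r} in {seq!r}")
            raise ValueError(f"invalid DNA base {ch!r} in {seq!r}")
        code = (code << 2) | d
    return code


def decode(code: int, k: int) -> str:
    """Inverse of :func:`encode`: unpack ``code`` into a k-base string."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes complemented, N -> N)."""
    for ch in seq:
        if ch.upper() not in _IUPAC:
            raise ValueError(f"invalid DNA base {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_code(code: int, k: int) -> int:
    """Reverse complement computed directly on a packed code.

    Complements each 2-bit digit (d -> 3-d) and reverses digit order;
    equivalent to ``encode(reverse_complement(decode(code, k)))``.
    """
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def partition_of(code: int, n_partitions: int) -> int:
    """Index of the spectrum partition owning ``code`` (code mod n_partitions)."""
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    return int(code) % n_partitions


@dataclass
class KmerScan:
    """All k-mer start positions of one read with their packed codes.

    ``codes[i]`` is the packed code of the k-mer starting at offset ``i``;
    ``valid[i]`` is False where the window overlaps an ambiguous base (the
    code entry is then meaningless).  A read shorter than k yields an empty
    scan.
    """

    read_id: str
    k: int
    length: int
    codes: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def positions(self) -> list[tuple[int, object]]:
        """(offset, code or AMBIGUOUS) for every k-mer start, offsets ascending."""
        return [
            (i, int(self.codes[i]) if self.valid[i] else AMBIGUOUS)
            for i in range(len(self.codes))
        ]

    def __iter__(self) -> Iterator[tuple[int, object]]:
        return iter(self.positions)


def digits_of(seq: str) -> np.ndarray:
    """Map a DNA string to an int8 digit array; ambiguous bases become -1."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _DIGIT_LUT[raw]


def digits_to_str(digits: np.ndarray) -> str:
    """Inverse of :func:`digits_of` for unambiguous digit arrays."""
    return _ASCII_LUT[digits].tobytes().decode("ascii")


def kmer_code_matrix(digits: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes of every k-window of a digit matrix, by Horner evaluation.

    ``digits`` has shape (n_reads, read_length) with -1 marking ambiguous
    bases.  Returns ``(codes, valid)`` of shape (n_reads, read_length-k+1):
    int64 codes and a boolean mask that is False wherever the window touches
    an ambiguous base.
    """
    n, length = digits.shape
    w = length - k + 1
    if w <= 0:
        return (np.zeros((n, 0), dtype=np.int64), np.zeros((n, 0), dtype=bool))
    d = digits.astype(np.int64)
    bad = (d < 0).astype(np.int64)
    d = np.where(d < 0, 0, d)
    codes = np.zeros((n, w), dtype=np.int64)
    for p in range(k):
        codes *= 4
        codes += d[:, p : p + w]
    csum = np.zeros((n, length + 1), dtype=np.int64)
    np.cumsum(bad, axis=1, out=csum[:, 1:])
    valid = (csum[:, k:] - csum[:, :w]) == 0
    return codes, valid


def revcomp_code_matrix(digits: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of the reverse complement of every k-window.

    Companion to :func:`kmer_code_matrix` (same shape and validity mask);
    window j's value is the code of the reverse complement of the k-mer
    starting at j on the forward strand.
    """
    n, length = digits.shape
    w = length - k + 1
    if w <= 0:
        return np.zeros((n, 0), dtype=np.int64)
    d = digits.astype(np.int64)
    d = np.where(d < 0, 0, d)
    codes = np.zeros((n, w), dtype=np.int64)
    for p in range(k):
        # most significant digit of the revcomp is the complement of the
        # window's last base
        codes *= 4
        codes += 3 - d[:, k - 1 - p : k - 1 - p + w]
    return codes


def scan_read(seq: str, k: int, read_id: str = "") -> KmerScan:
    """Enumerate every k-mer of ``seq`` as packed codes.

    Windows overlapping ambiguous bases are flagged invalid rather than
    raising; a read shorter than k produces an empty scan.
    """
    digits = digits_of(seq)
    codes, valid = kmer_code_matrix(digits.reshape(1, -1), k)
    return KmerScan(
        read_id=read_id, k=k, length=len(seq), codes=codes[0], valid=valid[0]
    )
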