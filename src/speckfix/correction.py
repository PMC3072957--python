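"""The correction stages: filter, vote+fix (optionally iterated), trim.

A read is *error-free* when every one of its k-mers is solid in the
spectrum (its solidity vector is all zero — a T-string).  For an erroneous
read, a substitution at position j corrupts every k-mer window covering j —
min{k, j+1, l-j, l-k+1} of them — so the voting algorithm tries, for every
weak k-mer and every single-base substitution inside it, whether the mutated
k-mer is solid; each success casts one vote for (position, base).  The fixing
step applies the substitution with the most votes (ties: smallest position,
then base order A<C<G<T), one substitution per fixing pass, and re-filters;
the optional iterative policy repeats vote/fix to reach reads with more than
one error.  Reads that remain erroneous are trimmed to their longest
all-solid stretch when that loses at most ``max_trim`` bases, and discarded
otherwise.

All stages are deterministic: identical inputs and parameters give
byte-identical outputs, and results are invariant to the spectrum partition
count because solidity (AND) and vote (ADD) combination commute with
partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from speckfix.io_formats import ReadRecord
from speckfix.kmer_codec import digits_of, digits_to_str, kmer_code_matrix
from speckfix.spectrum import PartitionedSpectrum

__all__ = [
    "CorrectionOutcome",
    "CorrectionResult",
    "ReadTooShortError",
    "Status",
    "correct_dataset",
    "filter_reads",
    "fix_read",
    "iterate_fix",
    "solidity_vector",
    "trim_read",
    "vote",
]

DEFAULT_MAX_TRIM = 4
DEFAULT_ITERATIONS = 1

_VOTE_CHUNK = 1 << 17  # weak k-mers expanded per voting chunk (memory bound)


class Status(Enum):
    """Per-read correction outcome."""

    ERROR_FREE = "error_free"
    FIXED = "fixed"
    TRIMMED = "trimmed"
    DISCARDED = "discarded"
    UNFIXED = "unfixed"  # still erroneous, trimming disabled


class ReadTooShortError(ValueError):
    """Read shorter than k: it has no k-mers and no solidity vector."""


@dataclass
class CorrectionOutcome:
    """Final state of one read after the pipeline."""

    read_id: str
    status: Status
    sequence: str
    quality: str | None = None
    spos: int = 0
    n_substitutions: int = 0
    trim: tuple[int, int] | None = None  # (start, length) when TRIMMED


@dataclass
class CorrectionResult:
    """All per-read outcomes of a dataset run plus summary counting."""

    outcomes: list[CorrectionOutcome]
    k: int
    threshold: int
    n_partitions: int
    n_iterations: int

    def counts(self) -> dict[str, int]:
        c = {s.value: 0 for s in Status}
        for o in self.outcomes:
            c[o.status.value] += 1
        c["total"] = len(self.outcomes)
        c["substitutions"] = sum(o.n_substitutions for o in self.outcomes)
        return c

    def output_records(self, include_discarded: bool = False) -> list[ReadRecord]:
        recs = []
        for o in self.outcomes:
            if o.status is Status.DISCARDED and not include_discarded:
                continue
            recs.append(ReadRecord(id=o.read_id, sequence=o.sequence, quality=o.quality))
        return recs


# ---------------------------------------------------------------------------
# per-read stage operations
# ---------------------------------------------------------------------------


def solidity_vector(spectrum: PartitionedSpectrum, read: str) -> np.ndarray:
    """Weak-k-mer flags for one read: 1 = weak, 0 = solid, one per k-mer start.

    Windows overlapping ambiguous bases are weak.  Raises
    :class:`ReadTooShortError` for reads shorter than k.
    """
    if len(read) < spectrum.k:
        raise ReadTooShortError(f"read length {len(read)} < k={spectrum.k}")
    digits = digits_of(read).reshape(1, -1)
    codes, valid = kmer_code_matrix(digits, spectrum.k)
    solid = spectrum.solid_mask(codes, valid)
    return (~solid[0]).astype(np.uint8)


def filter_reads(
    spectrum: PartitionedSpectrum, reads: Iterable[str | ReadRecord]
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, np.ndarray]]]:
    """Split reads into error-free and erroneous (with stored solidity vectors).

    Reads shorter than k are placed in the erroneous set with an empty
    vector; downstream they fall through to the discard policy.
    """
    error_free: list[ReadRecord] = []
    erroneous: list[tuple[ReadRecord, np.ndarray]] = []
    for i, r in enumerate(reads):
        rec = r if isinstance(r, ReadRecord) else ReadRecord(id=f"r{i}", sequence=r)
        if len(rec.sequence) < spectrum.k:
            erroneous.append((rec, np.zeros(0, dtype=np.uint8)))
            continue
        sv = solidity_vector(spectrum, rec.sequence)
        if sv.any():
            erroneous.append((rec, sv))
        else:
            error_free.append(rec)
    return error_free, erroneous


def _accumulate_votes(
    spectrum: PartitionedSpectrum,
    digits: np.ndarray,
    dig_rows: np.ndarray,
    vm_rows: np.ndarray,
    starts: np.ndarray,
    codes: np.ndarray,
    vm: np.ndarray,
) -> None:
    """Add votes for one flat list of weak k-mers into ``vm`` (R, L, 4).

    Each weak, unambiguous k-mer is described by its read row in ``digits``
    (``dig_rows``), its target row in ``vm`` (``vm_rows``), its start offset
    and its packed code: for every offset p in the window and every base b
    different from the current one, the single-substitution k-mer is queried
    and, when solid, votes[vm_row, start+p, b] is incremented.
    """
    k = spectrum.k
    shifts = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)  # digit p weight
    alt = np.arange(1, 4, dtype=np.int64)  # +1..+3 mod 4: the 3 other bases
    for s in range(0, dig_rows.size, _VOTE_CHUNK):
        rows = dig_rows[s : s + _VOTE_CHUNK]
        vrows = vm_rows[s : s + _VOTE_CHUNK]
        st = starts[s : s + _VOTE_CHUNK]
        cd = codes[s : s + _VOTE_CHUNK]
        offs = st[:, None] + np.arange(k)  # (n, k) read positions
        cur = digits[rows[:, None], offs].astype(np.int64)  # (n, k)
        bases = (cur[:, :, None] + alt[None, None, :]) % 4  # (n, k, 3)
        cand = (
            cd[:, None, None]
            + (bases - cur[:, :, None]) * shifts[None, :, None]
        )
        solid = spectrum.solid_mask(cand)
        n_idx = np.broadcast_to(vrows[:, None, None], solid.shape)
        p_idx = np.broadcast_to(offs[:, :, None], solid.shape)
        np.add.at(vm, (n_idx[solid], p_idx[solid], bases[solid]), 1)


def vote(
    spectrum: PartitionedSpectrum,
    read: str,
    sv: np.ndarray,
    spos: int = 0,
) -> np.ndarray:
    """Voting matrix (read length x 4 bases) for one erroneous read.

    Only weak k-mers starting at or after ``spos`` vote (everything before
    the saved start position is known solid from the previous fixing pass);
    weak slots from ambiguous windows cannot form candidate codes and cast
    no votes.
    """
    digits = digits_of(read).reshape(1, -1)
    codes, valid = kmer_code_matrix(digits, spectrum.k)
    weak = np.asarray(sv, dtype=bool) & valid[0]
    weak[:spos] = False
    vm = np.zeros((1, len(read), 4), dtype=np.int32)
    starts = np.nonzero(weak)[0]
    zeros = np.zeros(starts.size, dtype=np.intp)
    _accumulate_votes(spectrum, digits, zeros, zeros, starts, codes[0][starts], vm)
    return vm[0]


def fix_read(read: str, vm: np.ndarray) -> tuple[str, bool]:
    """Apply the highest-voted single substitution to the read.

    Ties break to the smallest position, then base order A<C<G<T (row-major
    argmax).  Returns the (possibly unchanged) read and whether a base was
    changed; an all-zero matrix changes nothing.
    """
    vm = np.asarray(vm)
    flat = int(np.argmax(vm))
    if vm.flat[flat] <= 0:
        return read, False
    j, b = divmod(flat, 4)
    return read[:j] + "ACGT"[b] + read[j + 1 :], True


def trim_read(
    read: str | ReadRecord,
    sv: np.ndarray,
    max_trim: int = DEFAULT_MAX_TRIM,
    k: int | None = None,
) -> CorrectionOutcome:
    """Trim an erroneous read to its longest all-solid substring, or discard.

    A run of r consecutive solid k-mer starts spans a substring of
    r + k - 1 bases; the leftmost longest run wins ties.  The read is
    trimmed when at most ``max_trim`` bases are lost and discarded
    otherwise (including when no solid k-mer exists at all).
    """
    rec = read if isinstance(read, ReadRecord) else ReadRecord(id="", sequence=read)
    sv = np.asarray(sv, dtype=np.uint8)
    length = len(rec.sequence)
    if k is None:
        k = length - len(sv) + 1 if len(sv) else length + 1
    best_start, best_run = 0, 0
    run_start, run = 0, 0
    for i, bit in enumerate(sv):
        if bit == 0:
            if run == 0:
                run_start = i
            run += 1
            if run > best_run:
                best_start, best_run = run_start, run
        else:
            run = 0
    if best_run == 0:
        return CorrectionOutcome(
            read_id=rec.id, status=Status.DISCARDED, sequence=rec.sequence,
            quality=rec.quality,
        )
    keep = best_run + k - 1
    if length - keep > max_trim:
        return CorrectionOutcome(
            read_id=rec.id, status=Status.DISCARDED, sequence=rec.sequence,
            quality=rec.quality,
        )
    seq = rec.sequence[best_start : best_start + keep]
    qual = rec.quality[best_start : best_start + keep] if rec.quality else None
    return CorrectionOutcome(
        read_id=rec.id,
        status=Status.TRIMMED,
        sequence=seq,
        quality=qual,
        trim=(best_start, keep),
    )


# ---------------------------------------------------------------------------
# batched fixing over uniform-length read groups
# ---------------------------------------------------------------------------


def _fix_group(
    spectrum: PartitionedSpectrum,
    digits: np.ndarray,
    n_iterations: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Iterated vote/fix over a matrix of erroneous same-length reads.

    Returns (digits, fixed_mask, n_subs, weak) after the iteration budget:
    the possibly modified digit matrix, which rows reached an all-solid
    state, per-row substitution counts, and the final weak-k-mer matrix.
    """
    k = spectrum.k
    n, length = digits.shape
    codes, valid = kmer_code_matrix(digits, k)
    weak = ~spectrum.solid_mask(codes, valid)
    n_subs = np.zeros(n, dtype=np.int32)
    fixed = np.zeros(n, dtype=bool)
    active = weak.any(axis=1) & ~fixed
    for _ in range(n_iterations):
        rows = np.nonzero(active)[0]
        if rows.size == 0:
            break
        votable = weak[rows] & valid[rows]
        r_local, starts = np.nonzero(votable)
        vm = np.zeros((rows.size, length, 4), dtype=np.int32)
        _accumulate_votes(
            spectrum,
            digits,
            rows[r_local],
            r_local,
            starts,
            codes[rows[r_local], starts],
            vm,
        )
        flat = vm.reshape(rows.size, -1)
        arg = flat.argmax(axis=1)
        has_vote = flat[np.arange(rows.size), arg] > 0
        stuck = rows[~has_vote]
        active[stuck] = False
        ch = rows[has_vote]
        if ch.size == 0:
            break
        j, b = np.divmod(arg[has_vote], 4)
        digits[ch, j] = b
        n_subs[ch] += 1
        codes[ch], valid[ch] = kmer_code_matrix(digits[ch], k)
        weak[ch] = ~spectrum.solid_mask(codes[ch], valid[ch])
        done = ch[~weak[ch].any(axis=1)]
        fixed[done] = True
        active[done] = False
    return digits, fixed, n_subs, weak


def iterate_fix(
    spectrum: PartitionedSpectrum,
    erroneous: Sequence[tuple[ReadRecord, np.ndarray]],
    n_iterations: int = DEFAULT_ITERATIONS,
) -> list[tuple[ReadRecord, np.ndarray, Status | None, int]]:
    """Alternate voting/fixing and re-filtering over the erroneous reads.

    Each pass applies at most one substitution per read, then refreshes the
    read's solidity vector; reads whose vector becomes all-zero exit as
    FIXED and are not re-voted.  Returns, per input read, the (possibly
    corrected) record, its final solidity vector, FIXED or None (still
    erroneous), and the number of substitutions applied.
    """
    results: list = [None] * len(erroneous)
    groups: dict[int, list[int]] = {}
    for i, (rec, sv) in enumerate(erroneous):
        if len(rec.sequence) < spectrum.k:
            results[i] = (rec, np.asarray(sv, dtype=np.uint8), None, 0)
        else:
            groups.setdefault(len(rec.sequence), []).append(i)
    for length, idxs in groups.items():
        digits = np.vstack([digits_of(erroneous[i][0].sequence) for i in idxs])
        digits, fixed, n_subs, weak = _fix_group(spectrum, digits, n_iterations)
        for row, i in enumerate(idxs):
            rec = erroneous[i][0]
            amb = digits[row] < 0
            if amb.any():  # restore ambiguous characters untouched by fixing
                orig = np.frombuffer(
                    rec.sequence.upper().encode("ascii"), dtype=np.uint8
                )
                out = np.frombuffer(
                    digits_to_str(np.where(amb, 0, digits[row])).encode("ascii"),
                    dtype=np.uint8,
                ).copy()
                out[amb] = orig[amb]
                seq = out.tobytes().decode("ascii")
            else:
                seq = digits_to_str(digits[row])
            new_rec = ReadRecord(id=rec.id, sequence=seq, quality=rec.quality)
            status = Status.FIXED if fixed[row] else None
            results[i] = (
                new_rec,
                weak[row].astype(np.uint8),
                status,
                int(n_subs[row]),
            )
    return results


# ---------------------------------------------------------------------------
# whole-dataset pipeline
# ---------------------------------------------------------------------------


def correct_dataset(
    reads: Iterable[str | ReadRecord],
    k: int = 21,
    threshold: int = 6,
    n_partitions: int = 1,
    n_iterations: int = DEFAULT_ITERATIONS,
    max_trim: int = DEFAULT_MAX_TRIM,
    trim: bool = True,
    spectrum: PartitionedSpectrum | None = None,
    n_buckets: int | None = None,
    backend: str = "bloom",
    batch_size: int = 65536,
) -> CorrectionResult:
    """Run the full pipeline: build spectrum, filter, fix (iterated), trim.

    Defaults follow the standard parameterisation: k=21, solidity threshold
    M=6, at most 4 trimmed bases, one fixing iteration.  With ``trim=False``
    reads that remain erroneous after the fixing budget keep their
    (partially corrected) sequence under status UNFIXED, which is the mode
    base-level accounting expects.  Outcomes preserve input order.
    """
    records: list[ReadRecord] = []
    for i, r in enumerate(reads):
        records.append(
            r if isinstance(r, ReadRecord) else ReadRecord(id=f"r{i}", sequence=r)
        )
    if spectrum is None:
        spectrum = PartitionedSpectrum.build(
            records,
            k=k,
            threshold=threshold,
            n_partitions=n_partitions,
            n_buckets=n_buckets,
            backend=backend,
            batch_size=batch_size,
        )
    outcomes: list[CorrectionOutcome | None] = [None] * len(records)
    erroneous: list[tuple[ReadRecord, np.ndarray]] = []
    err_pos: list[int] = []
    for i, rec in enumerate(records):
        if len(rec.sequence) < spectrum.k:
            outcomes[i] = CorrectionOutcome(
                read_id=rec.id, status=Status.DISCARDED, sequence=rec.sequence,
                quality=rec.quality,
            )
            continue
        sv = solidity_vector(spectrum, rec.sequence)
        if sv.any():
            erroneous.append((rec, sv))
            err_pos.append(i)
        else:
            outcomes[i] = CorrectionOutcome(
                read_id=rec.id, status=Status.ERROR_FREE, sequence=rec.sequence,
                quality=rec.quality,
            )
    fixed_results = iterate_fix(spectrum, erroneous, n_iterations)
    for i, (rec, sv, status, n_subs) in zip(err_pos, fixed_results):
        if status is Status.FIXED:
            outcomes[i] = CorrectionOutcome(
                read_id=rec.id,
                status=Status.FIXED,
                sequence=rec.sequence,
                quality=rec.quality,
                n_substitutions=n_subs,
            )
        elif trim:
            out = trim_read(rec, sv, max_trim=max_trim, k=spectrum.k)
            out.n_substitutions = n_subs
            outcomes[i] = out
        else:
            outcomes[i] = CorrectionOutcome(
                read_id=rec.id,
                status=Status.UNFIXED,
                sequence=rec.sequence,
                quality=rec.quality,
                n_substitutions=n_subs,
            )
    return CorrectionResult(
        outcomes=list(outcomes),  # type: ignore[arg-type]
        k=spectrum.k,
        threshold=spectrum.threshold,
        n_partitions=spectrum.n_partitions,
        n_iterations=n_iterations,
    )
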