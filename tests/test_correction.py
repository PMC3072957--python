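"""Filtering, voting, fixing, iteration and trimming semantics."""

import numpy as np
import pytest

import speckfix as sf
from speckfix.correction import ReadTooShortError
from speckfix.io_formats import ReadRecord
from speckfix.spectrum import PartitionedSpectrum

K = 21


def build_exact(reads, k=K, threshold=6, n_partitions=1):
    return PartitionedSpectrum.build(
        reads, k=k, threshold=threshold, n_partitions=n_partitions, backend="exact"
    )


def mutate(seq: str, j: int) -> str:
    """Deterministic single substitution at position j."""
    new = "ACGT"[("ACGT".index(seq[j]) + 1) % 4]
    return seq[:j] + new + seq[j + 1 :]


def vote_oracle(spectrum, read, sv, spos=0):
    """Brute-force voting: re-query every single-substitution k-mer string."""
    l, k = len(read), spectrum.k
    vm = np.zeros((l, 4), dtype=int)
    for i in range(l - k + 1):
        if i < spos or not sv[i]:
            continue
        kmer = read[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        for p in range(k):
            for b in "ACGT":
                if b == kmer[p]:
                    continue
                if spectrum.is_solid(kmer[:p] + b + kmer[p + 1 :]):
                    vm[i + p, "ACGT".index(b)] += 1
    return vm


@pytest.fixture(scope="module")
def clean_cov():
    """Error-free tiling of a 200 bp genome: every window 6 times, so every
    genomic k-mer has multiplicity >= 6 and is solid at the default M."""
    genome = sf.random_genome(200, seed=77)
    windows = [genome[i : i + 36] for i in range(len(genome) - 36 + 1)]
    reads = windows * 6
    return genome, windows, build_exact(reads)


def test_solidity_vector_clean_read_all_zero():
    read = sf.random_genome(36, seed=4)
    spec = build_exact([read] * 6)
    assert not sf.solidity_vector(spec, read).any()


def test_solidity_vector_length_and_too_short(clean_cov):
    _, win, spec = clean_cov
    sv = sf.solidity_vector(spec, win[0])
    assert len(sv) == 36 - K + 1
    with pytest.raises(ReadTooShortError):
        sf.solidity_vector(spec, "A" * (K - 1))


@pytest.mark.parametrize("j", [0, 5, 17, 20, 35])
def test_single_error_weak_window(clean_cov, j):
    """A substitution at j makes weak exactly the k-mers covering j."""
    _, win, spec = clean_cov
    read = win[0]
    sv = sf.solidity_vector(spec, mutate(read, j))
    l = len(read)
    expect_lo, expect_hi = max(0, j - K + 1), min(j, l - K)
    weak = np.nonzero(sv)[0]
    assert weak.min() == expect_lo and weak.max() == expect_hi
    assert len(weak) == min(K, j + 1, l - j, l - K + 1)


def test_filter_reads_split_is_exhaustive_and_disjoint(clean_cov):
    _, win, spec = clean_cov
    reads = list(win[:20])
    reads[3] = mutate(reads[3], 10)
    good, bad = sf.filter_reads(spec, reads)
    assert len(good) + len(bad) == 20
    assert {rec.id for rec, _ in bad} == {"r3"}
    assert all(sv.any() for _, sv in bad)


def test_vote_matches_brute_force_oracle(clean_cov):
    _, win, spec = clean_cov
    for idx, j in [(0, 7), (1, 0), (2, 30)]:
        read = mutate(win[10 + idx * 7], j)
        sv = sf.solidity_vector(spec, read)
        vm = sf.vote(spec, read, sv)
        assert (vm == vote_oracle(spec, read, sv)).all()


def test_vote_never_votes_for_current_base(clean_cov):
    _, win, spec = clean_cov
    read = mutate(win[0], 12)
    sv = sf.solidity_vector(spec, read)
    vm = sf.vote(spec, read, sv)
    digits = [("ACGT".index(c)) for c in read]
    assert all(vm[j, digits[j]] == 0 for j in range(len(read)))


def test_vote_bounded_by_covering_kmer_count(clean_cov):
    _, win, spec = clean_cov
    read = mutate(win[40], 20)
    sv = sf.solidity_vector(spec, read)
    vm = sf.vote(spec, read, sv)
    l = len(read)
    for j in range(l):
        bound = min(K, j + 1, l - j, l - K + 1)
        assert vm[j].max() <= bound


def test_vote_argmax_recovers_single_error(clean_cov):
    _, win, spec = clean_cov
    original = win[50]
    j = 18
    read = mutate(original, j)
    sv = sf.solidity_vector(spec, read)
    vm = sf.vote(spec, read, sv)
    pos, base = divmod(int(np.argmax(vm)), 4)
    assert pos == j and "ACGT"[base] == original[j]
    assert vm[j].max() == min(K, j + 1, len(read) - j, len(read) - K + 1)


def test_fix_read_applies_single_substitution_and_tiebreak():
    vm = np.zeros((10, 4), dtype=int)
    assert sf.fix_read("A" * 10, vm) == ("A" * 10, False)
    vm[4, 2] = 3
    fixed, changed = sf.fix_read("A" * 10, vm)
    assert changed and fixed == "AAAAGAAAAA"
    vm[7, 1] = 3  # tie: earlier position wins
    assert sf.fix_read("A" * 10, vm)[0] == "AAAAGAAAAA"
    vm2 = np.zeros((10, 4), dtype=int)
    vm2[2, 1] = vm2[2, 3] = 5  # tie at one position: base order A<C<G<T
    assert sf.fix_read("A" * 10, vm2)[0] == "AACAAAAAAA"


def test_iterate_fix_two_errors_needs_two_iterations(clean_cov):
    _, win, spec = clean_cov
    original = win[60]
    read = mutate(mutate(original, 2), 30)  # errors >= k apart
    sv = sf.solidity_vector(spec, read)
    one = sf.iterate_fix(spec, [(ReadRecord(id="x", sequence=read), sv)], 1)
    two = sf.iterate_fix(spec, [(ReadRecord(id="x", sequence=read), sv)], 2)
    assert one[0][2] is None  # still erroneous after one pass
    assert two[0][2] is sf.Status.FIXED
    assert two[0][0].sequence == original and two[0][3] == 2


def test_more_iterations_never_leave_more_reads_erroneous(clean_cov):
    _, win, spec = clean_cov
    pairs = []
    for idx in range(8):
        read = mutate(win[10 + idx * 7], 3 + idx * 2)
        pairs.append((ReadRecord(id=f"r{idx}", sequence=read),
                      sf.solidity_vector(spec, read)))
    remaining = [
        sum(1 for r in sf.iterate_fix(spec, pairs, n) if r[2] is None)
        for n in (1, 2, 3)
    ]
    assert remaining[0] >= remaining[1] >= remaining[2]


def test_trim_error_at_last_base():
    """l=36, k=21, weak only at the final k-mer start: keep 35 bases."""
    sv = np.zeros(16, dtype=np.uint8)
    sv[15] = 1
    out = sf.trim_read("A" * 36, sv, max_trim=4, k=21)
    assert out.status is sf.Status.TRIMMED
    assert out.trim == (0, 35) and len(out.sequence) == 35


def test_trim_mid_read_error_discards():
    """An error at j=18 leaves no >=32-base all-solid substring."""
    sv = np.zeros(16, dtype=np.uint8)
    sv[0:16] = 0
    for i in range(max(0, 18 - 21 + 1), min(18, 15) + 1):
        sv[i] = 1
    out = sf.trim_read("A" * 36, sv, max_trim=4, k=21)
    assert out.status is sf.Status.DISCARDED


def test_trim_prefers_leftmost_longest_run():
    sv = np.array([0, 0, 1, 0, 0, 1, 0, 0], dtype=np.uint8)
    out = sf.trim_read("A" * 12, sv, max_trim=100, k=5)
    assert out.trim == (0, 6)


def test_trim_all_weak_discards():
    out = sf.trim_read("A" * 10, np.ones(6, dtype=np.uint8), max_trim=100, k=5)
    assert out.status is sf.Status.DISCARDED


def test_correct_dataset_error_free_input_is_identity(clean_cov):
    _, win, _ = clean_cov
    reads = win * 6
    res = sf.correct_dataset(reads, k=K, threshold=6)
    assert all(o.status is sf.Status.ERROR_FREE for o in res.outcomes)
    assert [o.sequence for o in res.outcomes] == reads


def test_correct_dataset_reduces_error_rate(small_sim):
    res = sf.correct_dataset(small_sim.reads, n_iterations=2, trim=False)
    orig = {r.id: r.sequence for r in small_sim.originals}
    before = sf.error_rate([(r.sequence, orig[r.id]) for r in small_sim.reads])
    after = sf.error_rate(
        [(o.sequence, orig[o.read_id]) for o in res.outcomes]
    )
    assert after.mismatches < before.mismatches


def test_outcome_partition_and_conservation(small_sim):
    res = sf.correct_dataset(small_sim.reads, n_iterations=1, trim=True)
    assert len(res.outcomes) == len(small_sim.reads)
    spec = PartitionedSpectrum.build(
        [r.sequence for r in small_sim.reads], k=21, threshold=6, backend="exact"
    )
    for o in res.outcomes[:300]:
        if o.status in (sf.Status.ERROR_FREE, sf.Status.FIXED):
            assert not sf.solidity_vector(spec, o.sequence).any()
        elif o.status is sf.Status.TRIMMED:
            assert not sf.solidity_vector(spec, o.sequence).any()
            assert 36 - len(o.sequence) <= 4
        if o.quality is not None:
            assert len(o.quality) == len(o.sequence)


def test_short_and_all_ambiguous_reads_are_discarded(clean_cov):
    _, win, _ = clean_cov
    reads = list(win) * 6 + ["ACGT", "N" * 36]
    res = sf.correct_dataset(reads, k=K, threshold=6)
    assert res.outcomes[-2].status is sf.Status.DISCARDED  # shorter than k
    assert res.outcomes[-1].status is sf.Status.DISCARDED  # no unambiguous k-mer


def test_determinism(small_sim):
    reads = small_sim.reads[:400]
    a = sf.correct_dataset(reads, n_iterations=2)
    b = sf.correct_dataset(reads, n_iterations=2)
    assert [(o.status, o.sequence) for o in a.outcomes] == [
        (o.status, o.sequence) for o in b.outcomes
    ]


def test_reduction_equivalence_across_partitions(small_sim):
    """Per-partition solidity/vote combination equals the unpartitioned run."""
    reads = small_sim.reads[:600]
    results = [
        sf.correct_dataset(reads, n_iterations=2, n_partitions=n, backend="exact")
        for n in (1, 3, 4)
    ]
    base = [(o.status, o.sequence) for o in results[0].outcomes]
    for other in results[1:]:
        assert [(o.status, o.sequence) for o in other.outcomes] == base
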