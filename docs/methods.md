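# Methods

## Model and assumptions

Correction rests on the spectral-alignment picture of short-read data:
the multiset of k-mers of all reads approximates the genome's k-mer set,
because at coverage C every genomic k-mer recurs (expected multiplicity
m = C·(L−k+1)/L) while a substitution error creates up to
min{k, j+1, l−j, l−k+1} k-mers (j the error position, l the read length)
that are essentially unique. A k-mer is *solid* when its multiplicity
reaches the threshold M, *weak* otherwise; an error-free read is one
whose every k-mer is solid. The assumptions that make this work:

- errors are substitutions (no indels — a deliberate non-goal);
- coverage is high enough that m comfortably exceeds M (m ≳ 2M);
- the genome is not so repetitive that error k-mers coincide with
  genomic ones (at k = 21 coincidences are negligible for non-repetitive
  sequence).

Both strands of every k-mer occurrence are inserted into the spectrum,
so queries are strand-symmetric through a single forward-code lookup.

## Data structures

**Packed codes.** A k-mer maps to an integer by A,C,G,T → 0..3, leftmost
base most significant (numeric order = lexicographic order; the choice
of digit order is free since codes are used only as hash input and
modulo the partition count). k ≤ 31 fits int64. Windows overlapping
N/IUPAC bases cannot be packed; they are flagged, never inserted, always
weak, and cast no votes, so a read whose errors sit next to an N falls
through to trimming.

**Counting Bloom filter.** One counter array per spectrum partition;
counters saturate at 15 (4-bit semantics), query returns the minimum
over the h = 8 addressed buckets — an upper bound on true multiplicity,
never an undercount. Bucket addressing is double hashing
g_i(x) = h1(x) + i·h2(x) mod N_B over two fixed-seed splitmix64 mixes
(h2 forced odd), which preserves the classical FPP = (1 − e^−α)^h model
and is fully deterministic; N_B is a power of two so the modulo is a
mask. `n_inserted` counts insert *calls* (k-mer occurrences); the
capacity model's N_E is *distinct* elements — the planner takes N_E as
an estimate and the automatic filter sizing uses total occurrences as a
generous stand-in, which over-provisions and keeps the realised FPP
below plan.

**Partitioning.** Partition c mod N_PE owns code c: local spectra are
pairwise disjoint and cover all 4^k codes. Queries go to the owning
partition only — a k-mer can never have been inserted elsewhere, so
owner-routing is exactly equivalent to querying all partitions and
AND/ADD-reducing, and the whole pipeline is invariant to N_PE (verified
byte-for-byte for N_PE ∈ {1, 2, 4, 8} in the system tests). With
per-partition sizing at α = 0.25 the residual Bloom collisions are far
too weak to lift a weak k-mer past M, which is why invariance holds in
practice even though different N_PE values hash different element sets.

## The correction stages

1. **Filter.** Solidity vector per read (bit per k-mer start, 1 = weak);
   all-zero vectors exit as ERROR_FREE. Reads shorter than k are
   discarded.
2. **Vote.** For each weak, unambiguous k-mer, each in-window position
   and each of the 3 alternative bases, the single-substitution k-mer is
   queried; solidity casts one vote for (position, base). Votes for the
   read's current base are impossible by construction, and no vote count
   can exceed the number of weak k-mers covering its position.
3. **Fix.** The single highest-voted substitution is applied — ties
   break to the smallest position, then base order A<C<G<T (row-major
   argmax), making the pipeline deterministic. Applying one substitution
   per pass and re-filtering guards against a bad vote cascading; a
   minimum-vote threshold beyond "at least one" was deliberately not
   imposed, since verification is delegated to the next filtering pass.
4. **Iterate.** With an iteration budget > 1, still-erroneous reads are
   re-voted (from the first weak position — everything before the saved
   start position SPOS is known solid) and re-fixed; reads whose vector
   clears exit as FIXED; reads that receive zero votes are abandoned
   early since the spectrum is static. One iteration fixes one error per
   read; two reach two-error reads. More iterations never increase the
   number of remaining erroneous reads.
5. **Trim.** A run of r consecutive solid k-mer starts spans r + k − 1
   bases. The leftmost longest such substring is kept if at most
   `max_trim` bases are lost; otherwise the read is DISCARDED. A read
   with no solid k-mer at all is discarded (a substring shorter than k
   contains no k-mers and is not considered a valid trim). With
   trimming disabled (the mode base-level accounting requires, since it
   needs positional correspondence) still-erroneous reads keep their
   partially corrected sequence under a fifth status, UNFIXED.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| k | 21 | k-mer length; long enough that error k-mers are unique, short enough for dense coverage |
| M | 6 | solidity threshold; separates m ≈ 33 (C = 75, L = 36) from error multiplicities ≈ 1–2 |
| h | 8 | Bloom hash functions |
| α | 0.25 | design load factor; FPP ≈ 5.7×10⁻⁶ |
| N_PE | 1 | spectrum partitions; results invariant, memory per partition shrinks |
| max_trim | 4 | largest acceptable length loss when trimming |
| iterations | 1 | fixing passes (2 reaches two-error reads; evaluation runs use 2) |

## Synthetic data

The simulator emulates substitution-error short-read datasets: i.i.d.
uniform random genome (GC configurable, default 0.5), round(C·G/L) reads
at uniform random start positions, both strands by default, each base
independently substituted with probability e uniformly over the three
alternatives, constant high quality scores. Ground truth is the
error-free original of each read (in read orientation) plus a table of
every injected error.

What it does **not** emulate: genomic repeats, coverage bias, position-
and quality-dependent error profiles, indels, paired ends. Consequences:
correction quality measured here is an upper bound on real-data
performance — on a random 100 kb genome the correct-correction rate
comes out around 94%, higher than on a real 4.6 Mb bacterial genome
where repeats make some votes ambiguous and coverage dips create weak
genomic k-mers. The *relative* behaviour (error-rate reduction,
near-zero miscorrection, >99% detection sensitivity, partition
invariance) is what the tests establish.

Genome ends receive ramp-down coverage (a k-mer at the first base is
covered by a single read start), so a small fraction of error-free reads
near the ends carries weak k-mers; this is visible as specificity
slightly below 100% and a few unfixable reads, and is a property of
linear genomes, not a defect.

## Evaluation conventions

- **Classification**: a read the pipeline did not pass through as
  ERROR_FREE counts as "detected erroneous". Sensitivity and specificity
  are undefined (reported as None/NA) when their denominator is empty.
- **Error rate**: base-by-base against the error-free original; for
  length-mismatched pairs the shorter sequence is slid gaplessly along
  the longer, the minimum-mismatch offset is kept and the shorter length
  enters the denominator.
- **Base accounting**: every original error base is exactly one of CC
  (restored), IC (changed to a third base), EU (unchanged); EI counts
  originally correct bases newly corrupted. All three rates R_CC, R_IC,
  R_EI are reported relative to the total number of original base errors
  (CC + IC + EU). Equal-length pairs only; mismatched pairs are skipped
  and counted.

## Numerical and implementation choices

- Saturating insertion is applied per batch as "add tally, clip at 15",
  which is arithmetically identical to per-occurrence saturation.
- Voting, filtering and fixing are vectorised over read batches
  (candidate k-mer codes are generated by digit arithmetic on packed
  codes, never by string editing); the per-read public functions and the
  batched pipeline share one kernel, and a string-based brute-force
  voting oracle checks it in the tests.
- The exact hash-table spectrum backend (`backend="exact"`) is a
  first-class drop-in used for small problems and as the collision-free
  oracle; its queries saturate at 15 to match the Bloom contract.
- Problem sizes in the shipped tests and the acceptance script: a 100 kb
  genome at C = 75 (≈208 k reads) for the system-level checks, ≤2 kb
  genomes for oracle equivalence, 2²⁰-bucket filters for the empirical
  FPP check. These sizes give stable statistics (≥10⁵ Bernoulli trials
  wherever a rate is asserted) while keeping a full run to a few
  minutes.

## Known limitations

- Substitutions only; indels shift every downstream k-mer and are out of
  scope.
- Quality scores are carried through but never consulted.
- Multiplicities cap at 15, so the spectrum cannot distinguish
  high-copy repeats from unique sequence; correction inside repeats can
  vote for the wrong paralog.
- The capacity planner's N_E is distinct k-mers; datasets dominated by
  errors (many near-unique k-mers) need the α budget read against the
  error k-mer count, not the genome size.
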