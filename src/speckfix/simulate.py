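"""Synthetic genomes and error-bearing read datasets with ground truth.

The simulator emulates the kind of benchmark datasets used to grade
substitution-error correction: reads of a fixed length L are drawn with
uniform random start positions (from both strands by default) off a
reference genome until the target coverage C is reached — round(C*G/L)
reads — and each base is independently substituted, with probability e, by
one of the three other bases chosen uniformly.  Alongside the error-bearing
reads it emits the error-free originals (in read orientation, so the
per-read Hamming distance equals the number of injected errors) and a table
of every injected error.

No indels, no quality model (qualities are written as a constant high
score) and no fragment-size model: the pipeline under test corrects
substitutions only and never interprets qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from speckfix.kmer_codec import digits_of, digits_to_str

__all__ = ["SimulationConfig", "SimulationResult", "random_genome", "simulate_reads"]

from speckfix.io_formats import ReadRecord

DEFAULT_QUALITY_CHAR = "I"  # Phred+33 Q40


def random_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """I.i.d. random genome sequence; deterministic under ``seed``.

    ``gc`` sets the expected G+C fraction (split evenly between G and C;
    A and T share the remainder).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A C G T
    digits = rng.choice(4, size=length, p=probs).astype(np.int8)
    return digits_to_str(digits)


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset."""

    genome_length: int | None = None
    genome: str | None = None
    coverage: float = 75.0
    read_length: int = 36
    error_rate: float = 0.015
    seed: int = 0
    both_strands: bool = True
    gc: float = 0.5

    @property
    def n_reads(self) -> int:
        g = len(self.genome) if self.genome else self.genome_length
        return int(round(self.coverage * g / self.read_length))


@dataclass
class SimulationResult:
    """Reads with injected errors, their error-free originals, and the truth table."""

    reads: list[ReadRecord]
    originals: list[ReadRecord]
    errors: pd.DataFrame  # read_id, pos, true_base, read_base
    genome: str
    config: SimulationConfig


_RC_DIGIT = np.array([3, 2, 1, 0], dtype=np.int8)


def simulate_reads(config: SimulationConfig) -> SimulationResult:
    """Draw reads off the genome and inject substitution errors.

    Start positions are uniform over the valid range; when
    ``config.both_strands`` each read is reverse-complemented with
    probability 1/2.  The originals keep the read's orientation, and the
    error table records, per injected error, the read position, the true
    base and the sequenced base.
    """
    cfg = config
    genome = cfg.genome if cfg.genome else random_genome(cfg.genome_length, cfg.seed, cfg.gc)
    g, length = len(genome), cfg.read_length
    if length > g:
        raise ValueError(f"read_length {length} exceeds genome length {g}")
    n = cfg.n_reads
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EC5]))
    gdig = digits_of(genome)
    if (gdig < 0).any():
        raise ValueError("genome contains ambiguous bases")
    starts = rng.integers(0, g - length + 1, size=n)
    windows = gdig[starts[:, None] + np.arange(length)]
    if cfg.both_strands:
        rc = rng.random(n) < 0.5
        windows[rc] = _RC_DIGIT[windows[rc][:, ::-1]]
    err_mask = rng.random((n, length)) < cfg.error_rate
    shift = rng.integers(1, 4, size=(n, length), dtype=np.int8)
    mutated = np.where(err_mask, (windows + shift) % 4, windows).astype(np.int8)

    reads, originals = [], []
    qual = DEFAULT_QUALITY_CHAR * length
    for i in range(n):
        rid = f"r{i}"
        reads.append(ReadRecord(id=rid, sequence=digits_to_str(mutated[i]), quality=qual))
        originals.append(ReadRecord(id=rid, sequence=digits_to_str(windows[i])))
    ridx, pos = np.nonzero(err_mask)
    bases = "ACGT"
    errors = pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in ridx],
            "pos": pos,
            "true_base": [bases[d] for d in windows[ridx, pos]],
            "read_base": [bases[d] for d in mutated[ridx, pos]],
        }
    )
    return SimulationResult(
        reads=reads, originals=originals, errors=errors, genome=genome, config=cfg
    )


def write_errors_tsv(errors: pd.DataFrame, path) -> None:
    """Write the injected-error table as TSV."""
    errors.to_csv(path, sep="\t", index=False)


def read_errors_tsv(path) -> pd.DataFrame:
    """Read an injected-error table written by :func:`write_errors_tsv`."""
    return pd.read_csv(path, sep="\t", dtype={"read_id": str})


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return int(np.count_nonzero(digits_of(a) != digits_of(b)))


def reads_to_strings(records: Sequence[ReadRecord]) -> list[str]:
    return [r.sequence for r in records]
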