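"""Shared fixtures: small simulated datasets and the full-scale study fixture."""

from __future__ import annotations

import numpy as np
import pytest

import speckfix as sf


@pytest.fixture(scope="session")
def small_sim():
    """2 kb genome, moderate coverage — quick end-to-end material."""
    genome = sf.random_genome(2000, seed=42)
    cfg = sf.SimulationConfig(
        genome=genome, coverage=40, read_length=36, error_rate=0.02, seed=42
    )
    return sf.simulate_reads(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """The full-scale study conditions: 100 kb genome, C=75, L=36, e=1.5%."""
    genome = sf.random_genome(100_000, seed=1234)
    cfg = sf.SimulationConfig(
        genome=genome, coverage=75, read_length=36, error_rate=0.015, seed=1234
    )
    return sf.simulate_reads(cfg)


@pytest.fixture(scope="session")
def study_runs(study_sim):
    """Pipeline outcomes on the study fixture for every partition count.

    k=21, M=6, two fixing iterations, trimming off — the configuration
    base-level accounting expects.
    """
    runs = {}
    for n_pe in (1, 2, 4, 8):
        runs[n_pe] = sf.correct_dataset(
            study_sim.reads,
            k=21,
            threshold=6,
            n_partitions=n_pe,
            n_iterations=2,
            trim=False,
        )
    return runs


def truth_labels(sim) -> dict[str, bool]:
    """Per-read has-error labels from the simulator's truth table."""
    labels = {r.id: False for r in sim.originals}
    for rid in sim.errors.read_id:
        labels[rid] = True
    return labels


def detected_labels(result) -> dict[str, bool]:
    """Per-read detected-as-erroneous labels from pipeline outcomes."""
    return {
        o.read_id: o.status is not sf.Status.ERROR_FREE for o in result.outcomes
    }


@pytest.fixture
def rng():
    return np.random.default_rng(7)
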