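"""Shared fixtures: seeded libraries reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import specklesplice as ss
from specklesplice.model import SpliceUsageModel, predict_and_evaluate, train_test_split

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def zero6():
    return ss.KmerEnergyTable.zeros(6)


@pytest.fixture(scope="session")
def null_library(zero6):
    """Null-model library: all-zero table, n=1e4, L=25, 100 reads/reporter."""
    return ss.simulate_library(10_000, 25, zero6, reads=100, seed=1)


@pytest.fixture(scope="session")
def benchmark():
    """Sparse-table recovery benchmark: 20 causal words at |dG| = 1 kT.

    n=5e4 reporters, L=25, 100 reads each; a seeded 80/20 split with
    enrichment scores fitted on the training portion and evaluated on the
    held-out portion.
    """
    truth = ss.sparse_benchmark_table(k=6, n_words=20, magnitude=1.0, seed=1)
    library = ss.simulate_library(50_000, 25, truth, reads=100, seed=2)
    train, test = train_test_split(library, 0.2, seed=3)
    results = SpliceUsageModel(train).fit(method="enrichment")
    evaluation = predict_and_evaluate(test, results.score_table, holdout=0.0)
    return {
        "truth": truth,
        "library": library,
        "train": train,
        "test": test,
        "results": results,
        "scores": results.score_table,
        "evaluation": evaluation,
    }


@pytest.fixture()
def toy_transcript_factory():
    """3-exon toy transcript on a neutral G/U background with an insertion slot."""
    base = "G" * 40 + "U" * 30 + "G" * 40 + "U" * 30 + "G" * 40
    segments = [
        (0, 40, "exon"),
        (40, 70, "intron"),
        (70, 110, "exon"),
        (110, 140, "intron"),
        (140, 180, "exon"),
    ]

    def build(insert_at=None, word=""):
        seq = base
        if insert_at is not None:
            seq = base[:insert_at] + word + base[insert_at + len(word):]
        return ss.TranscriptAnnotation(seq, segments)

    return build
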