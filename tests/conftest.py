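"""Shared fixtures and the independent brute-force signature oracle."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromidfinder.markers import MarkerDatabase
from chromidfinder.synthetic import GeneratorParams, generate_benchmark, toy_marker_database

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain string slicing + Counter + dicts,
# sharing no code with chromidfinder.signatures
# ---------------------------------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _oracle_counts(seq: str, k: int) -> Counter:
    counts = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    return Counter({w: c for w, c in counts.items() if "N" not in w})


def oracle_relative_abundance(seq: str, k: int) -> dict[str, float]:
    """rho(w) per word, by literal word enumeration over both strands."""
    ck = _oracle_counts(seq, k) + _oracle_counts(oracle_revcomp(seq), k)
    c1 = _oracle_counts(seq, 1) + _oracle_counts(oracle_revcomp(seq), 1)
    total_k = sum(ck.values())
    total_1 = sum(c1.values())
    f1 = {b: c1[b] / total_1 for b in "ACGT"}
    rho = {}
    for letters in itertools.product("ACGT", repeat=k):
        word = "".join(letters)
        denom = 1.0
        for b in letters:
            denom *= f1[b]
        rho[word] = (ck[word] / total_k) / denom if denom > 0 else 0.0
    return rho


def oracle_distance(seq_a: str, seq_b: str, k: int, scale: float = 10.0) -> float:
    ra = oracle_relative_abundance(seq_a, k)
    rb = oracle_relative_abundance(seq_b, k)
    return scale * sum(abs(ra[w] - rb[w]) for w in ra) / 4**k


def random_dna(length: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_db() -> MarkerDatabase:
    return toy_marker_database()


@pytest.fixture(scope="session")
def benchmark50(toy_db):
    """The seed-11, n=50 default-parameter benchmark plus one pipeline state.

    Session-scoped: generation and pipeline steps 1-3 are shared by all
    tests that evaluate the default study conditions.
    """
    from chromidfinder.classify import prepare_pipeline

    pool, truth = generate_benchmark(50, params=GeneratorParams(), seed=11)
    state = prepare_pipeline(pool, toy_db)
    return pool, truth, state
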