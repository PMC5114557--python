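"""Shared fixtures: tiny alignments, toy chains, record tables."""

from __future__ import annotations

import numpy as np
import pytest

from msabias import (
    Alignment,
    DatasetRecord,
    SimConfig,
    gen_structure,
)
from msabias.msa_metrics import CANONICAL_AA


@pytest.fixture
def identical_alignment() -> Alignment:
    """10 identical gap-free rows: NEFF must be exactly 1."""
    return Alignment(
        query_id="q",
        ids=tuple(f"s{i}" for i in range(10)),
        rows=("ACDEFGHIKL",) * 10,
    )


@pytest.fixture
def fully_variable_alignment() -> Alignment:
    """20 rows, every column a permutation of the whole alphabet: NEFF 20."""
    rows = tuple(
        "".join(CANONICAL_AA[(r + c) % 20] for c in range(30)) for r in range(20)
    )
    return Alignment(query_id="s0", ids=tuple(f"s{i}" for i in range(20)), rows=rows)


@pytest.fixture
def small_alignment() -> Alignment:
    """3 rows, 2 columns; column types {A} and {C, D} so NEFF = 1.5."""
    return Alignment(query_id="q", ids=("q", "h1", "h2"), rows=("AC", "AD", "AC"))


@pytest.fixture(scope="session")
def toy_chain():
    """Deterministic compact 35-residue chain."""
    return gen_structure(SimConfig(seed=11, length=35))


def random_alignment(rng: np.random.Generator, n_rows: int, n_cols: int,
                     gap_rate: float = 0.1) -> Alignment:
    """Helper for randomized fixtures: arbitrary letters and gaps."""
    alphabet = list(CANONICAL_AA) + ["-"]
    probs = [(1 - gap_rate) / 20] * 20 + [gap_rate]
    rows = []
    for r in range(n_rows):
        letters = rng.choice(alphabet, size=n_cols, p=probs)
        if r == 0:
            letters[rng.integers(0, n_cols)] = "A"  # query keeps ≥1 residue
        rows.append("".join(letters))
    return Alignment(
        query_id="q",
        ids=tuple(f"s{i}" for i in range(n_rows)),
        rows=tuple(rows),
    )


def make_records(counts, length: int = 100, **kwargs) -> list[DatasetRecord]:
    return [
        DatasetRecord(id=f"r{k}", length=length, homolog_count=int(c), **kwargs)
        for k, c in enumerate(counts)
    ]
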