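"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from transnp.io_core import PileupColumn


def make_column(
    counts: dict[str, int],
    contig_id: str = "ctg1",
    position: int = 0,
    individuals: list[str] | None = None,
) -> PileupColumn:
    """Build a pileup column from a base -> read-count mapping."""
    obs = []
    i = 0
    for base, n in counts.items():
        for _ in range(n):
            ind = individuals[i % len(individuals)] if individuals else None
            obs.append((f"r{i}", base, ind, None))
            i += 1
    return PileupColumn(contig_id, position, obs)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
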