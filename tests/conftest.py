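"""Shared fixtures and sequence helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), size=n)])


def substitute(residues: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position to a uniformly chosen different base."""
    out = list(residues)
    for p in positions:
        others = BASES.replace(out[p], "")
        out[p] = others[rng.integers(0, len(others))]
    return "".join(out)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba JIT once so individual test timings stay meaningful."""
    from viropanel.align import glocal_alignment, local_alignment

    glocal_alignment("ACGT", "ACGTACGT")
    local_alignment("ACGT", "ACGTACGT")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240203)
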