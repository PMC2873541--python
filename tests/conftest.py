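"""Shared fixtures: small random sequences and index pairs."""

import numpy as np
import pytest

from coalign.seedkit import parse_seed_pattern

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(n: int, seed: int = 0, masked_fraction: float = 0.0) -> str:
    """Uppercase random nucleotide sequence, optionally soft-masked runs."""
    rng = np.random.default_rng(seed)
    arr = BASES[rng.integers(0, 4, size=n)].copy()
    if masked_fraction > 0:
        run = max(5, n // 50)
        lower = np.zeros(n, dtype=bool)
        while lower.mean() < masked_fraction:
            p = int(rng.integers(0, max(1, n - run)))
            lower[p : p + run] = True
        arr = np.where(lower, arr + 32, arr).astype(np.uint8)
    return arr.tobytes().decode("ascii")


@pytest.fixture(scope="session")
def seed11():
    return parse_seed_pattern("111*1**1*1**11*111")


@pytest.fixture(scope="session")
def seed7():
    return parse_seed_pattern("1111111")


@pytest.fixture(scope="session")
def tiny_seed():
    # weight-4 seed keeps brute-force oracles cheap
    return parse_seed_pattern("11*1*1")
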