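import math
import random

import numpy as np
import pytest
from hypothesis import settings

import barcodegap as bg

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None, database=None
)
settings.load_profile("ci")


BASES = "ACGT"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def random_alignment(rng: random.Random, n: int, L: int, mut: float = 0.1) -> bg.BarcodeAlignment:
    """A random alignment built by mutating a common ancestor: related
    enough that K2P never saturates at moderate mut."""
    anc = [rng.choice(BASES) for _ in range(L)]
    seqs = []
    for _ in range(n):
        s = list(anc)
        for k in range(L):
            if rng.random() < mut:
                s[k] = rng.choice(BASES)
        seqs.append("".join(s))
    ids = [f"sp{i:02d}" for i in range(n)]
    return bg.BarcodeAlignment(ids=ids, seqs=seqs)


def brute_force_k2p(a: str, b: str):
    """Independent per-site tally + direct formula evaluation."""
    ts = tv = m = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        m += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    P, Q = ts / m, tv / m
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


@pytest.fixture(scope="session")
def pencilfish():
    """One seeded full-study simulation shared across tests."""
    return bg.simulate(bg.preset("pencilfish-like", seed=20240901))


@pytest.fixture(scope="session")
def pencilfish_dm(pencilfish):
    return bg.distance_matrix(pencilfish.alignment)


@pytest.fixture
def tiny_alignment():
    return bg.BarcodeAlignment(
        ids=["a", "b", "c", "d"],
        seqs=["ACGTACGT", "GCGTACGT", "ACGAACGT", "ACGTACGA"],
    )
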