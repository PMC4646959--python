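import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ribotax as rt

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_reference():
    """Six well-separated genera, three species each — tiny but realistic."""
    return rt.build_reference(n_genera=6, species_per_genus=3,
                              inter_genus_div=0.15, intra_genus_div=0.02, seed=11)


@pytest.fixture(scope="session")
def small_hmm(small_reference):
    return rt.build_hmm(small_reference)


@pytest.fixture(scope="session")
def toy_db():
    """Two genera with hand-checkable word content (k=3 keeps counts tiny)."""
    lin_a = rt.Lineage(("Bacteria", "P1", "C1", "O1", "F1", "Alpha"))
    lin_b = rt.Lineage(("Bacteria", "P1", "C1", "O1", "F2", "Beta"))
    return rt.ReferenceDB(
        sequences={"a1": "AAAAACCCCC", "a2": "AAAAAGGGGG",
                   "b1": "TTTTTGGGGG", "b2": "TTTTTCCCCC"},
        lineages={"a1": lin_a, "a2": lin_a, "b1": lin_b, "b2": lin_b},
        k=3,
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
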