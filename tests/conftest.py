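import numpy as np
import pytest
from hypothesis import settings

from strpopkit.model import Genotype, GenotypeTable

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")


@pytest.fixture
def biallelic_table():
    """25 AA / 50 AB / 25 BB at one locus: exact Hardy-Weinberg counts."""
    calls = ([Genotype.of("12", "12")] * 25
             + [Genotype.of("12", "13")] * 50
             + [Genotype.of("13", "13")] * 25)
    ids = [f"i{k}" for k in range(100)]
    return GenotypeTable("pop", ids, ["L1"], {"L1": calls})


@pytest.fixture
def two_locus_table():
    """Two independent-ish loci over 8 individuals, one missing call."""
    l1 = [Genotype.of(a, b) for a, b in
          [("12", "13"), ("12", "12"), ("13", "14"), ("12", "13"),
           ("14", "14"), ("12", "14"), ("13", "13"), ("12", "13")]]
    l2 = [Genotype.of(a, b) for a, b in
          [("9", "10"), ("9", "9"), ("10", "10"), ("9", "10"),
           ("9", "9"), ("10", "10"), ("9", "10"), ("9", "9")]]
    l2[3] = None
    ids = [f"s{k}" for k in range(8)]
    return GenotypeTable("mini", ids, ["LA", "LB"], {"LA": l1, "LB": l2})


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)
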