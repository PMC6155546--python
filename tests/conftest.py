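import numpy as np
import pytest

from gyrbench.refdb import MarkerRecord
from gyrbench.synthetic_data import make_reference_set, mock_preset, simulate_reads


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def _tax(phylum, family, genus, species, strain):
    cls = "Bacilli" if phylum == "Firmicutes" else "Gammaproteobacteria"
    return ("Bacteria", phylum, cls, "order", family, genus, species, strain)


@pytest.fixture
def toy_db():
    """Three well-separated markers: two congeneric gyrB + one parE."""
    return [
        MarkerRecord(
            "sp1_gyrB",
            _tax("Firmicutes", "Lactobacillaceae", "Lactobacillus", "Lactobacillus sakei", "s1"),
            "gyrB",
            "ACGTACGTACGTACGTACGTACGTACGTAC",
        ),
        MarkerRecord(
            "sp2_gyrB",
            _tax("Firmicutes", "Lactobacillaceae", "Lactobacillus", "Lactobacillus algidus", "s2"),
            "gyrB",
            "ACGTACGTACGTACGTACGTACGTACGTTG",
        ),
        MarkerRecord(
            "sp1_parE",
            _tax("Firmicutes", "Lactobacillaceae", "Lactobacillus", "Lactobacillus sakei", "s1"),
            "parE",
            "TTGCATGCATGCAAGGCCTTGCATCCGGAA",
        ),
    ]


@pytest.fixture(scope="session")
def mc1_small():
    """A small error-free MC1 run shared by cheap truth-recovery tests."""
    spec = mock_preset("MC1", depth=20_000, error_rate=0.0, seed=11)
    refs = make_reference_set(spec)
    reads, truth = simulate_reads(spec, refs)
    return spec, refs, reads, truth
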