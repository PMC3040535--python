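import random
from pathlib import Path

import numpy as np
import pytest

from phoskit import (
    Protein,
    SyntheticConfig,
    annotate_site,
    generate_proteome,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def uniprot_fixture_path() -> Path:
    return DATA_DIR / "uniprot_fixture.xml"


@pytest.fixture
def simple_protein() -> Protein:
    p = Protein(accession="P1", sequence="MSTSYKRSTA")
    annotate_site(p, 2, "S", source="UniProt")
    annotate_site(p, 5, "Y", source="UniProt")
    return p


@pytest.fixture(scope="session")
def small_proteome():
    """Small synthetic proteome: quick to train on, still carries signal."""
    return generate_proteome(
        SyntheticConfig(n_proteins=60, mean_length=250, seed=11)
    )


def random_protein(rng: random.Random, index: int, with_track: bool = True) -> Protein:
    """A random protein with phospho annotations and an optional track."""
    length = rng.randint(20, 120)
    seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
    p = Protein(accession=f"R{index:04d}", sequence=seq)
    for pos in range(1, length + 1):
        if seq[pos - 1] in "STY" and rng.random() < 0.2:
            annotate_site(p, pos, seq[pos - 1], source="test")
    if with_track:
        p.add_track("disorder", [round(rng.random(), 6) for _ in range(length)])
    return p


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
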