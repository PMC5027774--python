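import numpy as np
import pytest

from barcodekit.distances import DistanceMatrix
from barcodekit.seqio import Alignment, SequenceRecord
from barcodekit.synthetic_data import (
    default_coi_config,
    default_morphology_config,
    default_rhodopsin_config,
    simulate_alignment,
    simulate_morphology,
)


def make_alignment(seqs: dict[str, str], species: dict[str, str] | None = None,
                   marker: str = "COI") -> Alignment:
    """Alignment from {specimen_id: sequence} (+ optional species labels)."""
    species = species or {}
    return Alignment([
        SequenceRecord(sid, species.get(sid, sid.split("_")[0]), marker, seq)
        for sid, seq in seqs.items()
    ])


def make_dm(labels: list[str], pct: np.ndarray) -> DistanceMatrix:
    """DistanceMatrix from a percent-scale square array."""
    pct = np.asarray(pct, dtype=float)
    sites = np.full_like(pct, 500, dtype=np.int64)
    return DistanceMatrix(list(labels), pct / 100.0, sites)


def random_alignment(rng: np.random.Generator, n_records: int = 10,
                     length: int = 50, n_species: int = 3,
                     ambiguity_frac: float = 0.0) -> Alignment:
    bases = np.array(list("ACGT"))
    extra = np.array(list("RYN-"))
    seqs = {}
    species = {}
    for i in range(n_records):
        chars = rng.choice(bases, size=length)
        if ambiguity_frac:
            mask = rng.random(length) < ambiguity_frac
            chars[mask] = rng.choice(extra, size=int(mask.sum()))
        sid = f"sp{i % n_species}_r{i:02d}"
        seqs[sid] = "".join(chars)
        species[sid] = f"species {i % n_species}"
    return make_alignment(seqs, species)


@pytest.fixture(scope="session")
def rhodopsin_fixture():
    """464-site nuclear alignment with the three-variable-site pattern."""
    return simulate_alignment(default_rhodopsin_config(seed=1))


@pytest.fixture(scope="session")
def coi_fixture():
    """652-site barcode-like alignment (70 specimens, 4 species)."""
    return simulate_alignment(default_coi_config(seed=3))


@pytest.fixture(scope="session")
def morph_fixture():
    """Morphology table simulated at the reference parameters, n=20/species."""
    return simulate_morphology(default_morphology_config(seed=1))
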