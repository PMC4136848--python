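from __future__ import annotations

import numpy as np
import pytest

from serscan.seqdata import AMINO_ACIDS, ProteinRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140818)


def random_protein(rng: np.random.Generator, length: int, cys_rate: float = 0.15,
                   protein_id: str = "p") -> ProteinRecord:
    """Random protein with a controllable cysteine rate."""
    background = AMINO_ACIDS.replace("C", "")
    chars = rng.choice(list(background), size=length)
    mask = rng.random(length) < cys_rate
    chars[mask] = "C"
    return ProteinRecord(id=protein_id, sequence="".join(chars))


@pytest.fixture
def small_proteome(rng):
    """A small mixed fixture proteome with truth, built once per test."""
    from serscan.synth_fixtures import ProteomeConfig, generate_proteome

    config = ProteomeConfig(
        n_ser=30, n_decoy_no_gpi=30, n_decoy_no_pattern=30, n_background=60
    )
    return generate_proteome(config, seed=11)
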