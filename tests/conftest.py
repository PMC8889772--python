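"""Shared helpers: seeded random lipidome samples for oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from coldomics.metrics import LipidomeSample
from coldomics.simulate import default_species_panel


def random_sample(rng: np.random.Generator, n_species: int = 50) -> LipidomeSample:
    """A random sample over a random subset of the default panel."""
    panel = default_species_panel()
    idx = rng.choice(len(panel), size=min(n_species, len(panel)), replace=False)
    conc = {panel[i]: float(rng.uniform(0.01, 100.0)) for i in idx}
    return LipidomeSample(
        sample_id="rand", genotype="G", treatment="T", replicate=1, concentrations=conc
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
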