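"""Shared fixtures: small synthetic populations and toy maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epirilqtl import synthetic_data as sd
from epirilqtl.io_core import EpigenotypeMap, MarkerMap, TraitVector
from epirilqtl import mapping


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimulationConfig:
    return sd.SimulationConfig(n_lines=200, seed=7)


@pytest.fixture(scope="session")
def epi(sim_cfg) -> EpigenotypeMap:
    return sd.simulate_epigenotypes(sim_cfg, seed=7)


@pytest.fixture(scope="session")
def scanpos(epi) -> mapping.ScanPositions:
    return mapping.genotype_probabilities(epi, step_cM=2.0)


@pytest.fixture
def toy_map() -> MarkerMap:
    """Two markers on one chromosome, 10 cM / 20 kb apart."""
    return MarkerMap(pd.DataFrame({
        "marker_id": ["A", "B"],
        "chrom": ["chr1", "chr1"],
        "pos_cM": [0.0, 10.0],
        "phys_start": [1000, 21000],
        "phys_end": [3000, 23000],
    }))


def planted_trait(epi: EpigenotypeMap, marker: str, var_explained: float,
                  seed: int, trait_id: str = "t") -> TraitVector:
    """Gaussian trait with a planted marker effect explaining a given
    fraction of total variance."""
    rng = np.random.default_rng(seed)
    g = epi.coded()[marker].to_numpy(float)
    g = np.where(np.isnan(g), np.nanmean(g), g)
    sd_g = g.std()
    beta = np.sqrt(var_explained / (1.0 - var_explained)) / sd_g
    y = beta * g + rng.normal(0.0, 1.0, len(g))
    return TraitVector(trait_id=trait_id, values=pd.Series(y, index=epi.calls.index))
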