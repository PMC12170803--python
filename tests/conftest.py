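import numpy as np
import pandas as pd
import pytest

from prp.resources import load_bundle
from prp.simulate import SimulationConfig, simulate_reference, simulate_resources
from prp.variants import COMPLEMENT, TranscriptModel

TOY_CDS = "ATGGCTTGGTAA"  # M A W *


@pytest.fixture(scope="session")
def toy_plus():
    """'+' strand toy transcript with CDS at chr1:100-111."""
    genome = {"chr1": "N" * 99 + TOY_CDS + "N" * 10}
    tx = TranscriptModel("g1", "g1.t1", "chr1", "+", ((100, 111),))
    return genome, tx


@pytest.fixture(scope="session")
def toy_minus():
    """'-' strand transcript whose CDS equals the '+' toy CDS."""
    rc = "".join(COMPLEMENT[b] for b in reversed(TOY_CDS))
    genome = {"chr1": "N" * 99 + rc + "N" * 10}
    tx = TranscriptModel("g1", "g1.t1", "chr1", "-", ((100, 111),))
    return genome, tx


@pytest.fixture(scope="session")
def sim_reference():
    return simulate_reference(SimulationConfig(seed=11, n_genes=4,
                                               cds_length_range=(60, 120)))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory, sim_reference):
    """A fully-populated resource bundle over the toy reference."""
    out = tmp_path_factory.mktemp("resources")
    cfg = simulate_resources(
        SimulationConfig(seed=11, n_genes=4, cds_length_range=(60, 120)),
        sim_reference,
        out,
    )
    return load_bundle(cfg), cfg


@pytest.fixture(scope="session")
def separable_table():
    """A tiny, perfectly separable 34-feature table."""
    from prp.features import FEATURE_NAMES

    rng = np.random.default_rng(0)
    n = 120
    labels = np.array([1, 0] * (n // 2))
    data = {name: rng.normal(size=n) for name in FEATURE_NAMES}
    data["gnomAD_AFv4"] = labels * 10.0 + rng.normal(scale=0.01, size=n)
    return pd.DataFrame(data, columns=list(FEATURE_NAMES)), labels
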