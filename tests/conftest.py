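import numpy as np
import pytest

from spikecontam import (
    AnalysisConfig,
    ErccMix,
    ErccTranscript,
    default_dilution_config,
    load_ercc_reference,
    simulate,
)


@pytest.fixture(scope="session")
def mix():
    return load_ercc_reference("bundled")


@pytest.fixture()
def tiny_mix():
    return ErccMix(
        (
            ErccTranscript("ERCC-00001", 1000, 1.0),
            ErccTranscript("ERCC-00002", 500, 2.0),
        ),
        spike_mass_pg=25.0,
    )


@pytest.fixture(scope="session")
def dilution():
    """Default dilution scenario, seed 1: (table, meta, truth)."""
    return simulate(default_dilution_config(seed=1))


@pytest.fixture()
def config():
    return AnalysisConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20190416)
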