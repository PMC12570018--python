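import pytest

from metamethyl.motif_model import Motif
from metamethyl.synthetic_data import (PlantedMotif, SimulationConfig,
                                       generate, simulate)


def small_config(seed: int = 7) -> SimulationConfig:
    """A scaled-down bundle for unit tests (the defaults are used in the
    end-to-end acceptance test)."""
    return SimulationConfig(
        seed=seed,
        n_contigs=1,
        contig_length_bp=30_000,
        planted_motifs=[PlantedMotif(Motif("GATC", 1, "6mA"), 0.8, 0.02)],
        genes=(20, 600),
        prophage=(8_000, 0.5),
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(small_config())


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    generate(small_config(), out)
    return out
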