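import pytest

from thermobin.io import Lineage
from thermobin.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the shipped scenario at the default seed."""
    return run_pipeline(RunConfig(seed=0))


@pytest.fixture()
def toy_taxonomy():
    """Small reference taxonomy: two families in one phylum, plus outgroups."""
    return {
        "s_g1a": Lineage.from_names("Bacteria", "P1", "C1", "O1", "F1", "G1", "G1_a"),
        "s_g1b": Lineage.from_names("Bacteria", "P1", "C1", "O1", "F1", "G1", "G1_b"),
        "s_g2": Lineage.from_names("Bacteria", "P1", "C1", "O1", "F1", "G2", "G2_a"),
        "s_f2": Lineage.from_names("Bacteria", "P1", "C1", "O1", "F2", "G3", "G3_a"),
        "s_p2": Lineage.from_names("Bacteria", "P2", "C9", "O9", "F9", "G9", "G9_a"),
        "s_arch": Lineage.from_names("Archaea", "PA", "CA", "OA", "FA", "GA", "GA_a"),
    }
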