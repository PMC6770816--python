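import warnings

import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from melscreen import activity_io
from melscreen.activity_io import (ActivityRecord, AssayProfile,
                                   CompoundProfile)
from melscreen.pipeline import run_pipeline, run_synthetic_pipeline
from melscreen.synthetic_chembl import SyntheticConfig, generate

warnings.filterwarnings("ignore", message="only .* eligible inactive")

#: reduced universe for fast structural tests
SMALL_CONFIG = dict(n_compounds=300, n_orphans=4)

#: the study-condition defaults: 2000 compounds, 30% active, noise 0.5
DEFAULT_SEED = 2025


@pytest.fixture(scope="session")
def small_universe():
    return generate(SyntheticConfig(seed=7, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_linked(small_universe):
    u = small_universe
    return activity_io.link_tables(u.records, u.compounds, u.assays)


@pytest.fixture(scope="session")
def default_universe():
    return generate(SyntheticConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_pipeline(default_universe):
    u = default_universe
    linked = activity_io.link_tables(u.records, u.compounds, u.assays)
    return run_pipeline(linked, seed=DEFAULT_SEED, universe=u)


@pytest.fixture
def toy_tables():
    """Three hand-written records with fully resolvable ids."""
    records = [
        ActivityRecord("r1", "c1", "a1", target_id="MTNR1A",
                       standard_type="IC50", standard_value=1000.0,
                       standard_units="nM"),
        ActivityRecord("r2", "c1", "a2", target_id="MTNR1B",
                       standard_type="Ki", standard_value=1.0,
                       standard_units="nM"),
        ActivityRecord("r3", "c2", "a1", target_id="MTNR1A",
                       standard_type="Inhibition", standard_value=55.0,
                       standard_units="%"),
    ]
    compounds = [
        CompoundProfile("c1", smiles="CC(=O)Nc1ccc(O)cc1",
                        pref_name="Paracetamol", max_phase=4),
        CompoundProfile("c2", smiles="O"),
    ]
    assays = [
        AssayProfile("a1", description="Binding at MTNR1A receptor",
                     assay_type="binding", target_class="GPCR",
                     organism="Homo sapiens"),
        AssayProfile("a2", description="Binding at MTNR1B receptor",
                     assay_type="binding", target_class="GPCR",
                     organism="Homo sapiens"),
    ]
    return records, compounds, assays
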