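import warnings

import numpy as np
import pytest

import mozzipk as m

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def reference():
    return m.reference_params()


@pytest.fixture(scope="session")
def table_structural(reference):
    """Reference individual curve: 0.28 ng absorbed, 5.5 pg/h, 18.5 h lag."""
    return m.StructuralParams(dose_ng=0.28, tlag_h=18.5,
                              kel_ng_per_h=0.0055)


@pytest.fixture(scope="session")
def small_design():
    """Paired two-batch design kept small for fast likelihood tests."""
    design = m.default_design()
    design.batches = design.batches[:2]
    design.n_per_timepoint = 4
    return design


@pytest.fixture(scope="session")
def small_study(small_design, reference):
    cfg = m.SimulationConfig(design=small_design, truth=reference, seed=42)
    return cfg, m.simulate_pk_study(cfg)


@pytest.fixture(scope="session")
def mono_design():
    """Single-arm reduced design (4 batches, ivermectin alone)."""
    design = m.default_design()
    for b in design.batches:
        b.arms = ("IVM",)
    design.n_per_timepoint = 4
    return design
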