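import numpy as np
import pytest

from grxkinetics import KineticParameters, build_ecoli_system, build_wildtype_core


@pytest.fixture
def grx1_params():
    """Yeast Grx1 assay constants and background (package defaults)."""
    return KineticParameters()


@pytest.fixture
def ecoli_params():
    """Default constants of the GR-coupled reciprocal-plot system."""
    return KineticParameters(k1=0.1, k2_wt=1e-5, grx_tot=1.0)


@pytest.fixture
def wt_core(grx1_params):
    """Wild-type core at assay-scale clamps (PSSG 70 uM, GSH 998 uM)."""
    return build_wildtype_core(grx1_params, 70.0, 998.0)


@pytest.fixture
def ecoli_irreversible(ecoli_params):
    return build_ecoli_system(ecoli_params, reversible=False)


@pytest.fixture
def ecoli_reversible(ecoli_params):
    return build_ecoli_system(ecoli_params, reversible=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
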