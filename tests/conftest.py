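import numpy as np
import pytest

from countgp.simulate import SimulationDesign, simulate_timecourse


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_timecourse():
    """12 genes, half dynamic, low dispersion: cheap shared fixture."""
    design = SimulationDesign(n_genes=12, dispersion_level="low",
                              expression_level="high", seed=7)
    return simulate_timecourse(design)
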