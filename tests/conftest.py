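import numpy as np
import pytest

STANDARD_DAYS = np.array([0.0, 1.0, 7.0, 14.0, 21.0, 28.0])


@pytest.fixture
def days():
    return STANDARD_DAYS.copy()


@pytest.fixture
def starved_well():
    """One simulated post-starvation well with known planted fractions."""
    from quiescreen.simulate import default_populations, simulate_well_events

    pops = default_populations(dead_frac=0.3, g0=0.7, g2=0.2, g1m=0.1,
                               doublet_frac=0.1)
    events, labels = simulate_well_events(pops, 20000, seed=42)
    return events, labels, pops
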