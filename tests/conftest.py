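import numpy as np
import pytest

import nephrosim as ns


@pytest.fixture(scope="session")
def ref_params():
    return ns.TumorParameters()


@pytest.fixture(scope="session")
def ref_layout(ref_params):
    return ns.StateLayout(ref_params)


def random_state(layout, seed, scale=1e6):
    rng = np.random.default_rng(seed)
    return ns.CellStateVector(layout, core=rng.random(layout.n) * scale)


@pytest.fixture(scope="session")
def scenario_results():
    """Full treated runs of all packaged scenarios (shared; ~2 s total)."""
    out = {}
    for name in ns.scenario_names():
        sc = ns.load_scenario(name)
        out[name] = (sc, ns.run_scenario(sc))
    return out


@pytest.fixture(scope="session")
def free_growth_fits():
    """Fitted free-growth rates for typical, T1 and T4 (500 h, well-mixed)."""
    fits = {}
    for name in ("typical", "T1", "T4"):
        sc = ns.load_scenario(name)
        result = ns.run_simulation(sc.params, horizon_h=500, mode="wellmixed")
        fits[name] = ns.fit_growth_rate(result)
    return fits
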