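import pytest

from cliquescreen import (FixtureSpec, ScreenConfig, benzene, make_library,
                          propane, toluene)


@pytest.fixture(scope="session")
def benzene_mol():
    return benzene()


@pytest.fixture(scope="session")
def toluene_mol():
    return toluene()


@pytest.fixture(scope="session")
def propane_mol():
    return propane()


@pytest.fixture()
def small_library():
    """12 varied compounds, 4-9 heavy atoms, mixed topologies."""
    lib = []
    for i, topo in enumerate(("chain", "tree", "ring", "ring+substituent")):
        spec = FixtureSpec(seed=50 + 10 * i, n_heavy=(4, 9), topology=topo)
        for m in make_library(spec, 3):
            lib.append(m)
    # renumber record indices to be file-order consistent
    from dataclasses import replace
    return [replace(m, record_index=i) for i, m in enumerate(lib)]


@pytest.fixture()
def config_2d():
    return ScreenConfig(dimension=2, threshold_2d=0, workers=1)
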