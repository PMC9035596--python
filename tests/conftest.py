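import pytest

import boolmac as bm


@pytest.fixture(scope="session")
def toys():
    return bm.toy_fixtures()


@pytest.fixture(scope="session")
def toggle(toys):
    return toys["toggle"]["network"]


@pytest.fixture(scope="session")
def macro_net():
    return bm.load_macrophage_network()


@pytest.fixture(scope="session")
def macro_rules():
    return bm.macrophage_label_rules()


@pytest.fixture(scope="session")
def macro_envs():
    return {e.name: e for e in bm.macrophage_environments()}


@pytest.fixture(scope="session")
def macro_env_census(macro_net, macro_rules, macro_envs):
    """Labeled attractor tables of the six named environments (computed once)."""
    out = {}
    for name, env in macro_envs.items():
        if env.free:
            continue
        aset = bm.attractors_by_environment(macro_net, env)
        out[name] = (aset, bm.label_set(aset, macro_rules, macro_net))
    return out


@pytest.fixture(scope="session")
def macro_full_census(macro_net, macro_rules):
    """Full 2^29 census decomposed over the 512 input combinations.

    The slowest fixture of the suite (about a minute); shared by every test
    that asserts on the global attractor landscape.
    """
    aset = bm.find_attractors_exhaustive(macro_net)
    labels = bm.label_set(aset, macro_rules, macro_net)
    return aset, labels
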