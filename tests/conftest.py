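from pathlib import Path

import pytest

from dynmod import ModuleSpace, build_dcm, generate_random_bn, load_fixture, parse_rules

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def or_gate_net():
    return load_fixture("or_gate")


@pytest.fixture(scope="session")
def grn_net():
    return load_fixture("example_grn")


@pytest.fixture(scope="session")
def grn_dcm(grn_net):
    return build_dcm(grn_net)


@pytest.fixture(scope="session")
def grn_space(grn_dcm):
    return ModuleSpace(grn_dcm)


@pytest.fixture(scope="session")
def spn_net():
    """Synthetic reconstruction of the single-cell segment-polarity network."""
    return parse_rules((DATA_DIR / "spn_single_cell_synthetic.txt").read_text())


@pytest.fixture(scope="session")
def spn_space(spn_net):
    return ModuleSpace(build_dcm(spn_net))


def random_networks(count, n_range=(5, 12), k_range=(1, 3), seed0=0):
    """Deterministic battery of random Boolean networks for property tests."""
    nets = []
    for i in range(count):
        n = n_range[0] + (i * 7) % (n_range[1] - n_range[0] + 1)
        k = min(n, k_range[0] + i % (k_range[1] - k_range[0] + 1))
        bias = (0.25, 0.5, 0.75)[i % 3]
        nets.append(generate_random_bn(n=n, k=k, bias=bias, seed=seed0 + i))
    return nets
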