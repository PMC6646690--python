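import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from lion import (NodeKind, SynthConfig, build_tripartite, generate_benchmark,
                  layer_from_pairs)


@pytest.fixture
def chain_net():
    """PPI chain g1-g2-g3-g4, disease D1 -> {g1}, lncRNAs on g2 and g4."""
    return build_tripartite(
        layer_from_pairs(NodeKind.LNCRNA, NodeKind.PROTEIN,
                         [("L1", "G2"), ("L2", "G4")]),
        layer_from_pairs(NodeKind.PROTEIN, NodeKind.PROTEIN,
                         [("G1", "G2"), ("G2", "G3"), ("G3", "G4")]),
        layer_from_pairs(NodeKind.DISEASE, NodeKind.PROTEIN, [("D1", "G1")]),
    )


def triangle_module(prefix, lnc_ids):
    """PPI triangle on three proteins with the given lncRNAs attached to the
    first protein; yields (lnc_pairs, ppi_pairs)."""
    a, b, c = (f"{prefix}{i}" for i in (1, 2, 3))
    lnc_pairs = [(l, a) for l in lnc_ids]
    ppi_pairs = [(a, b), (b, c), (a, c)]
    return lnc_pairs, ppi_pairs


@pytest.fixture
def two_disease_net():
    """Two disjoint eligible (triangle) disease modules with 3 and 5 lncRNAs."""
    lnc_a, ppi_a = triangle_module("A", [f"LA{i}" for i in range(1, 4)])
    lnc_b, ppi_b = triangle_module("B", [f"LB{i}" for i in range(1, 6)])
    return build_tripartite(
        layer_from_pairs(NodeKind.LNCRNA, NodeKind.PROTEIN, lnc_a + lnc_b),
        layer_from_pairs(NodeKind.PROTEIN, NodeKind.PROTEIN, ppi_a + ppi_b),
        layer_from_pairs(NodeKind.DISEASE, NodeKind.PROTEIN,
                         [("D1", "A1"), ("D2", "B1")]),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """One deterministic synthetic benchmark shared across tests."""
    return generate_benchmark(SynthConfig(rng_seed=12345))
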