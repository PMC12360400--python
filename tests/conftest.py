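import numpy as np
import pytest

from retinox.generate import GeneratorConfig, generate_arteriolar_tree
from retinox.hemodynamics import FlowSolverConfig, iterate_flow
from retinox.network import Node, VascularNetwork, VesselSegment


@pytest.fixture
def small_tree():
    """Seeded 8-terminal arteriolar tree (unsolved)."""
    return generate_arteriolar_tree(GeneratorConfig(seed=1, n_terminals=8))


@pytest.fixture
def solved_tree():
    """Seeded 8-terminal tree with converged hemodynamics."""
    net = generate_arteriolar_tree(GeneratorConfig(seed=1, n_terminals=8))
    iterate_flow(net, FlowSolverConfig())
    return net


@pytest.fixture
def single_vessel():
    """One straight vessel with imposed flow, for oxygen-field tests."""
    length = 600.0
    return VascularNetwork(
        nodes=[
            Node(0, np.array([-length / 2, 0.0, 0.0])),
            Node(1, np.array([length / 2, 0.0, 0.0])),
        ],
        segments=[
            VesselSegment(id=0, from_node=0, to_node=1, diameter=40.0,
                          length=length, order=3, is_terminal=True,
                          flow=500.0, hematocrit=0.4, viscosity=2.5)
        ],
        inlet_node=0,
    )


def series_network(g_ratio=1.0, n=2):
    """Chain of n equal-diameter segments; conductance tweaked via length."""
    nodes = [Node(i, np.array([400.0 * i, 0.0, 0.0])) for i in range(n + 1)]
    segs = []
    for i in range(n):
        segs.append(VesselSegment(
            id=i, from_node=i, to_node=i + 1, diameter=40.0,
            length=400.0 * (g_ratio if i == 1 else 1.0),
            order=min(i + 1, 5), is_terminal=(i == n - 1),
            viscosity=2.0, hematocrit=0.4,
        ))
    return VascularNetwork(nodes=nodes, segments=segs, inlet_node=0)
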