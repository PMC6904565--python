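import numpy as np
import pytest

from xylemflow.network import (BoundaryConditions, LumenEdge, NetworkNode,
                               VesselNetwork)
from xylemflow.synthetic import SyntheticSpec, generate_network, simulate


def parallel_vessel_network(radii_um, length_um=3300.0, spacing_um=200.0):
    """n straight solitary vessels spanning bottom to top, shared nothing."""
    nodes, lumens = [], []
    for v, r in enumerate(radii_um):
        x = v * spacing_um
        nodes.append(NetworkNode(2 * v, x, 0.0, 0.0, "bottom"))
        nodes.append(NetworkNode(2 * v + 1, x, 0.0, length_um, "top"))
        lumens.append(LumenEdge(v, 2 * v, 2 * v + 1, r))
    return VesselNetwork(nodes=nodes, lumens=lumens, connections=[],
                         sample_length_um=length_um, xylem_area_mm2=1.0)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_vessels=80, noise_sd_ug_s=0.0)


@pytest.fixture(scope="session")
def small_network(small_spec):
    net, masks = generate_network(small_spec, seed=11)
    return net, masks


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return simulate(small_spec, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def dense_solve(network: VesselNetwork, bc: BoundaryConditions):
    """Independent dense direct solve of the node-balance system."""
    nodes = network.nodes
    idx = {n.id: i for i, n in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    for e in network.all_edges():
        g = 1.0 / network.edge_resistance(e)
        a, b = idx[e.node_a], idx[e.node_b]
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g
    group_of = network.vessel_group_map()
    vessel_of_node = {}
    for l in network.lumens:
        if l.vessel_id >= 0:
            vessel_of_node.setdefault(l.node_a, l.vessel_id)
            vessel_of_node.setdefault(l.node_b, l.vessel_id)
    fixed = {}
    for node in nodes:
        if node.tag == "bottom":
            fixed[idx[node.id]] = bc.bottom
        elif node.tag == "top":
            fixed[idx[node.id]] = bc.top_for_group(
                group_of[vessel_of_node[node.id]])
    free = [i for i in range(n) if i not in fixed]
    p = np.zeros(n)
    for i, v in fixed.items():
        p[i] = v
    rhs = -lap[np.ix_(free, list(fixed))] @ np.array(list(fixed.values()))
    p[free] = np.linalg.solve(lap[np.ix_(free, free)], rhs)
    return {node.id: p[idx[node.id]] for node in nodes}
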