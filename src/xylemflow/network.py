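"""Vessel/pit resistance networks and steady pressure-driven flow.

A xylem segment is represented as a graph whose nodes are points inside
vessel lumina (plus the sample's top and bottom faces) and whose edges are
either lumen intervals (Hagen–Poiseuille resistance) or inter-vessel
connections (pit fields, or vessel relays decomposed into pit–lumen–pit).
Steady flow under imposed boundary pressures is the solution of the Kirchhoff
node-balance system on this resistance graph.

Sign convention: positive flow is upward (+z); the axial gradient of a vessel
is (bottom pressure − top pressure)/sample length, so a bottom-to-top drop
drives positive flow and a positive gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units

logger = logging.getLogger(__name__)

TAG_TOP = "top"
TAG_BOTTOM = "bottom"
TAG_INTERIOR = "interior"

CONNECTION_KINDS = ("pit_field", "relay_pit", "relay_lumen")


class NetworkError(ValueError):
    """Invalid network structure or arguments."""


class SingularNetworkError(NetworkError):
    """A connected component has no pressure-assigned node."""


def hp_lumen_resistance(radius_um: float, length_um: float,
                        eta_mpa_s: float = units.ETA_WATER_MPA_S,
                        rho_kg_m3: float = units.RHO_WATER_KG_M3) -> float:
    """Hagen–Poiseuille resistance of a cylindrical lumen, kPa/(µg s⁻¹).

    The volumetric HP resistance 8ηL/(πr⁴) is divided by the fluid density to
    convert to mass-flow units, then converted from SI to kPa/(µg s⁻¹).
    """
    if radius_um <= 0 or length_um <= 0 or eta_mpa_s <= 0 or rho_kg_m3 <= 0:
        raise NetworkError(
            f"hp_lumen_resistance requires positive arguments, got "
            f"r={radius_um}, L={length_um}, eta={eta_mpa_s}, rho={rho_kg_m3}")
    return 8.0e12 * eta_mpa_s * length_um / (np.pi * radius_um ** 4 * rho_kg_m3)


def pit_connection_resistance(area_mm2: float,
                              r_pit: float = units.R_PIT_GRAPEVINE,
                              rho_kg_m3: float = units.RHO_WATER_KG_M3) -> float:
    """Pit-field resistance from membrane area, kPa/(µg s⁻¹).

    resistance = r_pit / area, with r_pit the grapevine literature constant
    (168, printed as MPa m⁻¹ s⁻¹; the units are taken such that dividing by
    the membrane area in m² yields a volumetric resistance in MPa s m⁻³ —
    see docs/methods.md for the unit discussion).  In the package's working
    units the conversion collapses to r_pit / (area_mm2 · rho).
    """
    if area_mm2 <= 0:
        raise NetworkError(f"pit area must be positive, got {area_mm2}")
    return r_pit / (area_mm2 * rho_kg_m3)


@dataclass(frozen=True)
class NetworkNode:
    id: int
    x: float
    y: float
    z: float
    tag: str = TAG_INTERIOR

    def __post_init__(self):
        if self.tag not in (TAG_TOP, TAG_BOTTOM, TAG_INTERIOR):
            raise NetworkError(f"unknown node tag {self.tag!r}")


@dataclass(frozen=True)
class LumenEdge:
    """An axial interval of a vessel lumen.

    ``vessel_id`` < 0 marks a relay conduit (the short transverse lumen of a
    vessel relay); those are excluded from per-vessel accounting.
    """
    vessel_id: int
    node_a: int
    node_b: int
    radius_um: float

    def __post_init__(self):
        if self.radius_um <= 0:
            raise NetworkError(
                f"lumen radius must be positive (vessel {self.vessel_id}, "
                f"nodes {self.node_a}-{self.node_b}): {self.radius_um}")


@dataclass(frozen=True)
class ConnectionEdge:
    """Inter-vessel connection: a pit field, or one leg of a vessel relay."""
    kind: str
    node_a: int
    node_b: int
    vessel_a: int
    vessel_b: int
    area_mm2: float | None = None
    diameter_um: float | None = None

    def __post_init__(self):
        if self.kind not in CONNECTION_KINDS:
            raise NetworkError(f"unknown connection kind {self.kind!r}")
        if self.kind in ("pit_field", "relay_pit"):
            if self.area_mm2 is None or self.area_mm2 <= 0:
                raise NetworkError(
                    f"{self.kind} between vessels {self.vessel_a},{self.vessel_b} "
                    f"requires a positive pit area, got {self.area_mm2}")
        elif self.diameter_um is None or self.diameter_um <= 0:
            raise NetworkError(
                f"relay_lumen between vessels {self.vessel_a},{self.vessel_b} "
                f"requires a positive diameter, got {self.diameter_um}")


@dataclass
class BoundaryConditions:
    """Pressures imposed on the sample faces, kPa.

    ``top`` is a single value applied to every top node, or a mapping from
    vessel-group index to the pressure applied to that group's top nodes.
    ``bottom`` is the uniform reference pressure (default 0).
    """
    top: float | Mapping[int, float]
    bottom: float = 0.0

    def top_for_group(self, group: int) -> float:
        if isinstance(self.top, Mapping):
            try:
                return float(self.top[group])
            except KeyError:
                raise NetworkError(f"no top pressure supplied for vessel group {group}")
        return float(self.top)


@dataclass
class VesselNetwork:
    nodes: list[NetworkNode]
    lumens: list[LumenEdge]
    connections: list[ConnectionEdge]
    sample_length_um: float
    xylem_area_mm2: float
    eta_mpa_s: float = units.ETA_WATER_MPA_S
    rho_kg_m3: float = units.RHO_WATER_KG_M3
    _node_index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise NetworkError("node ids are not unique")
        self._node_index = {n.id: i for i, n in enumerate(self.nodes)}
        for e in list(self.lumens) + list(self.connections):
            if e.node_a == e.node_b:
                raise NetworkError(f"self-loop at node {e.node_a}")
            for nid in (e.node_a, e.node_b):
                if nid not in self._node_index:
                    raise NetworkError(f"edge references unknown node {nid}")

    # -- basic accessors -------------------------------------------------
    def node(self, nid: int) -> NetworkNode:
        return self.nodes[self._node_index[nid]]

    @property
    def vessel_ids(self) -> list[int]:
        return sorted({l.vessel_id for l in self.lumens if l.vessel_id >= 0})

    def vessel_lumens(self, vessel_id: int) -> list[LumenEdge]:
        """Lumen edges of one vessel ordered bottom to top."""
        edges = [l for l in self.lumens if l.vessel_id == vessel_id]
        if not edges:
            raise NetworkError(f"unknown vessel id {vessel_id}")
        return sorted(edges, key=lambda l: min(self.node(l.node_a).z,
                                               self.node(l.node_b).z))

    def lumen_length_um(self, edge: LumenEdge) -> float:
        a, b = self.node(edge.node_a), self.node(edge.node_b)
        return float(np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2))

    def connection_length_um(self, edge: ConnectionEdge) -> float:
        a, b = self.node(edge.node_a), self.node(edge.node_b)
        return float(np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2))

    def edge_resistance(self, edge: LumenEdge | ConnectionEdge) -> float:
        """Hydraulic resistance of an edge in kPa/(µg s⁻¹)."""
        if isinstance(edge, LumenEdge):
            return hp_lumen_resistance(edge.radius_um, self.lumen_length_um(edge),
                                       self.eta_mpa_s, self.rho_kg_m3)
        if edge.kind in ("pit_field", "relay_pit"):
            return pit_connection_resistance(edge.area_mm2, rho_kg_m3=self.rho_kg_m3)
        # relay_lumen: HP resistance of the short transverse conduit
        length = max(self.connection_length_um(edge), 1.0)
        return hp_lumen_resistance(edge.diameter_um / 2.0, length,
                                   self.eta_mpa_s, self.rho_kg_m3)

    def all_edges(self) -> list[LumenEdge | ConnectionEdge]:
        return list(self.lumens) + list(self.connections)

    # -- structure -------------------------------------------------------
    def vessel_group_map(self) -> dict[int, int]:
        """Partition of vessels into connected components ('vessel groups').

        Groups are numbered 0..n-1 in order of their smallest member vessel
        id, so the partition is invariant under edge reordering.  Solitary
        vessels form singleton groups.
        """
        g = nx.Graph()
        g.add_nodes_from(self.vessel_ids)
        for c in self.connections:
            if c.vessel_a >= 0 and c.vessel_b >= 0 and c.vessel_a != c.vessel_b:
                g.add_edge(c.vessel_a, c.vessel_b)
        comps = sorted((sorted(c) for c in nx.connected_components(g)),
                       key=lambda c: c[0])
        return {v: gi for gi, comp in enumerate(comps) for v in comp}

    def n_groups(self) -> int:
        gm = self.vessel_group_map()
        return max(gm.values()) + 1 if gm else 0

    def top_node_of_vessel(self, vessel_id: int) -> int:
        chain = self.vessel_lumens(vessel_id)
        top = chain[-1]
        a, b = self.node(top.node_a), self.node(top.node_b)
        return a.id if a.z >= b.z else b.id

    def bottom_node_of_vessel(self, vessel_id: int) -> int:
        chain = self.vessel_lumens(vessel_id)
        bot = chain[0]
        a, b = self.node(bot.node_a), self.node(bot.node_b)
        return a.id if a.z <= b.z else b.id


def vessel_groups(network: VesselNetwork) -> dict[int, int]:
    """Mapping vessel id → group index (see VesselNetwork.vessel_group_map)."""
    return network.vessel_group_map()


# ---------------------------------------------------------------------------
# Generic resistor-network solve
# ---------------------------------------------------------------------------

def solve_resistor_network(n_nodes: int,
                           edges: Sequence[tuple[int, int, float]],
                           fixed: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    """Solve the Kirchhoff node-balance system of a resistor network.

    Parameters
    ----------
    n_nodes : number of nodes (indexed 0..n-1).
    edges : (a, b, R) triples with R > 0.
    fixed : node index → imposed potential.

    Returns
    -------
    potentials : array of node potentials.
    flows : signed flow per edge, positive from ``a`` to ``b``.

    Raises
    ------
    SingularNetworkError
        if some connected component contains no fixed node (its potentials
        would be undetermined); the error names the offending nodes.
    """
    if not fixed:
        raise SingularNetworkError("no boundary potentials assigned")
    a_idx = np.fromiter((e[0] for e in edges), dtype=np.int64, count=len(edges))
    b_idx = np.fromiter((e[1] for e in edges), dtype=np.int64, count=len(edges))
    res = np.fromiter((e[2] for e in edges), dtype=float, count=len(edges))
    if np.any(res <= 0):
        raise NetworkError("all edge resistances must be strictly positive")
    cond = 1.0 / res

    # components untouched by any fixed node are rejected, not zeroed
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(zip(a_idx.tolist(), b_idx.tolist()))
    fixed_set = set(fixed)
    for comp in nx.connected_components(g):
        if not comp & fixed_set:
            raise SingularNetworkError(
                f"component with no assigned boundary pressure: nodes {sorted(comp)[:10]}"
                + ("..." if len(comp) > 10 else ""))

    lap = sp.coo_matrix(
        (np.concatenate([cond, cond, -cond, -cond]),
         (np.concatenate([a_idx, b_idx, a_idx, b_idx]),
          np.concatenate([a_idx, b_idx, b_idx, a_idx]))),
        shape=(n_nodes, n_nodes)).tocsr()

    potentials = np.zeros(n_nodes)
    fixed_nodes = np.array(sorted(fixed_set), dtype=np.int64)
    potentials[fixed_nodes] = [fixed[i] for i in fixed_nodes]
    free = np.setdiff1d(np.arange(n_nodes), fixed_nodes, assume_unique=False)
    if free.size:
        a_ff = lap[free][:, free]
        rhs = -lap[free][:, fixed_nodes] @ potentials[fixed_nodes]
        potentials[free] = spla.spsolve(a_ff.tocsc(), rhs)
    flows = (potentials[a_idx] - potentials[b_idx]) * cond
    return potentials, flows


# ---------------------------------------------------------------------------
# FlowSolution
# ---------------------------------------------------------------------------

@dataclass
class FlowSolution:
    """Steady flow on a vessel network under given boundary pressures.

    ``edge_flows`` are signed positive from node_a to node_b of each edge in
    ``network.all_edges()`` order; per-vessel flows and gradients use the
    upward-positive convention.
    """
    network: VesselNetwork
    bc: BoundaryConditions
    node_pressures: dict[int, float]
    edge_flows: np.ndarray
    vessel_top_flow: dict[int, float]
    vessel_bottom_flow: dict[int, float]
    vessel_gradient_mpa_m: dict[int, float]

    @property
    def total_top_flow(self) -> float:
        return float(sum(self.vessel_top_flow.values()))

    @property
    def total_bottom_flow(self) -> float:
        return float(sum(self.vessel_bottom_flow.values()))

    def conservation_residuals(self) -> dict[int, float]:
        """Net signed inflow at every interior (non-fixed-pressure) node."""
        net: dict[int, float] = {}
        for e, q in zip(self.network.all_edges(), self.edge_flows):
            net[e.node_a] = net.get(e.node_a, 0.0) - q
            net[e.node_b] = net.get(e.node_b, 0.0) + q
        out = {}
        for n in self.network.nodes:
            if n.tag == TAG_INTERIOR:
                out[n.id] = net.get(n.id, 0.0)
        return out


def solve_flow(network: VesselNetwork, bc: BoundaryConditions) -> FlowSolution:
    """Solve steady flow for the given boundary conditions.

    Top pressures are broadcast per vessel group; every vessel's top node in
    group g receives ``bc.top_for_group(g)``.  Bottom nodes receive the
    uniform reference pressure.
    """
    group_of = network.vessel_group_map()
    nid_to_ix = {n.id: i for i, n in enumerate(network.nodes)}
    # a top/bottom node may be shared by several vessels; vessel group is
    # consistent across them because shared nodes imply a connection
    vessel_of_node: dict[int, int] = {}
    for l in network.lumens:
        if l.vessel_id >= 0:
            vessel_of_node.setdefault(l.node_a, l.vessel_id)
            vessel_of_node.setdefault(l.node_b, l.vessel_id)

    fixed: dict[int, float] = {}
    for n in network.nodes:
        if n.tag == TAG_BOTTOM:
            fixed[nid_to_ix[n.id]] = float(bc.bottom)
        elif n.tag == TAG_TOP:
            v = vessel_of_node.get(n.id)
            if v is None:
                raise NetworkError(f"top node {n.id} belongs to no vessel")
            fixed[nid_to_ix[n.id]] = bc.top_for_group(group_of[v])
        if not np.isfinite(fixed.get(nid_to_ix[n.id], 0.0)):
            raise NetworkError(f"non-finite boundary pressure at node {n.id}")

    edges = [(nid_to_ix[e.node_a], nid_to_ix[e.node_b], network.edge_resistance(e))
             for e in network.all_edges()]
    potentials, flows = solve_resistor_network(len(network.nodes), edges, fixed)
    pressures = {n.id: float(potentials[i]) for i, n in enumerate(network.nodes)}

    top_flow, bottom_flow, gradient = {}, {}, {}
    # parallel edges can share a node pair, so key lumen flows by vessel too
    edge_flow_of = {}
    for e, q in zip(network.all_edges(), flows):
        if isinstance(e, LumenEdge):
            edge_flow_of[(e.vessel_id, e.node_a, e.node_b)] = q
    for v in network.vessel_ids:
        chain = network.vessel_lumens(v)
        for which, dest in (("top", top_flow), ("bottom", bottom_flow)):
            edge = chain[-1] if which == "top" else chain[0]
            q = edge_flow_of[(v, edge.node_a, edge.node_b)]
            za = network.node(edge.node_a).z
            zb = network.node(edge.node_b).z
            dest[v] = float(q if zb >= za else -q)  # upward positive
        p_bot = pressures[network.bottom_node_of_vessel(v)]
        p_top = pressures[network.top_node_of_vessel(v)]
        gradient[v] = units.pressure_gradient_mpa_m(p_bot - p_top,
                                                    network.sample_length_um)
    return FlowSolution(network, bc, pressures, flows,
                        top_flow, bottom_flow, gradient)


def vessel_axial_flow(solution: FlowSolution, vessel_id: int,
                      at: str = "top") -> float:
    """Signed flow of a vessel's boundary-adjacent lumen edge, µg s⁻¹."""
    if at not in ("top", "bottom"):
        raise NetworkError(f"'at' must be 'top' or 'bottom', got {at!r}")
    table = solution.vessel_top_flow if at == "top" else solution.vessel_bottom_flow
    if vessel_id not in table:
        raise NetworkError(f"unknown vessel id {vessel_id}")
    return table[vessel_id]


def specific_conductivity(total_flow_ug_s: float, gradient_mpa_m: float,
                          area_mm2: float) -> float:
    """Specific conductivity, kg m⁻¹ MPa⁻¹ s⁻¹.

    Total mass flow divided by the flow-weighted mean axial gradient and the
    domain cross-sectional area.
    """
    if area_mm2 <= 0:
        raise NetworkError(f"area must be positive, got {area_mm2}")
    if gradient_mpa_m <= 0:
        raise NetworkError(
            f"specific conductivity undefined for non-positive gradient "
            f"{gradient_mpa_m}")
    return units.specific_conductivity_si(total_flow_ug_s, gradient_mpa_m, area_mm2)
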