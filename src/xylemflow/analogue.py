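"""Ohm's-law analogue networks of heterogeneously connected xylem.

A small five-vessel resistor network (two lumen elements of 0.25 normalized
units per vessel, wall resistors of 1, end-node pressures 1 upstream and 0
downstream) illustrates how heterogeneous wiring redirects flow between
vessels of different widths.  Three panel variants are provided:

* ``a`` — the base network;
* ``b`` — lumen resistances of the bottom-right vessel doubled;
* ``c`` — additionally, lumen resistances of the central vessel halved.

The ``conductance_ratio`` operation compares the network's observed bulk
conductance (total flow / pressure difference) with the theoretical
conductance extrapolated from the lumina visible in the segment from halfway
to three-quarters along the network (the downstream half-lumina of the
central vessel and the upstream half-lumina of the two right-hand vessels):
their conductances are summed and divided by four to scale the quarter-length
segment to the whole network.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from . import units
from .network import (BoundaryConditions, LumenEdge, NetworkNode,
                      VesselNetwork, solve_resistor_network)

PANELS = ("a", "b", "c")

UPSTREAM_NODE = "U"
DOWNSTREAM_NODE = "D"

#: vessels whose lumina are modified in each panel: (vessel, factor)
PANEL_MODIFICATIONS = {
    "a": (),
    "b": (("bottom_right", 2.0),),
    "c": (("bottom_right", 2.0), ("central", 0.5)),
}

#: half-lumina lying in the half-to-three-quarters segment of the network
SEGMENT_ELEMENTS = (("central", "downstream"),
                    ("top_right", "upstream"),
                    ("bottom_right", "upstream"))


@dataclass(frozen=True)
class AnalogueEdge:
    kind: str          # 'lumen' or 'wall'
    vessel: str | None
    element: str | None
    node_a: str
    node_b: str
    resistance: float


@dataclass
class AnalogueNetwork:
    panel: str
    edges: list[AnalogueEdge]
    fixed_pressures: dict[str, float] = field(
        default_factory=lambda: {UPSTREAM_NODE: 1.0, DOWNSTREAM_NODE: 0.0})

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.node_a)
            seen.setdefault(e.node_b)
        return list(seen)

    @property
    def vessels(self) -> list[str]:
        out: dict[str, None] = {}
        for e in self.edges:
            if e.kind == "lumen":
                out.setdefault(e.vessel)
        return list(out)

    def lumen_resistance(self, vessel: str, element: str) -> float:
        for e in self.edges:
            if e.kind == "lumen" and e.vessel == vessel and e.element == element:
                return e.resistance
        raise KeyError(f"no lumen element {vessel}/{element}")


def _load_base_edges() -> list[AnalogueEdge]:
    text = (importlib.resources.files("xylemflow") / "data" / "fig8_edges.tsv"
            ).read_text()
    edges = []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        kind, vessel, element, a, b, r = line.split("\t")
        edges.append(AnalogueEdge(
            kind=kind,
            vessel=None if vessel == "-" else vessel,
            element=None if element == "-" else element,
            node_a=a, node_b=b, resistance=float(r)))
    return edges


def build_fig8_network(panel: str) -> AnalogueNetwork:
    """Build the analogue network for panel 'a', 'b' or 'c'."""
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; expected one of {PANELS}")
    edges = []
    mods = dict(PANEL_MODIFICATIONS[panel])
    for e in _load_base_edges():
        r = e.resistance
        if e.kind == "lumen" and e.vessel in mods:
            r *= mods[e.vessel]
        edges.append(AnalogueEdge(e.kind, e.vessel, e.element,
                                  e.node_a, e.node_b, r))
    return AnalogueNetwork(panel=panel, edges=edges)


@dataclass
class AnalogueSolution:
    network: AnalogueNetwork
    potentials: dict[str, float]
    edge_flows: list[float]

    @property
    def total_flow(self) -> float:
        total = 0.0
        for e, q in zip(self.network.edges, self.edge_flows):
            if e.node_a == UPSTREAM_NODE:
                total += q
            elif e.node_b == UPSTREAM_NODE:
                total -= q
        return total

    def element_flow(self, vessel: str, element: str) -> float:
        for e, q in zip(self.network.edges, self.edge_flows):
            if e.kind == "lumen" and e.vessel == vessel and e.element == element:
                return q
        raise KeyError(f"no lumen element {vessel}/{element}")

    def vessel_flow(self, vessel: str) -> float:
        """Flow through a vessel; for vessels with a mid-vessel injection the
        downstream element is reported."""
        return self.element_flow(vessel, "downstream")


def analogue_flows(network: AnalogueNetwork) -> AnalogueSolution:
    """Solve the analogue network with its fixed end-node pressures."""
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [(idx[e.node_a], idx[e.node_b], e.resistance) for e in network.edges]
    fixed = {idx[n]: p for n, p in network.fixed_pressures.items()}
    potentials, flows = solve_resistor_network(len(nodes), edges, fixed)
    return AnalogueSolution(network=network,
                            potentials={n: float(potentials[idx[n]]) for n in nodes},
                            edge_flows=list(flows))


def conductance_ratio(network: AnalogueNetwork) -> float:
    """Observed : theoretical conductance of an analogue network.

    theoretical = (Σ conductances of the half-to-three-quarters segment's
    lumina) / 4; observed = total flow / total pressure difference.
    """
    try:
        seg = [1.0 / network.lumen_resistance(v, e) for v, e in SEGMENT_ELEMENTS]
    except KeyError as err:
        raise ValueError(f"segment not identifiable in this network: {err}")
    theoretical = sum(seg) / 4.0
    sol = analogue_flows(network)
    dp = (network.fixed_pressures[UPSTREAM_NODE]
          - network.fixed_pressures[DOWNSTREAM_NODE])
    observed = sol.total_flow / dp
    return observed / theoretical


# ---------------------------------------------------------------------------
# Conversion to a physical VesselNetwork (for I/O and solver cross-checks)
# ---------------------------------------------------------------------------

def to_vessel_network(network: AnalogueNetwork,
                      sample_length_um: float = 3300.0) -> tuple[VesselNetwork,
                                                                 BoundaryConditions]:
    """Express the analogue as a physical vessel network.

    Lumen radii are chosen so each element's Hagen–Poiseuille resistance in
    kPa/(µg s⁻¹) equals its normalized resistance, and wall resistors become
    pit fields whose area gives resistance 1; with boundary pressures of
    1 kPa (bottom) and 0 (top), flows in µg s⁻¹ equal normalized units.
    """
    n_elem = 2
    elem_len = sample_length_um / (n_elem + 2)  # vessels span half the sample
    zs = {"U": 0.0, "TLm": elem_len, "TL1": 2 * elem_len,
          "BLm": elem_len, "BL1": 2 * elem_len,
          "C0": elem_len, "Cm": 2 * elem_len, "C1": 3 * elem_len,
          "TR0": 2 * elem_len, "TRm": 3 * elem_len,
          "BR0": 2 * elem_len, "BRm": 3 * elem_len,
          "D": sample_length_um}
    ys = {"U": 0.0, "D": 0.0,
          "TLm": 400.0, "TL1": 400.0, "TR0": 400.0, "TRm": 400.0,
          "BLm": -400.0, "BL1": -400.0, "BR0": -400.0, "BRm": -400.0,
          "C0": 0.0, "Cm": 0.0, "C1": 0.0}
    vessel_ids = {v: i for i, v in enumerate(network.vessels)}
    name_to_id = {n: i for i, n in enumerate(network.nodes)}
    nodes = []
    for n in network.nodes:
        tag = "bottom" if n == "U" else ("top" if n == "D" else "interior")
        nodes.append(NetworkNode(id=name_to_id[n], x=0.0, y=ys[n], z=zs[n],
                                 tag=tag))
    lumens, connections = [], []
    from .network import ConnectionEdge
    vessel_of_node: dict[str, int] = {}
    for e in network.edges:
        if e.kind != "lumen":
            continue
        vid = vessel_ids[e.vessel]
        vessel_of_node.setdefault(e.node_a, vid)
        vessel_of_node.setdefault(e.node_b, vid)
    for e in network.edges:
        a, b = name_to_id[e.node_a], name_to_id[e.node_b]
        if e.kind == "lumen":
            # some lumens run diagonally to the shared end nodes; resistance
            # is set from the actual edge length
            length = float(np.hypot(zs[e.node_b] - zs[e.node_a],
                                    ys[e.node_b] - ys[e.node_a]))
            # r such that HP resistance equals the normalized value
            r4 = (8.0e12 * units.ETA_WATER_MPA_S * length
                  / (np.pi * units.RHO_WATER_KG_M3 * e.resistance))
            lumens.append(LumenEdge(vessel_ids[e.vessel], a, b, r4 ** 0.25))
        else:
            area = units.R_PIT_GRAPEVINE / (e.resistance * units.RHO_WATER_KG_M3)
            connections.append(ConnectionEdge(
                kind="pit_field", node_a=a, node_b=b,
                vessel_a=vessel_of_node.get(e.node_a, -1),
                vessel_b=vessel_of_node.get(e.node_b, -1),
                area_mm2=area))
    net = VesselNetwork(nodes=nodes, lumens=lumens, connections=connections,
                        sample_length_um=sample_length_um, xylem_area_mm2=1.0)
    bc = BoundaryConditions(top=0.0, bottom=1.0)
    return net, bc
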