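"""Synthetic vessel networks and flow observations with known ground truth.

The generator emulates the census statistics of a first-year grapevine stem
internode: ~500 vessels in an annular xylem cross-section, lognormal
diameters that differ between dorsal/ventral and lateral sectors
(44 ± 34 µm vs 30 ± 20 µm), inter-vessel pit-field connections with
lognormal membrane areas (0.015 ± 0.012 mm²), a fraction of vessel relays
(narrow transverse conduits bridged by pit fields at both ends), and known
top boundary pressures drawn per vessel group from the observed range
(drops of 0 to 0.78 kPa).  Forward-simulated flow maps (optionally with
per-pixel Gaussian noise and a rigid registration jitter) provide ground
truth for recovery experiments on the inverse fit.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowmap import (FlowMap, MASK_DORSAL_VENTRAL, MASK_INNER, MASK_LATERAL,
                      MASK_OUTER, PixelGrid, downsample_to_pixels)
from .model import XylemFlowModel
from .network import (BoundaryConditions, ConnectionEdge, LumenEdge,
                      NetworkNode, VesselNetwork, solve_flow)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic stem. Defaults emulate the study system."""
    n_vessels: int = 500
    stem_radius_um: float = 1820.0          # ~10.4 mm² xylem annulus
    pith_radius_um: float = 500.0
    inner_boundary_um: float = 1550.0       # inner/outer radial split
    dv_wedge_deg: float = 99.0              # dorsal & ventral wedge half-width ×2
    diameter_dv_um: tuple[float, float] = (44.0, 34.0)       # mean, SD
    diameter_lateral_um: tuple[float, float] = (30.0, 20.0)  # mean, SD
    connection_p0: float = 0.9
    connection_lambda_um: float = 40.0      # decay of P(connect) with lumen gap
    connection_extra_per_pair: float = 1.3  # Poisson mean of repeat pit fields
    pit_area_mm2: tuple[float, float] = (0.015, 0.012)
    relay_fraction: float = 0.17
    relay_diameter_um: tuple[float, float] = (10.0, 11.0)
    relay_pit_area_mm2: tuple[float, float] = (0.004, 0.012)
    sample_length_um: float = 3300.0
    pixel_size_um: float = 78.0
    bc_mode: str = "per_group"              # 'uniform' | 'per_group'
    uniform_drop_kpa: float = 0.055
    drop_range_kpa: tuple[float, float] = (0.0, 0.78)
    noise_sd_ug_s: float = 0.05
    jitter_um: tuple[float, float] = (0.0, 0.0)
    min_wall_um: float = 2.0                # minimum gap between lumina

    def lognormal_params(self, mean: float, sd: float) -> tuple[float, float]:
        """Moment-matched (mu, sigma) of a lognormal with given mean and SD."""
        cv2 = (sd / mean) ** 2
        sigma2 = math.log1p(cv2)
        return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class DomainMasks:
    vessel_domains_radial: dict[int, str]
    vessel_domains_tangential: dict[int, str]
    pixel_mask: np.ndarray
    grid: PixelGrid


@dataclass
class SyntheticTruth:
    network: VesselNetwork
    masks: DomainMasks
    bc: BoundaryConditions
    noiseless: FlowMap
    noisy: FlowMap
    drops_kpa: np.ndarray
    seed: int


class PackingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _place_vessels(spec: SyntheticSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sample non-overlapping vessel centres and radii in the xylem annulus.

    Dart-throwing with a minimum wall thickness between lumina; radii are
    drawn per tangential sector (dorsal/ventral vs lateral wedges) and placed
    largest-first to keep packing feasible.
    """
    # draw the sector (by its area share) and the diameter first, then keep
    # that diameter while searching for a position, so rejected placements do
    # not bias the realized diameter distribution
    centres = np.zeros((spec.n_vessels, 2))
    radii = np.zeros(spec.n_vessels)
    sectors: list[str] = []
    half_wedge = math.radians(spec.dv_wedge_deg) / 2.0
    dv_area_share = 2.0 * spec.dv_wedge_deg / 360.0
    mu_dv, sg_dv = spec.lognormal_params(*spec.diameter_dv_um)
    mu_lat, sg_lat = spec.lognormal_params(*spec.diameter_lateral_um)
    for placed in range(spec.n_vessels):
        dv = bool(rng.random() < dv_area_share)
        d = rng.lognormal(*((mu_dv, sg_dv) if dv else (mu_lat, sg_lat)))
        r = min(d, 150.0) / 2.0  # truncate pathological tail draws
        for _ in range(2000):
            rr = math.sqrt(rng.uniform(spec.pith_radius_um ** 2,
                                       spec.stem_radius_um ** 2))
            th = rng.uniform(0.0, 2.0 * math.pi)
            x, y = rr * math.cos(th), rr * math.sin(th)
            # dorsal wedge around +y, ventral around −y
            ang = abs(math.atan2(x, y))  # angle from +y axis
            in_dv = ang <= half_wedge or ang >= math.pi - half_wedge
            if in_dv != dv:
                continue
            if rr + r > spec.stem_radius_um or rr - r < spec.pith_radius_um:
                continue
            if placed:
                dist = np.hypot(centres[:placed, 0] - x,
                                centres[:placed, 1] - y)
                if np.any(dist < radii[:placed] + r + spec.min_wall_um):
                    continue
            break
        else:
            raise PackingError(
                f"could not place vessel {placed} (radius {r:.1f} um) after "
                f"2000 attempts; reduce n_vessels or diameters.")
        centres[placed] = (x, y)
        radii[placed] = r
        sectors.append("dorsal_ventral" if dv else "lateral")
    return centres, radii, sectors


def _sample_connections(spec: SyntheticSpec, centres: np.ndarray,
                        radii: np.ndarray, rng: np.random.Generator
                        ) -> list[tuple[int, int, bool, float]]:
    """(i, j, is_relay, z_um) for each realized inter-vessel connection."""
    n = len(radii)
    out = []
    for i in range(n):
        d = np.hypot(centres[i + 1:, 0] - centres[i, 0],
                     centres[i + 1:, 1] - centres[i, 1])
        gap = d - radii[i] - radii[i + 1:]
        p = spec.connection_p0 * np.exp(-np.maximum(gap, 0.0)
                                        / spec.connection_lambda_um)
        hits = np.flatnonzero(rng.random(p.size) < p)
        for h in hits:
            j = i + 1 + h
            # connected pairs often share several distinct pit fields
            k = 1 + int(rng.poisson(spec.connection_extra_per_pair))
            for _ in range(k):
                is_relay = bool(rng.random() < spec.relay_fraction)
                z = float(rng.uniform(0.05, 0.95) * spec.sample_length_um)
                out.append((i, j, is_relay, z))
    return out


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def generate_network(spec: SyntheticSpec, seed: int
                     ) -> tuple[VesselNetwork, DomainMasks]:
    """Generate a vessel network and its domain masks; deterministic in seed."""
    rng = np.random.default_rng(seed)
    centres, radii, sectors = _place_vessels(spec, rng)
    conns = _sample_connections(spec, centres, radii, rng)

    mu_pa, sg_pa = spec.lognormal_params(*spec.pit_area_mm2)
    mu_rd, sg_rd = spec.lognormal_params(*spec.relay_diameter_um)
    mu_rp, sg_rp = spec.lognormal_params(*spec.relay_pit_area_mm2)

    # per-vessel sorted z breakpoints
    z_of_vessel: dict[int, list[float]] = {i: [] for i in range(spec.n_vessels)}
    for i, j, _, z in conns:
        z_of_vessel[i].append(z)
        z_of_vessel[j].append(z)

    nodes: list[NetworkNode] = []
    lumens: list[LumenEdge] = []
    connections: list[ConnectionEdge] = []
    node_at: dict[tuple[int, float], int] = {}

    def add_node(x, y, z, tag="interior") -> int:
        nid = len(nodes)
        nodes.append(NetworkNode(id=nid, x=float(x), y=float(y), z=float(z),
                                 tag=tag))
        return nid

    for v in range(spec.n_vessels):
        zs = sorted({0.0, spec.sample_length_um, *z_of_vessel[v]})
        x, y = centres[v]
        ids = []
        for z in zs:
            tag = ("bottom" if z == 0.0
                   else "top" if z == spec.sample_length_um else "interior")
            nid = add_node(x, y, z, tag)
            node_at[(v, z)] = nid
            ids.append(nid)
        for a, b in zip(ids[:-1], ids[1:]):
            lumens.append(LumenEdge(vessel_id=v, node_a=a, node_b=b,
                                    radius_um=radii[v]))

    relay_count = 0
    for i, j, is_relay, z in conns:
        na, nb = node_at[(i, z)], node_at[(j, z)]
        if not is_relay:
            area = float(rng.lognormal(mu_pa, sg_pa))
            connections.append(ConnectionEdge(
                kind="pit_field", node_a=na, node_b=nb,
                vessel_a=i, vessel_b=j, area_mm2=area))
        else:
            relay_count += 1
            rd = float(np.clip(rng.lognormal(mu_rd, sg_rd), 2.0, 40.0))
            xa, ya = centres[i]
            xb, yb = centres[j]
            m1 = add_node(xa + (xb - xa) / 3, ya + (yb - ya) / 3, z)
            m2 = add_node(xa + 2 * (xb - xa) / 3, ya + 2 * (yb - ya) / 3, z)
            a1 = float(rng.lognormal(mu_rp, sg_rp))
            a2 = float(rng.lognormal(mu_rp, sg_rp))
            connections.append(ConnectionEdge(
                kind="relay_pit", node_a=na, node_b=m1,
                vessel_a=i, vessel_b=j, area_mm2=a1))
            lumens.append(LumenEdge(vessel_id=-relay_count, node_a=m1,
                                    node_b=m2, radius_um=rd / 2.0))
            connections.append(ConnectionEdge(
                kind="relay_pit", node_a=m2, node_b=nb,
                vessel_a=i, vessel_b=j, area_mm2=a2))

    area_mm2 = math.pi * (spec.stem_radius_um ** 2
                          - spec.pith_radius_um ** 2) * 1e-6
    net = VesselNetwork(nodes=nodes, lumens=lumens, connections=connections,
                        sample_length_um=spec.sample_length_um,
                        xylem_area_mm2=area_mm2)
    masks = _build_masks(spec, centres, radii)
    return net, masks


def _build_masks(spec: SyntheticSpec, centres: np.ndarray,
                 radii: np.ndarray) -> DomainMasks:
    half_wedge = math.radians(spec.dv_wedge_deg) / 2.0
    radial, tangential = {}, {}
    for v, (x, y) in enumerate(centres):
        rr = math.hypot(x, y)
        radial[v] = "inner" if rr <= spec.inner_boundary_um else "outer"
        ang = abs(math.atan2(x, y))
        tangential[v] = ("dorsal_ventral"
                         if ang <= half_wedge or ang >= math.pi - half_wedge
                         else "lateral")
    extent = spec.stem_radius_um + spec.pixel_size_um
    n_px = int(math.ceil(2 * extent / spec.pixel_size_um))
    origin = (-n_px / 2 * spec.pixel_size_um, -n_px / 2 * spec.pixel_size_um)
    grid = PixelGrid((n_px, n_px), spec.pixel_size_um, origin_um=origin)
    jj, ii = np.meshgrid(np.arange(n_px), np.arange(n_px))
    xc = origin[0] + (jj + 0.5) * spec.pixel_size_um
    yc = origin[1] + (ii + 0.5) * spec.pixel_size_um
    rr = np.hypot(xc, yc)
    ang = np.abs(np.arctan2(xc, yc))
    mask = np.zeros((n_px, n_px), dtype=np.int16)
    # a pixel belongs to the xylem if its area overlaps the annulus, so pad
    # the radial test by the pixel half-diagonal
    pad = spec.pixel_size_um * 0.75
    in_xylem = (rr >= spec.pith_radius_um - pad) & (rr <= spec.stem_radius_um + pad)
    mask[in_xylem & (rr <= spec.inner_boundary_um)] |= MASK_INNER
    mask[in_xylem & (rr > spec.inner_boundary_um)] |= MASK_OUTER
    dv = (ang <= half_wedge) | (ang >= math.pi - half_wedge)
    mask[in_xylem & dv] |= MASK_DORSAL_VENTRAL
    mask[in_xylem & ~dv] |= MASK_LATERAL
    return DomainMasks(vessel_domains_radial=radial,
                       vessel_domains_tangential=tangential,
                       pixel_mask=mask, grid=grid)


# ---------------------------------------------------------------------------
# Boundary-pressure truth and forward observation
# ---------------------------------------------------------------------------

def generate_boundary_conditions(spec: SyntheticSpec, network: VesselNetwork,
                                 seed: int) -> tuple[BoundaryConditions, np.ndarray]:
    """Draw true top pressures; returns (bc, per-group drops in kPa)."""
    rng = np.random.default_rng(seed)
    n_groups = network.n_groups()
    if spec.bc_mode == "uniform":
        drops = np.full(n_groups, spec.uniform_drop_kpa)
    elif spec.bc_mode == "per_group":
        drops = rng.uniform(*spec.drop_range_kpa, size=n_groups)
    else:
        raise ValueError(f"unknown bc_mode {spec.bc_mode!r}")
    bc = BoundaryConditions(top={g: -d for g, d in enumerate(drops)})
    return bc, drops


def forward_flow_map(network: VesselNetwork, bc: BoundaryConditions,
                     masks: DomainMasks, noise_sd: float,
                     jitter_um: tuple[float, float], seed: int,
                     drops: np.ndarray | None = None) -> SyntheticTruth:
    """Forward-simulate the observed flow raster for known boundary pressures.

    The noiseless map bins the solved vessel flows on the grid; the noisy map
    first applies the registration jitter to the vessel coordinates, then adds
    independent zero-mean Gaussian noise to every nonzero pixel.
    """
    rng = np.random.default_rng(seed)
    sol = solve_flow(network, bc)
    grid = masks.grid
    clean = downsample_to_pixels(sol, grid)
    jgrid = PixelGrid(grid.shape, grid.pixel_size_um, grid.origin_um,
                      offset_um=tuple(jitter_um))
    shifted = (clean if jitter_um == (0.0, 0.0)
               else downsample_to_pixels(sol, jgrid))
    noisy = shifted.copy()
    nz = noisy != 0
    if noise_sd > 0:
        noisy[nz] += rng.normal(0.0, noise_sd, size=int(nz.sum()))
    px = grid.pixel_size_um
    noiseless_map = FlowMap(clean, px, grid.origin_um, mask=masks.pixel_mask)
    noisy_map = FlowMap(noisy, px, grid.origin_um, mask=masks.pixel_mask)
    if drops is None:
        drops = np.array([])
    return SyntheticTruth(network=network, masks=masks, bc=bc,
                          noiseless=noiseless_map, noisy=noisy_map,
                          drops_kpa=np.asarray(drops, dtype=float), seed=seed)


def simulate(spec: SyntheticSpec, seed: int) -> SyntheticTruth:
    """Full pipeline: network + truth pressures + noiseless/noisy maps."""
    net, masks = generate_network(spec, seed)
    bc, drops = generate_boundary_conditions(spec, net, seed + 1)
    return forward_flow_map(net, bc, masks, spec.noise_sd_ug_s,
                            spec.jitter_um, seed + 2, drops=drops)


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

def recovery_experiment(spec: SyntheticSpec, n_seeds: int = 5,
                        noise_sds: tuple[float, ...] | None = None,
                        scenario: str = "per_group",
                        out_path: str | None = None) -> pd.DataFrame:
    """Forward-then-invert round trips; per-seed recovery metrics.

    For each seed (and optionally each observation-noise level) the synthetic
    observation is fitted and the recovered per-group pressure drops are
    compared with the truth.  Returns a tidy DataFrame; optionally written as
    CSV.
    """
    levels = noise_sds if noise_sds is not None else (spec.noise_sd_ug_s,)
    rows = []
    for s in range(n_seeds):
        seed = 1000 + 17 * s
        net, masks = generate_network(spec, seed)
        bc, drops = generate_boundary_conditions(spec, net, seed + 1)
        for noise in levels:
            truth = forward_flow_map(net, bc, masks, noise, spec.jitter_um,
                                     seed + 2, drops=drops)
            model = XylemFlowModel(net, truth.noisy)
            res = model.fit(scenario=scenario)
            if scenario == "per_group":
                err = np.abs(res.drops - drops)
            else:
                err = np.abs(res.drops - drops.mean())
            rows.append({
                "seed": seed, "noise_sd": noise, "scenario": scenario,
                "n_groups": model.n_groups,
                "median_drop_error_kpa": float(np.median(err)),
                "max_drop_error_kpa": float(err.max()),
                "nse": res.nse,
                "total_flow_rel_error": res.total_flow_rel_error,
            })
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def constricted_pair(n_vessels: int = 60, seed: int = 0,
                     constriction_radius_factor: float = 0.35,
                     drop_kpa: float = 0.3
                     ) -> tuple[VesselNetwork, VesselNetwork, DomainMasks]:
    """A matched pair of networks for the flow-redirection mechanism.

    Both contain the same solitary vessels; in the 'truth' network every
    vessel of above-average radius carries a narrow serial constriction in
    its apical tenth (emulating narrower elements downstream of the sampled
    segment), while the 'fit' network has uniform lumina.  Fitting the fit
    network to observations forward-simulated from the truth network shows
    how serial heterogeneity suppresses wide-vessel flow below the
    homogeneous-gradient prediction.
    """
    spec = SyntheticSpec(n_vessels=n_vessels, connection_p0=0.0,
                         relay_fraction=0.0, bc_mode="uniform",
                         uniform_drop_kpa=drop_kpa, noise_sd_ug_s=0.0)
    rng = np.random.default_rng(seed)
    centres, radii, sectors = _place_vessels(spec, rng)
    mean_r = radii.mean()
    z_break = 0.9 * spec.sample_length_um

    def build(constrict: bool) -> VesselNetwork:
        nodes, lumens = [], []
        for v in range(n_vessels):
            x, y = centres[v]
            n0 = len(nodes)
            nodes.append(NetworkNode(n0, x, y, 0.0, "bottom"))
            nodes.append(NetworkNode(n0 + 1, x, y, z_break, "interior"))
            nodes.append(NetworkNode(n0 + 2, x, y, spec.sample_length_um, "top"))
            r_top = radii[v]
            if constrict and radii[v] > mean_r:
                r_top = constriction_radius_factor * mean_r
            lumens.append(LumenEdge(v, n0, n0 + 1, radii[v]))
            lumens.append(LumenEdge(v, n0 + 1, n0 + 2, r_top))
        area = math.pi * (spec.stem_radius_um ** 2 - spec.pith_radius_um ** 2) * 1e-6
        return VesselNetwork(nodes=nodes, lumens=lumens, connections=[],
                             sample_length_um=spec.sample_length_um,
                             xylem_area_mm2=area)

    masks = _build_masks(spec, centres, radii)
    return build(True), build(False), masks
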