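"""File formats: network files, flow-map rasters, run configuration.

Network file format (plain text, tab- or space-separated, '#' comments)::

    HEADER
    sample_length_um 3300
    xylem_area_mm2 10.4
    eta_mpa_s 1.002e-09
    rho_kg_m3 998
    NODES
    # id x y z tag
    0 12.5 -80.0 0.0 bottom
    ...
    LUMENS
    # vessel_id node_a node_b radius_um
    0 0 1 18.75
    ...
    CONNECTIONS
    # kind vessel_a vessel_b node_a node_b area_mm2 diam_um  ('-' if absent)
    pit_field 0 3 1 7 0.0152 -
    ...

The same schema round-trips through a single YAML document
(``network_to_dict``/``network_from_dict``).  Flow-map rasters are stored as
32-bit float TIFF (metadata in the image description) or as headered CSV;
masks as integer rasters in either dialect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flowmap import FlowMap
from .network import (ConnectionEdge, LumenEdge, NetworkError, NetworkNode,
                      VesselNetwork)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # shortest round-trippable double would also do


class FormatError(NetworkError):
    """Malformed input file; message carries the line number."""


# ---------------------------------------------------------------------------
# Network text format
# ---------------------------------------------------------------------------

def write_network(network: VesselNetwork, path: str | Path) -> None:
    f = lambda x: _FLOAT_FMT % x
    lines = ["# xylemflow network v1", "HEADER",
             f"sample_length_um {f(network.sample_length_um)}",
             f"xylem_area_mm2 {f(network.xylem_area_mm2)}",
             f"eta_mpa_s {f(network.eta_mpa_s)}",
             f"rho_kg_m3 {f(network.rho_kg_m3)}",
             "NODES", "# id x y z tag"]
    for n in network.nodes:
        lines.append(f"{n.id} {f(n.x)} {f(n.y)} {f(n.z)} {n.tag}")
    lines += ["LUMENS", "# vessel_id node_a node_b radius_um"]
    for l in network.lumens:
        lines.append(f"{l.vessel_id} {l.node_a} {l.node_b} {f(l.radius_um)}")
    lines += ["CONNECTIONS", "# kind vessel_a vessel_b node_a node_b area_mm2 diam_um"]
    for c in network.connections:
        area = f(c.area_mm2) if c.area_mm2 is not None else "-"
        diam = f(c.diameter_um) if c.diameter_um is not None else "-"
        lines.append(f"{c.kind} {c.vessel_a} {c.vessel_b} "
                     f"{c.node_a} {c.node_b} {area} {diam}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> VesselNetwork:
    header: dict[str, float] = {}
    nodes: list[NetworkNode] = []
    lumens: list[LumenEdge] = []
    connections: list[ConnectionEdge] = []
    section = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in ("HEADER", "NODES", "LUMENS", "CONNECTIONS"):
            section = line
            continue
        parts = line.split()
        try:
            if section == "HEADER":
                header[parts[0]] = float(parts[1])
            elif section == "NODES":
                nodes.append(NetworkNode(id=int(parts[0]), x=float(parts[1]),
                                         y=float(parts[2]), z=float(parts[3]),
                                         tag=parts[4]))
            elif section == "LUMENS":
                lumens.append(LumenEdge(vessel_id=int(parts[0]),
                                        node_a=int(parts[1]),
                                        node_b=int(parts[2]),
                                        radius_um=float(parts[3])))
            elif section == "CONNECTIONS":
                area = None if parts[5] == "-" else float(parts[5])
                diam = None if parts[6] == "-" else float(parts[6])
                connections.append(ConnectionEdge(
                    kind=parts[0], vessel_a=int(parts[1]),
                    vessel_b=int(parts[2]), node_a=int(parts[3]),
                    node_b=int(parts[4]), area_mm2=area, diameter_um=diam))
            else:
                raise FormatError(f"{path}:{ln}: record outside any section")
        except (IndexError, ValueError, NetworkError) as err:
            raise FormatError(f"{path}:{ln}: invalid {section} record "
                              f"{line!r}: {err}") from err
    for key in ("sample_length_um", "xylem_area_mm2"):
        if key not in header:
            raise FormatError(f"{path}: missing HEADER field {key}")
    try:
        return VesselNetwork(
            nodes=nodes, lumens=lumens, connections=connections,
            sample_length_um=header["sample_length_um"],
            xylem_area_mm2=header["xylem_area_mm2"],
            eta_mpa_s=header.get("eta_mpa_s", 1.002e-9),
            rho_kg_m3=header.get("rho_kg_m3", 998.0))
    except NetworkError as err:
        raise FormatError(f"{path}: {err}") from err


def network_to_dict(network: VesselNetwork) -> dict:
    return {
        "format": "xylemflow-network", "version": 1,
        "sample_length_um": network.sample_length_um,
        "xylem_area_mm2": network.xylem_area_mm2,
        "eta_mpa_s": network.eta_mpa_s,
        "rho_kg_m3": network.rho_kg_m3,
        "nodes": [[int(n.id), float(n.x), float(n.y), float(n.z), n.tag]
                  for n in network.nodes],
        "lumens": [[int(l.vessel_id), int(l.node_a), int(l.node_b),
                    float(l.radius_um)] for l in network.lumens],
        "connections": [[c.kind, int(c.vessel_a), int(c.vessel_b),
                         int(c.node_a), int(c.node_b),
                         None if c.area_mm2 is None else float(c.area_mm2),
                         None if c.diameter_um is None else float(c.diameter_um)]
                        for c in network.connections],
    }


def network_from_dict(d: dict) -> VesselNetwork:
    return VesselNetwork(
        nodes=[NetworkNode(id=n[0], x=n[1], y=n[2], z=n[3], tag=n[4])
               for n in d["nodes"]],
        lumens=[LumenEdge(vessel_id=l[0], node_a=l[1], node_b=l[2],
                          radius_um=l[3]) for l in d["lumens"]],
        connections=[ConnectionEdge(kind=c[0], vessel_a=c[1], vessel_b=c[2],
                                    node_a=c[3], node_b=c[4], area_mm2=c[5],
                                    diameter_um=c[6])
                     for c in d["connections"]],
        sample_length_um=d["sample_length_um"],
        xylem_area_mm2=d["xylem_area_mm2"],
        eta_mpa_s=d.get("eta_mpa_s", 1.002e-9),
        rho_kg_m3=d.get("rho_kg_m3", 998.0))


def write_network_yaml(network: VesselNetwork, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(network),
                                         sort_keys=False))


def read_network_yaml(path: str | Path) -> VesselNetwork:
    return network_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Flow-map rasters
# ---------------------------------------------------------------------------

def write_flowmap(fmap: FlowMap, path: str | Path) -> None:
    """Write a raster as float32 TIFF (.tif/.tiff) or headered CSV (.csv)."""
    path = Path(path)
    meta = {"pixel_size_um": fmap.pixel_size_um,
            "origin_um": list(fmap.origin_um),
            "offset_um": list(fmap.offset_um)}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, fmap.values.astype(np.float32),
                         description=json.dumps(meta))
        if fmap.mask is not None:
            tifffile.imwrite(path.with_suffix(".mask" + path.suffix),
                             fmap.mask.astype(np.int16))
    elif path.suffix.lower() == ".csv":
        lines = [f"# pixel_size_um {_FLOAT_FMT % fmap.pixel_size_um}",
                 f"# origin_um {_FLOAT_FMT % fmap.origin_um[0]} "
                 f"{_FLOAT_FMT % fmap.origin_um[1]}",
                 f"# offset_um {_FLOAT_FMT % fmap.offset_um[0]} "
                 f"{_FLOAT_FMT % fmap.offset_um[1]}"]
        for row in np.asarray(fmap.values, dtype=np.float32):
            lines.append(",".join(_FLOAT_FMT % v for v in row))
        Path(path).write_text("\n".join(lines) + "\n")
        if fmap.mask is not None:
            mlines = [",".join(str(int(v)) for v in row) for row in fmap.mask]
            path.with_suffix(".mask.csv").write_text("\n".join(mlines) + "\n")
    else:
        raise ValueError(f"unsupported flow-map extension {path.suffix!r}")


def read_flowmap(path: str | Path) -> FlowMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray().astype(float)
            desc = tf.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        mask_path = path.with_suffix(".mask" + path.suffix)
        mask = tifffile.imread(mask_path) if mask_path.exists() else None
    elif path.suffix.lower() == ".csv":
        meta = {}
        rows = []
        for raw in path.read_text().splitlines():
            if raw.startswith("#"):
                parts = raw[1:].split()
                if parts[0] in ("pixel_size_um",):
                    meta[parts[0]] = float(parts[1])
                elif parts[0] in ("origin_um", "offset_um"):
                    meta[parts[0]] = [float(parts[1]), float(parts[2])]
            elif raw.strip():
                rows.append([float(v) for v in raw.split(",")])
        values = np.array(rows)
        mask_path = path.with_suffix(".mask.csv")
        mask = (np.loadtxt(mask_path, delimiter=",", dtype=int, ndmin=2)
                if mask_path.exists() else None)
    else:
        raise ValueError(f"unsupported flow-map extension {path.suffix!r}")
    return FlowMap(values, meta.get("pixel_size_um", 1.0),
                   tuple(meta.get("origin_um", (0.0, 0.0))),
                   tuple(meta.get("offset_um", (0.0, 0.0))), mask)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one analysis run (YAML round-trippable)."""
    out_dir: str = "run_out"
    network_path: str | None = None       # None → synthesize
    flowmap_path: str | None = None
    scenarios: tuple[str, ...] = ("uniform", "total_flow", "per_group")
    seed: int = 0
    pixel_size_um: float = 78.0
    registration_offset_um: tuple[float, float] = (0.0, 0.0)
    smoothing_size: int = 5
    fit_tol: float = 1e-10
    max_iter: int = 500
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        d["registration_offset_um"] = list(self.registration_offset_um)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["scenarios"] = tuple(d.get("scenarios", ()))
        d["registration_offset_um"] = tuple(d.get("registration_offset_um",
                                                  (0.0, 0.0)))
        return cls(**d)


def pipeline_run(config: RunConfig) -> dict:
    """solve → fit (all requested scenarios) → stats → reports.

    Writes per-scenario summaries, a per-vessel table, the run's resolved
    configuration and a JSON report into ``config.out_dir``; returns the
    report dictionary.
    """
    from .model import XylemFlowModel
    from .stats import flow_weighted_summary, transverse_gradients
    from .synthetic import SyntheticSpec, simulate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "scenarios": {}}

    if config.network_path is None:
        spec = SyntheticSpec(**config.synthetic)
        truth = simulate(spec, config.seed)
        network, observed = truth.network, truth.noisy
        write_network(network, out / "network.txt")
        write_flowmap(observed, out / "observed.csv")
        report["synthetic"] = True
    else:
        network = read_network(config.network_path)
        if config.flowmap_path is None:
            raise ValueError("flowmap_path required when network_path is given")
        observed = read_flowmap(config.flowmap_path)
        if config.registration_offset_um != (0.0, 0.0):
            observed.offset_um = tuple(config.registration_offset_um)
        report["synthetic"] = False

    model = XylemFlowModel(network, observed,
                           smoothing_size=config.smoothing_size)
    tables = []
    for scen in config.scenarios:
        res = model.fit(scenario=scen, tol=config.fit_tol,
                        max_iter=config.max_iter)
        (out / f"summary_{scen}.txt").write_text(res.summary() + "\n")
        tab = res.vessel_table()
        tab.insert(0, "scenario", scen)
        tables.append(tab)
        pmap = res.pixel_pressure_map()
        grads = transverse_gradients(pmap, observed.pixel_size_um)
        flows = np.array([max(q, 0.0) for q in res.vessel_flows.values()])
        gvals = np.array(list(res.vessel_gradients.values()))
        axial = (flow_weighted_summary(gvals, flows) if flows.sum() > 0
                 else None)
        report["scenarios"][scen] = {
            "objective": res.objective,
            "nse": None if np.isnan(res.nse) else res.nse,
            "total_flow_rel_error": res.total_flow_rel_error,
            "drop_kpa_max": float(res.drops.max()) if res.drops.size else 0.0,
            "transverse_gradient_mean_mpa_m": grads.mean,
            "transverse_gradient_median_mpa_m": grads.median,
            "axial_gradient_fw_mean_mpa_m": axial.mean if axial else None,
        }
        logger.info("scenario %s: objective=%.4g NSE=%.4f", scen,
                    res.objective, res.nse)
    pd.concat(tables).to_csv(out / "vessel_table.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    return report
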