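"""Inverse estimation of top boundary pressures from an observed flow raster.

The forward problem (steady Kirchhoff flow on the vessel network, binned to
the observation grid) is linear in the imposed top pressure drops, and vessel
groups are hydraulically independent, so the whole sensitivity of the pixel
raster to the per-group pressure-drop vector is assembled from a single
unit-drop solve.  Fitting is then:

* ``uniform`` / ``uniform_masked`` — one scalar drop, closed form;
* ``total_flow`` — scalar drop matching the observed total flow, exact;
* ``per_group`` — one drop per vessel group, bound-constrained linear least
  squares solved with the trust-region-reflective algorithm.

The objective in every map-fitting scenario is the 5×5-window-averaged
residual sum of squares (see flowmap.residual_objective).

Usage follows the statsmodels pattern::

    model = XylemFlowModel(network, observed_map)
    res = model.fit(scenario="per_group")
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from . import stats as stats_mod
from . import units
from .flowmap import FlowMap, downsample_to_pixels, residual_objective, smooth_mask_aware
from .network import BoundaryConditions, VesselNetwork, solve_flow

logger = logging.getLogger(__name__)

SCENARIOS = ("uniform", "uniform_masked", "total_flow", "per_group")


class DegenerateFitError(ValueError):
    """The observation carries no signal the scenario could fit."""


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


class XylemFlowModel:
    """Vessel-network flow model bound to an observed flow raster.

    Parameters
    ----------
    network : VesselNetwork
    observed : FlowMap
        Observed per-pixel mass flow (µg s⁻¹); its mask and registration
        offset are honoured.
    assignment : 'centroid' or 'area'
        How vessel top-slice flows are attributed to pixels.
    smoothing_size : int
        Side of the residual moving-average window (5 in the reference
        protocol).
    include_empty_pixels : bool
        Whether unmasked pixels containing no modelled vessel contribute
        residuals (they do by default, with model value 0).
    """

    def __init__(self, network: VesselNetwork, observed: FlowMap,
                 assignment: str = "centroid", smoothing_size: int = 5,
                 include_empty_pixels: bool = True):
        self.network = network
        self.observed = observed
        self.assignment = assignment
        self.smoothing_size = smoothing_size
        self.group_of = network.vessel_group_map()
        self.n_groups = max(self.group_of.values()) + 1 if self.group_of else 0

        # one unit-drop solve: top pressure −1 kPa everywhere (drop of 1 kPa);
        # per-group response is the restriction to that group's vessels
        self.unit_solution = solve_flow(network, BoundaryConditions(top=-1.0))
        self.unit_vessel_flow = dict(self.unit_solution.vessel_top_flow)

        grid = observed.grid
        self._group_rasters = np.zeros((self.n_groups,) + grid.shape)
        vessel_pixel: dict[int, tuple[int, int] | None] = {}
        for v, q in self.unit_vessel_flow.items():
            node = network.node(network.top_node_of_vessel(v))
            px = grid.pixel_of(node.x, node.y)
            vessel_pixel[v] = px
        self.vessel_pixel = vessel_pixel
        if self.assignment == "centroid":
            for v, q in self.unit_vessel_flow.items():
                px = vessel_pixel[v]
                if px is not None:
                    self._group_rasters[self.group_of[v]][px] += q
        else:
            for g in range(self.n_groups):
                sub = _GroupView(self.unit_solution, self.group_of, g)
                self._group_rasters[g] = downsample_to_pixels(
                    sub, grid, assignment=self.assignment)
        dropped = [v for v, px in vessel_pixel.items() if px is None]
        if dropped:
            logger.warning("%d vessels outside the observation grid", len(dropped))

        include = observed.include.copy()
        if not include_empty_pixels:
            occupied = self._group_rasters.any(axis=0)
            include &= occupied
        self.include = include

    # -- internals -------------------------------------------------------
    def _design(self, include: np.ndarray) -> np.ndarray:
        """(n_include_pixels, n_groups) matrix of smoothed unit responses."""
        cols = [smooth_mask_aware(r, include, self.smoothing_size)[include]
                for r in self._group_rasters]
        return np.column_stack(cols) if cols else np.zeros((int(include.sum()), 0))

    def _resolve_include(self, include):
        if include is None:
            return self.include
        include = np.asarray(include, dtype=bool)
        if include.shape != self.observed.values.shape:
            raise ValueError("include mask shape mismatch")
        return include & self.include

    def model_raster(self, drops: np.ndarray) -> np.ndarray:
        """Pixel raster for a per-group pressure-drop vector (kPa)."""
        drops = np.asarray(drops, dtype=float)
        return np.tensordot(drops, self._group_rasters, axes=1)

    # -- fitting ---------------------------------------------------------
    def fit(self, scenario: str = "uniform", include=None,
            observed_total: float | None = None,
            bounds: tuple[float, float] = (0.0, np.inf),
            max_iter: int = 500, tol: float = 1e-10) -> "FlowFitResults":
        """Fit top boundary pressures under the given scenario.

        ``uniform_masked`` restricts the objective to the observed map's
        'inner' domain unless an explicit ``include`` raster is given.
        ``bounds`` constrain per-group pressure drops (kPa); the default
        allows only non-negative drops, consistent with upward sap flow.
        """
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
        if scenario == "uniform_masked" and include is None:
            include = self.observed.domain("inner")
        include = self._resolve_include(include)

        if scenario == "total_flow":
            if observed_total is None:
                observed_total = self.observed.total
            if observed_total <= 0:
                raise DegenerateFitError("observed total flow must be positive")
            k_unit = self.unit_solution.total_top_flow
            if k_unit <= 0:
                raise DegenerateFitError("network has zero conductance")
            drop = observed_total / k_unit
            drops = np.full(self.n_groups, drop)
            return self._results("total_flow", drops, include, n_iter=0)

        obs = self.observed.values
        if not np.any(obs[include] != 0):
            raise DegenerateFitError("observed map is zero on all unmasked pixels")
        w_obs = smooth_mask_aware(obs, include, self.smoothing_size)[include]

        if scenario in ("uniform", "uniform_masked"):
            unit_raster = self._group_rasters.sum(axis=0)
            s = smooth_mask_aware(unit_raster, include, self.smoothing_size)[include]
            ss = float(s @ s)
            if ss == 0:
                raise DegenerateFitError("no modelled flow falls on unmasked pixels")
            drop = float(s @ w_obs) / ss
            drops = np.full(self.n_groups, drop)
            return self._results(scenario, drops, include, n_iter=0)

        # per_group: bound-constrained linear least squares (TRF)
        a = self._design(include)
        col_norm = np.linalg.norm(a, axis=0)
        observable = col_norm > 1e-12 * max(col_norm.max(), 1.0)
        clamped = np.flatnonzero(~observable)
        if clamped.size:
            logger.info("%d vessel groups overlap no unmasked pixel; "
                        "clamped to zero drop", clamped.size)
        a_obs = a[:, observable]

        lo, hi = bounds
        res = lsq_linear(a_obs, w_obs, bounds=(lo, hi), method="trf",
                         tol=tol, max_iter=max_iter)
        if res.status == 0:
            raise FitConvergenceError(
                f"per-group fit did not converge in {max_iter} iterations "
                f"({res.message})", res.x)
        drops = np.zeros(self.n_groups)
        drops[observable] = res.x
        return self._results("per_group", drops, include,
                             n_iter=int(res.nit), clamped=clamped)

    def _results(self, scenario, drops, include, n_iter=0,
                 clamped=np.array([], dtype=int)) -> "FlowFitResults":
        raster = self.model_raster(drops)
        objective, resid = residual_objective(raster, self.observed.values,
                                              include, self.smoothing_size)
        obs_in = self.observed.values[include]
        mod_in = raster[include]
        nse = stats_mod.nse(obs_in, mod_in) if np.ptp(obs_in) > 0 else np.nan
        total_obs = float(obs_in.sum())
        total_mod = float(mod_in.sum())
        rel_err = (total_mod - total_obs) / total_obs if total_obs != 0 else np.nan
        vessel_flows = {v: q * drops[self.group_of[v]]
                        for v, q in self.unit_vessel_flow.items()}
        vessel_gradients = {
            v: units.pressure_gradient_mpa_m(
                drops[self.group_of[v]], self.network.sample_length_um)
            for v in vessel_flows}
        modelled = FlowMap(raster, self.observed.pixel_size_um,
                           self.observed.origin_um, self.observed.offset_um,
                           self.observed.mask)
        return FlowFitResults(
            model=self, scenario=scenario, drops=drops,
            include=include, modelled=modelled, residual_smoothed=resid,
            objective=objective, nse=nse, total_flow_rel_error=rel_err,
            vessel_flows=vessel_flows, vessel_gradients=vessel_gradients,
            clamped_groups=clamped, n_iter=n_iter)


class _GroupView:
    """Restriction of a FlowSolution to one vessel group (for binning)."""

    def __init__(self, solution, group_of, g):
        self.network = solution.network
        self.vessel_top_flow = {v: q for v, q in solution.vessel_top_flow.items()
                                if group_of[v] == g}


@dataclass
class FlowFitResults:
    """Fitted boundary pressures and fit diagnostics.

    ``drops`` are per-group pressure drops in kPa (bottom − top, positive
    drives upward flow); ``top_pressures`` are the equivalent imposed top
    pressures relative to a zero bottom reference.
    """
    model: XylemFlowModel
    scenario: str
    drops: np.ndarray
    include: np.ndarray
    modelled: FlowMap
    residual_smoothed: np.ndarray
    objective: float
    nse: float
    total_flow_rel_error: float
    vessel_flows: dict[int, float]
    vessel_gradients: dict[int, float]
    clamped_groups: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_iter: int = 0

    @property
    def top_pressures(self) -> np.ndarray:
        return -self.drops

    @property
    def uniform_drop(self) -> float:
        """Scalar drop for single-pressure scenarios."""
        if self.scenario == "per_group":
            raise ValueError("per-group fit has no single drop; use .drops")
        return float(self.drops[0]) if self.drops.size else 0.0

    @property
    def total_modelled_flow(self) -> float:
        return float(sum(self.vessel_flows.values()))

    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(top={g: -d for g, d in enumerate(self.drops)})

    def solution(self):
        """Full FlowSolution under the fitted boundary pressures."""
        return solve_flow(self.model.network, self.boundary_conditions())

    def pixel_pressure_map(self) -> np.ndarray:
        """Per-pixel flow-weighted mean imposed pressure drop (kPa).

        Pixels containing no flowing vessel are NaN ('empty').
        """
        grid = self.model.observed.grid
        num = np.zeros(grid.shape)
        den = np.zeros(grid.shape)
        for v, q in self.vessel_flows.items():
            px = self.model.vessel_pixel.get(v)
            if px is None:
                continue
            drop = self.drops[self.model.group_of[v]]
            num[px] += q * drop
            den[px] += q
        out = np.full(grid.shape, np.nan)
        np.divide(num, den, out=out, where=den != 0)
        return out

    def vessel_table(self) -> pd.DataFrame:
        net = self.model.network
        rows = []
        for v in sorted(self.vessel_flows):
            chain = net.vessel_lumens(v)
            mean_r = float(np.mean([l.radius_um for l in chain]))
            rows.append({"vessel": v, "group": self.model.group_of[v],
                         "radius_um": mean_r,
                         "flow_ug_s": self.vessel_flows[v],
                         "gradient_mpa_m": self.vessel_gradients[v],
                         "drop_kpa": self.drops[self.model.group_of[v]]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        d = self.drops
        lines = [
            "Xylem flow boundary-pressure fit",
            "=" * 40,
            f"scenario:            {self.scenario}",
            f"vessel groups:       {self.model.n_groups}",
            f"fitted drop (kPa):   "
            + (f"{d[0]:.4g}" if self.scenario != "per_group"
               else f"min {d.min():.4g} / median {np.median(d):.4g} / max {d.max():.4g}"),
            f"objective:           {self.objective:.6g}",
            f"NSE:                 {self.nse:.4f}",
            f"total-flow error:    {self.total_flow_rel_error:+.2%}",
            f"clamped groups:      {self.clamped_groups.size}",
            f"iterations:          {self.n_iter}",
        ]
        return "\n".join(lines)

    def plot_maps(self, axes=None):
        """Observed / modelled / residual rasters side by side."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 4))
        for ax, (title, data) in zip(axes, [
                ("observed", self.model.observed.values),
                ("modelled", self.modelled.values),
                ("residual (5x5 mean)", self.residual_smoothed)]):
            im = ax.imshow(np.where(self.include, data, np.nan))
            ax.set_title(title)
            ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return axes
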