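"""Inverse boundary-pressure estimation (all scenarios)."""

import itertools

import numpy as np
import pytest

from xylemflow.flowmap import FlowMap, smooth_mask_aware
from xylemflow.model import (DegenerateFitError, XylemFlowModel)
from xylemflow.network import BoundaryConditions, solve_flow
from xylemflow.synthetic import (SyntheticSpec, forward_flow_map,
                                 generate_boundary_conditions,
                                 generate_network, simulate)


@pytest.fixture(scope="module")
def truth():
    spec = SyntheticSpec(n_vessels=80, noise_sd_ug_s=0.0)
    return simulate(spec, 11)


@pytest.fixture(scope="module")
def noisy_truth():
    spec = SyntheticSpec(n_vessels=80, bc_mode="uniform",
                         uniform_drop_kpa=0.3, noise_sd_ug_s=0.05)
    return simulate(spec, 23)


class TestUniformFit:
    def test_noiseless_self_consistency(self):
        spec = SyntheticSpec(n_vessels=60, bc_mode="uniform",
                             uniform_drop_kpa=0.21, noise_sd_ug_s=0.0)
        t = simulate(spec, 5)
        res = XylemFlowModel(t.network, t.noisy).fit("uniform")
        assert res.uniform_drop == pytest.approx(0.21, rel=1e-9)
        assert res.nse >= 0.999999

    def test_linearity_in_observation(self, noisy_truth):
        t = noisy_truth
        m1 = XylemFlowModel(t.network, t.noisy)
        r1 = m1.fit("uniform")
        doubled = FlowMap(2 * t.noisy.values, t.noisy.pixel_size_um,
                          t.noisy.origin_um, t.noisy.offset_um, t.noisy.mask)
        r2 = XylemFlowModel(t.network, doubled).fit("uniform")
        assert r2.uniform_drop == pytest.approx(2 * r1.uniform_drop, rel=1e-9)

    def test_matches_grid_search_oracle(self, noisy_truth):
        t = noisy_truth
        model = XylemFlowModel(t.network, t.noisy)
        res = model.fit("uniform")
        from xylemflow.flowmap import residual_objective
        drops = np.linspace(0.0, 1.0, 2001)
        objs = [residual_objective(model.model_raster(np.full(model.n_groups, d)),
                                   t.noisy.values, model.include)[0]
                for d in drops]
        best = drops[int(np.argmin(objs))]
        assert res.uniform_drop == pytest.approx(best, abs=5e-4)
        assert res.objective <= min(objs) + 1e-12

    def test_all_zero_observation_degenerate(self, truth):
        zero = FlowMap(np.zeros_like(truth.noisy.values),
                       truth.noisy.pixel_size_um, truth.noisy.origin_um,
                       mask=truth.noisy.mask)
        with pytest.raises(DegenerateFitError):
            XylemFlowModel(truth.network, zero).fit("uniform")


class TestTotalFlowFit:
    def test_unit_consistency(self, truth):
        model = XylemFlowModel(truth.network, truth.noisy)
        k = model.unit_solution.total_top_flow
        res = model.fit("total_flow", observed_total=k)
        assert res.uniform_drop == pytest.approx(1.0, rel=1e-12)
        res2 = model.fit("total_flow", observed_total=2 * k)
        assert res2.uniform_drop == pytest.approx(2.0, rel=1e-12)

    def test_reproduces_forward_total(self, truth):
        model = XylemFlowModel(truth.network, truth.noisy)
        res = model.fit("total_flow")
        assert res.total_modelled_flow == pytest.approx(
            truth.noisy.total, rel=1e-12)


class TestPerGroupFit:
    def test_noiseless_exact_recovery(self, truth):
        model = XylemFlowModel(truth.network, truth.noisy)
        res = model.fit("per_group")
        observable = np.setdiff1d(np.arange(model.n_groups),
                                  res.clamped_groups)
        err = np.abs(res.drops - truth.drops_kpa)
        assert np.median(err[observable]) <= 1e-6
        assert res.nse >= 0.999

    def test_zero_observation_zero_drops(self, truth):
        zero = FlowMap(np.zeros_like(truth.noisy.values),
                       truth.noisy.pixel_size_um, truth.noisy.origin_um,
                       mask=truth.noisy.mask)
        model = XylemFlowModel(truth.network, zero)
        with pytest.raises(DegenerateFitError):
            model.fit("per_group")

    def test_matches_active_set_qp_oracle(self):
        """Bound-constrained LS on a small instance vs exhaustive active sets."""
        spec = SyntheticSpec(n_vessels=14, noise_sd_ug_s=0.08)
        t = simulate(spec, 3)
        model = XylemFlowModel(t.network, t.noisy)
        n = model.n_groups
        assert n <= 16
        a = model._design(model.include)
        b = smooth_mask_aware(t.noisy.values, model.include, 5)[model.include]
        col = np.linalg.norm(a, axis=0)
        keep = col > 1e-12 * col.max()
        a = a[:, keep]
        nk = a.shape[1]
        best = np.inf
        # oracle: enumerate which variables are clamped at the 0 bound
        for active in itertools.product([False, True], repeat=nk):
            free = [i for i in range(nk) if not active[i]]
            x = np.zeros(nk)
            if free:
                sol, *_ = np.linalg.lstsq(a[:, free], b, rcond=None)
                if np.any(sol < -1e-12):
                    continue
                x[free] = np.clip(sol, 0.0, None)
            r = a @ x - b
            best = min(best, float(r @ r))
        res = model.fit("per_group")
        assert res.objective <= best + 1e-8

    def test_scenario_nesting(self, noisy_truth):
        t = noisy_truth
        model = XylemFlowModel(t.network, t.noisy)
        obj_pg = model.fit("per_group").objective
        obj_u = model.fit("uniform").objective
        from xylemflow.flowmap import residual_objective
        obj_zero = residual_objective(np.zeros_like(t.noisy.values),
                                      t.noisy.values, model.include)[0]
        assert obj_pg <= obj_u + 1e-9 <= obj_zero + 2e-9

    def test_per_group_nse_beats_uniform(self, noisy_truth):
        t = noisy_truth
        model = XylemFlowModel(t.network, t.noisy)
        assert model.fit("per_group").nse >= model.fit("uniform").nse - 1e-12


class TestMaskedFit:
    def test_masked_fit_ignores_outer_pixels(self, noisy_truth):
        t = noisy_truth
        # corrupt outer-domain pixels; the masked fit must not move
        model = XylemFlowModel(t.network, t.noisy)
        res_inner = model.fit("uniform_masked")
        corrupted = t.noisy.values.copy()
        outer = t.noisy.domain("outer")
        corrupted[outer] += 17.0
        cmap = FlowMap(corrupted, t.noisy.pixel_size_um, t.noisy.origin_um,
                       mask=t.noisy.mask)
        res_inner2 = XylemFlowModel(t.network, cmap).fit("uniform_masked")
        assert res_inner2.uniform_drop == pytest.approx(
            res_inner.uniform_drop, rel=1e-9)


class TestPixelPressureMap:
    def test_single_vessel_pixel_value(self, truth):
        res = XylemFlowModel(truth.network, truth.noisy).fit("per_group")
        pmap = res.pixel_pressure_map()
        # pixels with exactly one vessel report that vessel's drop
        seen = {}
        for v, px in res.model.vessel_pixel.items():
            seen.setdefault(px, []).append(v)
        for px, vs in seen.items():
            if px is None or len(vs) != 1:
                continue
            v = vs[0]
            if res.vessel_flows[v] != 0:
                assert pmap[px] == pytest.approx(
                    res.drops[res.model.group_of[v]], rel=1e-12)

    def test_flow_weighted_mean_hand_case(self):
        """drops 1 and 3 kPa: equal flows -> 2; flows 3:1 -> 1.5."""
        from xylemflow.model import FlowFitResults  # noqa: F401 (doc anchor)
        num = 1.0 * 1.0 + 3.0 * 1.0
        assert num / 2.0 == pytest.approx(2.0)
        num2 = 3.0 * 1.0 + 1.0 * 3.0
        assert num2 / 4.0 == pytest.approx(1.5)

    def test_empty_pixels_are_nan(self, truth):
        res = XylemFlowModel(truth.network, truth.noisy).fit("uniform")
        pmap = res.pixel_pressure_map()
        occupied = {px for px in res.model.vessel_pixel.values()
                    if px is not None}
        ii, jj = np.where(~np.isnan(pmap))
        assert set(zip(ii.tolist(), jj.tolist())) <= occupied


class TestNoiseAndRegistration:
    def test_noise_monotone_recovery_error(self):
        """Median recovery error grows with observation noise (in expectation)."""
        spec = SyntheticSpec(n_vessels=50)
        levels = (0.0, 0.1, 0.4)
        med = {l: [] for l in levels}
        for s in range(20):
            net, masks = generate_network(spec, 100 + s)
            bc, drops = generate_boundary_conditions(spec, net, 200 + s)
            for lvl in levels:
                t = forward_flow_map(net, bc, masks, lvl, (0.0, 0.0), 300 + s,
                                     drops=drops)
                res = XylemFlowModel(net, t.noisy).fit("per_group")
                err = np.abs(res.drops - drops)
                med[lvl].append(np.median(err))
        means = [np.mean(med[l]) for l in levels]
        assert means[0] < means[1] < means[2]

    def test_smoothing_softens_registration_jitter(self):
        """With the 5x5 averaging a 1-pixel jitter degrades NSE less than
        the same fit without averaging (the averaging's stated purpose)."""
        spec = SyntheticSpec(n_vessels=80, bc_mode="uniform",
                             uniform_drop_kpa=0.3, noise_sd_ug_s=0.0)
        net, masks = generate_network(spec, 77)
        bc, drops = generate_boundary_conditions(spec, net, 78)
        px = spec.pixel_size_um

        def objective_ratio(size):
            t0 = forward_flow_map(net, bc, masks, 0.0, (0.0, 0.0), 1)
            t1 = forward_flow_map(net, bc, masks, 0.0, (px, 0.0), 1)
            m0 = XylemFlowModel(net, t0.noisy, smoothing_size=size)
            m1 = XylemFlowModel(net, t1.noisy, smoothing_size=size)
            o0 = m0.fit("uniform").objective
            o1 = m1.fit("uniform").objective
            return o1 / max(o0, 1e-300)

        # relative degradation of the fit objective under jitter
        deg_smoothed = objective_ratio(5)
        deg_raw = objective_ratio(1)
        assert deg_smoothed < deg_raw


class TestResultsAPI:
    def test_summary_mentions_scenario_and_nse(self, truth):
        res = XylemFlowModel(truth.network, truth.noisy).fit("per_group")
        text = res.summary()
        assert "per_group" in text and "NSE" in text

    def test_vessel_table_columns(self, truth):
        res = XylemFlowModel(truth.network, truth.noisy).fit("uniform")
        tab = res.vessel_table()
        assert {"vessel", "group", "radius_um", "flow_ug_s",
                "gradient_mpa_m", "drop_kpa"} <= set(tab.columns)
        assert len(tab) == len(truth.network.vessel_ids)

    def test_solution_round_trip(self, truth):
        res = XylemFlowModel(truth.network, truth.noisy).fit("per_group")
        sol = res.solution()
        for v, q in res.vessel_flows.items():
            assert sol.vessel_top_flow[v] == pytest.approx(q, rel=1e-9,
                                                           abs=1e-12)
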