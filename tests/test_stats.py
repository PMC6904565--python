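"""Summary statistics, HP-deviation tests, ANOVA, flow shares."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xylemflow.stats import (StatsError, flow_redirection, flow_share_report,
                             flow_weighted_summary, hp_deviation_test,
                             hp_theoretical_flow, nse, transverse_gradients,
                             two_way_anova)


class TestNSE:
    def test_perfect_model(self, rng):
        o = rng.normal(size=50)
        assert nse(o, o) == 1.0

    def test_mean_model_is_zero(self, rng):
        o = rng.normal(size=50)
        assert nse(o, np.full_like(o, o.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self, rng):
        o = rng.normal(size=30)
        m = o + rng.normal(scale=0.3, size=30)
        expected = 1 - ((o - m) ** 2).sum() / ((o - o.mean()) ** 2).sum()
        assert nse(o, m) == pytest.approx(expected, rel=1e-12)

    def test_constant_observation_rejected(self):
        with pytest.raises(StatsError):
            nse([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_rescale_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        o = rng.normal(size=40)
        m = o + rng.normal(scale=0.5, size=40)
        assert nse(scale * o + shift, scale * m + shift) == pytest.approx(
            nse(o, m), rel=1e-9)


class TestWeightedSummary:
    def test_equal_weights_reduce_to_ordinary(self, rng):
        x = rng.normal(size=25)
        s = flow_weighted_summary(x, np.ones(25))
        assert s.mean == pytest.approx(x.mean(), rel=1e-12)
        assert s.sd == pytest.approx(x.std(ddof=1), rel=1e-12)

    def test_single_positive_weight_degenerate(self):
        with pytest.warns(RuntimeWarning):
            s = flow_weighted_summary([3.0, 5.0], [1.0, 0.0])
        assert s.mean == 3.0
        assert s.sd == 0.0

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=20)
        w = rng.random(20)
        s = flow_weighted_summary(x, w)
        mu = (w * x).sum() / w.sum()
        var = (w * (x - mu) ** 2).sum() / (w.sum() - (w ** 2).sum() / w.sum())
        assert s.mean == pytest.approx(mu, rel=1e-12)
        assert s.sd == pytest.approx(np.sqrt(var), rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(1e-3, 1e3))
    def test_weight_scale_invariance(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        w = rng.random(15) + 0.1
        s1 = flow_weighted_summary(x, w)
        s2 = flow_weighted_summary(x, c * w)
        assert s2.mean == pytest.approx(s1.mean, rel=1e-9)
        assert s2.sd == pytest.approx(s1.sd, rel=1e-9)

    def test_mean_within_range(self, rng):
        x = rng.normal(size=10)
        w = rng.random(10)
        s = flow_weighted_summary(x, w)
        assert x.min() <= s.mean <= x.max()

    def test_all_zero_weights_rejected(self):
        with pytest.raises(StatsError):
            flow_weighted_summary([1.0, 2.0], [0.0, 0.0])


class TestTransverseGradients:
    def test_uniform_map_zero_gradients(self):
        p = np.full((6, 6), 0.4)
        g = transverse_gradients(p, 78.0)
        assert g.n_pairs == 2 * 6 * 5
        assert np.all(g.gradients_mpa_m == 0.0)

    def test_unit_arithmetic(self):
        p = np.full((1, 2), np.nan)
        p[0, 0], p[0, 1] = 0.0, 0.078  # kPa, 78 um apart
        g = transverse_gradients(p, 78.0)
        assert g.n_pairs == 1
        assert g.gradients_mpa_m[0] == pytest.approx(1.0, rel=1e-12)

    def test_matches_bruteforce_neighbour_enumeration(self, rng):
        p = rng.normal(size=(7, 9))
        p[rng.random((7, 9)) < 0.3] = np.nan
        g = transverse_gradients(p, 50.0)
        expected = []
        for i in range(7):
            for j in range(9):
                if np.isnan(p[i, j]):
                    continue
                for di, dj in ((1, 0), (0, 1)):  # each unordered pair once
                    ii, jj = i + di, j + dj
                    if ii < 7 and jj < 9 and not np.isnan(p[ii, jj]):
                        expected.append(abs(p[i, j] - p[ii, jj]) / 50.0 * 1e3)
        assert g.n_pairs == len(expected)
        assert sorted(g.gradients_mpa_m) == pytest.approx(sorted(expected),
                                                          rel=1e-12)


class TestHPTheoreticalFlow:
    def test_fourth_power_ratio(self):
        assert hp_theoretical_flow(40.0, 0.07) / hp_theoretical_flow(20.0, 0.07) \
            == pytest.approx(16.0, rel=1e-12)

    def test_vanishes_at_zero_radius(self):
        assert hp_theoretical_flow(1e-6, 0.07) < 1e-20

    def test_consistent_with_lumen_resistance(self):
        from xylemflow.network import hp_lumen_resistance
        r, grad, length = 30.0, 0.069, 2500.0
        drop_kpa = grad * length * 1e-3
        expected = drop_kpa / hp_lumen_resistance(r, length)
        assert hp_theoretical_flow(r, grad) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        q = hp_theoretical_flow(np.linspace(10, 60, 51), 0.07)
        assert np.all(np.diff(q) > 0)


class TestHPDeviationTest:
    def test_on_curve_flows_give_null(self):
        r = np.linspace(15.0, 40.0, 60)
        q = hp_theoretical_flow(r, 0.07)
        results = hp_deviation_test(r, q, 0.07)
        assert results
        for res in results:
            assert res.t == 0.0 and res.p == 1.0

    def test_shifted_residuals_match_t_formula(self, rng):
        r = rng.uniform(20.0, 21.0, size=10)  # one window captures all
        noise = rng.normal(scale=0.05, size=10)
        c = 0.4
        q = hp_theoretical_flow(r, 0.07) + c + noise
        results = hp_deviation_test(r, q, 0.07, window_um=6.0)
        full = [res for res in results if res.n == 10]
        assert full
        resid = c + noise
        t_expected = resid.mean() / (resid.std(ddof=1) / np.sqrt(10))
        assert full[0].t == pytest.approx(t_expected, rel=1e-9)
        assert full[0].df == 9

    def test_detects_suppression_threshold(self):
        """Flows suppressed above a radius threshold: p crosses 0.05 nearby."""
        rng = np.random.default_rng(42)
        r = rng.uniform(10.0, 60.0, size=400)
        q = hp_theoretical_flow(r, 0.07)
        q *= np.where(r > 35.0, 0.45, 1.0)       # suppress wide vessels
        q += rng.normal(scale=0.01 * np.maximum(q, 1e-6), size=400)
        results = hp_deviation_test(r, q, 0.07)
        sig = [res.center_radius_um for res in results if res.p < 0.05]
        assert sig
        assert min(r for r in sig if r > 20) == pytest.approx(35.0, abs=4.0)

    def test_null_calibration_rejection_rate(self):
        """Under the null the 5% level rejects ~5% of the time (1000 seeds)."""
        rejections = 0
        n_sims = 1000
        for s in range(n_sims):
            rng = np.random.default_rng(10_000 + s)
            r = rng.uniform(17.0, 23.0, size=25)
            q = hp_theoretical_flow(r, 0.07) + rng.normal(scale=0.3, size=25)
            results = hp_deviation_test(r, q, 0.07, window_um=6.0,
                                        step_um=1.0)
            centre = [res for res in results if res.n == 25]
            assert centre
            if centre[0].p < 0.05:
                rejections += 1
        rate = rejections / n_sims
        # binomial 3-sigma band around 0.05 for n=1000
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_sims) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestTwoWayAnova:
    def test_null_balanced_design_small_f(self, rng):
        n = 40
        radial = ["inner", "outer"] * (n // 2)
        tang = ["dorsal_ventral"] * (n // 2) + ["lateral"] * (n // 2)
        values = rng.normal(size=n)  # no effect anywhere
        table = two_way_anova(values, radial, tang)
        assert set(table.index) >= {"radial", "tangential", "interaction"}
        assert (table.loc[["radial", "tangential"], "PR(>F)"] > 0.001).all()

    def test_balanced_known_effect_matches_closed_form(self):
        # balanced 2x2, n=4 per cell, pure radial main effect of size 2
        values, radial, tang = [], [], []
        base = {("inner", "dorsal_ventral"): 0.0, ("inner", "lateral"): 0.0,
                ("outer", "dorsal_ventral"): 2.0, ("outer", "lateral"): 2.0}
        eps = [0.1, -0.1, 0.05, -0.05]
        for (r, t), mu in base.items():
            for e in eps:
                values.append(mu + e)
                radial.append(r)
                tang.append(t)
        table = two_way_anova(values, radial, tang)
        values = np.array(values)
        n = len(values)
        # closed-form balanced main-effect SS: n_level * sum (level mean - grand)^2
        mean_in = values[np.array(radial) == "inner"].mean()
        mean_out = values[np.array(radial) == "outer"].mean()
        ss_a = sum(8 * (m - values.mean()) ** 2
                   for m in (mean_in, mean_out))
        cell_means = {k: np.mean([v for v, r, t in zip(values, radial, tang)
                                  if (r, t) == k]) for k in base}
        ss_err = sum((v - cell_means[(r, t)]) ** 2
                     for v, r, t in zip(values, radial, tang))
        f_expected = (ss_a / 1) / (ss_err / (n - 4))
        assert table.loc["radial", "F"] == pytest.approx(f_expected, rel=1e-9)

    def test_single_factor_degenerate_rejected(self):
        with pytest.raises(StatsError):
            two_way_anova([1, 2, 3, 4], ["inner"] * 4,
                          ["dorsal_ventral", "lateral"] * 2)

    def test_empty_cell_rejected(self):
        with pytest.raises(StatsError):
            two_way_anova([1, 2, 3, 4, 5, 6],
                          ["inner", "inner", "inner", "inner", "outer", "outer"],
                          ["dorsal_ventral", "dorsal_ventral", "lateral",
                           "lateral", "dorsal_ventral", "dorsal_ventral"])


class TestFlowShares:
    def test_single_domain_fraction_one(self):
        rep = flow_share_report({0: 1.0, 1: 2.0}, {0: "inner", 1: "inner"})
        assert rep["flow_fraction"].tolist() == [1.0]

    def test_two_equal_domains(self):
        rep = flow_share_report({0: 1.5, 1: 1.5}, {0: "inner", 1: "outer"})
        assert rep["flow_fraction"].tolist() == pytest.approx([0.5, 0.5])

    def test_three_domain_spreadsheet_oracle(self):
        flows = {0: 2.0, 1: 3.0, 2: 5.0, 3: 10.0}
        doms = {0: "a", 1: "a", 2: "b", 3: "c"}
        grads = {0: 0.05, 1: 0.05, 2: 0.1, 3: 0.2}
        areas = {"a": 2.0, "b": 1.0, "c": 1.0}
        rep = flow_share_report(flows, doms, areas, grads).set_index("domain")
        assert rep.loc["a", "flow_fraction"] == pytest.approx(0.25)
        assert rep.loc["b", "flow_fraction"] == pytest.approx(0.25)
        assert rep.loc["c", "flow_fraction"] == pytest.approx(0.5)
        # domain a: 5 ug/s, fw gradient 0.05, area 2 mm^2
        assert rep.loc["a", "specific_conductivity"] == pytest.approx(
            5e-9 / (0.05 * 2e-6), rel=1e-9)
        assert rep["flow_fraction"].sum() == pytest.approx(1.0)

    def test_unlabelled_vessel_rejected(self):
        with pytest.raises(StatsError):
            flow_share_report({0: 1.0, 1: 1.0}, {0: "inner"})


class TestFlowRedirection:
    def test_identical_fits_nothing_redirected(self):
        flows = {0: 1.0, 1: 2.0}
        radii = {0: 10.0, 1: 30.0}
        red = flow_redirection(flows, dict(flows), radii)
        assert red.redirected_share == 0.0

    def test_two_vessel_swap(self):
        a = {0: 3.0, 1: 1.0}
        b = {0: 2.0, 1: 2.0}
        radii = {0: 40.0, 1: 10.0}
        red = flow_redirection(a, b, radii)
        assert red.redirected_share == pytest.approx(1.0 / 4.0)
        assert red.wide_loss_fraction == pytest.approx(1.0 / 3.0)

    def test_gains_balance_losses_when_totals_conserved(self, rng):
        n = 30
        a = {v: float(rng.random() + 0.1) for v in range(n)}
        delta = rng.normal(size=n)
        delta -= delta.mean()  # conserve the total
        b = {v: a[v] + delta[v] for v in range(n)}
        red = flow_redirection(a, b, {v: 20.0 for v in range(n)})
        gains = sum(c for c in red.per_vessel_change.values() if c > 0)
        losses = -sum(c for c in red.per_vessel_change.values() if c < 0)
        assert gains == pytest.approx(losses, rel=1e-9)

    def test_mismatched_networks_rejected(self):
        with pytest.raises(StatsError):
            flow_redirection({0: 1.0}, {1: 1.0}, {0: 1.0})

    def test_ledger_oracle_random_case(self, rng):
        n = 12
        a = {v: float(rng.random()) for v in range(n)}
        b = {v: float(rng.random()) for v in range(n)}
        radii = {v: float(rng.uniform(10, 50)) for v in range(n)}
        red = flow_redirection(a, b, radii)
        mean_r = np.mean(list(radii.values()))
        gains = sum(max(b[v] - a[v], 0.0) for v in range(n))
        assert red.redirected_share == pytest.approx(
            gains / sum(b.values()), rel=1e-12)
        wide = [v for v in range(n) if radii[v] > mean_r]
        losses = sum(max(a[v] - b[v], 0.0) for v in wide)
        assert red.wide_loss_fraction == pytest.approx(
            losses / sum(a[v] for v in wide), rel=1e-12)
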