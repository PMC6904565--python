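"""Summary statistics and hypothesis tests on fitted flow solutions.

Covers model-fit evaluation (Nash–Sutcliffe efficiency), flow-weighted
summaries with reliability-weight standard deviations, transverse
pressure-gradient distributions between adjacent pixels, comparison of
vessel flows to the idealized Hagen–Poiseuille radius–flow curve (sliding
radius-window t-tests), two-way ANOVA across xylem domains, per-domain flow
shares, and the redistribution of flow between two fitted scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import units
from .network import hp_lumen_resistance, specific_conductivity


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Nash–Sutcliffe efficiency
# ---------------------------------------------------------------------------

def nse(observed, modelled) -> float:
    """Nash–Sutcliffe efficiency, 1 − Σ(o−m)²/Σ(o−ō)².

    Ranges from −∞ to 1; 0 means the model predicts no better than the
    observation mean, 1 a perfect match.  Undefined (error) for constant
    observations.
    """
    o = np.asarray(observed, dtype=float).ravel()
    m = np.asarray(modelled, dtype=float).ravel()
    if o.shape != m.shape:
        raise StatsError("observed and modelled lengths differ")
    if o.size < 2:
        raise StatsError("NSE needs at least two observations")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0:
        raise StatsError("NSE undefined for constant observations")
    return 1.0 - float(np.sum((o - m) ** 2)) / denom


# ---------------------------------------------------------------------------
# Flow-weighted summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedSummary:
    mean: float
    sd: float
    n: int
    weight_total: float


def flow_weighted_summary(values, weights) -> WeightedSummary:
    """Weighted mean and SD with reliability weights.

    mean = Σwx/Σw; variance = Σw(x−μ)² / (Σw − Σw²/Σw).  Scale-invariant in
    the weights.  With all weight on a single value the SD is reported as 0
    with a warning (the reliability-weight denominator vanishes).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise StatsError("values and weights lengths differ")
    if np.any(w < 0):
        raise StatsError("weights must be non-negative")
    sw = w.sum()
    if sw <= 0:
        raise StatsError("at least one positive weight required")
    mean = float((w * x).sum() / sw)
    denom = sw - (w ** 2).sum() / sw
    if denom <= 0:
        warnings.warn("weighted SD undefined for effectively one observation; "
                      "reporting 0", RuntimeWarning, stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.sqrt((w * (x - mean) ** 2).sum() / denom))
    return WeightedSummary(mean=mean, sd=sd, n=int((w > 0).sum()),
                           weight_total=float(sw))


# ---------------------------------------------------------------------------
# Transverse gradients
# ---------------------------------------------------------------------------

@dataclass
class GradientDistribution:
    gradients_mpa_m: np.ndarray
    n_pairs: int
    mean: float
    median: float


def transverse_gradients(pressure_map: np.ndarray,
                         pixel_size_um: float) -> GradientDistribution:
    """Pressure gradients between 4-connected adjacent non-empty pixels.

    ``pressure_map`` holds per-pixel imposed pressure drops in kPa with NaN
    marking empty pixels.  Every unordered neighbour pair is counted once;
    the gradient is |ΔP| / pixel distance, in MPa m⁻¹.
    """
    p = np.asarray(pressure_map, dtype=float)
    grads = []
    for axis in (0, 1):
        a = p[:-1, :] if axis == 0 else p[:, :-1]
        b = p[1:, :] if axis == 0 else p[:, 1:]
        ok = ~np.isnan(a) & ~np.isnan(b)
        grads.append(np.abs(a[ok] - b[ok]))
    diffs = np.concatenate(grads) if grads else np.array([])
    g = units.pressure_gradient_mpa_m(diffs, pixel_size_um)
    return GradientDistribution(
        gradients_mpa_m=g, n_pairs=int(g.size),
        mean=float(g.mean()) if g.size else np.nan,
        median=float(np.median(g)) if g.size else np.nan)


# ---------------------------------------------------------------------------
# Hagen–Poiseuille reference curve and deviation test
# ---------------------------------------------------------------------------

def hp_theoretical_flow(radius_um, gradient_mpa_m: float,
                        eta_mpa_s: float = units.ETA_WATER_MPA_S,
                        rho_kg_m3: float = units.RHO_WATER_KG_M3):
    """Idealized HP mass flow (µg s⁻¹) of an open lumen at a given gradient.

    Q(r) = ρπr⁴·∇P/(8η); computed through the lumen-resistance function so
    the two stay consistent by construction.
    """
    if gradient_mpa_m <= 0:
        raise StatsError("gradient must be positive")
    r = np.asarray(radius_um, dtype=float)
    length = 1000.0  # cancels: ΔP over L divided by resistance of L
    drop_kpa = gradient_mpa_m * length / units.KPA_PER_UM_TO_MPA_PER_M
    res = np.array([hp_lumen_resistance(ri, length, eta_mpa_s, rho_kg_m3)
                    for ri in np.atleast_1d(r)])
    q = drop_kpa / res
    return q if np.ndim(radius_um) else float(q[0])


@dataclass(frozen=True)
class HPDeviationResult:
    center_radius_um: float
    window_um: float
    n: int
    t: float
    p: float
    df: int
    mean_residual: float


def hp_deviation_test(radii_um, flows_ug_s, gradient_mpa_m: float,
                      window_um: float = 6.0, step_um: float = 1.0,
                      eta_mpa_s: float = units.ETA_WATER_MPA_S,
                      rho_kg_m3: float = units.RHO_WATER_KG_M3
                      ) -> list[HPDeviationResult]:
    """Sliding-window t-test of vessel-flow residuals against the HP curve.

    Residuals are observed minus theoretical flow at each vessel's radius; in
    each window (centred on integer-µm steps across the radius range) a
    two-tailed one-sample t-test of mean 0 is performed.  Windows with fewer
    than two vessels are skipped with a warning.  Residuals that are exactly
    zero-variance give t = 0, p = 1.
    """
    r = np.asarray(radii_um, dtype=float)
    q = np.asarray(flows_ug_s, dtype=float)
    if r.shape != q.shape:
        raise StatsError("radii and flows lengths differ")
    resid = q - hp_theoretical_flow(r, gradient_mpa_m, eta_mpa_s, rho_kg_m3)
    centers = np.arange(np.floor(r.min()), np.ceil(r.max()) + step_um / 2, step_um)
    out = []
    skipped = 0
    for c in centers:
        sel = np.abs(r - c) <= window_um / 2
        n = int(sel.sum())
        if n < 2:
            skipped += 1
            continue
        x = resid[sel]
        if np.ptp(x) == 0 and x[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_1samp(x, 0.0)
        out.append(HPDeviationResult(center_radius_um=float(c),
                                     window_um=window_um, n=n,
                                     t=float(t), p=float(p), df=n - 1,
                                     mean_residual=float(x.mean())))
    if skipped:
        warnings.warn(f"{skipped} windows with <2 vessels skipped",
                      RuntimeWarning, stacklevel=2)
    return out


def hp_deviation_window_scan(radii_um, flows_ug_s, gradient_mpa_m,
                             windows_um=(6.0, 8.0, 10.0, 12.0),
                             **kw) -> pd.DataFrame:
    """Robustness scan of the deviation test over window widths."""
    rows = []
    for w in windows_um:
        for res in hp_deviation_test(radii_um, flows_ug_s, gradient_mpa_m,
                                     window_um=w, **kw):
            rows.append({"window_um": w, "center_radius_um": res.center_radius_um,
                         "n": res.n, "t": res.t, "p": res.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-way ANOVA across domains
# ---------------------------------------------------------------------------

def two_way_anova(values, radial, tangential) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (Type II SS) on an unbalanced layout.

    ``radial`` (inner/outer) and ``tangential`` (dorsal_ventral/lateral) are
    categorical factor labels.  Returns F, df and p per factor and for the
    interaction.  Raises on empty factor cells.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "radial": list(radial), "tangential": list(tangential)})
    counts = df.groupby(["radial", "tangential"], observed=True).size()
    levels_r = df["radial"].nunique()
    levels_t = df["tangential"].nunique()
    if levels_r < 2 or levels_t < 2:
        raise StatsError("both factors need at least two levels")
    if len(counts) < levels_r * levels_t:
        raise StatsError("empty factor cell in two-way ANOVA layout")
    if (counts < 2).any():
        raise StatsError("each factor cell needs at least two observations")
    fit = smf.ols("value ~ C(radial) * C(tangential)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index={
        "C(radial)": "radial", "C(tangential)": "tangential",
        "C(radial):C(tangential)": "interaction", "Residual": "residual"})
    return table


# ---------------------------------------------------------------------------
# Flow shares and redistribution
# ---------------------------------------------------------------------------

def flow_share_report(vessel_flows: dict[int, float],
                      vessel_domains: dict[int, str],
                      domain_areas_mm2: dict[str, float] | None = None,
                      vessel_gradients: dict[int, float] | None = None
                      ) -> pd.DataFrame:
    """Per-domain vessel counts, flow fractions and specific conductivities.

    ``vessel_domains`` must assign every vessel to exactly one domain label
    (a partition).  Conductivities are reported when per-domain areas and
    per-vessel gradients are supplied; the gradient used is the flow-weighted
    mean within the domain.
    """
    vessels = sorted(vessel_flows)
    missing = [v for v in vessels if v not in vessel_domains]
    if missing:
        raise StatsError(f"vessels without a domain label: {missing[:5]}")
    total = sum(vessel_flows.values())
    rows = []
    for dom in sorted(set(vessel_domains[v] for v in vessels)):
        members = [v for v in vessels if vessel_domains[v] == dom]
        flow = sum(vessel_flows[v] for v in members)
        row = {"domain": dom, "n_vessels": len(members),
               "vessel_fraction": len(members) / len(vessels),
               "flow_ug_s": flow,
               "flow_fraction": flow / total if total else np.nan}
        if domain_areas_mm2 is not None and vessel_gradients is not None:
            w = np.array([max(vessel_flows[v], 0.0) for v in members])
            g = np.array([vessel_gradients[v] for v in members])
            if w.sum() > 0 and dom in domain_areas_mm2:
                gmean = float((w * g).sum() / w.sum())
                row["flow_weighted_gradient_mpa_m"] = gmean
                row["specific_conductivity"] = (
                    specific_conductivity(flow, gmean, domain_areas_mm2[dom])
                    if gmean > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FlowRedirection:
    per_vessel_change: dict[int, float]
    redirected_share: float
    wide_loss_fraction: float
    mean_radius_um: float


def flow_redirection(flows_a: dict[int, float], flows_b: dict[int, float],
                     radii_um: dict[int, float],
                     mean_radius_um: float | None = None) -> FlowRedirection:
    """Flow redistribution between two fitted scenarios on one network.

    change = flow_B − flow_A per vessel.  The redirected share is the sum of
    positive changes over the scenario-B total flow; the wide-vessel loss
    fraction is the summed losses of vessels wider than the mean radius over
    their scenario-A flow.
    """
    if set(flows_a) != set(flows_b):
        raise StatsError("the two fits cover different vessel sets")
    if set(radii_um) != set(flows_a):
        raise StatsError("radius table does not match the vessel set")
    if mean_radius_um is None:
        mean_radius_um = float(np.mean(list(radii_um.values())))
    change = {v: flows_b[v] - flows_a[v] for v in flows_a}
    total_b = sum(flows_b.values())
    gains = sum(c for c in change.values() if c > 0)
    redirected = gains / total_b if total_b else np.nan
    wide = [v for v in flows_a if radii_um[v] > mean_radius_um]
    wide_losses = sum(-change[v] for v in wide if change[v] < 0)
    wide_flow_a = sum(flows_a[v] for v in wide)
    wide_loss = wide_losses / wide_flow_a if wide_flow_a else np.nan
    return FlowRedirection(per_vessel_change=change,
                           redirected_share=redirected,
                           wide_loss_fraction=wide_loss,
                           mean_radius_um=mean_radius_um)
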