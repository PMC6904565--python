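# Methods

## Flow model

A stem segment's xylem is represented as a resistance graph. Nodes are
points inside vessel lumina — placed at the sample's bottom (z = 0) and top
(z = L) faces and wherever an inter-vessel connection attaches — plus two
auxiliary nodes per vessel relay. Edges are:

* **Lumen segments.** Each axial interval of a vessel carries the
  Hagen–Poiseuille resistance of a cylinder, converted to mass-flow units:
  `R = 8 η L / (π r⁴ ρ)`. Internally pressures are kPa, flows µg s⁻¹ and
  lengths µm, so `R` is carried in kPa/(µg s⁻¹); all SI conversions live in
  `units.py`. Each vessel is a simple chain in z; a segment uses a single
  radius (the generator emits constant per-vessel radii; data-derived
  networks may supply per-interval mean radii).
* **Pit fields.** An inter-vessel pit field of membrane area `A` (mm²) has
  resistance `r_pit / A` with the grapevine area-specific constant
  `r_pit = 168`. The constant's published unit (MPa m⁻¹ s⁻¹) is not the
  conventional unit of an area-specific pit resistance; we keep the number
  and interpret the units so that `r_pit / A` (A in m²) is a volumetric
  resistance in MPa s m⁻³, which makes the downstream arithmetic
  dimensionally consistent. In working units the conversion collapses to
  `R = r_pit / (A_mm² · ρ)`. With the mean membrane area of 0.015 mm² this
  gives ≈ 11.2 kPa/(µg s⁻¹), about 200× the lumen resistance of a typical
  20 µm vessel over the 3.3 mm sample — pit membranes dominate transverse
  resistance, as they should.
* **Vessel relays.** A relay is modelled explicitly as relay-pit →
  relay-lumen → relay-pit in series; the relay lumen is an HP element whose
  diameter is the relay diameter and whose length is the transverse
  inter-vessel distance (floored at 1 µm).

Steady flow under Dirichlet boundary pressures is the solution of the
Kirchhoff node-balance system, assembled as a sparse weighted Laplacian and
solved by a sparse direct factorization. Components containing no
pressure-assigned node are rejected with an error naming the nodes rather
than silently zeroed. Sign convention: positive flow is upward (+z); a
vessel's axial gradient is `(P_bottom − P_top)/L` in MPa m⁻¹.

Fluid constants default to water at 20 °C (η = 1.002 × 10⁻⁹ MPa s,
ρ = 998 kg m⁻³) and are configurable per network.

## Vessel groups and boundary conditions

Vessel groups are the connected components of the vessel-level graph whose
edges are inter-vessel connections (pit fields and relays); solitary vessels
are singleton groups, and the numbering (by smallest member id) is invariant
to edge order. The bottom face carries a single reference pressure
(default 0 kPa); top pressures are either uniform or set independently per
group, broadcast to every member vessel's top node. Because groups are
hydraulically independent and the system is linear, one unit-drop solve
yields the full sensitivity of every vessel flow (and hence of the model
raster) to the per-group drop vector.

## Comparing model and observation

Vessel top-slice flows are summed into the pixels of the observation grid
by top-centroid assignment (configurable to approximate area-weighted
splitting); a rigid in-plane registration offset can be applied. Residuals
(model − observed) on unmasked pixels are averaged over a 5×5-pixel moving
window before summing squares; the window tolerates the small tissue
deformations expected between imaging modalities. At raster borders and
mask edges the window average is normalized by the number of unmasked
in-window pixels. Observed pixels containing no modelled vessel contribute
residuals with model value 0 by default (configurable), since an empty model
pixel under observed flow is genuine disagreement.

Scenarios:

* **uniform** — flows are linear in the single drop `d`, so the minimizer of
  `‖W(d·m − o)‖²` is the closed form `d* = ⟨Wm, Wo⟩/⟨Wm, Wm⟩` from one
  unit-drop solve (`W` is the smoothing operator, `m` the unit raster).
* **uniform-masked** — the same, restricted to the inner xylem domain.
* **total-flow** — `d = Q_obs / Q_unit`, exact, no iteration.
* **per-group** — bound-constrained linear least squares in the drop vector
  (`drop ≥ 0` by default, consistent with upward sap flow and with fitted
  top pressures being non-positive). Solved with the trust-region-reflective
  algorithm as implemented for linear problems in
  `scipy.optimize.lsq_linear(method="trf")`. A general nonlinear TRF with a
  warm start was tried first and converged poorly on this ill-conditioned
  problem (column norms scale with r⁴ and span ~6 decades); the linear TRF
  solver reaches machine-precision optima in a handful of iterations, so it
  is used and no initial iterate is needed. Convergence tolerance 1e-10,
  500-iteration cap, with a diagnostic error carrying the last iterate on
  failure. Groups whose smoothed unit response vanishes on all unmasked
  pixels are structurally unidentifiable; they are clamped to zero drop and
  reported.

Fit quality is summarized by the Nash–Sutcliffe efficiency
`1 − Σ(o−m)²/Σ(o−ō)²` over unmasked raw (unsmoothed) pixels, the windowed
objective, and the relative total-flow error.

Identifiability caveat: two groups whose vessels fall in exactly the same
pixels are mutually indistinguishable at the raster; at default synthetic
density this affects ~5% of groups, which is why recovery criteria are
stated on the median (and on observable groups).

## Statistics

* **Flow-weighted summaries** use weighted means with the reliability-weight
  variance `Σw(x−μ)²/(Σw − Σw²/Σw)`; equal weights reduce exactly to the
  ordinary mean and sample SD, and the result is invariant to rescaling the
  weights. A single effectively-weighted observation yields SD 0 with a
  warning.
* **Transverse gradients** are `|ΔP|/distance` between 4-connected non-empty
  pixels of the flow-weighted pixel pressure map, each unordered pair counted
  once. Diagonal neighbours are excluded; "adjacent" is taken as
  edge-adjacency, a documented convention.
* **HP deviation test**: residuals between per-vessel flows and the HP curve
  at the flow-weighted mean gradient are tested for zero mean in sliding
  radius windows (default width 6 µm, centred at 1 µm steps, two-tailed
  one-sample t-test; windows with fewer than two vessels are skipped). A
  window-width scan up to 12 µm is exposed as a robustness utility.
  Zero-variance zero residuals report t = 0, p = 1.
* **Two-way ANOVA** across radial (inner/outer) and tangential
  (dorsal-ventral/lateral) domains uses fixed effects with Type II sums of
  squares — appropriate for the unbalanced layouts these designs produce —
  via an OLS fit; empty or singleton cells raise errors.
* **Specific conductivity** is total flow over (flow-weighted mean axial
  gradient × domain cross-sectional area), reported in
  kg m⁻¹ MPa⁻¹ s⁻¹.
* **Flow redirection** between two fitted scenarios reports per-vessel flow
  changes, the share of total flow redirected (sum of positive changes over
  the richer scenario's total) and the loss fraction of vessels wider than
  the mean radius relative to their baseline flow.

## Synthetic generator

The generator emulates the census of a first-year grapevine internode
(~10.4 mm² xylem annulus, ~500 vessels) and is a pure function of
(spec, seed):

* **Geometry.** Vessel centres are dart-thrown into the annulus with a
  minimum 2 µm wall between lumina. The tangential sector
  (two dorsal/ventral wedges of 99° vs the lateral remainder, ≈55% of area)
  and the diameter are drawn *before* the position search, so packing
  rejections do not bias the realized diameter distribution. Diameters are
  lognormal, moment-matched to 44 ± 34 µm (dorsal/ventral) and 30 ± 20 µm
  (lateral); the pooled draw reproduces ≈37.7 µm mean. The lognormal choice
  gives positive support with the heavy right tail these distributions show.
* **Connectivity.** Vessel pairs connect with probability
  `p₀ exp(−gap/λ)` (p₀ = 0.9, λ = 40 µm on the lumen gap), and a connected
  pair carries 1 + Poisson(1.3) distinct pit fields at independent heights —
  real pit fields repeat between the same pair, which is how ~490
  connections coexist with only ~180 group merges. ~17% of connections are
  relays (diameter lognormal 10 ± 11 µm, clipped to 2–40 µm; relay pit areas
  lognormal 0.004 mm² with CV 3). Pit areas are lognormal 0.015 ± 0.012 mm².
  Defaults yield ~440–520 connections, ~300 groups and ~210 solitary vessels
  per 500-vessel realization.
* **Truth pressures.** Uniform (default drop 0.055 kPa) or per-group drops
  drawn uniformly from [0, 0.78] kPa.
* **Observation.** The solved vessel flows are binned on a 78 µm grid
  covering the stem; Gaussian noise (default SD 0.05 µg s⁻¹) is added to
  nonzero pixels, and an optional rigid jitter displaces the binning to
  emulate registration error. The noiseless map and the truth drops are kept
  alongside.

What the generator does **not** emulate: MRI physics (partial volume,
signal-dependent noise), vessel tortuosity and endings (all synthetic
vessels are open top-to-bottom, as in the reference sample), within-vessel
radius variation, and spatially correlated noise. Passing recovery tests
therefore demonstrates correctness of the solver/fit machinery under the
stated noise model, not robustness to every artefact of real imaging data.

The `constricted_pair` harness builds matched networks in which vessels of
above-average radius carry a narrow serial element in their apical tenth
(the truth) or not (the fit network). Fitting the unconstricted network to
observations generated from the constricted one reproduces the redirection
mechanism: per-group fitted pressures absorb the unseen serial resistances,
wide-vessel gradients fall below narrow-vessel gradients, and the
wide-vessel flow share drops below the homogeneous-gradient HP prediction.

## Toy analogue networks

The five-vessel Ohm's-law analogue (two 0.25-unit lumen elements per vessel,
1-unit walls, end pressures 1/0) is stored as a versioned fixture
(`data/fig8_edges.tsv`). Its wiring is not derivable from the published
text alone; it was reconstructed by exhaustively enumerating wall placements
over the vessel nodes and accepting the unique wiring (up to a top/bottom
mirror) that reproduces, at the printed 2-decimal precision, all six
published quantities — the three panel-c element flows (0.28, 0.46, 0.62)
and the three observed:theoretical conductance ratios (0.41, 0.43, 0.31) —
together with the described panel ordering of central-vessel flows. The
six quantities serve as the transcription's acceptance gate: a mismatch
would indicate a transcription error, to be revisited before suspecting the
solver. Panel b doubles every bottom-right lumen element and panel c
additionally halves every central lumen element, applying the per-vessel
phrasing of the construction to all of a vessel's elements.

The theoretical conductance extrapolates the lumina visible in the
half-to-three-quarters segment (downstream half of the central vessel,
upstream halves of both right-hand vessels): their conductances are summed
and divided by 4 to scale the quarter-length segment to the whole network;
observed conductance is total flow over the end-to-end pressure difference.

`to_vessel_network` re-expresses the analogue with physical radii and pit
areas chosen so each element's resistance in kPa/(µg s⁻¹) equals its
normalized value, letting the production solver and the file formats be
exercised against the same printed numbers.

## Numerical choices

* Sparse direct solve (`scipy.sparse.linalg.spsolve`) on the reduced
  Laplacian; dense-oracle equivalence is enforced in tests at 1e-9 relative
  on ≤50-node networks.
* Interior-node conservation is asserted at 1e-9 of the node's total
  incident flow, with an epsilon floor of 1e-6 × total flow for nodes whose
  flows are numerically zero.
* The 5×5 window is a uniform separable filter; the mask-aware form divides
  the windowed sum of included residuals by the included count.
* Rasters are written as float32 TIFF or text CSV with `%.17g` floats, so
  write→read round trips are bit-exact for the stored precision.
* Pixel grids are row-major from the top-left, 0-based, with physical µm
  coordinates (origin at the stem centre for synthetic grids); a point maps
  to the pixel containing it by floor division.

## Problem sizes used in the checked examples

The test suite exercises 500-vessel networks for the full-scale recovery
check and the end-to-end pipeline, 50–120-vessel networks for property
tests, ≤16-group instances for the exhaustive active-set oracle of the
bounded least-squares fit, and 1000 simulations of 20–25 vessels for the
null calibration of the HP deviation test. These sizes were chosen to match
the scale of the emulated dataset where it matters (one full-size recovery
per run) while keeping the rest of the suite quick to iterate on.

## Known limitations

* The printed pit-resistance constant is used verbatim with a documented
  unit interpretation (above); if a different convention was intended, all
  pit resistances scale by a common factor and fitted pressures rescale
  accordingly, leaving NSE-type diagnostics unchanged.
* Per-vessel (sub-group) pressure fitting, joint registration-and-pressure
  optimization, embolism and capacitive (time-dependent) effects are out of
  scope.
* Uncertainty on fitted pressures is available only as seed-replicate spread
  via the recovery experiment, not as analytic standard errors: the bound
  constraints and raster identifiability structure make naive OLS errors
  misleading.
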