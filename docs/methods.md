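# Methods

This note describes the models and procedures the package implements,
the assumptions behind them, the parameters that matter, and what the
synthetic experiments do and do not demonstrate.

## Pollen source term

Pollen emission is modelled in two stages per grid cell.

**Development.** Ready-to-fly pollen matures under accumulated heat.
The heat sum H is the running sum of max(T − T_co, 0) per step from a
taxon-specific start day — on daily mean temperature (K day) for birch
and olive, on hourly mean temperature (K hour) for alder. Flowering
starts around a mapped threshold H_fs and ends after the cell has
released its seasonal total. The development rate is

    d(p_rdy)/dt = S φ (ξ N_tot) · (T − T_co)/ΔH · h(T − T_co)
                  · p_fs(H/H_fs) · p_fe(D),

with S the cell area, φ the tree-cover fraction, N_tot the
climatological seasonal release per unit crown area, ΔH = H_fe − H_fs,
and h the Heaviside function. `p_fs` is a piecewise-linear ramp over the
threshold uncertainty band (0 below (1−δ_H)·H_fs, 1 above (1+δ_H)·H_fs,
0.5 at the threshold); `p_fe` ramps from 1 to 0 over the release band
(1−δ_N, 1+δ_N) and hard-stops development beyond it. The exact closed
forms of the ramp interiors and the wind factor are a design choice
here; the endpoints (thresholds, uncertainty bands, maximum scaling) are
fixed by the taxon tables. Each form sits behind its own function so
alternate shapes can be swapped.

Two implementation details matter:

- the end ramp is evaluated on the cumulative *potential* development
  fraction D (the fraction that would have been released had nothing
  ended the season), and the ramp is integrated in closed form within
  each time step. Read as a population of trees whose individual
  season-end thresholds are uniform over (1−δ_N, 1+δ_N), the aggregate
  seasonal total then equals S·φ·ξ·N_tot *exactly* — evaluating the ramp
  on the realized released fraction instead would overshoot the budget
  by up to δ_N, and sampling it at step boundaries would leak several
  percent of discretization error;
- the released fraction is tracked against ξ·N_tot, not N_tot, so the
  phenological timing is independent of ξ and the full-season emission
  field is exactly proportional to ξ per cell. The assimilation depends
  on this linearity.

**Release.** Whenever ready pollen is available, a fraction
(1 − e^(−Δt/τ)) of the stock is released per step, amplified by wind and
convection — f_wind = 1 + (max−1)(1 − e^(−(U+w*)/U_sat)), saturating at
the taxon's maximum scaling — and suppressed linearly to zero between
the humidity thresholds (q_low, q_high) and the precipitation thresholds
(0, P_high). The released amount is capped at the available stock (the
wind amplification could otherwise exceed it for Δt ≫ τ). Emission that
weather blocks stays in the stock for later steps.

The three shipped parameter sets (alder, birch, olive) live in YAML
files under `pollenda/data/`, one field per coefficient: cut-offs 4 /
3.5 / 0 °C, N_tot 10⁸ / 10⁸ / 3·10⁸ grains m⁻² yr⁻¹, τ = 1 h, humidity
thresholds 50/80, 50/90, 50/80 %, P_high = 0.5 mm h⁻¹, wind saturation
5 m s⁻¹ with maximum scaling 1.5, grain diameters 22 / 22 / 28 μm at
800 kg m⁻³, uncertainty bands δ_H = δ_N = 0.10, and the season-wide
assimilation windows (alder 5 Jan – 31 May, birch 10 Mar – 1 Jul, olive
1 Apr – 31 Jul).

## Transport stand-in

The full 3-D dispersion model is out of scope; transport is a declared
2-D stand-in built on the assumption that pollen stays within a
well-mixed boundary layer (mixing height 1000 m). Emission flux is
converted to a concentration tendency, advected with first-order upwind
fluxes on the divergence-free synthetic wind, diffused explicitly
(K = 5000 m² s⁻¹), and removed at a first-order deposition rate given by
Stokes settling of the grain divided by the mixing height (≈ 1.2·10⁻⁵
s⁻¹ for birch — a one-day residence time). Lateral boundaries are open
for outflow with zero inflow. Each meteorology step is one sparse
substep matrix applied a CFL-limited number of times (CFL ≤ 0.8), so the
forward model is an explicit linear operator and the adjoint — the
transposed substeps applied in reverse — satisfies the dot-product
identity to round-off. Station footprints are adjoint runs seeded with
the station's bilinear sampling kernel over the window.

The scheme's numerical diffusion is the price of its simplicity:
first-order upwind at 1° cells smears plumes on scales comparable to the
physical transport itself. The inversion experiments therefore run at
0.5° cells, where the smearing no longer dominates the station-scale
signal. Cell geometry uses a constant metric at the domain-mean
latitude; the operator's conserved quantity under closed conditions is
the plain concentration sum in that metric.

## Observations and screening

Daily station values are bilinear samples of the near-surface field.
Before assimilation they are averaged into non-overlapping 2-day bins
anchored at the assimilation-window start (a bin with one valid day
keeps that day's value; a bin with none is invalid). The averaging
suppresses day-to-day sampling noise the season-total inversion cannot
fit but would be penalized for; a Monte-Carlo experiment in the test
suite confirms the correlation gain. Station-years must have ≥ 30 valid
days in the window, ≥ 5 of them non-zero, and a 2-day Pearson
correlation with the model strictly above 0.3; the rules commute.
Accepted stations are split 80/20 into assimilation and evaluation
subsets; spatially isolated stations (nearest neighbour beyond a
configured distance) always assimilate, and an optional region-coverage
check redraws the split.

## Assimilation

One ξ per cell per year per taxon, assimilated as ζ = ln ξ over the
whole flowering season; simulation starts at the heat-accumulation start
day but the cost is evaluated only inside the window. Defaults:
ρ = 250 km, B = 1000 · correlation, Φ = 6 (grains m⁻³ units). Only the
Φ:B ratio matters for the location of the minimum; both are exposed as
configuration. The Gaussian correlation matrix is numerically
rank-deficient on fine grids, so a 10⁻⁶ nugget is added before the
Cholesky factorization.

The descent runs in the preconditioned variable w with
ζ = √scale · L w (C = L Lᵀ), which makes the prior term ½‖w‖² and lets
the limited-memory quasi-Newton iterations reduce the well-constrained
large-scale directions first — the regime the truncated-iteration
watchdog is designed around. Without the preconditioning the optimizer
fits the strongest stations' noise before resolving the regional field.

After every iteration the pair (J_bg, J_obs) is recorded; iteration 0 is
the background. Points from optimizer-unstable steps (negative cosine
between successive steps) or that fail to reduce J_obs are excluded. A
hyperbola J_obs = a + b/(J_bg + c) is fitted by least squares to the
accepted points; the *initial slope* is the chord over the first
accepted step (the fitted slope at the background point, J_bg = 0, is
numerically unbounded), and the iterations stop at the accepted point
nearest to where the fitted slope has fallen to 5% of it — the 20-fold
reduction. Degenerate cases (fewer than 3 points, failed fit) stop at
the last iteration with a warning. The result is ξ at the stopping
iteration; the full iterate path and per-iteration evaluation RMSE are
kept for diagnostics.

The analytic single-station optimum
ξ_opt = (ȳ/z̄)(1 + μν̄)/(1 + μ̄²) — which shows why imperfectly
correlated series bias the assimilated totals low — is implemented as
`xi_opt_closed_form` and verified against the scalar log-transformed
assimilation by Monte Carlo.

## Bias calibration and validation

The whole-period ratio r_s = Σ SPIn_model / Σ SPIn_obs is computed per
station over all years with ≥ 30 valid observation days (no correlation
screening), interpolated over the domain with a linear-kernel radial
basis function (smoothing 10, degree-1 polynomial tail so that constant
fields and far extrapolation behave; a degree-0 fallback covers
collinear station sets), and the emission map is *divided* by it: the
ratio is model-over-observation, so values above 1 reduce the emission.
Validation uses r_st = Σ obs / Σ model per station over co-valid days
only (reported in that orientation, observations over model), decile
tables from independently sorted values, inter-annual SPIn correlations
restricted to stations with more than 3 valid years, and footprint
union maps.

## Synthetic data: what it does and does not emulate

The generators are pure functions of configuration and seed.
Meteorology: a southward-warm latitudinal gradient (0.7 K/deg), a
seasonal warming trend (0.08 K/day), AR(1) spatially-smooth noise (2 K,
lag-1 0.8), winds from an AR(1) random streamfunction (divergence-free,
4 m s⁻¹ mean), event precipitation (15% wet days), an hourly mode with a
4 K diurnal cycle for alder. Landscape: smooth tree-cover fields (mean
0.15), flowering-start thresholds increasing with latitude, constant
ΔH = 60 K day, birch absent south of 40° N. Truth correction fields are
smooth log-symmetric fields spanning [0.5, 2], with a ~600 km
correlation scale — the synoptic scale at which regional pollen
production is coherent. Observation error is multiplicative,
mean-unbiased lognormal (σ = 0.3 by default) with 5% missing days; the
real error structure of volumetric traps is not characterized in the
literature this emulates, so the lognormal is a stand-in motivated only
by positivity and right skew. Station networks are either uniform
random, clustered (dense national networks plus one guaranteed isolated
site), or stratified (jittered lattice — a network engineered for
coverage).

Passing the synthetic experiments therefore shows the *machinery* is
correct and well-posed: exact adjoint, exact budget, correct screening,
an inversion that recovers a recoverable truth and stops before fitting
noise. It does not show that real pollen seasons are recovered with
these accuracies — real landscapes, observation errors, and model errors
are all harsher than the emulation.

## Experiment design and problem sizes

The shipped experiments (in `pollenda.experiments`) use sizes chosen to
keep the full suite within minutes on one CPU while preserving the
geometry that matters:

- adjoint identity: 8×6 cells, 20 days — exact by construction, the
  test tolerance (10⁻¹⁰) is loose against the observed ~10⁻¹⁶;
- linear-oracle equivalence: 10×10 cells, 20 stations, a 120-day
  window, noise-free; "full convergence" needs ~3000 quasi-Newton
  iterations to match the explicit source-receptor least-squares
  solution below 1% relative RMSE (0.3% observed);
- parameter recovery: a 15°×12° domain at 0.5° (30×24 cells), 30
  stratified stations, truth scale ~600 km, σ = 0.3, three independent
  years per replicate and three replicates; the asserted statistic is
  the median over the nine year-draws. Single-year outcomes are
  heavy-tailed: a 6-station evaluation subset occasionally worsens
  under assimilation for reasons invisible to assimilation-side
  diagnostics, which is precisely why the summary is a median;
- over-fitting protection: 12×10 cells at 1°, 6 assimilating and 6
  held-out stations, σ = 0.5 — deliberately coarse and noisy so that
  full convergence overfits; again a median over three replicates;
- calibration closed loop: a uniform ×2 model bias (true ξ = 0.5,
  first guess 1), noise-free, 12 stations.

## Known limitations

- The transport stand-in is 2-D, first-order, and diffusive; its
  footprints are wider than a high-order 3-D model would give.
- One mixing height and one deposition pathway; no wet deposition, no
  vertical structure, no injection-height profile (grain size and
  density enter only through the settling velocity).
- The ramp interiors of p_fs, p_fe, f_thr and the exponential wind
  saturation are decided forms; only their endpoints are pinned by the
  taxon tables.
- The L-curve watchdog is a heuristic: on hard draws it can stop several
  iterations from the evaluation-optimal point, and no
  assimilation-side rule can do better when the held-out stations
  disagree with the assimilated ones.
- Hourly (alder) scenarios cost ~24× the daily ones; the shipped
  experiments use birch's daily configuration.
- The correction field is time-independent within a season and
  uncoupled across years; within-season emission errors are explicitly
  out of scope.
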