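# pollenda

Desk-scale reanalysis machinery for tree-pollen seasons: a heat-sum
phenology and release model for alder, birch, and olive pollen, a linear
adjoint-equipped atmospheric transport stand-in, season-total 4D-VAR
inversion of the annual pollen-release correction field, and
post-assimilation bias calibration — exercised end-to-end on synthetic
meteorology, landscapes, and observation networks.

## The problem

Dispersion models predict the *timing* of tree pollen seasons well, but
the *amount* of pollen a forest releases in a given year — the Seasonal
Pollen Integral, SPIn = Σ daily mean concentration [pollen·day·m⁻³] — is
the most uncertain part of the system, varying by factors of several
between years and regions. Continental reanalyses solve this by
assimilating decades of daily Hirst-trap counts into the model: the
unknown is a per-cell, per-year unitless correction ξ(i,j,yr) to the
climatological seasonal release N_tot,

    N(i,j,yr) = ξ(i,j,yr) · N_tot ,      ξ = exp(ζ),  ζ_b = 0 ,

estimated by minimizing, over one whole flowering season,

    J(ζ) = ½ (y − G ξ)ᵀ Φ⁻¹ (y − G ξ) + ½ ζᵀ B⁻¹ ζ ,

where `G` is the (exactly linear in ξ) chain *emission → transport →
station sampling → 2-day averaging*, Φ is a scalar observation
covariance and B = scale · exp(−d²/ρ²) a Gaussian spatial background
covariance with ρ ≈ 250 km. Because the problem is ill-posed, the
quasi-Newton minimization is regularized by *truncated iterations*: the
(J_bg, J_obs) trade-off curve is fitted with a hyperbola and the
iterations stop where its slope has dropped 20-fold (to 5% of the
initial slope). A residual low bias — the analytic consequence of
imperfect model–observation correlation, ξ_opt = (ȳ/z̄)(1+μν̄)/(1+μ̄²) —
is removed afterwards by a climatological calibration: the whole-period
station ratio r_s = SPIn_model/SPIn_obs is interpolated over the domain
with a linear-kernel radial basis function and divided out of the
emission map.

This package rebuilds that pipeline at desk scale, with a synthetic-data
module generating every input the real system takes from a
meteorological reanalysis, land-cover inventories, and an aerobiological
network — so the whole method is testable against a known truth on one
CPU in minutes.

## A worked example

```python
import numpy as np
from pollenda import (GridSpec, NoiseConfig, RunConfig,
                      build_year_scenario, run_da, run_first_guess)
from pollenda.experiments import footprint_union

cfg = RunConfig(
    grid=GridSpec(0.0, 12.0, 46.0, 56.0, 24, 20),   # 0.5 degree cells
    n_stations=25, station_layout="stratified",
    noise=NoiseConfig(lognormal_sigma=0.3, missing_prob=0.05),
    xi_smooth_cells=12.0, seed=4,
)
scen = build_year_scenario(cfg, 2000)   # truth season + noisy observations
fg = run_first_guess(scen)              # unconstrained reference run, xi = 1
da = run_da(scen, fg, cfg)

mask = footprint_union(scen, da.assim_ids)
print(da.result.diagnostics.stop_index,
      round(da.result.rmse_ratio_eval, 2),
      round(np.corrcoef(da.result.xi[mask], scen.xi_true[mask])[0, 1], 2))
```

prints

```
3 0.33 0.94
```

— the L-curve watchdog truncated the minimization at iteration 3; the
held-out evaluation stations' RMSE dropped to 0.33 of the unconstrained
run; and the recovered correction field correlates with the hidden truth
at r = 0.94 over the cells the station footprints constrain. The
`examples/` directory holds one short narrative script per capability
(scenario generation, the emission model, transport and its adjoint,
assimilation, calibration), each printing the numbers it computes.

A thin CLI mirrors the three-run protocol (first guess → assimilation →
final) with serialized intermediate artifacts:

```bash
pollenda generate    --config cfg.yaml --workspace ws/
pollenda first-guess --config cfg.yaml --workspace ws/
pollenda assimilate  --config cfg.yaml --workspace ws/
pollenda calibrate   --config cfg.yaml --workspace ws/
pollenda final       --config cfg.yaml --workspace ws/
pollenda diagnose    --config cfg.yaml --workspace ws/
```

## Layout

- `src/pollenda/synthetic.py` — meteorology, landscape, truth-field,
  network, and observation generators (pure functions of config + seed)
- `src/pollenda/phenology.py` — heat-sum development and
  weather-modulated release (the source term)
- `src/pollenda/transport.py` — 2-D advection–diffusion–deposition with
  an exact discrete adjoint and station footprints
- `src/pollenda/observations.py` — sampling, 2-day averaging, screening
  filters, SPIn, the 80/20 station split
- `src/pollenda/assimilation.py` — cost/gradient, preconditioned
  quasi-Newton descent, L-curve truncation
- `src/pollenda/calibration.py` — SPIn-ratio calibration and validation
  ratios
- `src/pollenda/pipeline.py` — the three-run protocol and diagnostics
- `src/pollenda/experiments.py` — the self-contained synthetic-truth
  experiments the tests and the acceptance script run
- `docs/methods.md` — model description, assumptions, parameter choices,
  and known limitations
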