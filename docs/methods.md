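# Methods

## Model

The core isotherm describes adsorption on one *sitegroup* — a class of
surface regions sharing a single parameter set — as a ladder of stepwise
equilibria.  The first molecule binds a region with effective constant `K1`
raised through a cooperativity exponent `α` (`[AS] = (K1 x)^α [S]`); each
of the `m` subsequent layers binds with a common constant `K2`
(`[A_j S] = K2 x [A_{j-1} S]`); and the final step is multiplied by
`1 + (m/(m+1))(C.T. − 1)`, where the condensation term
`C.T. = (1 + z + z² + z³ + z⁴)^{3/2}`, `z = K2 x`, grows without bound as
`z → 1` and beyond, modelling capillary condensation.  Normalizing by the
region balance and summing loading-weighted populations yields the closed
form evaluated by `sorbfit.models.uptake_single`; multiple sitegroups add.

Assumptions worth keeping in mind:

* one `K2` for all layers beyond the first (a Klotz-style ladder with
  per-step constants is deliberately out of scope);
* condensation is pinned to `K2 x → 1` rather than `x → 1`, so the same
  form serves subcritical gases (`x = P/P_sat`), supercritical fluids
  (`x = P`) and solutions (`x` = concentration or activity) — the library
  never interprets or converts the abscissa;
* the adsorption branch only; desorption hysteresis is not modelled;
* `Q` is absolute (never excess) uptake and is non-negative.

Parameters, units, allowed ranges:

| parameter | meaning | range | notes |
|---|---|---|---|
| `α` | first-step cooperativity exponent | (0, ∞) | `α = 0` is rejected; it would nullify the first step. |
| `K1` | first-step constant, 1/x units | [0, ∞) | `K1 = 0` gives the null isotherm (allowed). |
| `K2` | subsequent-step constant, 1/x units | [0, ∞) | condensation near `K2 x ≈ 1`. |
| `m` | effective layers beyond the first | [0, ∞] | continuous; `∞` is a sentinel, not a large float. |
| `N` | first-layer capacity, uptake units | [0, ∞) | mmol/g whenever surface areas are wanted. |

For finite `m > 0` the saturation plateau is `(1 + m)N`; `m = 0` reduces
exactly to Sips (Langmuir when `α = 1`); the infinite-`m` sentinel uses the
analytic limit (`z^m → 0` for `z < 1`), which is the α-generalized
Anderson form and reduces to BET at `K2 = 1` and to GAB under
`K1 = c_G k`, `K2 = k`.

## Numerical evaluation

* **Near the condensation point.**  The two layer-sum ratios
  `(1 − z^{m+1})/(1 − z)` and `(1 − (m+2)z^{m+1} + (m+1)z^{m+2})/(1 − z)²`
  are indeterminate at `z = 1` and catastrophically cancelling nearby.  For
  `|1 − z| < 10⁻²` they are evaluated by a generalized-binomial series
  around `z = 1` (valid for continuous `m`), accumulated to machine
  convergence; outside the window the closed forms are used.  The window is
  wide enough that the closed-form side retains ≥ 12 significant digits,
  so the two branches agree to ~10⁻¹³ relative at the seam and both match
  explicit state-population summation to better than 10⁻¹⁰.
* **Powers.**  `(K2 x)^m` and `(K1 x)^α` are computed in log space;
  underflow flushes to zero and an exponent above ~690 (the double
  precision ceiling) raises a range error rather than returning `inf`.
  Fitted `m` above 10³ sets a `large_m` flag: the plateau is unresolved and
  the exact value of `m` no longer affects the uptake noticeably.
* **x = 0.**  `Q(0) = 0` is short-circuited exactly, which also disposes of
  the `0⁰` subterm that formally appears when `m = 0` (it is multiplied by
  `C.T. − 1 = 0`).

## Fitscore

Pointwise errors are `(√Q_exp − √Q_model)²` — a compromise between
absolute error (over-weights high uptakes) and relative error (divides by
zero at low uptakes); the pairs (0.09, 0.16) and (0.64, 0.81) contribute
equally.  Errors are integrated over `u = x^{1/3}` with multitrapezoid
weights (endpoints half the adjacent gap, interior points half the
bracketing span; the weights telescope to `u_N − u_1`), making the score
independent of how densely each pressure region was sampled.  With
`Γ = Σ wᵢ (√Q_exp,i − √Q_model,i)²` and `Λ = Σ wᵢ Q_exp,i`,
`fitscore = Λ/(Λ+Γ)`: 1 is a perfect fit, ≥ 0.95 good, ≥ 0.99 excellent.

Two readings of the printed definitions were possible; this package
integrates the *squared-residual on the √Q scale* in `Γ` but the *plain
uptake* in `Λ`, which keeps the two commensurate and reproduces the
equal-contribution example above.  Datasets are anchored at (0, 0) (a
synthetic anchor is prepended when missing, and recorded), so integration
always starts at the origin of the cube-root axis; duplicate activities are
rejected because zero gaps make the weights ill-defined.  RMSE/MAE/MARE/R²
are intentionally not offered as objectives.

## Fitting

Maximizing the fitscore equals minimizing `Γ`, a weighted least-squares
problem in `y = √Q`.  `sorbfit.fitting.fit` solves it with a trust-region
reflective bounded least-squares solver in **log-parameter coordinates**
(the equilibrium constants span ≥ 6 decades across real materials; log
coordinates also keep the iterates positive).  Zero lower bounds are
floored at tiny positive values in the search; exact zeros (`m = 0`,
`K2 = 0`, `m = ∞`) are reachable through the fixed-parameter mask instead.

* **Multi-start.**  32 seeded random starts by default: `K1` log-uniform
  over `[10⁻², 10⁶]/x_max`, `α` log-uniform over `[0.25, 4]`, `m`
  log-uniform over `[0.05, 50]`, `K2` uniform over its bounds (later
  sitegroups staggered toward smaller `K2`, i.e. condensation activated at
  higher `x`), capacities uniform up to their bound and split across
  sitegroups.  Each start runs a bounded local solve at 10⁻⁸ tolerance;
  the best is polished at 10⁻¹².  The returned fitscore is the maximum
  over all starts, and same data + seed + options reproduce the result
  bit for bit.
* **Default bounds.**  `α ∈ [10⁻², 10²]`, `K1 ∈ [0, 10⁸]`,
  `K2 ∈ [0, 10]`, `m ∈ [0, 10⁶]`, `N ∈ [0, 10·max Q]`; Anderson/GAB-type
  classical fits cap their multilayer constant so the model stays inside
  its domain on the data grid.  Surface-area mode tightens `K2` to
  `[2/3, 3/2]` (the condensation point should sit near the bulk saturation
  activity) and `N` to `2·max Q` (the data are assumed to reach at least
  half a monolayer).
* **Sitegroup labelling.**  The additive model is symmetric under sitegroup
  permutation; results are reported sorted by `K1` descending.  When two
  sitegroups improve the fitscore by < 0.005 over one, the comparison
  command recommends the simpler model (the threshold is this package's
  default and is configurable — ten free parameters overfit easily).
* **BET regression.**  The classical narrow-window analysis is ordinary
  least squares of `x/(Q(1−x))` on `x`; `N = 1/(slope+intercept)`,
  `K1 = 1 + slope/intercept`.  A non-positive intercept *or* non-positive
  fitted capacity flags "no valid linear range" (for data whose BET
  transform is exact the intercept `1/(N K1)` is positive by construction;
  what actually goes negative for convex Type III/V shapes is
  `slope + intercept`).  `bet_model_fitscore` scores the resulting BET
  model over the whole data range, which is how the package compares the
  narrow-window method against whole-isotherm fits.

## Bootstrap confidence intervals

Each observation `yᵢ = √Qᵢ` is perturbed by `±stepᵢ` with equiprobable
signs, where `stepᵢ` is the smallest of: both neighbour increments
`|yᵢ − yᵢ₋₁|`, `|yᵢ₊₁ − yᵢ|`, the fit residual `|yᵢ − y_pred,i|`, and
`yᵢ` itself (which guarantees non-negativity).  The (0,0) anchor never
moves.  Perturbed values are squared back to uptakes and refit starting
from the unperturbed optimum; per-parameter and surface-area intervals are
the 2.5/97.5 percentiles (linear interpolation) over converged replicates,
5000 by default, which makes interval endpoints reproducible across seeds
to about the last reported digit.  One seeded RNG stream serves the whole
run; sign draws consume one uniform each, in data order then replicate
order.  Refits that fail to converge are dropped and counted (> 10%
failures adds a warning; 100% is an error).  An `interval_union` helper
merges intervals from repeat experimental runs into their widest span.

**Documented limitation.**  The step size is an *estimate of the
measurement error of each point*, taken as a minimum of several proxies.
On densely sampled, low-noise, smooth data the neighbour increments near a
plateau and the post-fit residual (which a five-parameter fit partially
absorbs) both sit below the true noise scale, so the bootstrap spread
underestimates the sampling spread of the estimator — the package's own
coverage experiments (2% multiplicative noise, 40-point cube-root grids,
500 replicates) measure ~70–80% per-parameter coverage against the nominal
95%.  The scheme's premise holds when point spacing on the √Q scale is
coarse relative to the noise, as in typical experimental isotherms.
Treat intervals from very dense, very clean data as lower bounds on the
uncertainty.

## Whole-isotherm surface area

`SA (m²/g) = 602.214 · Σ_g N_g σ_g`, with `N_g` in mmol/g and `σ_g` in
nm²; the prefactor is Avogadro's number × 10⁻¹⁸ m²/nm² × 10⁻³ mol/mmol.
Registered cross-sections: N₂ 0.162 (77 K), Ar 0.142 (87 K), H₂O 0.114
with 0.106 selectable (literature water values span ~0.079–0.165 nm²);
all overridable per call.  Values are computed and stored at full
precision; any rounding (e.g. 3 significant figures for display) is
cosmetic and never feeds back into computation.  A unit guard rejects
capacities not in mmol/g.

## Synthetic data

`simulate_isotherm` evaluates a model on a grid — 40 points uniform in
`x^{1/3}` on (0, 1] by default, matching the fitscore's integration
abscissa — and applies a noise model: multiplicative Gaussian (default 1%
relative, a generic stand-in for instrument scatter) or additive Gaussian
on the √Q scale; uptakes are clipped at zero and the anchor stays exact.
The generating parameters and seed are recorded in the dataset metadata.
`iupac_presets` provides six parameter sets whose shapes carry the
qualitative signatures of the IUPAC physisorption types (the numeric
values are this package's own, chosen for clean signatures):
monolayer saturation (1), unrestricted multilayer (2), weak-interaction
convex (3), condensation step to a plateau (4), weak-first-step plus
condensation (5), and a two-sitegroup stepwise shape with well-separated
condensation activities (6).

What the generator does *not* emulate: correlated or heteroscedastic
instrument error, buoyancy/dead-volume artifacts, desorption branches, or
the irregular activity grids of real instruments.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under clean
conditions, not robustness to every experimental pathology.

## Test problem sizes

The test suite runs property checks at 10⁴ random parameter draws,
parameter-recovery at 40-point grids, bootstrap stability at the
production 5000 replicates, and the coverage experiment at a scaled-down
500 replicates × 100 repeats — sizes chosen to exercise every claim on a
single CPU in minutes.

## Known limitations

* Adsorption branch only; no hysteresis, pore-size distributions,
  t-plot/αs or micropore-volume analyses.
* No BET consistency-criteria (Rouquerol-rule) window selection; the BET
  window is caller-chosen.
* No temperature dependence of `K1`/`K2`; fits are per-isotherm.
* Surface-tension-based condensation models and per-step binding ladders
  are out of scope.
* No instrument-vendor or adsorption-information-format parsers; input is
  the plain CSV dialect.
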