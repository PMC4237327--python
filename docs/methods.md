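# Methods

## The model

The package treats gliomagenesis as a counting problem in the adult neural
stem cell (NSC) compartment. Three empirically anchored ingredients:

1. **Mutation supply.** Each cell division mutates any given gene with
   probability `u`. With 29 glioma proto-oncogenes among 18,440
   protein-coding genes, the per-division oncogenic hit probability is
   `u_o = 29u`. The number of hits after `D` divisions is Binomial(`D`,
   `u_o`); because `D` is large (10⁴–10⁵ over a lifetime) and `u_o` tiny,
   the Poisson law with intensity `λ = u_o·D` is used everywhere, with the
   exact binomial retained as a test oracle. The mutation rate is held
   constant across the lifespan; genome-instability feedback is out of
   scope.

2. **Ordered multistage transformation.** Transformation requires at least
   `n_min` hits, and only some temporal orderings of the hits transform.
   Of the `x!` orderings of `x` hits, on average `S` are transforming, so
   `P₁(λ) = Σ_{x=n_min}^{29} (S/x!)·Poisson(x; λ)`. Unlike the classical
   Armitage–Doll model this sums over all admissible sequence lengths
   rather than fixing one. `S` is a single scalar applied to every length —
   a deliberate simplification, since length-resolved multiplicities are
   not empirically available. The ordering factor sits behind a seam:
   * `factorial` (default): transforming fraction `S/x!`, `S ≤ x!`;
   * `permutation`: denominator `perm(29, x)` (ordered gene sequences
     drawn from the oncogene pool), for sensitivity analysis;
   * `complete`: every ordering transforms (`S` unused) — this is the
     classical multistage limit used in the power-law tests.
   Because the sum starts at `x = n_min`, the binding cap on `S` is
   `n_min!` (1 for `n_min` = 1, 120 for `n_min` = 5).

3. **Population dynamics.** The NSC pool is `N(t) = N₀·e^{−kt}`; the
   per-cell division rate rises linearly from 251/year at age 0 to
   318/year at age 85 (clamped outside; a constant-rate mode exists for
   scenario comparison). The anchors derive from 48-h time-lapse counts —
   1.37 and 1.74 divisions per 48 h — annualised with 183 periods/year
   (366/2), the value that reproduces both printed integers; 182.5 would
   round the young-adult rate down to 250. Whether the ramp is anchored at
   birth or at young adulthood is not empirically settled; both anchors
   are configuration-exposed.

Population-level: `P(t) = 1 − (1 − P₁)^{N(t)}` (at least one transformed
cell), evaluated through `expm1/log1p`. Prevalence is `10⁵·P(t)` per
100,000 persons; incidence is its numerical derivative per 100,000
person-years, by second-order central differences with second-order
one-sided stencils at the grid edges (exact for quadratics). Transformation
is identified with clinical incidence — no latency, competing mortality or
cohort correction.

### Validity regime

In the rare-event regime incidence ∝ d/dt[e^{−kt}λ(t)^{n_min}], which
turns negative once `t` exceeds roughly `n_min/k`: NSC depletion then
outpaces mutation accumulation and modelled prevalence declines. The model
is meaningful only while that crossover lies beyond the horizon of
interest. `run_model` computes the exact expressions regardless and warns
when `P(t_max) > 0.5`; the synthetic-table generator refuses to emit the
negative bin-averaged rates that arise past the crossover.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `u` | per-gene per-division mutation probability | **required** | no silent default; take from a published somatic estimate (Frank 2010). Study condition: 3e-7 |
| `n_onco`, `G` | oncogene / gene counts | 29 / 18,440 | from the packaged catalogue |
| `n_min` | minimum oncogenic hits | 5 | sweep 1–29 supported; demographic data select 4–5 |
| `S` | transforming sequence multiplicity | fitted (≤ `n_min!`) | study condition 100 for `n_min` = 5 |
| `N₀` | NSCs at birth | **required** | degenerate with `S` (only `N₀·S` identified); study condition 1e5 |
| `k` | NSC decay constant (1/y) | fitted in [1e-4, 1] | peak at 80 y needs k ≈ 0.038 at the study conditions |
| `r_young`, `r_aged` | division-rate anchors (1/y) | 251, 318 | annualised 48-h counts |
| `dt`, `t_max` | grid (years) | 0.001, 100 | dt ≤ 0.01 enforced |

**Study conditions.** `u` and `N₀` are required inputs because the
empirical chain that fixes them (a published somatic mutation-frequency
estimate; histology counts scaled per mm and along the 10-mm germinal
tract, then extrapolated to birth) does not pin unique values — the
conversion arithmetic is implemented in `population.py`, but the final
extrapolation is read off graphs. For its own examples, tests and
acceptance script the package fixes one set of conditions: `u` = 3e-7
(within the published estimate's range, chosen so that with `N₀·S` below
the modelled peak lands at a registry-like ~20 cases per 100,000
person-years), `N₀` = 1e5, `S` = 100, `n_min` = 5, and for the synthetic
generator `k` = 0.0385 — the value that places the incidence peak at
80 years under those conditions. These were fixed once, before the
validation suite was built around them.

## Calibration

The fit minimises `Σ_b w_b (model_b − obs_b)²` over age bins, where
`model_b` is the trapezoidal time-average of model incidence over the bin
and `w_b = 1/max(obs_b, floor)²` (relative-error weighting; floor 0.1 per
100k·py guards empty bins). The search is one-dimensional: for each
candidate `k` the model is run at `S = 1` and `S` is profiled out in
closed form (`Σw·m·o / Σw·m²`, incidence being linear in `S` in the
rare-event regime), clipped to `(0, n_min!]`. Because the profiled `S`
pins to its bounds wherever the curve cannot meet the data at any scale,
the objective has flat plateaus in `k`; the optimiser therefore scans 40
log-spaced `k` values and refines with bounded Brent inside the best
bracket. The reported optimum re-runs the model at the fitted `(k, S)` so
the final objective uses exact (not profiled-linear) rates.

Feasibility of an `(n_min, k, S)` scenario = mean weighted squared
residual ≤ 0.05 per bin **and** fitted peak age within 80 ± 5 y. Both
thresholds are package choices (config-exposed); enlarging the tolerance
can only keep or gain feasibility.

`N₀` is held fixed during every fit and the `N₀·S` degeneracy is logged
each time.

### Peak-age placement

`calibrate_peak_age` exploits that the incidence peak age is monotone
decreasing in `k` (faster depletion pulls the maximum earlier) and
bisects `k` until the gridded `argmax` hits the target; at `dt` = 0.001 y
it places the peak at 80.00 y in ~40 model runs.

## Parametric bootstrap

The resampling unit follows the registry-rate construction: per bin,
events ~ Binomial(`round(sample_size × bin width)` person-years,
rate/10⁵); empirical rates are rebuilt, the model refitted with the same
fixed parameters, and the 95% band is the pointwise 2.5–97.5 percentile
envelope of the replicate incidence curves (defaults `B` = 1000,
`sample_size` = 100,000; all driven by one seeded generator,
bit-reproducible). Replicate refits reuse the *observed* table's weights:
recomputing `1/obs²` weights from each noisy replicate correlates the
weights with the noise and biases the profiled amplitude low by tens of
percent, which also breaks the expected 1/√n shrinkage of the bands.
Note the 1/√n CLT scaling of the band width only materialises once the
informative bins' expected event counts are well clear of 0–1, i.e. at
denominators of ~10⁶ person-years for the study-condition amplitudes.

## Synthetic tables

The generator emulates CBTRUS-style demographic tables: 5-year bins 0–85
plus an open-ended 85+ bin, mean incidence per 100,000 person-years per
bin, obtained by bin-averaging a forward model run and (optionally)
multiplying each bin by mean-one lognormal noise
(`exp(σz − σ²/2)`, default σ = 0.1 ≈ 10% relative error). What it does
*not* emulate: registry artefacts such as diagnosis lag, reporting
completeness drift, cohort effects, competing mortality, or within-bin
population age structure (bins are time-averaged, not
population-weighted). Passing recovery and coverage tests on these tables
therefore validates the estimation machinery under the model's own
assumptions, not the model's adequacy for real registry data.

## Numerical choices

- All pmf arithmetic in log space; probabilities below 1e-300 flushed to 0.
- `D(t)` uses the exact piecewise-linear integral (no quadrature error);
  fractional division counts enter the Poisson intensity directly, and the
  binomial oracle rounds to integer `D`.
- The per-cell sum truncates at `x` = 29 — exact for the model (29
  distinct oncogenes) and numerically irrelevant below λ ≈ 0.5.
- Ratio curves define 0/0 = 1 (at age 0 both scenarios are zero).
- Grid: halving `dt` from 0.002 to 0.001 moves the peak by < 0.01 y;
  extending `t_max` leaves curves on the common grid unchanged except the
  final point's one-sided derivative stencil.
- Default test grid `dt` = 0.01 y, `t_max` = 100 y (10⁴ steps), chosen
  because bin averages and peak locations are already stable there;
  headline computations use `dt` = 0.001 (10⁵ steps).

## Known limitations

- `n_min`, `S`, `k`, `N₀·S` are jointly only weakly identified by a single
  age-incidence curve; the sweep orders scenarios by misfit but is not a
  formal model-selection procedure.
- The single-scalar `S` ignores that multiplicity plausibly grows with
  sequence length; the `permutation` seam bounds the effect but neither
  reading is empirically grounded.
- Incidence is per initial birth cohort (literal derivative of `P`); a
  hazard-style variant `incidence/(1 − P)` is exported alongside, and the
  two are indistinguishable in the rare-event regime.
- The division-rate anchors extrapolate rodent time-lapse data to the
  aging human; the constant-rate scenario exists precisely to bracket that
  uncertainty (its net effect is the ≈1.9× prevalence ratio at 85).
- The packaged 29-gene catalogue fixes `n_onco`; gene identities carry
  provenance tags only and never enter the arithmetic.
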