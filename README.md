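# nscglioma

A multistage model of glioma incidence across the human lifespan, driven by
neural-stem-cell (NSC) population dynamics.

Glioma is the most common primary brain tumour, and age is the strongest
known risk factor: registry data (CBTRUS-style age-grouped tables) show
incidence rising across adulthood to a peak near 80 years. The most likely
cell-of-origin is the adult neural stem cell. This package implements, tests
and calibrates a mechanistic model in which glioma arises when one NSC
accumulates enough oncogenic mutations, in a permitted temporal order,
through its ordinary divisions — while the NSC pool itself shrinks
exponentially with age and the surviving cells divide faster. The interplay
of rising per-cell risk and falling cell number reproduces the
characteristic late-life incidence peak without assuming differential
susceptibility across the population.

It is intended for quantitative cancer-biology and epidemiological-modelling
work: fitting the model to age-grouped incidence tables, asking how many
oncogenic hits the demographic curve supports, and propagating sampling
uncertainty into confidence bands.

## Model

Ages run on a uniform grid (default `dt` = 0.001 y). With per-gene
per-division mutation probability `u` and `n_onco` = 29 glioma
proto-oncogenes among `G` = 18,440 protein-coding genes, the per-division
probability of an oncogenic hit is `u_o = n_onco·u`. A cell that has
undergone `D(t)` divisions carries Binomial(`D`, `u_o`) hits, approximated
by Poisson with intensity `λ(t) = u_o·D(t)`:

- division rate: `r(t)` linear from 251 to 318 divisions/cell/year between
  ages 0 and 85 (constant mode available), `D(t) = ∫₀ᵗ r(s) ds` in closed
  form;
- per-cell transformation probability (multistage, order-aware):
  `P₁(t) = Σ_{x=n_min}^{29} (S/x!)·Poisson(x; λ(t))`, where `n_min` is the
  minimum number of hits and `S` the average number of transforming
  mutational sequences (so `S/x!` is the transforming fraction of the `x!`
  orderings);
- NSC pool: `N(t) = N₀·e^{−kt}`;
- population level: `P(t) = 1 − (1 − P₁(t))^{N(t)}`, prevalence
  `= 10⁵·P(t)`, incidence `= d/dt` prevalence (central differences).

Calibration fits `(k, S)` to an age-binned incidence table by weighted
least squares (bounded scalar search over `k`, `S` profiled in closed
form); `N₀` is held fixed because only `N₀·S` is identified in the
rare-event regime. A parametric bootstrap (per-bin binomial event counts,
refit per replicate) yields pointwise 95% bands.

## Worked example

Place the incidence peak at 80 years by calibrating the NSC decay constant,
with the remaining parameters at the package's documented study conditions
(`u` = 3e-7, `N₀` = 1e5, `S` = 100, `n_min` = 5):

```python
import numpy as np
import nscglioma as ng

k_hat, peak, curves = ng.calibrate_peak_age(
    80.0, n_min=5, S=100.0, u=3e-7, N0=1e5,
    grid=ng.SimulationGrid(dt=0.001, t_max=100.0),
)
```

This prints (via the obvious f-strings):

```
k_hat = 0.03846 /year
peak age = 80.003 years
incidence at peak = 21.87 per 100,000 person-years
prevalence at 80 = 774.3 per 100,000
NSCs remaining at 80 = 4609 of 100000
divisions per NSC by 80 = 22602
```

Read: an NSC pool decaying at ~3.8%/year, with each surviving cell having
divided ~22,600 times by age 80, puts the incidence maximum at 80 years at
a registry-like amplitude of ~22 cases per 100,000 person-years.

The same workflow from the shell — generate a noisy synthetic registry
table, then ask which `n_min` the data support:

```bash
nscglioma make-synthetic --u 3e-7 --n0 1e5 --k 0.0385 --s 100 --n-min 5 \
    --dt 0.01 --noise multiplicative-lognormal --sigma 0.1 --seed 42 \
    --out table.csv
nscglioma calibrate --u 3e-7 --n0 1e5 --dt 0.01 --table table.csv \
    --n-min-range 3:7 --out report.csv
```

```
best n_min=5: k_hat=0.0384049, S_hat=96.8038, objective=0.130356, peak=80.14 y, feasible=True
```

The sweep recovers the generating hit number (5) and decay constant
(0.0385) from the noisy table; shallower (`n_min` = 3, 4) and steeper
(`n_min` = 6, 7) variants fit visibly worse, and for `n_min` ≥ 6 the
profiled multiplicity saturates its ordering cap `n_min!`. The net effect
of the age-increasing division rate (`nscglioma compare`) raises lifetime
prevalence by a factor ≈ 1.87 at age 85 relative to a constant young-adult
rate — the acceleration of NSC cycling alone almost doubles the burden.

The estimator interface mirrors scikit-learn:

```python
model = ng.GliomaIncidenceModel(u=3e-7, N0=1e5, n_min=5).fit(table)
model.k_, model.S_, model.peak_age_   # fitted attributes
model.predict([60.0, 70.0, 80.0])     # incidence per 100k person-years
```

## Layout

- `src/nscglioma/mutation.py` — per-cell transformation probability (exact
  binomial, Poisson approximation, ordering models)
- `src/nscglioma/population.py` — `N(t)`, `r(t)`, `D(t)` and the empirical
  unit conversions
- `src/nscglioma/pipeline.py` — age-resolved curves, prevalence, numerical
  incidence, scenario comparison
- `src/nscglioma/inference.py` — calibration, `n_min` sweeps, parametric
  bootstrap, scikit-learn estimator
- `src/nscglioma/tables.py`, `genes.py`, `synthetic.py`, `config.py`,
  `cli.py` — registry-table IO, the 29-gene fixture, the synthetic-table
  generator and the command line

See `docs/methods.md` for modelling assumptions, parameter choices and
known limitations.
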