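# pollinet

Quantitative analysis of plant–pollinator interaction networks along
environmental gradients: network assembly from transect-walk records,
specialization / nestedness / asymmetry indices, fixed-marginal null
models, secondary-extinction robustness, a composite land-use intensity
index, mixed-effects gradient models, and piecewise path analysis — plus a
synthetic-study generator with known ground truth so every stage can be
validated end to end.

It is written for community ecologists who record flower visits on
standardized walks and want to ask how interaction structure (who visits
whom, and how exclusively) changes with temperature, elevation or land
use.

## The quantities at the core

For an integer interaction matrix *a* (plants × pollinators, cell
*a<sub>ij</sub>* = visit events, marginals *A<sub>i</sub>*, *A<sub>j</sub>*,
total *m*):

- **d′** — species-level specialization. For a focal species with counts
  *a<sub>k</sub>* over partners (total *A*) and partner availability
  *q<sub>k</sub> = A<sub>k</sub>/m*,
  *d = Σ (a<sub>k</sub>/A) ln((a<sub>k</sub>/A)/q<sub>k</sub>)*
  (Kullback–Leibler divergence of use from availability), standardized
  between the most generalized integer allocation of *A* events
  (*d<sub>min</sub>*, found exactly) and *d<sub>max</sub> = ln(m/A)*:
  0 = opportunistic, 1 = maximally exclusive.
- **H₂′** — network-level complementary specialization: the Shannon
  entropy of *a/m* standardized between the minimum- and maximum-entropy
  integer matrices with the observed marginals.
- **WNODF** — weighted nestedness (0–100): after sorting rows and columns
  by decreasing totals, the percentage of the poorer species' cells that
  are nonzero and strictly smaller than the richer species' cells,
  averaged over all row and column pairs (ties score 0).
- **Dependence asymmetry** (−1…1): per link, the difference between the
  pollinator's and the plant's dependence, normalized by the larger one,
  averaged over links.
- **Robustness R** — area under the secondary-extinction survivor curve
  under random removal of one trophic level; 1 − 1/(2p) for a fully
  connected network with *p* removed species, 1/2 for a one-to-one
  network.
- Nestedness and robustness are **standardized against Patefield null
  ensembles** (uniform integer tables with the observed marginals):
  z = (observed − null mean)/null sd.
- The gradient stage fits **linear mixed models** (random site intercept,
  containment df, AICc model comparison, marginal R² per fixed effect)
  and a **piecewise structural equation model**: one mixed regression per
  endogenous variable over a DAG, d-separation basis set, Fisher's
  C = −2 Σ ln p (χ², 2k df), and exhaustive AICc search over optional
  paths.

## Worked example

```python
import pollinet as pn

study = pn.generate_study(pn.GeneratorConfig(seed=7))   # 18 sites, 993-4390 m
table = pn.walk_metric_table(study)                     # assemble + filter + indices
print(len(study.records), len(table))                   # 1273 records, 71 networks

fit = pn.fit_metric_vs_elevation(
    table.dropna(subset=["mean_dprime_pollinator"]), "mean_dprime_pollinator")
t = fit.term("elevation")
print(f"slope={t.estimate:.2e}  t={t.t:.2f}  df={t.df:.0f}  p={t.p:.4f}  R2={t.r2:.2f}")
```

prints

```
1273 71
slope=-1.47e-04  t=-8.65  df=16  p=0.0000  R2=0.63
```

i.e. community-mean pollinator specialization drops by ≈0.15 per 1,000 m
of elevation in this simulated study (the generator's
temperature→specialization link is positive, and temperature falls with
elevation), the site-level test is strongly significant, and elevation
accounts for ~63% of the variance. Continuing,

```python
rep = pn.recover_parameters(study, include_robustness=False)
print(rep.sem_best_has_mat_edge, round(rep.sem_delta_without_mat_edge, 2))
# True 12.42
```

the exhaustive path-model search keeps the direct temperature→
specialization edge, and removing it costs 12.4 AICc units.

A `pollinet` command-line tool wraps the same pipeline
(`simulate`, `build`, `metrics`, `nulls`, `robustness`, `lui`,
`gradient`, `sem`); see `pollinet --help`.

## Layout

- `pollinet.assembly` — records → per-walk networks, filters, pooling
- `pollinet.indices` — d′, H₂′, WNODF, dependence asymmetry
- `pollinet.nulls` — Patefield sampling, z standardization
- `pollinet.robustness` — extinction curves, R, standardized R
- `pollinet.lui` — composite land-use intensity index
- `pollinet.gradient` — mixed models, AICc, sensitivity analyses
- `pollinet.sem` — piecewise path analysis
- `pollinet.simulate` — synthetic gradient studies with ground truth

Method details, parameter defaults and known limitations are documented
in [`docs/methods.md`](docs/methods.md).
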