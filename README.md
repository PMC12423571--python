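# seedpath

Assemblage-level path analysis of seed-size "downsizing": does human
pressure shrink the maximum seed size of plant assemblages — directly and
via the downsizing of fruit-eating vertebrates — and do assemblages of
anachronistic *mega-seeded* plants still carry the trait-matching imprint
of extinct megafrugivores?

The package is aimed at macroecologists working with species occurrence
points, range polygons and trait tables. It builds grid-cell assemblages,
computes upper-tail trait metrics, and fits observed-variable structural
equation models (SEM) with multiple-imputation pooling, backward path
pruning, permutation nulls and spatial-autoregressive robustness checks.
A synthetic-landscape generator with a known causal structure makes every
stage testable end to end without any external data download.

## The model

Each grid cell (30 km by default) is an assemblage. Its variables are

* `seed` — 95th-percentile maximum plant seed width (mm),
* `mass_extant` / `mass_extinct` — 95th-percentile maximum body mass (g)
  of extant and extinct frugivores,
* `footprint` — mean cumulative human-footprint index,
* `pc1`, `pc2` — the first two principal components of the environmental
  variables.

The a priori path model is the recursive linear system `y = By + ζ`,
`ζ ~ N(0, Ψ)`:

```
seed         ~ footprint + mass_extant + mass_extinct + pc1 + pc2
mass_extant  ~ footprint + pc1 + pc2
mass_extinct ~ pc1 + pc2
footprint    ~ pc1 + pc2
footprint    ~~ mass_extinct
mass_extant  ~~ mass_extinct
```

Estimation minimises the ML covariance-structure discrepancy
`F_ML = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p` with
`Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ`; the test statistic is `T = (n−1)F_ML`.
Robust ("MLR"-style) corrections provide sandwich standard errors and a
mean-scaled statistic from the empirical fourth moments. Fits across the
m = 20 imputation replicates of seed width are pooled by Rubin's rules
(D2 pooling for chi-square statistics), non-significant paths are removed
backwards until all remaining paths have pooled p ≤ 0.05, and the final
model is gated on RMSEA < 0.05, CFI > 0.95 and a non-significant
chi-square. Species with seeds strictly wider than 24.6 mm — the largest
seed an extant Malagasy frugivore is recorded to swallow — are classified
mega-seeded, and the analysis is repeated on the assemblages with and
without them.

## Worked example

```python
import seedpath as sp
from seedpath.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    simulate=sp.SimConfig(m_imputations=4),  # synthetic island landscape
    n_perm=199,
    master_seed=42,
    min_rows=20,
)
report = run_pipeline(cfg)
```

which prints (via the summary fields of `report`):

```
assemblages: {'h1_full': 157, 'h2_mega': 40, 'h2_nonmega': 117}
PC1/PC2 variance fractions: 0.682 / 0.312
h1 R^2(max seed width) = 0.408; criteria: {'rmsea_ok': True, 'cfi_ok': True, 'chi2_ok': True, 'all_ok': True}
h1 final model:
seed ~ footprint + mass_extant + mass_extinct + pc2
mass_extant ~ footprint + pc2
mass_extinct ~ pc2
footprint ~ pc1 + pc2
footprint ~~ mass_extinct
mass_extant ~~ mass_extinct
Moran's I = 0.322 (p = 0.001)
SAR lambda = 0.514
```

157 simulated assemblages pass the inclusion filters (≥50% land, ≥3
plants, ≥3 extant and ≥1 extinct frugivore species), 40 of them contain a
mega-seeded species. The pruned full model keeps the negative
footprint→extant-frugivore path and the positive frugivore→seed paths —
the built-in downsizing cascade — and explains 41% of the variance in
maximum seed width with a passing fit. Maximum seed width is spatially
autocorrelated (Moran's I = 0.32), so the spatial-error model (λ = 0.51)
re-checks the predictors.

The same stages are available from the shell:

```bash
seedpath simulate --seed 42 --out bundle/
seedpath build --bundle bundle/ --out built/
seedpath prune --tables built/ --model model.txt --out pruned/
seedpath run-all --seed 42 --out results/
```

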