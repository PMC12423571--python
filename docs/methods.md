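# Methods

## Scope and data model

seedpath analyses assemblage-level trait structure: grid cells of a
projected metric plane (default 30 km) hold co-occurring plant and
frugivore species, and every cell gets upper-tail trait metrics, a mean
human-footprint value and environmental principal-component scores.
Assemblages failing the inclusion rules — land fraction < 0.5, fewer than
3 plant species, fewer than 3 extant frugivores, or no extinct
frugivore — are excluded before modelling, and the removal counts are
logged per rule.

Cell membership for occurrence points uses half-open intervals, so a
boundary point belongs to exactly one cell; polygons mark presence under
an any-positive-area overlap rule (a `--overlap-rule centroid` variant is
available; the choice changes only edge cells). The upper-tail metric is
the linear-interpolation percentile at index `h = (level/100)(n−1)` on the
sorted sample (level 95 by default), which keeps the worked examples
exactly checkable and damps single extreme species.

Mega-seeded classification is a strict inequality: seed width > 24.6 mm,
the width of the largest seed recorded to be swallowed and dispersed by an
extant Malagasy frugivore. The 15 published mega-seeded species with their
printed widths ship with the package as a reference fixture.

## The SEM engine

Only observed variables are modelled (no latent variables, no mean
structure). A model is the recursive system `y = By + ζ`, `ζ ~ N(0, Ψ)`;
the exogenous block of Ψ (variances and covariances of the environmental
PCs) is free, as are the two hypothesised residual covariances
(footprint with extinct mass; extant with extinct mass).

* **Preprocessing.** Seed widths and body masses are natural-log
  transformed; all variables are then min-max scaled to [0, 1]. Scaling is
  computed per analysis subset (full / mega / non-mega), which changes
  unstandardized but not standardized coefficients.
* **Estimation.** `F_ML` is minimised by L-BFGS-B from the per-equation
  least-squares start, followed by a Newton polish on the analytic
  gradient (finite-difference Hessian, ridge-regularised). The polish
  matters because on min-max-scaled data the raw gradient components are
  large even at the optimum and line searches can stall. Convergence is
  declared on a scale-aware gradient criterion (gradient times natural
  parameter scales below 1e-5); up to 5 jittered restarts follow a
  failure, and non-convergence is flagged, never silently accepted.
* **Inference.** Normal-theory standard errors come from
  `(Δ'VΔ)⁻¹/(n−1)` with `V = ½D'(Σ⁻¹⊗Σ⁻¹)D`; the robust variant uses the
  empirical fourth-moment matrix Γ of the covariance elements for a
  sandwich covariance and the mean-scaled statistic `T/c`,
  `c = tr(UΓ)/df`. Under multivariate normality `c → 1` and the sandwich
  reduces to the normal-theory covariance (checked by simulation).
  The test statistic uses the Wishart multiplier `n−1`.
* **Indices.** `CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0)` against the
  independence baseline (free variances only), and
  `RMSEA = sqrt(max(T−df,0)/(df(n−1)))`. The a priori model is saturated
  (df = 0), so indices become informative only after pruning.
* **Effects.** Total effects are `(I−B)⁻¹ − I`; standardized coefficients
  rescale by implied standard deviations; `R²` of an endogenous outcome is
  `1 − Ψ_ii/Σ(θ̂)_ii`.

## Pooling and model refinement

Fits over the m imputation replicates are pooled by Rubin's rules
(within-variance Ū, between-variance B_m, total `Ū + (1+1/m)B_m`, t
reference with the classical degrees of freedom; identical replicates
degenerate to the single-fit normal inference). Chi-square statistics are
pooled with the D2 (statistic-pooling) rule and its F reference, and
pooled CFI/RMSEA are computed from the pooled statistics. Backward
pruning removes the directed path with the highest pooled p while it
exceeds α = 0.05, breaking ties toward the smaller mean |standardized
estimate|; the two hypothesised residual covariances are structural and
never pruned. Final models are gated on RMSEA < 0.05 (strict), CFI > 0.95
(strict) and chi-square p > 0.05.

## Permutation nulls and spatial checks

The permutation null shuffles the assemblage-level maximum seed width
across assemblages (all other columns fixed), refits the final model, and
reports add-one empirical p-values, which cannot be zero. A species-level
variant (reshuffling the species-to-width map before re-deriving cell
metrics) is available through the `preprocess` hook. Spatial weights are
queen contiguity on the grid (rook and k-nearest variants provided),
row-standardized for the SAR model; isolated cells are linked to their
nearest neighbour. Moran's I uses the permutation p-value, two-sided
around the expectation −1/(n−1). The SAR model is the *error* variant
`y = Xβ + u`, `u = λWu + ε`, fitted by the concentrated log-likelihood
with the log-determinant from precomputed eigenvalues; at λ = 0 it equals
ordinary least squares exactly (and `fit_sar_error(..., lam=0.0)` exposes
that evaluation).

## The synthetic landscape

The generator builds an abstract elliptical island, not a real geography.
Its purpose is a full input bundle (trait tables, occurrence points,
range discs, environmental/footprint/land-mask rasters, m = 20 imputation
replicates covering 57.7% of plant species) whose assemblage-level causal
structure is known, so pipeline recovery can be scored against ground
truth.

Design, in generation order:

1. **Environment.** Two latent axes — a north–south seasonal-drought
   gradient and a radial highland dome — drive three observed raster
   layers (the third is nearly a pure mixture), so the first two principal
   components recover the axes and conditioning on them controls the
   environment.
2. **Footprint.** Concentrates in the highlands and drier zones plus a
   large smooth environment-independent component (at ~54 km correlation
   scale). That unique component is what identifies footprint paths
   against the PCs.
3. **Extant frugivores.** Body masses lognormal; species are placed by
   *trait-rank to field-quantile matching* on a suitability field
   `−0.7·footprint − 0.3·elevation + 0.6·ν` (ν a smooth guild-specific
   field), with small rank jitter. Range discs are ~45 km. Quantile
   matching yields a smooth, low-variance trait–environment coupling; the
   guild fields must be smooth at or above disc scale, otherwise range
   smoothing erases them from the realized upper-percentile surfaces.
4. **Extinct megafrugivores.** As above on a drought/highland field, but
   the guild-specific component is first orthogonalized against
   footprint, the environment axes and the *realized* extant-mass
   surface, so that by construction the megafaunal legacy carries no
   signal usable by the gape-limited flora.
5. **Plants.** Bulk species draw widths from a lognormal truncated at the
   24.6 mm swallowing threshold (gape-limited dispersal) and are placed
   against the realized extant-mass surface minus a direct footprint
   repulsion of large-seeded species. A fixed number of mega-seeded
   relicts (default 15) live only in the upper half of the legacy
   gradient with restricted ranges (~20 km); each relict's width matches
   the realized extinct-mass value at its home cell — larger relicts
   where larger megafrugivores occurred.

All randomness flows from one seed; two runs with the same configuration
are identical. Defaults are frozen as the package's study conditions:
30 km cells on a 420 × 600 km island (280 cells, ~160 passing filters, of
which ~20–25% are mega-cells), 750 plant species, 80 extant and 20
extinct frugivores, m = 20 imputations with log-scale noise 0.15.

What the generator does **not** emulate: real climate surfaces and
species lists, occurrence-record errors and sampling bias, imperfect
range maps, non-disc range shapes, and the MICE imputation model (the
replicates are Gaussian perturbations on the log scale, a stand-in).
Passing recovery tests therefore demonstrates the correctness of the
pipeline's machinery under known structure, not the field validity of
the ecological conclusions.

## Known limitations

* The extinct-mass surface is generated by ~20 species, so it has bounded
  effective spatial degrees of freedom (a few dozen). With ~160
  assemblages treated as independent, the SEM inference is
  anticonservative for that surface's paths: chance partial associations
  of |0.1–0.2| are sometimes retained as significant in the non-mega
  subset. This mirrors the motivation for the SAR robustness stage, which
  accounts for the residual spatial structure that path-model inference
  ignores; the pipeline reports both.
* Test-suite and acceptance-script problem sizes (replicate counts,
  permutation counts, pipeline-run counts) are reduced relative to a full
  study so the default runs complete in minutes; the checks keep their
  statistical form at those sizes.
* Min-max scaling makes unstandardized coefficients subset-specific;
  comparisons across subsets should use standardized estimates.
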