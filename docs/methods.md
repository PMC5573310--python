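# Methods

Statistical model, conventions, and numerical choices behind `neurocca`.
Units: cortical thickness in mm; FA dimensionless; radial/axial diffusivity
(DR/DA) in 10⁻⁴ mm²/s; age and education in years; sex coded 0 = male,
1 = female.

## 1. Synthetic cohort generator (`neurocca.synthetic`)

Each subject belongs to one of up to four groups — `NC` (cognitively normal
controls), `pureADD`, `pureSVaD`, `mixed` — with group-specific covariate
profiles (for example NC: age 62.5 ± 7.5 y, 71% female, education
12.5 ± 5.0 y). Feature values for view *v* (GM thickness or one WM DTI
metric) are

```
y_ij = b_v + d_vj' (c_i − c̄_NC) + g_v · 1[i affected group, j affected set]
       + s_v · 1[i ∈ latent groups] · u_i · 1[j ∈ latent support] + ε_ij
```

with `b_v` the healthy baseline (thickness 2.5 mm; FA 0.475; DR 5.670;
DA 12.334), `d_vj` small per-feature covariate slopes centered on the NC
covariate means, `g_v` the group degeneration effect (negative for
thickness and FA, positive for DR/DA), `u_i ~ N(0,1)` a shared subject
score that induces the rank-1 GM↔WM coupling of strength `s_v`, and
`ε_ij ~ N(0, σ_v²)` independent noise. Defaults are study-shaped (group
sizes 56/40/32/23); every parameter is a `GeneratorConfig` field. The
generator is a *sampling model for method validation*, not a biophysical
simulator: no spatial autocorrelation beyond the latent support, no
longitudinal structure, Gaussian noise only.

Geometry: thickness features live on two icosphere hemispheres (40,962
vertices each by default, i.e. 10·4⁶+2; adjacency from triangle edges via
`trimesh`); DTI features live on a one-voxel-thick skeleton modeled as a 2D
grid with 4- or 8-connectivity. Desk-scale runs use small feature counts on
the same geometry classes.

Reproducibility: all randomness flows from integer seeds through
`numpy.random.default_rng([master, stage, counter])`; derived seeds are
below 2³¹. Identical configs give bit-identical cohorts.

## 2. W-score normative model (`neurocca.wscore`)

Per feature, OLS of the control measurements on (1, age, sex, education):
`W = (y − x'β̂) / σ̂`, where `σ̂² = RSS / (n − k)` with `k` the number of
regression parameters (intercept included). Under this matching-denominator
convention the controls scored on their own model have per-feature mean
exactly 0 and SD exactly 1 (up to floating point), and `W = +1.65`
corresponds to the 95th percentile under Gaussian noise. Guard rails: at
least 5 controls and `n > k`; a covariate that is constant in the controls
is rejected by name (pass an empty covariate list explicitly for an
intercept-only model); features with zero residual SD are flagged
degenerate and score as NaN rather than ±inf.

## 3. Sparse CCA (`neurocca.scca`)

Penalized matrix decomposition on the cross-product `M = X'Z` of the
column-centered views: alternate

```
u ← argmax u'Mv  s.t. ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c_x, (u ≥ 0)
v ← argmax u'Mv  s.t. ‖v‖₂ ≤ 1, ‖v‖₁ ≤ c_z, (v ≥ 0)
```

Each step is soft-thresholding followed by L2 normalization, with the
threshold chosen so the L1 constraint is active exactly. The L1 budget is
`c = l1_fraction · √p` (floored at 1), with `l1_fraction = 0.5` by default —
roughly half the feature dimension. Non-negativity is on by default in both
views so the weights read as degeneration loadings of consistent sign.
Initialization is the leading right singular vector of `M`; the bilinear
objective is monotonically non-decreasing and iteration stops at relative
tolerance 1e-8 (an internal assertion fails loudly if ascent is ever
violated). The reported `canonical_correlation` is the Pearson correlation
of the subject projections `Xu` and `Zv`.

Numerical choices:

- The per-step threshold solves `‖S(a, δ)‖₁ = c‖S(a, δ)‖₂` in closed form
  on the sorted-prefix interval (a quadratic in δ per active-set size,
  vectorized with cumulative sums); bisection is kept as a fallback and as
  an independent test oracle. Ties are broken toward the lowest feature
  index.
- `scale` controls view preprocessing: `"center"` (default), `"standardize"`
  (unit column SD), or `"whiten"` (within-view decorrelation). With inactive
  L1 budgets and no sign constraint, the alternating scheme converges to the
  leading singular pair of `X'Z`, which maximizes cross-**covariance**; it
  equals classical CCA (maximal cross-**correlation**) only when each view
  is whitened, since canonical correlations are invariant to nonsingular
  within-view transforms. The oracle-equivalence test therefore runs under
  `scale="whiten"`; sparse analyses default to `"center"`.

## 4. Pair-permutation inference (`neurocca.permutation`)

Under the null of no GM↔WM coupling, the subject pairing between the two
views is exchangeable. Null datasets re-pair the rows of one view with a
uniformly sampled *derangement* (rejection sampling; no subject keeps its
own pair; `forbid_fixed_points=False` relaxes this to arbitrary
permutations). Each of the B null datasets gets its own child seed
`default_rng([seed, iteration])`, so results are reproducible and
independent of execution order. The p-value is the plain exceedance ratio
`#{r_null > r_obs}/B` (an `add_one` option gives the (1+count)/(1+B)
variant); B = 2,000 by default. Replicates whose null fit fails are
recorded; more than 5% failures aborts the test.

## 5. Group-difference maps (`neurocca.groupdiff`)

Feature-wise GLM t-statistics for a group contrast with nuisance
covariates, TFCE enhancement, then max-statistic FWE correction:

- **TFCE**: `e(j) = Σ_h extent(j,h)^E · h^H · dh` over thresholds `h`,
  with 2D defaults E = 1, H = 2. Thresholds follow the midpoint rule
  `(i − ½)·dh` with `dh = 0.1 × max|map|` by default, which matches the
  isolated-peak closed form `h^(H+1)/(H+1)` to ≈0.25% at that step size and
  makes the scaling identity `tfce(k·m) = k^(H+1)·tfce(m)` exact. Connected
  components are tracked incrementally with a union-find over features
  sorted by height. Negative statistics are enhanced on the negated map
  and re-signed.
- **FWE**: Freedman–Lane permutation (fit the nuisance-only model, permute
  its residuals, re-add the nuisance fit) preserves covariate structure
  under the null. For each permutation the map-wide maximum enhanced
  statistic is recorded per direction; corrected p-values are
  `(1 + #{max_null ≥ e_obs}) / (1 + B)`, two-sided via a factor-2 Bonferroni
  over directions, capped at 1. Default B = 5,000 (desk-scale suites use
  500).

## 6. Pipeline (`neurocca.pipeline`, `neurocca.cli`)

`run_pipeline(RunConfig)`: generate or load a cohort → fit normative models
on NC per modality → W-score everyone → per patient group: TFCE/FWE group
maps versus NC and, per DTI metric, sCCA between GM and WM W-scores with
the pair-permutation test. Stage seeds are derived from the master seed, so
a pipeline report is bit-reproducible and every reported number can be
recomputed by calling the underlying module directly with the stage seed.
Outputs are TSV/YAML only; `provenance.yaml` stores the config, its hash,
and package version.

## 7. Validation strategy and problem sizes

Acceptance-style checks (see `tests/test_acceptance.py`) use desk-scale
problem sizes chosen by this package so the full suite runs in minutes on
one CPU: W-score calibration on 100 × 500 (tolerance 1e-8) and percentile
on 100,000 draws (±1); CCA-oracle equivalence on 50 instances (n = 60,
p, q ≤ 5, 1e-6); support recovery with 10/10 planted features among
200/300 at signal-to-noise 2 (mean sensitivity ≥ 0.8 over 20 seeds;
measured 1.0); permutation calibration over 200 null replicates at B = 200
(rejection in the binomial 99% band [0.02, 0.09]; measured 0.070); FWE
calibration over 100 replicates at B = 500 (in [0.01, 0.11]; measured
0.020); TFCE closed forms (5% / 1e-6).

## 8. Known limitations

- **W-scoring couples the views at small control samples.** W-scores are
  residuals (plus predictions) from a model estimated on finitely many
  controls; the estimation error projects *both* modalities onto the column
  space of the shared covariate design. The identity pairing therefore
  carries a weak common component that a derangement destroys, so the
  pair-permutation test on W-scored views is mildly **anti-conservative**
  even when the underlying modalities are independent given covariates:
  with ~30 controls we measured a rejection rate at α = .05 of ≈0.15 when
  scoring subjects on their own model and ≈0.10 when scoring patients on a
  control-fitted model, versus 0.05–0.07 on truly independent views. The
  effect shrinks as the control sample grows (estimation error scales like
  √(k/n)). Consequence: small sCCA p-values obtained from W-scored views at
  small n should be read with this inflation in mind; the calibration suite
  verifies the test on independent views, where it is exact by
  construction.
- The permutation p-value uses the strict exceedance ratio, so `p = 0` is
  possible; use `add_one=True` for a strictly positive estimator.
- TFCE values depend on `dh`; the default relative step (0.1 × map max) is
  accurate to ~0.25% for isolated peaks but any fixed step is a quadrature
  approximation.
- The generator's Gaussian, spatially-uncorrelated noise understates the
  smoothness of real imaging maps; TFCE's advantage over peak-level
  statistics is correspondingly understated in simulation.
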