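# Methods note

This note records the statistical model behind `agescreen`, the design of the
synthetic data generator, and the numerical choices that matter for
reproducing its results.

## 1. Epigenetic age and acceleration

**Age transform.** All clock arithmetic happens on the transformed age scale

```
F(age) = log((age + 1) / (adult_age + 1))      age <= adult_age
F(age) = (age - adult_age) / (adult_age + 1)   age >  adult_age
```

with `adult_age = 20`. F is continuous with continuous first derivative
`1/(adult_age+1)` at the knot and maps `age > -1` onto the real line. A
consequence used throughout: an additive offset `d` on the transformed scale
equals an offset of exactly `d * (adult_age + 1)` **years** for adults, but is
compressed by a factor `(age+1)/(adult_age+1)` for children. Year-scale
claims ("the injected acceleration is 7.5 years") are therefore exact only on
the adult branch; the acceptance checks for acceleration recovery, batch
restoration and screen calibration run on adult-age cohorts for this reason.

**Clocks.** A clock is `raw = intercept + sum_j w_j * beta_j` followed by the
inverse transform. Missing probes follow an *available-only* policy by
default: the raw score sums available terms only and the per-sample coverage
fraction is reported (a warning notes that predictions may be offset); a
`fail` policy raises instead. The mitotic score (`pcgt_age`) is the plain mean
beta over a Polycomb-target probe set.

**Control model and EAA.** On control samples only,

```
DNAmAge ~ const + Age + Sex [+ cell proportions] + PC1..PCK
```

is fitted by OLS. Controls' EAA are the fit residuals; any other sample's EAA
is observed minus predicted. The calibration metric is
`MAE = median(|EAA_i|)` over the fitting controls. For residuals that are
N(0, sd) this has closed form `sd * z_0.75 ≈ 0.6745 * sd`, which the tests
use as an oracle. When cell-composition correction (CCC) is on and the
proportions sum to one, the last cell-type column is dropped to keep the
design full rank.

**Technical PCs.** PCA with centring but **no scaling** on raw control-probe
intensities (samples x features). Scores are the centred data projected on
the right singular vectors; each component's sign is fixed so its
largest-magnitude loading is positive (determinism). The number of PCs is
chosen by a scree elbow: the point with maximum perpendicular distance to the
chord joining the first and last scree points, ties broken toward smaller K.
The published 450K screen's optimum (17) is available as `"paper-default"`.

**Screen.** Eligible disorders (≥ `min_n` = 5 samples, ≥ `min_adults` = 2 with
age ≥ 20) are compared to controls with a two-sided Wilcoxon rank-sum test:
exact null distribution when `min(n1, n2) <= 10` and the pooled sample has no
ties, otherwise normal approximation with continuity correction. P-values are
Bonferroni-corrected over the disorders tested in the run, α = 0.01.

## 2. Other analytics

**Deconvolution.** Per sample, `min_p ||beta - R p||^2` subject to `p >= 0`
and `sum(p) <= 1` (default) or `= 1`. The solver is Lawson–Hanson NNLS,
escalating to an exact active-set KKT solve on the probability simplex when
the NNLS optimum leaves the feasible set. Probes are matched by id and sorted
canonically, so results are order-invariant; missing betas are dropped
pairwise per sample.

**Entropy.** Per sample over N usable probes,
`1/(N log2(1/2)) * sum_i [b log2 b + (1-b) log2(1-b)]` with the exact
`0*log 0 = 0` convention: 1 at β ≡ 0.5, 0 at β ∈ {0,1}, 0.5 for (0.5, 0).
Entropy acceleration reuses the control-model machinery with the response
swapped.

**DMPs.** Per-probe OLS with a shared design matrix, vectorised as
`(X'X)^{-1} X'Y` with per-probe residual variances and t-tests (cross-checked
against statsmodels in the tests). Age contrast: controls only, target `Age`.
Disease contrast: controls plus one case group, target `Disease_status`
(case = 1, so hypomethylated-in-cases means a negative coefficient).
Zero-variance probes are excluded and the Bonferroni divisor is the number of
probes actually tested. Clock-site profiles add `Age^2`; case deviations are
observed minus predicted beta, optionally standardised by the per-probe
residual scale.

**Annotation.** Continuous tracks are summarised per probe as the per-base
mean over `[pos - 200, pos + 200]` (2·200+1 bases; uncovered bases count 0;
windows truncated at 0 and at the chromosome end), implemented as a cumulative
integral of the piecewise-constant track. Signals are Z-scored (ddof = 1)
across probes; replicates are averaged after Z-scoring (NFC); RNA uses
`log2(1 + sur+ + sur-)` before Z-scoring (NRE). CGI context uses distance to
the nearest contained CGI base: shore for 0 < d ≤ 2000, shelf for
2000 < d ≤ 4000, inclusive upper bounds. Enrichment is a two-sided Fisher
exact test (point-probability rule) on subset vs (universe − subset), with the
sample odds ratio and Haldane 0.5 added to all cells iff any cell is zero.

## 3. Synthetic data generator

The generator is designed so that every pipeline claim has a known truth.

**Clock probes.** Betas follow `squash(a_j + s_j * T)` with
`T = F(age) + (delta + eps + batch_shift) / (adult_age + 1)`. The "squash" is
a saturating **piecewise-linear** clip into [0.001, 0.999] rather than a true
sigmoid: the bundled clock (weights `w_j = 1/(n s_j)`, intercept
`-sum w_j a_j`) must invert the betas *exactly* back to age, and a genuine
sigmoid cannot be inverted by a linear clock. Anchor and slope ranges are
chosen so trajectories never leave the linear region at the default noise
levels; noise-free inversion error is ~1e-14 years.

**Noise and accelerations on the transformed scale.** The residual noise
(`residual_sd`, default 2), the injected accelerations `delta` and the
per-batch shifts all enter as `x / (adult_age + 1)` on the transformed scale,
so for adults they are *exactly* `x` years. Case age ranges default to
20–55, so "median case EAA = delta" holds in expectation without transform
bias.

**Batch effects.** Each batch gets (i) a coherent DNAmAge shift (drawn
standard normal, then centred and rescaled so the realised between-batch sd
equals `batch_effect_years` exactly — with only 4 batches the raw draw is
often far from its nominal sd, which would make correction benchmarks a test
of the rng), (ii) incoherent per-(batch, probe) beta offsets on non-clock
probes, and (iii) per-batch mean vectors in the control-probe intensities, so
batch is recoverable from the top technical PCs.

**Paired counterfactuals.** Every random quantity is drawn as a standard
variate and then multiplied by its scale. Two configs that differ only in
effect sizes (e.g. `batch_effect_years` 4 vs 0) therefore share every other
realisation — the batch-restoration check compares a cohort against its own
batch-free twin rather than an independent draw.

**Other probe classes.** Cell probes are convex mixtures of a bundled
reference with age-drifting Dirichlet proportions; aDMPs drift ±0.003
beta/year; disease DMPs shift ±0.1 in one disorder's cases; the rest are null.
A toy genome assigns positions every 1 kb on one chromosome, with enhancer
membership designed to give hypomethylated disease DMPs odds
`enhancer_odds = 6` relative to a base rate of 0.1, plus CGI/gene-body
intervals and tiled bedGraph tracks depleted around hypo probes.

**Key defaults** (see `SimulationConfig`): 300 controls; disorders
`accelerated` (+7.5 y) and `neutral` (0 y), 20 cases each, adult case ages;
4 batches, shift sd 4 y, intensity scale 300 over noise 50 (200 control
features); 2000 probes (30 clock, 60 cell, 150+150 aDMP, 100+20 disease);
residual sd 2 y; beta noise 0.02; QC log2-intensity mean 11.5 against the
10.5 threshold.

## 4. Numerical and testing choices

- OLS via `numpy.linalg` in the vectorised per-probe path, `statsmodels.OLS`
  for the single-response control model and slope summaries; the two are
  cross-checked in the tests.
- Wilcoxon and Fisher tests call scipy; the tests verify them against full
  combinatorial/hypergeometric enumeration oracles (all group sizes ≤ 6, all
  2×2 tables with total ≤ 30).
- Interval containment, CGI distances and windowed means use
  `numpy.searchsorted` over sorted arrays (0-based half-open convention
  everywhere); brute-force per-base oracles bound the error at 1e-9.
- Acceptance checks that quantify year-scale recovery use adult cohorts (see
  §1) and, for the batch-restoration margin, 600 controls — the median-based
  MAE at 300 controls has ~5% relative sampling noise, too coarse for a
  10% equivalence margin.

## 5. Limitations

- The generator's clock trajectories are effectively linear in transformed
  age; real clock CpGs saturate, so real-data coverage loss biases
  predictions in ways the synthetic bundle does not reproduce.
- Per-(batch, probe) offsets induce within-batch correlated errors that
  per-probe OLS treats as independent; at desk scale this can produce a small
  excess of jointly-significant DMP false positives. Passing technical PCs to
  `find_dmps` mitigates this, as on real arrays.
- Children's year-scale effects are compressed by the age transform
  (§1): screens on predominantly paediatric cohorts measure attenuated
  accelerations, which mirrors the real behaviour of Horvath-style clocks.
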