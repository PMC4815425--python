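# Methods

## Model and procedure

`metadeg` synthesises per-study differential-expression results for one gene
at a time. The unit of synthesis is the *contrast*: one treated-vs-control
comparison within one study and plant part. A study that assayed several
plant parts contributes each part as its own contrast, treated as
independent — not a conservative choice, but the only way to retain that
information without a multivariate model, and the convention the rest of the
package (design construction, roster generator) assumes.

**Effect sizes.** For arm means Ȳ₁ (treated), Ȳ₂ (control), unbiased
variances s₁², s₂² and replicate counts n₁, n₂, the log response ratio and
its approximated sampling variance are

    lnR = ln(Ȳ₁/Ȳ₂),    v = s₁²/(n₁Ȳ₁²) + s₂²/(n₂Ȳ₂²).

By default these formulas are applied to the expression values exactly as
provided, i.e. to means of log2-scale intensities. That is deliberate: GCRMA-style pipelines hand downstream analysis log2
matrices, and the pipeline takes them at face value. Whether
the ratio "should" instead be formed on back-transformed intensities is
genuinely open; `effect_scale: delog2` recomputes means and variances on
2^x replicate-wise for users who prefer the raw-intensity reading. Both
scales are tested; `as_given` is the default and is what every calibration
number in this repository uses. No Hedges-type small-sample bias correction
is applied — the plain formulation is the one in general use.

**Random-effects synthesis.** With K contrasts per gene, weights are
w_i = 1/(v_i + τ²), the pooled effect is μ̂ = Σwθ̂/Σw with s²_μ̂ = 1/Σw.
τ² is estimated by REML (default for the meta-analysis) via Fisher scoring
on the intercept-only restricted likelihood, or by the DerSimonian–Laird
moment estimator (default for the meta-regression, where the moment
estimator is the long-standing standard). The 95% CI uses a Student-t multiplier with K−1 df by default;
the test statistic z = μ̂/s_μ̂ and its two-sided p-value use the normal
distribution. This split — t-based interval, normal-based test — is the combination
classical meta-analysis texts describe and the one this pipeline adopts;
both pieces are independently configurable (`ci_distribution`).

**Meta-regression.** One categorical moderator at a time (plant part or
stress method), cell-means coding without an intercept so each coefficient
is a level mean. Residual τ² uses the moderator-adjusted (generalised) DL
estimator: fixed-effect-weighted WLS residual sum of squares Q_E, with
τ² = max(0, (Q_E − (K−m))/tr(P₀)). Final coefficients come from WLS with
weights 1/(v+τ²); coefficient tests and CIs are normal-based. The moderator
test Q_M is a Wald chi-square. Two hypotheses are sensible under no-intercept coding: that all level
means are equal (m−1 df — does the moderator matter?) and that all
coefficients are zero (m df — is there any response at all?). The default
is the equality test, the scientifically meaningful moderator question;
the m-df all-zero omnibus is available via `qm_df_convention: m`. Moderators are fit
one at a time; part analyses exclude seedling material, method analyses
exclude polyethylene-glycol treatments (each leaves too few contrasts to
estimate its own level).

**Moderated t-tests.** The per-study baseline shrinks each gene's pooled
two-sample variance toward a genome-wide prior under the scaled-F model:
s²_post = (d₀s₀² + d·s²_g)/(d₀ + d), t = logFC/√(s²_post(1/n₁+1/n₂)) with
d + d₀ df. (d₀, s₀²) come from the closed-form method of moments on log
residual variances; when the observed log-variance spread does not exceed
the chi-square sampling spread, d₀ = ∞ and s₀² is the arithmetic mean
variance (the convention of the reference limma implementation, with which the
test suite verifies agreement to ~1e-13). A contrast that yields zero DEGs
is a legitimate outcome, not an error.

**Multiplicity.** Benjamini–Hochberg step-up, applied separately per
analysis family (genome-wide meta-analysis; each meta-regression moderator;
each per-study contrast), so each scientific question controls its own
expected false-discovery proportion.

## Filters

Two pooled-sample inclusion rules precede all statistics: log2 intensity at
least log2(100) in ≥10% of all samples, and interquartile range of the log2
values across all arrays ≥0.5. The phrase "log2 fluorescence intensity of
100" is ambiguous; a log2 value of 100 is physically impossible for
microarray data, so the raw-scale reading (cutoff log2(100) ≈ 6.64) is the
default and the literal log2-scale reading is available via
`intensity_threshold_is_log2`. Quartiles use linear interpolation (the
numpy/R type-7 default), declared so threshold behaviour is exact; ties
follow from it.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha` | 0.05 | — | conventional FDR level |
| `tau2_method_meta` / `_metareg` | reml / dl | — | REML for efficiency; DL as the standard moment estimator for meta-regression |
| `ci_distribution` | student_t | — | t[K−1] interval accounts for estimating τ² |
| `intensity_threshold_raw` | 100 | raw fluorescence | standard low-expression cutoff for this array type |
| `intensity_min_fraction` | 0.10 | fraction of samples | keeps genes expressed in a subset of conditions |
| `iqr_threshold_log2` | 0.5 | log2 units | drops invariant genes |
| `qm_df_convention` | m_minus_1 | — | equality-of-means test |
| `var_floor` | 1e-8 | (ln-ratio)² | keeps weights finite when both arm variances are 0 (floored records are logged) |

## Synthetic generator

The generator emulates the structure of the motivating collection: ten
contrasts from eight studies (two studies assay both root and shoot; one
seedling study uses PEG; one uses deracination), 3 replicates per arm for
6-array studies and 2 for 4-array studies. Per gene: null with probability
`pi0` (0.8), otherwise μ_g ~ N(0, `effect_sd`² = 0.25); per contrast the
true effect is θ = μ + moderator shift + N(0, `tau2` = 0.05). Control
replicates are normal with sd `noise_sd` = 0.25 around
baseline + batch; treated replicates around (baseline + batch)·e^θ, so the
expected lnR on the analysis scale equals θ and the per-study batch shift
(sd 0.2, applied to both arms) cancels exactly from the ratio — batch is
between-study random error, not a modelled covariate (an
`asymmetric_batch` option breaks this for robustness stress-tests).
Baseline log2 intensities are N(8, 1): well above the intensity cutoff, the
location of a typical GCRMA-normalised array; replicate noise of 0.25 log2
units is typical biological-replicate variability for such data. Part
shifts are antisymmetric (root +d, shoot −d, d ~ N(0, sd²)), so each
level's shift is marginally normal with the stated sd while moderated genes
respond in opposite directions in the two parts; method shifts are
independent per level. Null genes have μ = 0 and no shifts but keep τ²
heterogeneity: they respond in individual studies, just not on average —
which is exactly the null the meta-analysis tests.

What the generator does **not** emulate: probe-level effects and
normalisation artifacts, cross-hybridisation, correlated genes, gene-specific
replicate variances within a contrast (variance heterogeneity appears only
between arms/contrasts), mean–variance trends, or time-series structure.
Passing calibration tests therefore demonstrates correctness of the
statistical machinery under the declared model, not robustness to everything
real arrays do.

Calibration runs use 2000 genes, 8 two-arm studies with 3 replicates per
arm, and (for the false-discovery measurement) 20 simulation seeds — sizes
chosen so each quantity's Monte-Carlo error is a small fraction of the
tolerance being checked while the whole suite stays interactive.

## Numerical choices

- REML Fisher scoring: convergence |Δτ²| < 1e-8, ≤100 iterations,
  truncation at 0, boundary detected by a non-positive score at τ² = 0;
  non-convergent genes fall back to DL with a per-gene flag. The batch
  (vectorised) and scalar paths are verified against each other and against
  a 1e-5-resolution grid search of the restricted likelihood.
- Weighted least squares via the one-hot shortcut (per-level weighted
  means, diagonal covariance) genome-wide, verified against the explicit
  matrix solve to 1e-10.
- p-values are clipped below at the smallest positive double so that
  extreme z-scores never underflow to 0 (the BH invariant requires
  p ∈ (0,1]).
- Genes observed in a single contrast pass through with τ² = 0 and a
  `k1_flag`; genes with a non-positive arm mean on the analysis scale are
  excluded from the effect table and reported.
- Orderings break ties lexicographically on gene id; in the CI-gap forest
  ordering, genes whose CI spans zero are sorted below the rest by
  descending |μ̂|, so the largest unresolved responses sit nearest the
  significant block.
- Moderation labels ("reversed" vs "differential magnitude") are post-hoc:
  FDR-significant Q_M plus opposite-signed, individually significant level
  means ⇒ reversed. These rules are this package's own, not asserted as the
  original classification.

## Known limitations

**Small-K anti-conservatism of the normal reference.** With realistic
replicate noise on the log2 scale, Eq-style sampling variances are of order
10⁻³–10⁻⁴ while τ² = 0.05, so the null distribution of z = μ̂/s_μ̂ with an
estimated τ² at K = 8 is close to Student-t with K−1 df, not normal.
Referring z to the normal (the classical large-K convention, and the
default here)
makes null p-values anti-conservative, and BH inherits the inflation: the
acceptance measurement of the realised false-discovery proportion under the
default conditions gives ≈0.16 at nominal 0.05 (the package's acceptance
script computes this), whereas referring the same statistics to t[K−1]
restores control (≈0.04, verified in development). The same mechanism makes
Q_M (χ²-referred Wald with DL-estimated τ² and ~7 residual df) mildly
anti-conservative, which a KS uniformity test at 2000 genes detects. The
Student-t *interval* is, by contrast, well calibrated (~95% coverage), since
it uses the K−1-df multiplier. Users who need strict FDR control at small K
should treat the normal-based p-values as liberal; a Knapp–Hartung-type adjustment is deliberately out of scope to keep the
default procedure the classical one.

**Other limitations.** Pseudo-independence of multi-part contrasts from the
same study understates correlation between them; no publication-bias
diagnostics; no multivariate or continuous-moderator models (a
multi-moderator design matrix is accepted but untested against any
reference); moderated t-tests implement the basic two-group shrinkage only
(no array weights, variance trend, or robust prior).
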