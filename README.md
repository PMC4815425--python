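# metadeg

Cross-study synthesis of differential gene expression by inverse-variance
weighted random-effects **meta-analysis** and **meta-regression**, with
per-study moderated t-tests as the conventional baseline.

Transcriptomic studies that ask the same question (say, how *Arabidopsis
thaliana* responds to water stress) only partially agree on which genes are
differentially expressed. Listing and intersecting per-study DEG sets ignores
both the precision of each study (its sampling variance) and genuine
between-study heterogeneity (batch effects, methodological differences).
`metadeg` synthesises per-study results the way quantitative research
synthesis does it: each gene's per-study response becomes an effect size with
a sampling variance, studies are combined with inverse-variance weights under
a random-effects model, and study-level covariates (plant part, stress
method) are tested by meta-regression. This recovers genes with small but
consistent responses that no single study can detect, and rejects large but
idiosyncratic ones.

## The model

For gene *g* in contrast *i* (one treated-vs-control comparison within one
study and plant part), with arm means Ȳ₁, Ȳ₂, variances s₁², s₂² and
replicate counts n₁, n₂:

- effect size (log response ratio): **lnR_i = ln(Ȳ₁/Ȳ₂)**
- sampling variance: **v_i = s₁²/(n₁Ȳ₁²) + s₂²/(n₂Ȳ₂²)**

Across K contrasts the random-effects model weights each contrast by
**w_i = 1/(v_i + τ²)**, where τ² (between-study variance) is estimated by
REML (default) or DerSimonian–Laird, and reports

- pooled effect **μ̂ = Σwθ̂/Σw** with variance **s²_μ̂ = 1/Σw**,
- a 95% CI **μ̂ ± s_μ̂ · t₀.₀₂₅[K−1]** (normal multiplier optional),
- **z = μ̂/s_μ̂** with a two-sided normal p-value,

and p-values are adjusted genome-wide by the Benjamini–Hochberg step-up
procedure. Meta-regression replaces the single mean by per-level means of a
categorical moderator (cell-means coding, no intercept), estimates residual
τ² by the moderator-adjusted DL estimator, and tests moderation with the
Wald chi-square **Q_M** (default: equality of level means, χ²[m−1]).
Moderated t-tests (empirical-Bayes variance shrinkage across genes) provide
the per-study comparison baseline.

A bundled synthetic-data generator emulates a realistic multi-study
collection — ten two-arm contrasts from eight studies, 2–3 biological
replicates per arm, log2-scale intensities, per-study batch shifts, a null
fraction, τ² heterogeneity and optional moderator effects — with full ground
truth, so every calibration claim is testable offline.

## Worked example

```python
import metadeg as md
from metadeg.synthgen import SimParams

params = SimParams(n_genes=1000, seed=42, part_effect_sd=0.3)
study, sheet, truth = md.simulate_collection(params)

result = md.run_meta_pipeline(study)          # filter -> lnR -> REML meta -> BH
gene_table, coef_table = md.run_metareg(result.effects, "part")
report = md.recovery_report(truth, result.fits, metareg_gene_table=gene_table)
```

This prints (via the stage log / the objects above):

```
retained after filtering: 981 of 1000
meta-analysis calls at FDR 0.05: 67 up, 79 down, 835 ns
           mu_hat  ci_lo  ci_hi    q
254948_at  -1.998 -2.510 -1.487  0.0
254341_at  -1.667 -1.956 -1.377  0.0
254815_at  -1.342 -1.497 -1.187  0.0
part-moderated genes (Q_M FDR < 0.05): 108
{'bias_mu': -0.002, 'rmse_mu': 0.094, 'tau2_median': 0.049, 'coverage': 0.94, ...}
```

Reading: 981 of 1000 simulated probe sets pass the intensity/IQR filters; the
meta-analysis calls 146 genes differentially expressed at FDR 0.05; the three
genes whose 95% CIs sit furthest from zero (the top of the CI-gap-sorted
forest plot) are strong repressions (μ̂ ≈ −2.0 to −1.3 ln-units); 108 genes
show significant part moderation (the generator planted opposite root/shoot
shifts of sd 0.3); and against the known truth the pooled estimates are
essentially unbiased (bias −0.002), the τ² median (0.049) matches the true
0.05, and the 95% CI covers the true mean for 94% of genes.

The same pipeline is scriptable from the shell:

```sh
metadeg simulate --genes 1000 --seed 42 --out sim/
metadeg filter --matrix sim/matrix.tsv --out sim/filtered.tsv
metadeg effects --matrix sim/filtered.tsv --sheet sim/samples.tsv --out sim/effects.tsv
metadeg meta --effects sim/effects.tsv --out sim/meta.tsv
metadeg metareg --effects sim/effects.tsv --moderator part --out sim/metareg.tsv
metadeg report --matrix sim/matrix.tsv --sheet sim/samples.tsv --out-prefix sim/rep
```

## Layout

- `metadeg.datamodel` – expression matrices, sample sheets, run configuration (TSV/YAML I/O)
- `metadeg.filtering` – probe-set intensity and IQR inclusion filters
- `metadeg.effects` – contrast summaries, lnR and its variance
- `metadeg.meta` – DL/REML τ², per-gene random-effects fits (vectorised)
- `metadeg.metareg` – moderator designs, weighted least squares, Q_M
- `metadeg.modttest` – per-study moderated t-tests
- `metadeg.inference` – BH step-up, gene calls, forest orderings, set comparisons
- `metadeg.synthgen` – synthetic multi-study generator with ground truth
- `metadeg.pipeline` / `metadeg.cli` – end-to-end drivers and the `metadeg` command
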