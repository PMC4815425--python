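"""Per-study moderated t-tests (empirical-Bayes variance shrinkage).

The comparison baseline for the meta-analysis: within a single contrast,
each gene's two-sample t statistic is computed with its residual variance
shrunk toward a genome-wide prior.  With residual df d = n1 + n2 - 2 and
per-gene pooled variance s2_g, the scaled-F hierarchical model
s2_g ~ s0^2 * chi2_d / d (given gene variance) with an inverse-chi-square
prior of d0 df and scale s0^2 gives the posterior variance

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated statistic

    t_mod = log_fc / sqrt(s2_post * (1/n1 + 1/n2)),  df = d + d0.

(d0, s0^2) are estimated across genes by the method of moments on
log residual variances (matching the closed-form moment estimator used
throughout the microarray literature).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import DataError, ExpressionStudy, RunConfig, log
from .inference import bh_adjust


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise DataError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (d0, s0^2) of the variance prior.

    Fits a scaled F distribution to the observed residual variances via
    the moments of log(s2): with z = log(s2),
    e = z - digamma(df/2) + log(df/2) has mean log(s0^2) + digamma(d0/2)
    - log(d0/2) and excess variance trigamma(d0/2).  Returns
    d0 = inf when the observed spread does not exceed the chi-square
    sampling spread (complete pooling).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise DataError("need >= 2 positive residual variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        # spread of log-variances does not exceed chi-square sampling
        # spread: complete pooling toward the plain mean variance
        d0 = np.inf
        s0_2 = s2[ok].mean()
    return float(d0), float(s0_2)


def moderated_t(
    study: ExpressionStudy,
    contrast_id: str,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Moderated t-test for every gene in one contrast.

    Returns a per-gene table with log_fc (mean difference on the log2
    scale), s2_g, s2_post, t_mod, df_total, p and BH-adjusted q.
    ``cfg.mod_t_d0`` forces the prior df (0 recovers the ordinary t,
    ``inf`` complete pooling); the prior also degenerates to the ordinary
    t with a warning if it cannot be estimated (e.g. all variances zero).
    """
    cfg = cfg or RunConfig()
    if study.samples is None:
        raise DataError("study must be annotated with a sample sheet")
    samples = study.samples
    study_id, _, part = contrast_id.partition(":")
    in_contrast = (samples["study_id"] == study_id) & (samples["part"] == part)
    if not in_contrast.any():
        raise DataError(f"no such contrast: {contrast_id}")
    t_cols = np.flatnonzero(in_contrast & (samples["arm"] == "treated"))
    c_cols = np.flatnonzero(in_contrast & (samples["arm"] == "control"))
    n1, n2 = len(t_cols), len(c_cols)
    if n1 < 2 or n2 < 2:
        raise DataError(
            f"contrast {contrast_id}: needs >=2 replicates per arm "
            f"(treated={n1}, control={n2})"
        )
    matrix = study.matrix.to_numpy()
    t_arm = matrix[:, t_cols]
    c_arm = matrix[:, c_cols]
    log_fc = t_arm.mean(axis=1) - c_arm.mean(axis=1)
    d = n1 + n2 - 2
    s2_g = (
        t_arm.var(axis=1, ddof=1) * (n1 - 1) + c_arm.var(axis=1, ddof=1) * (n2 - 1)
    ) / d

    if cfg.mod_t_d0 is not None:
        d0 = float(cfg.mod_t_d0)
        s0_2 = np.nan
        if np.isinf(d0) or d0 > 0:
            try:
                _, s0_2 = fit_f_dist(s2_g, d)
            except DataError:
                pass
    else:
        try:
            d0, s0_2 = fit_f_dist(s2_g, d)
        except DataError:
            log.warning(
                "contrast %s: variance prior not estimable, using ordinary t",
                contrast_id,
            )
            d0, s0_2 = 0.0, np.nan

    if d0 == 0.0:
        s2_post = s2_g
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2_g, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2_g) / (d0 + d)
        df_total = float(d + d0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.nextafter(0, 1), 1.0)
    out = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "contrast_id": contrast_id,
            "log_fc": log_fc,
            "s2_g": s2_g,
            "s2_post": s2_post,
            "t_mod": np.nan_to_num(t_mod, nan=0.0),
            "df_total": df_total,
            "p": p,
            "q": bh_adjust(p),
        }
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2) if np.isfinite(d0) or d0 == np.inf else np.nan
    log.info(
        "moderated t (%s): d0=%.3g, s0^2=%.3g, %d genes",
        contrast_id,
        d0,
        out.attrs["s0_2"],
        len(out),
    )
    return out


def moderated_t_all(
    study: ExpressionStudy, cfg: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Moderated t results for every estimable contrast in the collection."""
    from .datamodel import contrast_table

    results = {}
    for row in contrast_table(study).itertuples(index=False):
        if row.n1 >= 2 and row.n2 >= 2:
            results[row.contrast_id] = moderated_t(study, row.contrast_id, cfg)
    return results
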