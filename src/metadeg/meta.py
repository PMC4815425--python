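"""Per-gene random-effects meta-analysis across contrasts.

Given effect sizes theta_i with sampling variances v_i from K contrasts,
the random-effects model weights each contrast by

    w_i = 1 / (v_i + tau^2)

where tau^2 is the between-study variance, and reports the weighted mean
effect

    mu_hat = sum(w_i * theta_i) / sum(w_i),    var(mu_hat) = 1 / sum(w_i).

tau^2 is estimated by restricted maximum likelihood (default, Fisher
scoring) or by the DerSimonian-Laird moment estimator.  The 95% CI uses a
Student-t multiplier with K-1 degrees of freedom (default) or a normal
multiplier; the test statistic z = mu_hat / se and its two-sided p-value
are referred to the normal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import RunConfig, log

_REML_TOL = 1e-8
_REML_MAX_ITER = 100


@dataclass
class MetaFit:
    """Random-effects fit for one gene."""

    gene_id: str | None
    k: int
    tau2: float
    weights: np.ndarray      # normalised, sum to 1
    mu_hat: float
    se_mu: float
    ci_lo: float
    ci_hi: float
    z: float
    p: float
    q_cochran: float
    tau2_method: str
    converged: bool = True


def _as_arrays(theta, v) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    v = np.asarray(v, dtype=float)
    if theta.shape != v.shape or theta.ndim != 1:
        raise ValueError("theta and v must be 1-d arrays of equal length")
    if (v <= 0).any():
        raise ValueError("sampling variances must be positive")
    return theta, v


def cochran_q(theta, v) -> float:
    """Heterogeneity statistic with fixed-effect weights 1/v."""
    theta, v = _as_arrays(theta, v)
    w = 1.0 / v
    theta_fe = np.sum(w * theta) / np.sum(w)
    return float(np.sum(w * (theta - theta_fe) ** 2))


def dl_tau2(theta, v) -> float:
    """DerSimonian-Laird moment estimator of the between-study variance.

    tau2 = max(0, (Q - (K-1)) / (sum(w) - sum(w^2)/sum(w))) with w = 1/v.
    Returns 0 (with a warning) for K < 2.
    """
    theta, v = _as_arrays(theta, v)
    k = len(theta)
    if k < 2:
        warnings.warn("tau^2 undefined for a single contrast; returning 0")
        return 0.0
    w = 1.0 / v
    q = cochran_q(theta, v)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    if c <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / c))


def _reml_batch(
    theta: np.ndarray, v: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-scoring REML for a (G, K) batch of intercept-only models.

    ``mask`` marks observed entries (True = present); genes with < 2
    observed contrasts get tau2 = 0.  Returns (tau2, converged) arrays.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if mask is None:
        mask = np.ones_like(theta, dtype=bool)
    k = mask.sum(axis=1)
    vm = np.where(mask, v, np.inf)

    # DL start (vectorised)
    w0 = np.where(mask, 1.0 / vm, 0.0)
    sw0 = w0.sum(axis=1)
    theta0 = np.where(mask, theta, 0.0)
    mu_fe = np.einsum("gk,gk->g", w0, theta0) / np.where(sw0 > 0, sw0, 1.0)
    q = np.einsum("gk,gk->g", w0, np.where(mask, (theta0 - mu_fe[:, None]) ** 2, 0.0))
    c = sw0 - (w0**2).sum(axis=1) / np.where(sw0 > 0, sw0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where((k >= 2) & (c > 0), np.maximum(0.0, (q - (k - 1)) / c), 0.0)
    tau2_dl = tau2.copy()

    active = k >= 2
    converged = ~active  # k<2 genes are trivially done (tau2=0)
    for _ in range(_REML_MAX_ITER):
        if not active.any():
            break
        w = np.where(mask, 1.0 / (vm + tau2[:, None]), 0.0)
        sw = w.sum(axis=1)
        mu = np.einsum("gk,gk->g", w, theta0) / np.where(sw > 0, sw, 1.0)
        resid2 = np.where(mask, (theta0 - mu[:, None]) ** 2, 0.0)
        sw2 = (w**2).sum(axis=1)
        sw3 = (w**3).sum(axis=1)
        score = 0.5 * (np.einsum("gk,gk->g", w**2, resid2) - (sw - sw2 / sw))
        info = 0.5 * (sw2 - 2.0 * sw3 / sw + (sw2 / sw) ** 2)
        step = np.where(info > 0, score / np.where(info > 0, info, 1.0), 0.0)
        new = np.maximum(0.0, tau2 + np.where(active, step, 0.0))
        # boundary: negative score at tau2=0 => maximum is at the boundary
        done = np.abs(new - tau2) < _REML_TOL
        done |= (tau2 == 0.0) & (score <= 0.0)
        tau2 = np.where(active, new, tau2)
        newly = active & done
        converged |= newly
        active &= ~done
    # non-converged genes fall back to DL
    tau2 = np.where(~converged & (k >= 2), tau2_dl, tau2)
    return tau2, converged


def reml_tau2(theta, v) -> float:
    """REML estimate of tau^2 for one gene (intercept-only model).

    Fisher scoring, convergence |delta tau^2| < 1e-8, at most 100
    iterations; truncated at 0.  Falls back to the DerSimonian-Laird value
    with a warning if scoring does not converge.
    """
    theta, v = _as_arrays(theta, v)
    if len(theta) < 2:
        warnings.warn("tau^2 undefined for a single contrast; returning 0")
        return 0.0
    tau2, conv = _reml_batch(theta[None, :], v[None, :])
    if not conv[0]:
        warnings.warn("REML did not converge; falling back to DerSimonian-Laird")
    return float(tau2[0])


def restricted_loglik(tau2: float, theta, v) -> float:
    """Restricted log-likelihood of the intercept-only model at tau^2.

    Exposed for oracle cross-checks (grid searches in tests).
    """
    theta, v = _as_arrays(theta, v)
    w = 1.0 / (v + tau2)
    mu = np.sum(w * theta) / np.sum(w)
    return float(
        -0.5
        * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (theta - mu) ** 2)
        )
    )


def fit_random_effects(
    theta,
    v,
    cfg: RunConfig | None = None,
    gene_id: str | None = None,
    tau2: float | None = None,
) -> MetaFit:
    """Full random-effects fit for one gene.

    ``tau2`` may be supplied to force a value (e.g. 0 for the
    fixed-effects limit); otherwise it is estimated by the configured
    method.  K = 1 genes pass through with tau2 = 0.
    """
    cfg = cfg or RunConfig()
    theta, v = _as_arrays(theta, v)
    k = len(theta)
    if k == 0:
        raise ValueError("no contrasts supplied")
    converged = True
    method = cfg.tau2_method_meta
    if tau2 is None:
        if k == 1:
            tau2 = 0.0
        elif method == "dl":
            tau2 = dl_tau2(theta, v)
        else:
            t_arr, conv = _reml_batch(theta[None, :], v[None, :])
            tau2, converged = float(t_arr[0]), bool(conv[0])
    else:
        method = "fixed"
    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    mu = float(np.sum(w * theta) / sw)
    se = float(np.sqrt(1.0 / sw))
    if cfg.ci_distribution == "student_t" and k > 1:
        mult = float(stats.t.ppf(1 - cfg.alpha / 2, df=k - 1))
    else:
        mult = float(stats.norm.ppf(1 - cfg.alpha / 2))
    z = mu / se
    p = float(max(2 * stats.norm.sf(abs(z)), np.finfo(float).tiny))
    return MetaFit(
        gene_id=gene_id,
        k=k,
        tau2=float(tau2),
        weights=w / sw,
        mu_hat=mu,
        se_mu=se,
        ci_lo=mu - mult * se,
        ci_hi=mu + mult * se,
        z=float(z),
        p=p,
        q_cochran=cochran_q(theta, v) if k > 1 else 0.0,
        tau2_method=method,
        converged=converged,
    )


def fit_random_effects_table(
    effects: pd.DataFrame, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Vectorised per-gene random-effects fits for an effect-size table.

    ``effects`` is the long table produced by
    :func:`metadeg.effects.compute_effects` (columns gene_id, contrast_id,
    lnr, v).  Genes may be missing from some contrasts.  Returns one row
    per gene, in first-appearance order, with the MetaFit fields plus a
    ``k1_flag`` for single-contrast genes.
    """
    cfg = cfg or RunConfig()
    genes = effects["gene_id"].drop_duplicates()
    theta_w = effects.pivot(index="gene_id", columns="contrast_id", values="lnr")
    v_w = effects.pivot(index="gene_id", columns="contrast_id", values="v")
    theta_w = theta_w.loc[genes]
    v_w = v_w.loc[genes]
    theta = theta_w.to_numpy()
    v = v_w.to_numpy()
    mask = ~np.isnan(theta)
    k = mask.sum(axis=1)
    if (k == 0).any():
        log.warning("%d genes with no contrasts dropped", int((k == 0).sum()))
        keep = k > 0
        theta, v, mask, k = theta[keep], v[keep], mask[keep], k[keep]
        genes = genes[keep]

    if cfg.tau2_method_meta == "reml":
        tau2, converged = _reml_batch(theta, v, mask)
        n_fail = int((~converged).sum())
        if n_fail:
            log.warning("REML fell back to DL for %d genes", n_fail)
    else:
        # vectorised DL
        vm = np.where(mask, v, np.inf)
        w0 = np.where(mask, 1.0 / vm, 0.0)
        sw0 = w0.sum(axis=1)
        th0 = np.where(mask, theta, 0.0)
        mu_fe = np.einsum("gk,gk->g", w0, th0) / sw0
        q = np.einsum("gk,gk->g", w0, np.where(mask, (th0 - mu_fe[:, None]) ** 2, 0.0))
        c = sw0 - (w0**2).sum(axis=1) / sw0
        with np.errstate(invalid="ignore"):
            tau2 = np.where((k >= 2) & (c > 0), np.maximum(0.0, (q - (k - 1)) / c), 0.0)
        converged = np.ones(len(tau2), dtype=bool)

    vm = np.where(mask, v, np.inf)
    w = np.where(mask, 1.0 / (vm + tau2[:, None]), 0.0)
    sw = w.sum(axis=1)
    th0 = np.where(mask, theta, 0.0)
    mu = np.einsum("gk,gk->g", w, th0) / sw
    se = np.sqrt(1.0 / sw)
    if cfg.ci_distribution == "student_t":
        mult = np.where(k > 1, stats.t.ppf(1 - cfg.alpha / 2, df=np.maximum(k - 1, 1)),
                        stats.norm.ppf(1 - cfg.alpha / 2))
    else:
        mult = np.full(len(k), stats.norm.ppf(1 - cfg.alpha / 2))
    z = mu / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    # Cochran Q with fixed-effect weights
    w_fe = np.where(mask, 1.0 / vm, 0.0)
    sw_fe = w_fe.sum(axis=1)
    mu_fe = np.einsum("gk,gk->g", w_fe, th0) / sw_fe
    q_c = np.einsum(
        "gk,gk->g", w_fe, np.where(mask, (th0 - mu_fe[:, None]) ** 2, 0.0)
    )
    out = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "k": k,
            "tau2": tau2,
            "mu_hat": mu,
            "se_mu": se,
            "ci_lo": mu - mult * se,
            "ci_hi": mu + mult * se,
            "z": z,
            "p": p,
            "q_cochran": q_c,
            "k1_flag": k == 1,
            "reml_converged": converged,
        }
    )
    log.info(
        "meta: %d genes fitted (tau2 method %s, CI %s)",
        len(out),
        cfg.tau2_method_meta,
        cfg.ci_distribution,
    )
    return out
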