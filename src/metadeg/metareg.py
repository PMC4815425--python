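"""Per-gene mixed-effects meta-regression with one categorical moderator.

The model for contrast i is

    y_i = sum_l beta_l X_il + u_i + e_i,
    u_i ~ N(0, tau^2),  e_i ~ N(0, v_i),

with cell-means (no-intercept) coding: X_il indicates the moderator level
of contrast i, so each coefficient beta_l is the mean true effect at
level l (mu_root, mu_shoot, or a per-method mean).

Residual heterogeneity tau^2 uses the moderator-adjusted (generalised)
DerSimonian-Laird moment estimator by default (REML optional); final
coefficients come from weighted least squares with weights
1/(v_i + tau^2), with normal-based per-coefficient z, p and CI.

The moderator test Q_M is a Wald chi-square.  With the default
``m_minus_1`` convention it tests equality of all level means
(df = m - 1, the scientifically relevant moderator contrast); the ``m``
convention tests all coefficients equal to zero (df = m).

Study-design conventions for this collection: the *part* moderator keeps
root and shoot contrasts and excludes seedling material; the *method*
moderator keeps water withholding, mannitol and deracination and excludes
polyethylene-glycol treatments.  A study that assayed several plant parts
contributes each part as its own contrast, treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, RunConfig, log

#: moderator -> (levels kept, predicate naming excluded contrasts)
_MODERATOR_RULES = {
    "part": (("root", "shoot"), {"seedling": "seedling material excluded"}),
    "method": (
        ("water_withholding", "mannitol", "deracination"),
        {"peg": "polyethylene-glycol treatment excluded"},
    ),
}


@dataclass
class DesignMatrix:
    """No-intercept indicator design over contrasts for one moderator."""

    moderator: str
    X: pd.DataFrame                      # index contrast_id, one column per level
    level_names: list[str]
    exclusions: list[tuple[str, str]]    # (contrast_id, reason)

    @property
    def contrast_ids(self) -> list[str]:
        return list(self.X.index)


@dataclass
class MetaRegFit:
    """Meta-regression fit for one gene (long-format coefficients)."""

    gene_id: str | None
    coefficients: pd.DataFrame  # level, beta, se, z, p, ci_lo, ci_hi
    tau2_resid: float
    qm: float
    qm_df: int
    p_qm: float


def build_design(
    contrasts: pd.DataFrame, moderator: str, cfg: RunConfig | None = None
) -> DesignMatrix:
    """Build the one-hot design for ``moderator`` from a contrast table.

    ``contrasts`` needs columns contrast_id, part, method (one row per
    contrast; :func:`metadeg.datamodel.contrast_table` or an effect-size
    table both work).  Levels left empty by the exclusions are dropped
    with a warning; fewer than 2 surviving levels is fatal.
    """
    if moderator not in _MODERATOR_RULES:
        raise DataError(f"unknown moderator {moderator!r}; use 'part' or 'method'")
    keep_levels, excl_reasons = _MODERATOR_RULES[moderator]
    cols = ["contrast_id", moderator]
    table = contrasts[cols].drop_duplicates("contrast_id").set_index("contrast_id")
    exclusions: list[tuple[str, str]] = []
    rows = {}
    for cid, level in table[moderator].items():
        if level in excl_reasons:
            exclusions.append((cid, excl_reasons[level]))
        else:
            rows[cid] = level
    levels = [l for l in keep_levels if l in set(rows.values())]
    for l in set(keep_levels) - set(levels):
        log.warning("moderator %s: level %r has no contrasts, dropped", moderator, l)
    if len(levels) < 2:
        raise DataError(
            f"moderator {moderator!r} has {len(levels)} level(s) with data; "
            "need at least 2"
        )
    X = pd.DataFrame(0.0, index=pd.Index(rows, name="contrast_id"), columns=levels)
    for cid, level in rows.items():
        X.loc[cid, level] = 1.0
    log.info(
        "design (%s): %d contrasts x %d levels, %d excluded",
        moderator,
        *X.shape,
        len(exclusions),
    )
    return DesignMatrix(moderator=moderator, X=X, level_names=levels,
                        exclusions=exclusions)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, cov, fitted)."""
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular design matrix (collinear levels)") from exc
    beta = cov @ (Xw.T @ y)
    return beta, cov, X @ beta


def gdl_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Generalised DerSimonian-Laird residual tau^2 for a design X.

    Uses fixed-effect weights W0 = diag(1/v): tau^2 = max(0,
    (Q_E - (K - m)) / tr(P0)) where Q_E is the weighted residual sum of
    squares of the W0-weighted fit and P0 = W0 - W0 X (X'W0X)^-1 X'W0.
    """
    k, m = X.shape
    w0 = 1.0 / v
    beta0, cov0, fitted0 = _wls(X, y, w0)
    qe = float(np.sum(w0 * (y - fitted0) ** 2))
    # tr(P0) = sum(w0) - tr((X'W0X)^-1 X'W0^2 X)
    trp = float(np.sum(w0) - np.trace(cov0 @ (X.T @ (X * (w0**2)[:, None]))))
    if trp <= 0 or k <= m:
        return 0.0
    return max(0.0, (qe - (k - m)) / trp)


def _reml_tau2_design(y: np.ndarray, v: np.ndarray, X: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 100) -> float:
    """REML tau^2 for a general design via Fisher scoring on tr(P)."""
    tau2 = gdl_tau2(y, v, X)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        Xw = X * w[:, None]
        cov = np.linalg.inv(X.T @ Xw)
        py = w * (y - X @ (cov @ (Xw.T @ y)))
        P = np.diag(w) - Xw @ cov @ Xw.T
        score = 0.5 * (py @ py - np.trace(P))
        info = 0.5 * np.sum(P * P)
        if info <= 0:
            break
        new = max(0.0, tau2 + score / info)
        if abs(new - tau2) < tol or (tau2 == 0.0 and score <= 0):
            tau2 = new
            break
        tau2 = new
    return tau2


def qm_test(
    beta: np.ndarray, cov: np.ndarray, convention: str = "m_minus_1"
) -> tuple[float, int, float]:
    """Wald chi-square moderator test.

    ``m_minus_1``: equality of all level means, df = m - 1.
    ``m``: all coefficients zero, df = m.
    """
    beta = np.asarray(beta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    m = len(beta)
    if m < 2:
        raise DataError("Q_M undefined with a single moderator level")
    if convention == "m_minus_1":
        C = np.hstack([-np.ones((m - 1, 1)), np.eye(m - 1)])  # level_j - level_1
        d = C @ beta
        qm = float(d @ np.linalg.solve(C @ cov @ C.T, d))
        df = m - 1
    elif convention == "m":
        qm = float(beta @ np.linalg.solve(cov, beta))
        df = m
    else:
        raise DataError(f"unknown qm_df_convention {convention!r}")
    qm = max(qm, 0.0)
    return qm, df, float(max(stats.chi2.sf(qm, df), np.finfo(float).tiny))


def fit_meta_regression(
    y,
    v,
    design: DesignMatrix,
    cfg: RunConfig | None = None,
    gene_id: str | None = None,
) -> MetaRegFit:
    """Fit the meta-regression for one gene.

    ``y`` and ``v`` are aligned to ``design.contrast_ids`` (pass pandas
    Series indexed by contrast_id, or plain arrays in design row order).
    """
    cfg = cfg or RunConfig()
    if isinstance(y, pd.Series):
        y = y.reindex(design.contrast_ids).to_numpy()
    if isinstance(v, pd.Series):
        v = v.reindex(design.contrast_ids).to_numpy()
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    X = design.X.to_numpy()
    k, m = X.shape
    if len(y) != k or len(v) != k:
        raise DataError("y/v length does not match design")
    if np.isnan(y).any() or np.isnan(v).any():
        raise DataError("missing effect for a design contrast")
    if cfg.tau2_method_metareg == "reml":
        tau2 = _reml_tau2_design(y, v, X)
    else:
        tau2 = gdl_tau2(y, v, X)
    w = 1.0 / (v + tau2)
    beta, cov, _ = _wls(X, y, w)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    mult = stats.norm.ppf(1 - cfg.alpha / 2)
    coef = pd.DataFrame(
        {
            "level": design.level_names,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "ci_lo": beta - mult * se,
            "ci_hi": beta + mult * se,
        }
    )
    if m >= 2:
        qm, df, p_qm = qm_test(beta, cov, cfg.qm_df_convention)
    else:
        qm, df, p_qm = np.nan, 0, np.nan  # moderator test undefined
    return MetaRegFit(
        gene_id=gene_id,
        coefficients=coef,
        tau2_resid=float(tau2),
        qm=qm,
        qm_df=df,
        p_qm=p_qm,
    )


def fit_metareg_table(
    effects: pd.DataFrame, design: DesignMatrix, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised meta-regression over all genes.

    Exploits the one-hot design: the WLS solution is the per-level
    weighted mean and the coefficient covariance is diagonal, so the whole
    genome is fitted with array reductions (verified against the matrix
    path in the test suite).  Genes missing any design contrast are
    dropped with a warning.

    Returns ``(gene_table, coef_table)``: per-gene tau2_resid / qm /
    qm_df / p_qm, and long-format per-level coefficients.
    """
    cfg = cfg or RunConfig()
    if cfg.tau2_method_metareg == "reml":
        return _fit_metareg_table_loop(effects, design, cfg)
    cids = design.contrast_ids
    sub = effects[effects["contrast_id"].isin(cids)]
    genes = sub["gene_id"].drop_duplicates()
    y_w = sub.pivot(index="gene_id", columns="contrast_id", values="lnr")
    v_w = sub.pivot(index="gene_id", columns="contrast_id", values="v")
    y_w = y_w.reindex(index=genes, columns=cids)
    v_w = v_w.reindex(index=genes, columns=cids)
    complete = ~y_w.isna().any(axis=1)
    if (~complete).any():
        log.warning(
            "metareg: %d genes missing a design contrast, dropped",
            int((~complete).sum()),
        )
    y = y_w[complete].to_numpy()
    v = v_w[complete].to_numpy()
    genes = genes[complete.to_numpy()]
    X = design.X.to_numpy()  # (K, m) one-hot
    k, m = X.shape

    w0 = 1.0 / v                                   # (G, K)
    sw0_l = w0 @ X                                 # (G, m) per-level sums
    beta0 = (w0 * y) @ X / sw0_l
    fitted0 = beta0 @ X.T
    qe = np.sum(w0 * (y - fitted0) ** 2, axis=1)
    trp = w0.sum(axis=1) - ((w0**2) @ X / sw0_l).sum(axis=1)
    tau2 = np.maximum(0.0, (qe - (k - m)) / trp)

    w = 1.0 / (v + tau2[:, None])
    sw_l = w @ X
    beta = (w * y) @ X / sw_l                      # (G, m)
    var_l = 1.0 / sw_l
    se = np.sqrt(var_l)
    z = beta / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    mult = stats.norm.ppf(1 - cfg.alpha / 2)

    if cfg.qm_df_convention == "m_minus_1":
        # equality of level means: GLS common mean under H0, diagonal cov
        prec = 1.0 / var_l
        common = (beta * prec).sum(axis=1) / prec.sum(axis=1)
        qm = ((beta - common[:, None]) ** 2 * prec).sum(axis=1)
        qm_df = m - 1
    else:
        qm = (beta**2 / var_l).sum(axis=1)
        qm_df = m
    p_qm = np.maximum(stats.chi2.sf(qm, qm_df), np.finfo(float).tiny)

    gene_table = pd.DataFrame(
        {
            "gene_id": genes.to_numpy(),
            "tau2_resid": tau2,
            "qm": qm,
            "qm_df": qm_df,
            "p_qm": p_qm,
        }
    )
    coef_table = pd.DataFrame(
        {
            "gene_id": np.repeat(genes.to_numpy(), m),
            "level": np.tile(design.level_names, len(genes)),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "z": z.ravel(),
            "p": p.ravel(),
            "ci_lo": (beta - mult * se).ravel(),
            "ci_hi": (beta + mult * se).ravel(),
        }
    )
    log.info("metareg (%s): %d genes fitted", design.moderator, len(gene_table))
    return gene_table, coef_table


def _fit_metareg_table_loop(effects, design, cfg):
    gene_rows, coef_frames = [], []
    for gene_id, grp in effects.groupby("gene_id", sort=False):
        y = grp.set_index("contrast_id")["lnr"]
        v = grp.set_index("contrast_id")["v"]
        if y.reindex(design.contrast_ids).isna().any():
            continue
        fit = fit_meta_regression(y, v, design, cfg, gene_id=gene_id)
        gene_rows.append(
            {
                "gene_id": gene_id,
                "tau2_resid": fit.tau2_resid,
                "qm": fit.qm,
                "qm_df": fit.qm_df,
                "p_qm": fit.p_qm,
            }
        )
        cf = fit.coefficients.copy()
        cf.insert(0, "gene_id", gene_id)
        coef_frames.append(cf)
    return pd.DataFrame(gene_rows), pd.concat(coef_frames, ignore_index=True)


def classify_moderation(
    gene_table: pd.DataFrame,
    coef_table: pd.DataFrame,
    alpha: float = 0.05,
    qm_q: pd.Series | None = None,
) -> pd.DataFrame:
    """Post-hoc labelling of moderated genes from coefficient signs.

    A gene whose FDR-adjusted Q_M is below ``alpha`` is labelled
    ``reversed`` when its level means have opposite signs and each is
    individually significant (normal CI excluding zero), otherwise
    ``differential_magnitude``; non-significant Q_M genes are ``ns``.
    ``qm_q`` supplies the adjusted Q_M values (computed genome-wide by the
    caller); raw p_qm is used if omitted.
    """
    q = qm_q if qm_q is not None else gene_table.set_index("gene_id")["p_qm"]
    labels = []
    sig_levels = coef_table.assign(
        sig=(coef_table["ci_lo"] > 0) | (coef_table["ci_hi"] < 0)
    )
    by_gene = sig_levels.groupby("gene_id", sort=False)
    signs = by_gene["beta"].agg(lambda b: (b > 0).any() and (b < 0).any())
    all_sig = by_gene["sig"].all()
    for row in gene_table.itertuples(index=False):
        gid = row.gene_id
        if q.loc[gid] >= alpha:
            labels.append("ns")
        elif signs.loc[gid] and all_sig.loc[gid]:
            labels.append("reversed")
        else:
            labels.append("differential_magnitude")
    out = gene_table[["gene_id"]].copy()
    out["label"] = labels
    return out
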