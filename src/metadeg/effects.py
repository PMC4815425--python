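"""Per-contrast replicate summaries and the log expression ratio effect size.

For gene *g* in contrast *i* with treated-arm mean ``ybar1`` (n1 biological
replicates, unbiased variance ``s2_1``) and control-arm mean ``ybar2``
(n2, ``s2_2``), the effect size is the log response ratio

    lnR_i = ln(ybar1 / ybar2)

with approximated sampling variance

    v_i = s2_1 / (n1 * ybar1**2) + s2_2 / (n2 * ybar2**2).

By default lnR is computed on the expression values exactly as provided
(log2-scale means, taking GCRMA-style output at face value);
``scale="delog2"`` first back-transforms replicates with ``2**x`` and
recomputes means and variances on the raw intensity scale.

No small-sample (Hedges-type) bias correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionStudy, RunConfig, contrast_table, log

SUMMARY_COLUMNS = [
    "gene_id", "contrast_id", "study_id", "part", "method",
    "ybar1", "s2_1", "n1", "ybar2", "s2_2", "n2",
]

EFFECT_COLUMNS = [
    "gene_id", "contrast_id", "lnr", "v", "part", "method", "n1", "n2",
]


def summarize_contrasts(
    study: ExpressionStudy, scale: str = "as_given"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce replicates to per-gene, per-contrast arm means and variances.

    Returns ``(summaries, rejected)`` where ``rejected`` lists contrasts
    with fewer than 2 replicates in either arm (they are excluded from the
    summaries, with a reason, never silently dropped).
    """
    if study.samples is None:
        raise DataError("study must be annotated with a sample sheet")
    if scale not in ("as_given", "delog2"):
        raise DataError(f"unknown scale {scale!r}")
    matrix = study.matrix.to_numpy()
    if scale == "delog2":
        matrix = np.exp2(matrix)
    samples = study.samples
    contrasts = contrast_table(study)

    frames: list[pd.DataFrame] = []
    rejected: list[dict] = []
    for row in contrasts.itertuples(index=False):
        in_contrast = (samples["study_id"] == row.study_id) & (
            samples["part"] == row.part
        )
        t_cols = np.flatnonzero(in_contrast & (samples["arm"] == "treated"))
        c_cols = np.flatnonzero(in_contrast & (samples["arm"] == "control"))
        if len(t_cols) < 2 or len(c_cols) < 2:
            rejected.append(
                {
                    "contrast_id": row.contrast_id,
                    "reason": f"needs >=2 replicates per arm "
                    f"(treated={len(t_cols)}, control={len(c_cols)})",
                }
            )
            continue
        t = matrix[:, t_cols]
        c = matrix[:, c_cols]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": study.gene_ids,
                    "contrast_id": row.contrast_id,
                    "study_id": row.study_id,
                    "part": row.part,
                    "method": row.method,
                    "ybar1": t.mean(axis=1),
                    "s2_1": t.var(axis=1, ddof=1),
                    "n1": len(t_cols),
                    "ybar2": c.mean(axis=1),
                    "s2_2": c.var(axis=1, ddof=1),
                    "n2": len(c_cols),
                }
            )
        )
    for rej in rejected:
        log.warning("contrast rejected: %(contrast_id)s: %(reason)s", rej)
    summaries = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SUMMARY_COLUMNS)
    )
    return summaries, pd.DataFrame(rejected, columns=["contrast_id", "reason"])


def summarize_contrast(
    study: ExpressionStudy, contrast_id: str, scale: str = "as_given"
) -> pd.DataFrame:
    """Summaries for a single contrast; raises if it lacks replicates."""
    summaries, rejected = summarize_contrasts(study, scale=scale)
    if contrast_id in set(rejected["contrast_id"]):
        reason = rejected.set_index("contrast_id").loc[contrast_id, "reason"]
        raise DataError(f"contrast {contrast_id}: {reason}")
    out = summaries[summaries["contrast_id"] == contrast_id].reset_index(drop=True)
    if out.empty:
        raise DataError(f"no such contrast: {contrast_id}")
    return out


def effect_size(
    ybar1: float, s2_1: float, n1: int, ybar2: float, s2_2: float, n2: int
) -> tuple[float, float]:
    """lnR and its sampling variance for one gene in one contrast."""
    if ybar1 <= 0 or ybar2 <= 0:
        raise DataError("arm means must be positive on the analysis scale")
    lnr = np.log(ybar1) - np.log(ybar2)
    v = s2_1 / (n1 * ybar1**2) + s2_2 / (n2 * ybar2**2)
    return float(lnr), float(v)


def effect_sizes(
    summaries: pd.DataFrame, var_floor: float = 1e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised lnR / v for a summary table.

    Genes with a non-positive arm mean in a contrast are excluded from the
    effect table and returned separately (flagged, logged).  Zero sampling
    variances (all replicates identical in both arms) are raised to
    ``var_floor`` so downstream inverse-variance weights stay finite.
    """
    s = summaries
    ok = (s["ybar1"] > 0) & (s["ybar2"] > 0)
    excluded = s.loc[~ok, ["gene_id", "contrast_id"]].copy()
    if len(excluded):
        excluded["reason"] = "non-positive arm mean"
        log.warning(
            "%d gene x contrast records excluded (non-positive arm mean)",
            len(excluded),
        )
    s = s.loc[ok]
    lnr = np.log(s["ybar1"].to_numpy()) - np.log(s["ybar2"].to_numpy())
    v = s["s2_1"].to_numpy() / (s["n1"].to_numpy() * s["ybar1"].to_numpy() ** 2) + s[
        "s2_2"
    ].to_numpy() / (s["n2"].to_numpy() * s["ybar2"].to_numpy() ** 2)
    n_floored = int((v < var_floor).sum())
    if n_floored:
        log.info("variance floor %.1e applied to %d records", var_floor, n_floored)
    effects = pd.DataFrame(
        {
            "gene_id": s["gene_id"].to_numpy(),
            "contrast_id": s["contrast_id"].to_numpy(),
            "lnr": lnr,
            "v": np.maximum(v, var_floor),
            "part": s["part"].to_numpy(),
            "method": s["method"].to_numpy(),
            "n1": s["n1"].to_numpy(),
            "n2": s["n2"].to_numpy(),
        }
    )
    return effects, excluded


def compute_effects(
    study: ExpressionStudy, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Replicates -> contrast summaries -> effect-size table, per config."""
    cfg = cfg or RunConfig()
    summaries, _ = summarize_contrasts(study, scale=cfg.effect_scale)
    effects, _ = effect_sizes(summaries, var_floor=cfg.var_floor)
    return effects
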