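"""End-to-end convenience drivers tying the stages together."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import effects as effects_mod
from . import filtering, inference, meta, metareg, modttest
from .datamodel import ExpressionStudy, RunConfig, log


@dataclass
class MetaPipelineResult:
    study: ExpressionStudy            # post-filter collection (the call universe)
    filter_report: filtering.FilterReport | None
    effects: pd.DataFrame
    fits: pd.DataFrame
    calls: pd.DataFrame


def run_meta_pipeline(
    study: ExpressionStudy,
    cfg: RunConfig | None = None,
    apply_filter: bool = True,
) -> MetaPipelineResult:
    """Filter -> effect sizes -> per-gene random-effects meta -> FDR calls."""
    cfg = cfg or RunConfig()
    report = None
    if apply_filter:
        study, report = filtering.filter_probesets(study, cfg)
    eff = effects_mod.compute_effects(study, cfg)
    fits = meta.fit_random_effects_table(eff, cfg)
    calls = inference.classify_genes(fits, alpha=cfg.alpha)
    return MetaPipelineResult(study, report, eff, fits, calls)


def run_metareg(
    effects: pd.DataFrame, moderator: str, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Moderator design + per-gene meta-regression + family-wise FDR.

    Returns (gene_table with q_qm column, long coefficient table).
    """
    cfg = cfg or RunConfig()
    design = metareg.build_design(effects, moderator, cfg)
    gene_table, coef_table = metareg.fit_metareg_table(effects, design, cfg)
    gene_table = gene_table.copy()
    gene_table["q_qm"] = inference.bh_adjust(gene_table["p_qm"].to_numpy())
    return gene_table, coef_table


def run_comparison(
    study: ExpressionStudy,
    calls: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> inference.IntersectionReport:
    """Per-contrast moderated t-tests vs the meta-analysis call set.

    ``study`` must share the gene universe of ``calls`` (pass the
    post-filter study from :class:`MetaPipelineResult`).
    """
    cfg = cfg or RunConfig()
    per_study = modttest.moderated_t_all(study, cfg)
    return inference.compare_gene_sets(calls, per_study)
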