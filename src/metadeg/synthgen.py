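"""Synthetic multi-study expression collections with known ground truth.

The generator emulates the structure of a typical collection of
Affymetrix-style water-stress experiments: ~10 two-arm contrasts drawn
from 8 studies (two studies assay both root and shoot, contributing one
contrast per part), 2-3 biological replicates per arm, log2-scale
baseline intensities, per-study batch shifts applied to both arms, a null
fraction of genes, between-study heterogeneity tau^2, and optional
moderator-dependent effects by plant part or stress method.

For gene g in contrast s the true study-level effect is

    theta_gs = mu_g + shift(level_s) + N(0, tau2)

and replicates are drawn so that the expected log expression ratio on the
analysis scale equals theta_gs: control replicates are normal around
m0 = baseline_g + batch_s with sd ``noise_sd``, treated replicates around
m0 * exp(theta_gs).  Because the batch shift enters both arms it cancels
from lnR, mirroring the treatment of batch effects as between-study
random error rather than a modelled covariate.

Part-moderator shifts are antisymmetric (root +d, shoot -d with
d ~ N(0, part_effect_sd^2)), so each level's shift is marginally normal
with the stated sd while moderated genes respond in opposite directions
in the two parts; method shifts are drawn independently per level.  Null
genes (probability pi0) have mu_g = 0 and no moderator shifts, but still
carry tau2 heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionStudy, annotate, log


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    part: str
    method: str
    n1: int  # treated replicates
    n2: int  # control replicates

    @property
    def contrast_id(self) -> str:
        return f"{self.study_id}:{self.part}"


def default_roster() -> list[StudyDesign]:
    """Ten contrasts from eight studies, shaped like the source collection.

    Two studies assay both root and shoot; one seedling study uses PEG;
    one study uses deracination; array counts of 6 map to 3 replicates
    per arm and counts of 4 to 2 per arm.
    """
    return [
        StudyDesign("studyAB", "root", "water_withholding", 3, 3),
        StudyDesign("studyAB", "shoot", "water_withholding", 3, 3),
        StudyDesign("studyCD", "root", "mannitol", 3, 3),
        StudyDesign("studyCD", "shoot", "mannitol", 3, 3),
        StudyDesign("studyE", "seedling", "peg", 3, 3),
        StudyDesign("studyF", "shoot", "water_withholding", 3, 3),
        StudyDesign("studyG", "shoot", "water_withholding", 2, 2),
        StudyDesign("studyH", "shoot", "water_withholding", 3, 3),
        StudyDesign("studyI", "shoot", "water_withholding", 2, 2),
        StudyDesign("studyJ", "shoot", "deracination", 3, 3),
    ]


@dataclass
class SimParams:
    """Generator settings; defaults are the package's study conditions."""

    n_genes: int = 2000
    studies: list[StudyDesign] = field(default_factory=default_roster)
    pi0: float = 0.8                 # null-gene fraction
    effect_sd: float = 0.5           # sd of true mu_g for non-nulls (ln-ratio units)
    tau2: float = 0.05               # between-study variance (ln-ratio^2)
    part_effect_sd: float = 0.0      # sd of root-vs-shoot shifts (0 = no moderation)
    method_effect_sd: float = 0.0    # sd of per-method shifts
    baseline_log2_mean: float = 8.0  # control-arm log2 intensity location
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.25           # replicate-level log2 noise sd
    batch_sd: float = 0.2            # per-study additive log2 shift sd (both arms)
    asymmetric_batch: bool = False   # add an arm-specific batch term (stress test)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")
        for name in ("effect_sd", "tau2", "part_effect_sd", "method_effect_sd",
                     "baseline_log2_sd", "noise_sd", "batch_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for s in self.studies:
            if s.n1 < 2 or s.n2 < 2:
                raise ValueError(f"{s.contrast_id}: needs >= 2 replicates per arm")


@dataclass
class SimTruth:
    """Ground truth for recovery testing."""

    genes: pd.DataFrame   # gene_id, is_null, mu_true, shift_* columns
    theta: pd.DataFrame   # index gene_id, one column per contrast_id
    params: SimParams


_METHOD_LEVELS = ("water_withholding", "mannitol", "peg", "deracination")


def simulate_collection(
    params: SimParams,
) -> tuple[ExpressionStudy, pd.DataFrame, SimTruth]:
    """Draw a full annotated collection, its sample sheet, and the truth.

    Deterministic for a fixed ``params.seed``.  Genes whose implied
    control-arm mean would be non-positive in any contrast (possible only
    with extreme baseline/batch settings) are redrawn and counted.
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    gene_ids = pd.Index([f"{254000 + i}_at" for i in range(G)], name="gene_id")
    contrasts = params.studies
    study_ids = list(dict.fromkeys(s.study_id for s in contrasts))

    is_null = rng.random(G) < params.pi0
    mu = np.where(~is_null, rng.normal(0.0, params.effect_sd, G), 0.0)
    d_part = rng.normal(0.0, params.part_effect_sd, G) if params.part_effect_sd else np.zeros(G)
    d_part = np.where(is_null, 0.0, d_part)
    part_shift = {"root": d_part, "shoot": -d_part, "seedling": np.zeros(G)}
    method_shift = {}
    for level in _METHOD_LEVELS:
        s = rng.normal(0.0, params.method_effect_sd, G) if params.method_effect_sd else np.zeros(G)
        method_shift[level] = np.where(is_null, 0.0, s)

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, G)
    batch = {sid: rng.normal(0.0, params.batch_sd) for sid in study_ids}
    # redraw genes whose control mean would be non-positive somewhere
    min_batch = min(batch.values()) if batch else 0.0
    n_redrawn = 0
    for _ in range(100):
        bad = baseline + min_batch <= 0
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        baseline[bad] = rng.normal(
            params.baseline_log2_mean, params.baseline_log2_sd, int(bad.sum())
        )
    if n_redrawn:
        log.info("redrew baseline for %d genes (non-positive implied mean)", n_redrawn)

    theta = {}
    blocks: list[np.ndarray] = []
    sheet_rows: list[dict] = []
    col_ids: list[str] = []
    for s in contrasts:
        th = (
            mu
            + part_shift[s.part]
            + method_shift[s.method]
            + rng.normal(0.0, np.sqrt(params.tau2), G)
        )
        theta[s.contrast_id] = th
        m0 = baseline + batch[s.study_id]
        m1 = m0 * np.exp(th)
        if params.asymmetric_batch:
            m1 = m1 + rng.normal(0.0, params.batch_sd)
        treated = m1[:, None] + rng.normal(0.0, params.noise_sd, (G, s.n1))
        control = m0[:, None] + rng.normal(0.0, params.noise_sd, (G, s.n2))
        blocks.append(np.hstack([treated, control]))
        for arm, n in (("treated", s.n1), ("control", s.n2)):
            for i in range(1, n + 1):
                sid = f"{s.study_id}.{s.part}.{arm}{i}"
                col_ids.append(sid)
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "study_id": s.study_id,
                        "arm": arm,
                        "part": s.part,
                        "method": s.method,
                        "replicate_index": i,
                    }
                )

    matrix = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=col_ids)
    sheet = pd.DataFrame(sheet_rows)
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_null": is_null,
            "mu_true": mu,
            "shift_root": part_shift["root"],
            "shift_shoot": part_shift["shoot"],
            **{f"shift_{lvl}": method_shift[lvl] for lvl in _METHOD_LEVELS},
        }
    ).reset_index(drop=True)
    truth = SimTruth(
        genes=truth_genes,
        theta=pd.DataFrame(theta, index=gene_ids),
        params=params,
    )
    study = annotate(ExpressionStudy(matrix), sheet)
    log.info(
        "simulated %d genes x %d samples over %d contrasts (seed %d)",
        G,
        len(col_ids),
        len(contrasts),
        params.seed,
    )
    return study, sheet, truth


def simulate_effect_table(
    n_genes: int,
    k: int,
    tau2: float,
    effect_sd: float = 0.5,
    pi0: float = 0.0,
    v_range: tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw effect sizes directly at the lnR level (no expression matrix).

    Each gene receives K observed effects theta_i ~ N(mu_g, tau2 + v_i)
    with known sampling variances v_i ~ Uniform(v_range).  Useful for
    calibration checks where the estimand must be exactly specified.
    Returns ``(effects, truth)`` with truth columns gene_id, mu_true,
    is_null.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
    is_null = rng.random(n_genes) < pi0
    mu = np.where(~is_null, rng.normal(0.0, effect_sd, n_genes), 0.0)
    v = rng.uniform(v_range[0], v_range[1], (n_genes, k))
    theta = mu[:, None] + rng.normal(0.0, np.sqrt(tau2), (n_genes, k)) + rng.normal(
        0.0, 1.0, (n_genes, k)
    ) * np.sqrt(v)
    effects = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, k),
            "contrast_id": np.tile([f"c{j + 1}" for j in range(k)], n_genes),
            "lnr": theta.ravel(),
            "v": v.ravel(),
        }
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "mu_true": mu, "is_null": is_null})
    return effects, truth


def recovery_report(
    truth: SimTruth | pd.DataFrame,
    fits: pd.DataFrame,
    alpha: float = 0.05,
    metareg_gene_table: pd.DataFrame | None = None,
) -> dict:
    """Calibration summary of fitted meta-analyses against the truth.

    Reports bias and RMSE of mu_hat, the median tau2 estimate (with the
    true value when available), empirical 95% CI coverage of mu_true, the
    realised false-discovery proportion of BH calls at ``alpha`` and,
    when a meta-regression table is supplied, the Q_M type-I rate among
    genes with no moderator shift.
    """
    from .inference import bh_adjust

    genes = truth.genes if isinstance(truth, SimTruth) else truth
    merged = fits.merge(genes, on="gene_id", how="inner", validate="1:1")
    if len(merged) != len(fits):
        raise ValueError("gene ids in fits and truth do not match")
    err = merged["mu_hat"] - merged["mu_true"]
    covered = (merged["ci_lo"] <= merged["mu_true"]) & (
        merged["mu_true"] <= merged["ci_hi"]
    )
    q = bh_adjust(merged["p"].to_numpy())
    discovered = q < alpha
    n_disc = int(discovered.sum())
    n_false = int((discovered & merged["is_null"]).sum())
    report = {
        "n_genes": len(merged),
        "bias_mu": float(err.mean()),
        "rmse_mu": float(np.sqrt((err**2).mean())),
        "tau2_median": float(merged["tau2"].median()) if "tau2" in merged else np.nan,
        "coverage": float(covered.mean()),
        "n_discoveries": n_disc,
        "n_false_discoveries": n_false,
        "fdp": n_false / n_disc if n_disc else 0.0,
    }
    if isinstance(truth, SimTruth):
        report["tau2_true"] = truth.params.tau2
    if metareg_gene_table is not None:
        shift_cols = [c for c in genes.columns if c.startswith("shift_")]
        no_shift = genes.loc[
            (genes[shift_cols].abs().sum(axis=1) == 0), "gene_id"
        ]
        mr = metareg_gene_table[metareg_gene_table["gene_id"].isin(set(no_shift))]
        report["qm_type1_rate"] = float((mr["p_qm"] < alpha).mean())
    return report
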