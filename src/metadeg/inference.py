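"""FDR adjustment, gene calls, forest orderings and gene-set comparisons.

The Benjamini-Hochberg step-up adjustment maps each sorted p-value
p_(i) to q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, and is applied
separately per analysis family (genome-wide meta-analysis, each
meta-regression moderator, each per-study contrast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataError, log

#: |mu_hat| below which a meta-only discovery is flagged as "small effect"
SMALL_EFFECT = 0.05


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise DataError("p-values must be a 1-d sequence")
    bad = np.flatnonzero(~((p > 0) & (p <= 1)))
    if bad.size:
        raise DataError(f"p-value out of (0, 1] at index {bad[0]}: {p[bad[0]]!r}")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class IntersectionReport:
    """Meta-analysis vs per-contrast DEG set comparison."""

    per_contrast_counts: pd.Series      # DEGs per contrast
    support_counts: pd.Series           # per gene: number of supporting contrasts
    union: set
    meta_set: set
    meta_only: set
    t_only: set
    both: set
    pairwise: pd.Series                 # |meta  ^ contrast| per contrast
    meta_only_small: set                # meta-only genes with |mu_hat| < 0.05

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast_id": self.per_contrast_counts.index,
                "degs": self.per_contrast_counts.to_numpy(),
                "intersection_with_meta": self.pairwise.reindex(
                    self.per_contrast_counts.index
                ).to_numpy(),
            }
        )


def classify_genes(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Turn a per-gene meta-analysis table into up / down / ns calls.

    Applies BH genome-wide to the meta p-values, then calls a gene *up*
    (q < alpha, mu_hat > 0), *down* (q < alpha, mu_hat < 0) or *ns*.
    ``ci_gap`` is the distance from the CI bound nearer zero to zero
    (0 when the interval spans zero).
    """
    out = fits[["gene_id", "mu_hat", "ci_lo", "ci_hi"]].copy()
    q = bh_adjust(fits["p"].to_numpy())
    out["q"] = q
    sig = q < alpha
    out["call"] = np.where(
        sig & (out["mu_hat"] > 0), "up", np.where(sig & (out["mu_hat"] < 0), "down", "ns")
    )
    spans_zero = (out["ci_lo"] <= 0) & (out["ci_hi"] >= 0)
    out["ci_gap"] = np.where(
        spans_zero, 0.0, np.minimum(np.abs(out["ci_lo"]), np.abs(out["ci_hi"]))
    )
    counts = out["call"].value_counts()
    log.info(
        "calls at FDR %.3g: %d up, %d down, %d ns",
        alpha,
        counts.get("up", 0),
        counts.get("down", 0),
        counts.get("ns", 0),
    )
    return out


def sort_forest(calls: pd.DataFrame, mode: str = "ci_gap") -> pd.Index:
    """Gene ordering for the genome-wide forest plot.

    ``ci_gap``: genes whose CI excludes zero first, by descending distance
    of the nearer CI bound from zero; genes whose CI spans zero after, by
    descending |mu_hat|.  ``mu_magnitude``: all genes by descending
    |mu_hat|.  Ties break lexicographically on gene_id.
    """
    df = calls.copy()
    df["abs_mu"] = df["mu_hat"].abs()
    if mode == "ci_gap":
        df["group"] = (df["ci_gap"] == 0).astype(int)  # 0 = excludes zero
        df["key"] = np.where(df["group"] == 0, -df["ci_gap"], -df["abs_mu"])
        df = df.sort_values(["group", "key", "gene_id"], kind="stable")
    elif mode == "mu_magnitude":
        df = df.sort_values(["abs_mu", "gene_id"], ascending=[False, True],
                            kind="stable")
    else:
        raise DataError(f"unknown sort mode {mode!r}")
    return pd.Index(df["gene_id"])


def compare_gene_sets(
    meta_calls: pd.DataFrame, per_study_calls: dict[str, set | pd.DataFrame]
) -> IntersectionReport:
    """Intersect meta-analysis DEGs with per-contrast t-test DEGs.

    ``per_study_calls`` maps contrast_id to either a set of significant
    gene ids or a moderated-t result table with a ``q`` column (called at
    q < 0.05).  A contrast with zero DEGs contributes zeros everywhere;
    it is a legitimate outcome, not an error.
    """
    universe = set(meta_calls["gene_id"])
    meta_set = set(meta_calls.loc[meta_calls["call"] != "ns", "gene_id"])
    sets: dict[str, set] = {}
    for cid, val in per_study_calls.items():
        if isinstance(val, pd.DataFrame):
            val = set(val.loc[val["q"] < 0.05, "gene_id"])
        val = set(val)
        stray = val - universe
        if stray:
            raise DataError(
                f"contrast {cid}: gene(s) outside the meta universe, e.g. "
                f"{sorted(stray)[:3]}"
            )
        sets[cid] = val
    union = set().union(*sets.values()) if sets else set()
    support = pd.Series(
        {g: sum(g in s for s in sets.values()) for g in sorted(universe)},
        name="support",
        dtype=int,
    )
    mu = meta_calls.set_index("gene_id")["mu_hat"]
    meta_only = meta_set - union
    report = IntersectionReport(
        per_contrast_counts=pd.Series({c: len(s) for c, s in sets.items()}, dtype=int),
        support_counts=support,
        union=union,
        meta_set=meta_set,
        meta_only=meta_only,
        t_only=union - meta_set,
        both=meta_set & union,
        pairwise=pd.Series({c: len(meta_set & s) for c, s in sets.items()}, dtype=int),
        meta_only_small={g for g in meta_only if abs(mu.loc[g]) < SMALL_EFFECT},
    )
    log.info(
        "gene sets: meta %d, union of contrasts %d, meta-only %d (%d small)",
        len(meta_set),
        len(union),
        len(meta_only),
        len(report.meta_only_small),
    )
    return report


def render_forest(
    calls: pd.DataFrame, path, mode: str = "ci_gap", max_genes: int | None = None
) -> None:
    """Plain forest rendering (dot + CI line per gene) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sort_forest(calls, mode)
    df = calls.set_index("gene_id").loc[order]
    if max_genes:
        df = df.iloc[:max_genes]
    n = len(df)
    colors = df["call"].map({"up": "tab:red", "down": "tab:blue", "ns": "0.6"})
    y = np.arange(n)[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, n * 0.02)))
    ax.hlines(y, df["ci_lo"], df["ci_hi"], color=colors, lw=0.5)
    ax.plot(df["mu_hat"], y, ".", ms=1, color="black")
    ax.axvline(0.0, color="0.3", lw=0.8)
    ax.set_xlabel(r"weighted mean log expression ratio $\hat\mu$ (95% CI)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
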