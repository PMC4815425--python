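"""Probe-set inclusion filters applied before any statistics.

Two standard rules, both evaluated on the sample set pooled across all
studies:

* **intensity** -- the gene's log2 value must reach the configured cutoff
  (log2 of a raw fluorescence of 100 by default) in at least a fraction
  (default 10%) of all samples;
* **IQR** -- the interquartile range of the gene's log2 values across all
  arrays must be at least 0.5.

Quartiles use the linear-interpolation convention (numpy default,
"type 7"), so threshold behaviour is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionStudy, RunConfig, log


@dataclass
class FilterReport:
    """Per-rule pass counts and per-gene flags."""

    n_input: int
    n_pass_intensity: int
    n_pass_iqr: int
    n_retained: int
    flags: pd.DataFrame  # index gene_id; columns pass_intensity, pass_iqr, retained

    def to_frame(self) -> pd.DataFrame:
        return self.flags.reset_index()


def filter_probesets(
    study: ExpressionStudy, cfg: RunConfig | None = None
) -> tuple[ExpressionStudy, FilterReport]:
    """Apply both inclusion rules; retained genes keep input order."""
    cfg = cfg or RunConfig()
    if study.n_samples == 0:
        raise DataError("cannot filter a study with zero samples")
    values = study.matrix.to_numpy()
    cutoff = cfg.log2_intensity_cutoff

    frac_bright = (values >= cutoff).mean(axis=1)
    pass_intensity = frac_bright >= cfg.intensity_min_fraction

    q1, q3 = np.percentile(values, [25, 75], axis=1)  # linear interpolation
    pass_iqr = (q3 - q1) >= cfg.iqr_threshold_log2

    retained = pass_intensity & pass_iqr
    flags = pd.DataFrame(
        {
            "pass_intensity": pass_intensity,
            "pass_iqr": pass_iqr,
            "retained": retained,
        },
        index=study.gene_ids,
    )
    report = FilterReport(
        n_input=study.n_genes,
        n_pass_intensity=int(pass_intensity.sum()),
        n_pass_iqr=int(pass_iqr.sum()),
        n_retained=int(retained.sum()),
        flags=flags,
    )
    filtered = ExpressionStudy(study.matrix.loc[retained], study.samples)
    log.info(
        "filter: %d in, %d pass intensity, %d pass IQR, %d retained",
        report.n_input,
        report.n_pass_intensity,
        report.n_pass_iqr,
        report.n_retained,
    )
    return filtered, report
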