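"""Core containers, tabular I/O and run configuration.

An :class:`ExpressionStudy` holds a genes x samples matrix of log2-scale
fluorescence intensities (the scale GCRMA-style normalisation produces) for
one or more studies, together with a sample sheet that assigns every array
to a study, arm (treated / control), plant part and water-stress method.
A *contrast* is one treated-vs-control comparison within one study and
plant part; it is the unit of meta-analytic synthesis.

All tabular formats are plain tab-delimited text.  Missing values are not
supported: any non-numeric cell in an expression matrix is a hard error,
never an imputation trigger.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("metadeg")

ARMS = ("treated", "control")
PARTS = ("root", "shoot", "seedling")
METHODS = ("water_withholding", "mannitol", "peg", "deracination")

#: required sample-sheet columns, in canonical order
SHEET_COLUMNS = ("sample_id", "study_id", "arm", "part", "method")


class DataError(ValueError):
    """Malformed input data (matrix, sheet, or configuration)."""


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus (optional) sample annotations.

    Parameters
    ----------
    matrix:
        genes x samples DataFrame; index = gene/probe-set identifiers,
        columns = sample identifiers, values = log2 intensities.
    samples:
        one row per matrix column with the :data:`SHEET_COLUMNS` fields
        (plus ``replicate_index``), aligned to matrix column order, or
        ``None`` for an unannotated matrix.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.matrix.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate gene id: {dup!r}")
        if self.matrix.columns.has_duplicates:
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        values = self.matrix.to_numpy()
        if values.size and not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite expression value at gene {idx[r]!r}, "
                f"sample {self.matrix.columns[c]!r}"
            )
        if self.samples is not None:
            missing = [c for c in self.matrix.columns if c not in set(self.samples["sample_id"])]
            if missing:
                raise DataError(f"samples without sheet annotation: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.loc[list(gene_ids)], self.samples)


def read_expression_matrix(path: str | Path) -> ExpressionStudy:
    """Read a tab-delimited log2 expression matrix.

    First column = gene id, header row = sample ids.  Rejects duplicate
    gene ids, ragged rows and non-numeric cells, naming the offender.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise DataError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    ncol = len(header)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != ncol:
            raise DataError(
                f"{path}: ragged row at line {lineno} "
                f"({len(parts)} fields, expected {ncol})"
            )
        gid = parts[0]
        if gid in seen:
            raise DataError(f"{path}: duplicate gene id {gid!r} (line {lineno})")
        seen.add(gid)
        try:
            row = np.array(parts[1:], dtype=float)
        except ValueError:
            for j, cell in enumerate(parts[1:]):
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {sample_ids[j]!r}"
                    ) from None
            raise
        gene_ids.append(gid)
        rows.append(row)
    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(sample_ids))),
        index=pd.Index(gene_ids, name=header[0] or "gene_id"),
        columns=sample_ids,
    )
    log.info("read expression matrix %s: %d genes x %d samples", path, *matrix.shape)
    return ExpressionStudy(matrix)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and enum tokens; returns a normalised copy."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise DataError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    for col, allowed in (("arm", ARMS), ("part", PARTS), ("method", METHODS)):
        bad = sorted(set(sheet[col]) - set(allowed))
        if bad:
            raise DataError(
                f"unknown {col} value(s) {bad}; allowed tokens: {set(allowed)}"
            )
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample_id in sheet: {dup!r}")
    if "replicate_index" not in sheet.columns:
        sheet["replicate_index"] = (
            sheet.groupby(["study_id", "part", "arm"]).cumcount() + 1
        )
    return sheet


def read_sample_sheet(path: str | Path, expr: ExpressionStudy) -> ExpressionStudy:
    """Attach a sample sheet to an expression matrix.

    Every expression column must be matched by exactly one sheet row;
    orphan columns are a fatal error.  Sheet rows for samples absent from
    the matrix are reported and dropped.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return annotate(expr, sheet)


def annotate(expr: ExpressionStudy, sheet: pd.DataFrame) -> ExpressionStudy:
    """Join an in-memory sample sheet onto an expression matrix."""
    sheet = validate_sample_sheet(sheet)
    by_id = sheet.set_index("sample_id", drop=False)
    orphans = [c for c in expr.sample_ids if c not in by_id.index]
    if orphans:
        raise DataError(f"expression column(s) with no sample-sheet row: {orphans}")
    extra = sorted(set(by_id.index) - set(expr.sample_ids))
    if extra:
        log.warning("sample-sheet rows without expression columns ignored: %s", extra)
    aligned = by_id.loc[list(expr.sample_ids)].reset_index(drop=True)
    return ExpressionStudy(expr.matrix, aligned)


def contrast_table(study: ExpressionStudy) -> pd.DataFrame:
    """One row per (study_id, part) contrast with covariates and arm sizes."""
    if study.samples is None:
        raise DataError("expression study has no sample annotations")
    s = study.samples
    rows = []
    for (study_id, part), grp in s.groupby(["study_id", "part"], sort=False):
        methods = grp["method"].unique()
        if len(methods) > 1:
            raise DataError(
                f"contrast {study_id}:{part} mixes methods {list(methods)}"
            )
        rows.append(
            {
                "contrast_id": f"{study_id}:{part}",
                "study_id": study_id,
                "part": part,
                "method": methods[0],
                "n1": int((grp["arm"] == "treated").sum()),
                "n2": int((grp["arm"] == "control").sum()),
            }
        )
    return pd.DataFrame(rows)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene result table as TSV at full float precision.

    Round-trips through :func:`read_results` to >= 12 significant digits.
    """
    table = table.reset_index() if table.index.name else table
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    log.info("wrote %d rows to %s", len(table), path)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class RunConfig:
    """All tunable analysis settings with their standard defaults.

    ``intensity_threshold_raw`` is a raw-scale fluorescence cutoff (the
    filter keeps genes whose log2 value is >= log2 of it in at least
    ``intensity_min_fraction`` of samples); set
    ``intensity_threshold_is_log2`` to apply the cutoff literally on the
    log2 scale instead.
    """

    alpha: float = 0.05
    tau2_method_meta: str = "reml"          # {"reml", "dl"}
    tau2_method_metareg: str = "dl"         # {"dl", "reml"}
    ci_distribution: str = "student_t"      # {"student_t", "normal"}
    intensity_threshold_raw: float = 100.0
    intensity_min_fraction: float = 0.10
    iqr_threshold_log2: float = 0.5
    qm_df_convention: str = "m_minus_1"     # {"m_minus_1", "m"}
    seed: int = 0
    # plumbing knobs (implementation conveniences, not analysis settings)
    intensity_threshold_is_log2: bool = False
    effect_scale: str = "as_given"          # {"as_given", "delog2"}
    var_floor: float = 1e-8
    mod_t_d0: float | None = None           # force prior df (None = estimate)

    _CHOICES = {
        "tau2_method_meta": ("reml", "dl"),
        "tau2_method_metareg": ("dl", "reml"),
        "ci_distribution": ("student_t", "normal"),
        "qm_df_convention": ("m_minus_1", "m"),
        "effect_scale": ("as_given", "delog2"),
    }

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError(f"alpha must be in (0,1), got {self.alpha}")
        for name, allowed in self._CHOICES.items():
            if getattr(self, name) not in allowed:
                raise DataError(f"{name} must be one of {allowed}")
        if self.intensity_threshold_raw <= 0:
            raise DataError("intensity_threshold_raw must be positive")
        if not 0.0 <= self.intensity_min_fraction:
            raise DataError("intensity_min_fraction must be >= 0")
        if self.iqr_threshold_log2 < 0:
            raise DataError("iqr_threshold_log2 must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    @property
    def log2_intensity_cutoff(self) -> float:
        if self.intensity_threshold_is_log2:
            return self.intensity_threshold_raw
        return float(np.log2(self.intensity_threshold_raw))
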