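"""Clinical covariate handling: encoding, skew transforms, rare-factor filtering, summaries.

A raw cohort table mixes continuous measures (gestational age, days of
respiratory support, ...) and binary factors (sex, IUGR, surfactant
administration, ...) with occasional missing entries.  CCA needs a complete
numeric matrix, so :func:`encode` z-scores continuous variables, centers
binary indicators, and imputes the (rare) missing entries — mean for
continuous, mode for binary — logging how many were filled per column.

Sensitivity-analysis helpers mirror common robustness checks: power
transforms for skewed variables, removal of binary factors with fewer than
a given fraction of positive cases, and consistent subject exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalTable", "ClinicalMatrix", "CohortSummary",
    "encode", "transform_skewed", "filter_rare", "summarize", "drop_subjects",
]

VALID_TRANSFORMS = ("none", "cbrt", "sqrt", "square")


@dataclass
class ClinicalTable:
    """Raw clinical table: a DataFrame plus per-variable kind metadata.

    ``kinds[name]`` is ``"continuous"`` or ``"binary"``; binary columns hold
    only {0, 1, NaN}.  ``summary_stat[name]`` ("median" or "mean") controls
    cohort summaries; ``units[name]`` is a display label.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)
    summary_stat: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.data.columns:
            kind = self.kinds.get(name)
            if kind not in ("continuous", "binary"):
                raise ValueError(f"variable {name!r} has unknown kind {kind!r}")
            if kind == "binary":
                vals = self.data[name].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(f"binary variable {name!r} has values outside {{0,1}}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def binary_names(self) -> list[str]:
        return [c for c in self.names if self.kinds[c] == "binary"]


@dataclass
class ClinicalMatrix:
    """Encoded numeric covariate matrix X: complete, continuous columns standardized."""

    values: np.ndarray  # (n, p)
    names: list[str]
    kinds: dict[str, str]
    transforms: dict[str, str]
    imputed: dict[str, int]
    subject_index: pd.Index
    scale_binary: bool = False
    raw: pd.DataFrame | None = None  # imputed raw values, kept so transforms can re-encode

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names, index=self.subject_index)


@dataclass
class CohortSummary:
    """Per-variable cohort description (count/% for binary, center/range for continuous)."""

    rows: pd.DataFrame  # variable, kind, count, percent, center, stat, low, high, n_missing, denominator

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def encode(table: ClinicalTable, scale_binary: bool = False) -> ClinicalMatrix:
    """Encode a raw table into the numeric matrix entering CCA.

    Continuous columns are z-scored (sample sd); binary columns are centered
    at their mean, which retains prevalence information in the column scale —
    pass ``scale_binary=True`` to fully standardize them instead.  Missing
    entries are imputed first (mean / mode) and counted per column.

    Raises on constant columns: zero variance breaks correlation downstream.
    """
    if len(table.names) < 2:
        raise ValueError("need at least 2 variables to encode")
    if table.n_subjects < 3:
        raise ValueError("need at least 3 subjects to encode")

    raw = table.data.astype(float).copy()
    imputed: dict[str, int] = {}
    cols = []
    for name in table.names:
        col = raw[name]
        n_missing = int(col.isna().sum())
        imputed[name] = n_missing
        if n_missing:
            if table.kinds[name] == "continuous":
                fill = col.mean()
            else:
                fill = float(col.mode().iloc[0])
            col = col.fillna(fill)
            raw[name] = col
        vals = col.to_numpy()
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {name!r} is constant; drop it before encoding")
        if table.kinds[name] == "continuous" or scale_binary:
            cols.append((vals - vals.mean()) / sd)
        else:
            cols.append(vals - vals.mean())
    return ClinicalMatrix(
        values=np.column_stack(cols), names=list(table.names), kinds=dict(table.kinds),
        transforms={n: "none" for n in table.names}, imputed=imputed,
        subject_index=table.data.index, scale_binary=scale_binary, raw=raw,
    )


def transform_skewed(matrix: ClinicalMatrix, assignments: dict[str, str]) -> ClinicalMatrix:
    """Apply power transforms (cbrt / sqrt / square) to raw values, then re-standardize.

    Intended for right-skewed duration variables (days of ventilation,
    parenteral nutrition, ...) whose long tails violate the normality that
    parametric CCA leans on.
    """
    if matrix.raw is None:
        raise ValueError("matrix does not retain raw values; re-encode from the table")
    for name, tf in assignments.items():
        if name not in matrix.names:
            raise KeyError(f"unknown variable {name!r}")
        if tf not in VALID_TRANSFORMS:
            raise ValueError(f"unknown transform {tf!r}; choose from {VALID_TRANSFORMS}")
    raw = matrix.raw.copy()
    transforms = dict(matrix.transforms)
    for name, tf in assignments.items():
        vals = raw[name].to_numpy()
        if tf == "sqrt":
            if np.any(vals < 0):
                bad = float(vals[vals < 0][0])
                raise ValueError(f"sqrt transform on {name!r} hit a negative value ({bad})")
            raw[name] = np.sqrt(vals)
        elif tf == "cbrt":
            raw[name] = np.cbrt(vals)
        elif tf == "square":
            raw[name] = np.square(vals)
        transforms[name] = tf
    cols = []
    for name in matrix.names:
        vals = raw[name].to_numpy()
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {name!r} became constant after transform")
        if matrix.kinds[name] == "continuous" or matrix.scale_binary:
            cols.append((vals - vals.mean()) / sd)
        else:
            cols.append(vals - vals.mean())
    return replace(matrix, values=np.column_stack(cols), transforms=transforms, raw=raw)


def filter_rare(table: ClinicalTable, min_prevalence: float = 0.10) -> tuple[ClinicalTable, list[str]]:
    """Drop binary factors whose positive-case fraction is below ``min_prevalence``.

    Continuous variables are untouched.  Returns the filtered table and the
    dropped names.
    """
    if not 0 <= min_prevalence < 1:
        raise ValueError("min_prevalence must be in [0, 1)")
    dropped = []
    for name in table.binary_names():
        col = table.data[name].dropna()
        if len(col) and col.mean() < min_prevalence:
            dropped.append(name)
    if dropped and len(dropped) == len(table.names):
        warnings.warn("rare-factor filter removed every variable")
    new = ClinicalTable(
        data=table.data.drop(columns=dropped),
        kinds={k: v for k, v in table.kinds.items() if k not in dropped},
        units={k: v for k, v in table.units.items() if k not in dropped},
        summary_stat={k: v for k, v in table.summary_stat.items() if k not in dropped},
    )
    return new, dropped


def summarize(table: ClinicalTable) -> CohortSummary:
    """Cohort summary: binary → count and percent of non-missing (2 dp);
    continuous → median (or mean, per ``summary_stat``) and min–max range."""
    if not table.names:
        raise ValueError("empty table")
    rows = []
    for name in table.names:
        col = table.data[name]
        obs = col.dropna()
        n_missing = int(col.isna().sum())
        denom = len(obs)
        if table.kinds[name] == "binary":
            count = int(obs.sum())
            pct = round(100.0 * count / denom, 2) if denom else np.nan
            rows.append(dict(variable=name, kind="binary", count=count, percent=pct,
                             center=np.nan, stat="", low=np.nan, high=np.nan,
                             n_missing=n_missing, denominator=denom))
        else:
            stat = table.summary_stat.get(name, "median")
            center = float(obs.mean()) if stat == "mean" else float(obs.median())
            rows.append(dict(variable=name, kind="continuous", count=np.nan, percent=np.nan,
                             center=center, stat=stat, low=float(obs.min()), high=float(obs.max()),
                             n_missing=n_missing, denominator=denom))
    return CohortSummary(rows=pd.DataFrame(rows))


def drop_subjects(table: ClinicalTable, ids) -> ClinicalTable:
    """Remove subjects by index label, e.g. to exclude infants with focal lesions."""
    ids = pd.Index(ids)
    missing = ids.difference(table.data.index)
    if len(missing):
        raise KeyError(f"unknown subject id(s): {list(missing[:5])}")
    if len(ids) == len(table.data):
        raise ValueError("dropping every subject leaves an empty analysis")
    return replace(table, data=table.data.drop(index=ids))
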