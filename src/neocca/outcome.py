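"""Linear regression of neurodevelopmental outcome scores on canonical imaging variates.

Each (variate, outcome) cell is a simple linear regression over subjects
with an observed score (complete-case; follow-up is never complete in a
real cohort).  The slope F-statistic is ``F = (n-2) R^2 / (1-R^2)`` with
the conventional (1, n-2) degrees of freedom; an alternative value under a
(1, n-1) denominator-df convention is stored alongside, since published
tables sometimes print that df pair.  Multiple-comparison correction over
the variates × outcomes grid defaults to Bonferroni, with Holm and
Benjamini-Hochberg switches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RegressionResult", "regress_outcome", "outcome_table", "correct_multiple"]

P_FLOOR = np.finfo(float).tiny


@dataclass
class RegressionResult:
    f: float  # conventional F with df (1, n-2)
    f_alt_df: float  # F recomputed under the (1, n-1) df convention
    p: float
    slope: float
    r_squared: float
    n: int  # complete cases used
    df: tuple[int, int]


def regress_outcome(variate: np.ndarray, scores: np.ndarray) -> RegressionResult:
    """Regress an outcome score on one canonical variate over complete cases.

    Missing scores (NaN) are dropped; a perfect fit reports an infinite F
    with the p-value floored rather than zero.
    """
    variate = np.asarray(variate, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(variate) != len(scores):
        raise ValueError(f"length mismatch: {len(variate)} vs {len(scores)}")
    ok = np.isfinite(variate) & np.isfinite(scores)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"only {n} complete cases; need at least 3")
    x, y = variate[ok], scores[ok]
    if x.std() == 0:
        raise ValueError("variate has zero variance over complete cases")
    if y.std() == 0:
        raise ValueError("scores have zero variance over complete cases")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    if r2 >= 1.0:
        return RegressionResult(f=np.inf, f_alt_df=np.inf, p=P_FLOOR, slope=fit.slope,
                                r_squared=1.0, n=n, df=(1, n - 2))
    f = (n - 2) * r2 / (1 - r2)
    f_alt = (n - 1) * r2 / (1 - r2)
    p = float(stats.f.sf(f, 1, n - 2))
    return RegressionResult(f=f, f_alt_df=f_alt, p=max(p, P_FLOOR), slope=fit.slope,
                            r_squared=r2, n=n, df=(1, n - 2))


def outcome_table(variates: np.ndarray, outcomes: pd.DataFrame,
                  method: str = "bonferroni", alpha: float = 0.05) -> pd.DataFrame:
    """Regress every outcome on every variate; flag corrected significance.

    Returns one row per (variate, outcome) with F (both df conventions),
    p, slope, n, and the corrected-significance flag.
    """
    variates = np.atleast_2d(np.asarray(variates, dtype=float))
    if variates.shape[0] != len(outcomes):
        variates = variates.T
    rows = []
    for i in range(variates.shape[1]):
        for name in outcomes.columns:
            res = regress_outcome(variates[:, i], outcomes[name].to_numpy())
            rows.append(dict(variate=i + 1, outcome=name, F=res.f, F_alt_df=res.f_alt_df,
                             p=res.p, slope=res.slope, n=res.n))
    df = pd.DataFrame(rows)
    flags, threshold = correct_multiple(df["p"].to_numpy(), method=method, alpha=alpha)
    df["significant"] = flags
    df.attrs["corrected_threshold"] = threshold
    df.attrs["method"] = method
    df.attrs["alpha"] = alpha
    return df


def correct_multiple(p_values: np.ndarray, method: str = "bonferroni",
                     alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Multiple-comparison flags over a grid of raw p-values.

    Returns (flags, adjusted threshold); the threshold is ``alpha / k`` for
    Bonferroni and NaN for the step-wise methods, whose cutoffs are
    data-dependent.
    """
    p = np.asarray(p_values, dtype=float)
    shape = p.shape
    flat = p.ravel()
    if np.any(~np.isfinite(flat)):
        raise ValueError("p-value grid contains non-finite entries")
    key = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh",
           "benjamini-hochberg": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    flags = multipletests(flat, alpha=alpha, method=key)[0]
    threshold = alpha / len(flat) if key == "bonferroni" else np.nan
    return flags.reshape(shape), threshold
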