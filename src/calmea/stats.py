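"""Group comparisons and dose-response tabulation.

Reactive fractions are compared between conditions with a Pearson
chi-square test (no continuity correction) followed by a two-sided exact
Fisher test on the 2x2 reactive/non-reactive table; significance is
flagged from the Fisher p-value (the more conservative of the two) at
alpha = 0.05.  Group means are compared with Welch's unequal-variance
two-sided t test.  No multiple-testing correction is applied across
concentrations; the report notes this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FieldRecording
from . import quant

ALPHA = 0.05


@dataclass
class ContingencyTable2x2:
    """Counts a, b / c, d: (reactive, non-reactive) x (condition A, B)."""

    a: int
    b: int
    c: int
    d: int

    def as_array(self) -> np.ndarray:
        arr = np.array([[self.a, self.b], [self.c, self.d]], dtype=int)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        return arr


def _to_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return table.as_array()
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    return arr


def fisher_exact(table, two_sided: bool = True) -> float:
    """Exact Fisher test p-value for a 2x2 table.

    Two-sided by summing, over all tables with the observed margins, the
    hypergeometric probabilities no larger than that of the observed
    table.  A table with an empty margin carries no information; it
    yields p = 1 with a warning.
    """
    arr = _to_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("empty margin in 2x2 table; Fisher p set to 1", stacklevel=2)
        return 1.0
    alternative = "two-sided" if two_sided else "greater"
    return float(sps.fisher_exact(arr, alternative=alternative)[1])


def chi_square(table) -> Tuple[float, float]:
    """Pearson chi-square statistic (no continuity correction) and its
    p-value from the chi-square distribution with 1 df.

    Raises for zero expected counts (use :func:`fisher_exact` instead).
    """
    arr = _to_table(table).astype(float)
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n if n else np.zeros((2, 2))
    if n == 0 or (expected <= 0).any():
        raise ValueError(
            "zero expected count: the chi-square test is undefined; use fisher_exact"
        )
    stat = float(((arr - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def two_group_t(x, y) -> Tuple[float, float]:
    """Welch's unequal-variance two-sided t test."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def dose_response(
    conditions: Sequence[Tuple[str, Optional[float], Union[FieldRecording, np.ndarray]]],
    reference: str,
    stimulus_frame: Optional[int] = None,
    threshold: float = quant.DEFAULT_THRESHOLD,
    method: str = "sub",
    peak: str = "field",
    pool_mode: str = "none",
    pool_fraction: float = 0.20,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Reactive fractions per condition with comparisons to a reference.

    Each condition is ``(label, concentration, recording)``.  The full
    pipeline (offsets -> classification -> optional pool correction) is
    run per condition; every non-reference condition is compared to the
    reference by chi-square and exact Fisher tests on the 2x2
    reactive/non-reactive table.  Significance (``significant`` column)
    is flagged from the Fisher p-value at ``alpha``; p-value columns are
    NaN for the reference row and when only one condition is supplied.
    """
    labels = [c[0] for c in conditions]
    if reference not in labels:
        raise ValueError(f"reference condition {reference!r} not among conditions")
    per_condition = {}
    rows = []
    for label, conc, rec in conditions:
        offsets = quant.quantify_field(
            rec, stimulus_frame=stimulus_frame, method=method, peak=peak
        )
        calls = quant.classify_reactive(
            offsets["delta"].to_numpy(), threshold, cell_ids=offsets["cell_id"]
        )
        if pool_mode != "none":
            calls = quant.apply_pool_correction(calls, pool_fraction, pool_mode)
        per_condition[label] = calls
        rows.append(
            {
                "label": label,
                "concentration": conc,
                "n_total": calls.n_total,
                "n_reactive": calls.n_reactive,
                "fraction_reactive": calls.fraction_reactive,
            }
        )
    ref = per_condition[reference]
    for row in rows:
        if row["label"] == reference or len(conditions) < 2:
            row["chi2_stat"] = np.nan
            row["chi2_p"] = np.nan
            row["fisher_p"] = np.nan
            row["significant"] = False
            continue
        c = per_condition[row["label"]]
        table = np.array(
            [
                [c.n_reactive, c.n_total - c.n_reactive],
                [ref.n_reactive, ref.n_total - ref.n_reactive],
            ]
        )
        try:
            stat, chi_p = chi_square(table)
        except ValueError:
            stat, chi_p = np.nan, np.nan
        fp = fisher_exact(table)
        row["chi2_stat"] = stat
        row["chi2_p"] = chi_p
        row["fisher_p"] = fp
        row["significant"] = bool(fp < alpha)
    return pd.DataFrame(rows)
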