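"""Cohort characteristics tests: t-test for numeric, chi-square for categorical.

Pearson's chi-square is used without Yates continuity correction; expected
counts below 5 only trigger a logged warning (the test is still computed).
The t-test is available both from raw per-arm values and from published
(mean, sd, n) summaries, in pooled-variance and Welch variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or min(counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        object.__setattr__(self, "counts", counts.astype(float))


#: Demographic/clinical characteristics of the motivating HER2-positive
#: cohort (two arms by estrogen-receptor status, n = 21 ER- and n = 22 ER+),
#: as printed in its clinical characteristics table.  Columns are (ER-, ER+).
REFERENCE_COHORT_TABLES = {
    "stage": ContingencyTable(
        ("IIA", "IIB", "IIIA", "IIIB"),
        ("ER-", "ER+"),
        np.array([[4, 2], [13, 14], [4, 4], [0, 2]]),
    ),
    "ki67": ContingencyTable(
        ("<20", ">=20"), ("ER-", "ER+"), np.array([[10, 9], [11, 13]])
    ),
    "response": ContingencyTable(
        ("complete", "partial"), ("ER-", "ER+"), np.array([[13, 11], [8, 11]])
    ),
    "recurrence": ContingencyTable(
        ("yes", "no"), ("ER-", "ER+"), np.array([[3, 8], [18, 14]])
    ),
}

#: Arm sizes of the same cohort.
REFERENCE_ARM_SIZES = {"ER-": 21, "ER+": 22}


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        logger.warning(
            "%d expected cell count(s) below 5; chi-square approximation may be poor",
            int((expected < 5).sum()),
        )
    return float(stat), int(df), float(p)


def t_test(x, y, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test on raw values: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per arm")
    equal_var = _variant_flag(variant)
    if equal_var and np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_test_from_summaries(
    mean1, sd1, n1, mean2, sd2, n2, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided t-test from per-arm (mean, sd, n) summaries: (t, df, p)."""
    equal_var = _variant_flag(variant)
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _variant_flag(variant: str) -> bool:
    if variant == "pooled":
        return True
    if variant == "welch":
        return False
    raise ValueError(f"unknown t-test variant {variant!r}")


def crosstab(meta: pd.DataFrame, var: str, arm: str) -> ContingencyTable:
    """Build a ContingencyTable from two categorical metadata columns."""
    ct = pd.crosstab(meta[var], meta[arm])
    return ContingencyTable(
        tuple(map(str, ct.index)), tuple(map(str, ct.columns)), ct.to_numpy()
    )


def table_one(
    meta: pd.DataFrame,
    arm: str,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Arm-comparison p-values for a metadata table, one row per variable."""
    arms = meta[arm].dropna().unique()
    if arms.size != 2:
        raise ValueError("table_one expects exactly two arms")
    rows = []
    for var in numeric or []:
        x = meta.loc[meta[arm] == arms[0], var].dropna()
        y = meta.loc[meta[arm] == arms[1], var].dropna()
        t, df, p = t_test(x, y, variant=variant)
        rows.append({"variable": var, "test": f"t ({variant})", "statistic": t, "p_value": p})
    for var in categorical or []:
        stat, df, p = chi_square(crosstab(meta, var, arm))
        rows.append({"variable": var, "test": "chi-square", "statistic": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("variable")
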