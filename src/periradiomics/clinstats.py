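"""Clinical-characteristics statistics for benign/malignant cohorts.

Reproduces the statistics conventionally reported alongside a
benign-vs-malignant mammography cohort table: Pearson chi-square on
r x 2 contingency tables (with Yates continuity correction applied to
2 x 2 tables only) and the pooled-variance two-tailed two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi_square",
    "two_sample_t",
    "NSNCM_COHORT_TABLES",
]


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 table of nonnegative integer counts (benign, malignant).

    Parameters
    ----------
    rows : row-category labels, length r >= 2.
    benign, malignant : per-row counts for the two outcome columns.
    """

    rows: tuple[str, ...]
    benign: tuple[int, ...]
    malignant: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("contingency table needs at least 2 rows")
        if not (len(self.rows) == len(self.benign) == len(self.malignant)):
            raise ValueError("rows/benign/malignant lengths differ")
        counts = self.counts
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("total count must be positive")

    @property
    def counts(self) -> np.ndarray:
        return np.column_stack([self.benign, self.malignant]).astype(np.int64)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    corrected: bool
    expected: np.ndarray = field(repr=False, default=None)


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test on an r x 2 contingency table.

    For 2 x 2 tables the Yates continuity correction
    ``sum((|O - E| - 0.5)^2 / E)`` is applied; larger tables use the
    plain Pearson statistic ``sum((O - E)^2 / E)``.

    Raises
    ------
    ValueError
        If any row or column total is zero (expected counts undefined
        there, so the statistic is not computable on that margin).
    """
    counts = table.counts
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any():
        bad = [table.rows[i] for i in np.flatnonzero(row_tot == 0)]
        raise ValueError(f"zero row total for category {bad}")
    if (col_tot == 0).any():
        bad = ["benign", "malignant"][int(np.flatnonzero(col_tot == 0)[0])]
        raise ValueError(f"zero column total for outcome {bad!r}")
    corrected = counts.shape == (2, 2)
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=corrected)
    return ChiSquareResult(float(chi2), int(df), float(p), corrected, expected)


def two_sample_t(x, y) -> tuple[float, float]:
    """Two-tailed pooled-variance two-sample t test.

    Returns ``(t, p)``. Degenerate input with zero pooled variance and
    equal means reports ``(0.0, 1.0)`` rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


# Clinical-characteristics counts for a 1298-patient NSNCM surgical cohort
# (771 benign, 527 malignant): age bands, largest-diameter size split and
# BI-RADS breast-composition types. The empty malignant cell in the
# youngest age band is a structural zero.
NSNCM_COHORT_TABLES: dict[str, ContingencyTable] = {
    "age": ContingencyTable(
        rows=("<=20", "20-40", "40-60", ">60"),
        benign=(18, 348, 383, 22),
        malignant=(0, 66, 332, 129),
        name="Age, y",
    ),
    "size": ContingencyTable(
        rows=("<=20mm", ">20mm"),
        benign=(475, 296),
        malignant=(207, 320),
        name="Size, mm",
    ),
    "composition": ContingencyTable(
        rows=("A", "B", "C", "D"),
        benign=(9, 37, 666, 59),
        malignant=(23, 74, 417, 13),
        name="Breast composition type",
    ),
}
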