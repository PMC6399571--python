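"""Cohort-comparison statistics: Pearson chi-square on contingency tables,
pooled two-sample t tests from summary statistics, and fall rates per 1000
hospital days.

No Yates continuity correction anywhere: the two-site comparison tables
this package ships as a fixture reproduce their published statistics only
with the uncorrected Pearson form. The admission-level fall comparison is
constructed as faller vs. nonfaller admissions (an admission with at least
one fall counts once), the construction consistent with the published
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats
from scipy.stats import chi2_contingency

__all__ = [
    "ContingencyTable",
    "RateResult",
    "DegenerateTableError",
    "chi_square",
    "two_sample_t",
    "rate_per_1000",
    "rate_comparison_chi_square",
    "bundled_cohort_tables",
    "compare_sites",
    "cohort_summary",
]

_DATA_DIR = Path(__file__).parent / "data"


class DegenerateTableError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """r x k nonnegative integer counts with row/column labels."""

    counts: tuple
    row_labels: tuple
    col_labels: tuple

    @classmethod
    def from_array(cls, counts, row_labels=None, col_labels=None):
        a = np.asarray(counts)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
            raise DegenerateTableError("need at least a 2x2 table")
        if np.any(a < 0) or not np.allclose(a, np.round(a)):
            raise DegenerateTableError("counts must be nonnegative integers")
        r, k = a.shape
        return cls(
            counts=tuple(tuple(int(v) for v in row) for row in a),
            row_labels=tuple(row_labels or [f"row{i}" for i in range(r)]),
            col_labels=tuple(col_labels or [f"col{j}" for j in range(k)]),
        )

    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def chi_square(table: ContingencyTable | Sequence) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square: (statistic, df, p-value)."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_array(table)
    a = table.array()
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    expected = stats.contingency.expected_freq(a)
    if (expected <= 0).any():
        raise DegenerateTableError("zero expected cell count")
    stat, p, df, _ = chi2_contingency(a, correction=False)
    return float(stat), int(df), float(p)


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics (pooled-variance form by
    default; ``welch=True`` for unequal variances)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class RateResult:
    events: int
    exposure_days: float
    rate_per_1000: float


def rate_per_1000(events: int, exposure_days: float) -> RateResult:
    """Event rate per 1000 days of exposure."""
    if exposure_days <= 0:
        raise ValueError("exposure_days must be positive")
    if events < 0:
        raise ValueError("events must be nonnegative")
    return RateResult(int(events), float(exposure_days),
                      1000.0 * events / exposure_days)


def rate_comparison_chi_square(
    events1: int, days1: int, events2: int, days2: int
) -> tuple[float, int, float]:
    """Pearson chi-square comparing two per-day rates, via the 2x2 table of
    event-days vs. non-event-days."""
    if days1 <= events1 or days2 <= events2:
        raise ValueError("exposure days must exceed event counts")
    table = [[events1, days1 - events1], [events2, days2 - events2]]
    return chi_square(ContingencyTable.from_array(
        table, ("site1", "site2"), ("event_day", "no_event_day")
    ))


def bundled_cohort_tables() -> dict:
    """The packaged two-site comparison fixture (printed summary counts)."""
    with open(_DATA_DIR / "cohort_tables.yaml") as fh:
        return yaml.safe_load(fh)


def compare_sites(tables: dict | None = None) -> dict:
    """All two-site comparison statistics from a summary-count fixture.

    Returns chi-square results per categorical characteristic, pooled t for
    each mean/SD row, fall and injurious-fall rates per site, and the
    rate-comparison chi-squares.
    """
    t = tables or bundled_cohort_tables()
    out: dict = {"chi_square": {}, "t_test": {}, "rates": {}, "rate_chi_square": {}}
    for name, spec in t.get("contingency", {}).items():
        table = ContingencyTable.from_array(
            spec["counts"], spec.get("rows"), spec.get("cols")
        )
        stat, df, p = chi_square(table)
        out["chi_square"][name] = {"statistic": stat, "df": df, "p": p}
    for name, spec in t.get("summary", {}).items():
        stat, df, p = two_sample_t(
            spec["mean1"], spec["sd1"], spec["n1"],
            spec["mean2"], spec["sd2"], spec["n2"],
        )
        out["t_test"][name] = {"statistic": stat, "df": df, "p": p}
    for name, spec in t.get("rates", {}).items():
        r1 = rate_per_1000(spec["events1"], spec["days1"])
        r2 = rate_per_1000(spec["events2"], spec["days2"])
        out["rates"][name] = {
            "site1": r1.rate_per_1000, "site2": r2.rate_per_1000,
        }
        stat, df, p = rate_comparison_chi_square(
            spec["events1"], spec["days1"], spec["events2"], spec["days2"]
        )
        out["rate_chi_square"][name] = {"statistic": stat, "df": df, "p": p}
    return out


def cohort_summary(cohort) -> dict:
    """Descriptive summary of one synthetic cohort, in the shape of the
    site-comparison characteristics (marginals, LOS, fall rates)."""
    static = cohort.static
    n = len(static)
    out: dict = {
        "n_admissions": n,
        "hospital_days": cohort.total_hospital_days,
        "n_falls": cohort.n_falls,
    }
    if n == 0:
        return out
    out["fall_rate_per_1000"] = cohort.fall_rate_per_1000()
    injurious = cohort.events[cohort.events["injury_level"] != "none"]
    out["injurious_rate_per_1000"] = (
        1000.0 * len(injurious) / cohort.total_hospital_days
    )
    out["length_of_stay"] = {
        "mean": float(static["length_of_stay"].mean()),
        "sd": float(static["length_of_stay"].std(ddof=1)) if n > 1 else 0.0,
    }
    for col in ("sex", "age_bin", "diagnosis_group", "secondary_dx", "kpcs_group"):
        if col in static.columns:
            out[col] = (
                static[col].value_counts(normalize=True).sort_index().to_dict()
            )
    fallers = cohort.events["admission_id"].value_counts()
    out["fall_events"] = {
        "one": int((fallers == 1).sum()),
        "multiple": int((fallers > 1).sum()),
    }
    return out
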