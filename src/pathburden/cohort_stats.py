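"""Cohort demographics: group descriptives and the 2x2 chi-square test.

The sex comparison is the uncorrected Pearson chi-square on the 2x2
group-by-sex table (1 degree of freedom), computed from the closed form

    X^2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))

with the optional Yates continuity correction off by default.  Age is
continuous, so a chi-square is not directly applicable; a Welch two-sample
t-test is offered for it, labeled as this package's choice of method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out rows = group (case, control), cols = category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


def chi_square_2x2(
    t: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 table; returns (statistic, p).

    Raises on a zero margin (expected count of zero).
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: chi-square undefined")
    det = t.a * t.d - t.b * t.c
    num = abs(det)
    if continuity_correction:
        num = max(0.0, num - t.total / 2)
    stat = t.total * num * num / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


def describe_group(values) -> tuple[float, float, int]:
    """(mean, sample sd with n-1 denominator, n); sd is NaN for n < 2."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise ValueError("cannot describe an empty series")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else float("nan")
    return mean, sd, n


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); (statistic, p)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)


REQUIRED_METADATA = ["sample_id", "group", "age_years", "sex"]


def table1(metadata: pd.DataFrame) -> pd.DataFrame:
    """Demographics summary table for a case/control cohort.

    ``metadata`` columns: sample_id, group (case/control), age_years, sex
    (female/male), and optionally illness_duration_months and hamd_score
    for cases.  Emits per-group means/SDs, sex counts with percentages, and
    the uncorrected chi-square p for sex.  An all-one-sex cohort has a zero
    margin; the sex p-value is then reported as NaN ("not applicable").
    """
    missing = [c for c in REQUIRED_METADATA if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    if metadata["group"].isna().any() or not (
        set(metadata["group"]) <= {"case", "control"}
    ):
        raise ValueError("every sample needs a group label: case or control")
    cases = metadata[metadata["group"] == "case"]
    controls = metadata[metadata["group"] == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both case and control groups must be non-empty")

    rows = []

    def _numeric_row(label: str, col: str, cases_only: bool = False) -> None:
        cm, cs, _ = describe_group(cases[col])
        if cases_only:
            rows.append((label, round(cm, 2), round(cs, 2),
                         np.nan, np.nan, np.nan))
        else:
            hm, hs, _ = describe_group(controls[col])
            _, p = welch_t_test(cases[col].dropna(), controls[col].dropna())
            rows.append((label, round(cm, 2), round(cs, 2),
                         round(hm, 2), round(hs, 2), round(p, 3)))

    _numeric_row("age, years", "age_years")
    if "illness_duration_months" in metadata.columns and \
            cases["illness_duration_months"].notna().any():
        _numeric_row("illness duration, months", "illness_duration_months",
                     cases_only=True)
    if "hamd_score" in metadata.columns and cases["hamd_score"].notna().any():
        _numeric_row("HAMD score", "hamd_score", cases_only=True)

    sex_counts = {
        (g, s): int((metadata["group"].eq(g) & metadata["sex"].eq(s)).sum())
        for g in ("case", "control") for s in ("female", "male")
    }
    tab = ContingencyTable2x2(
        a=sex_counts[("case", "female")], b=sex_counts[("case", "male")],
        c=sex_counts[("control", "female")], d=sex_counts[("control", "male")],
    )
    try:
        _, sex_p = chi_square_2x2(tab, continuity_correction=False)
        sex_p = round(sex_p, 3)
    except ValueError:  # zero margin, e.g. an all-male cohort
        sex_p = np.nan
    n_case, n_ctrl = len(cases), len(controls)
    for sex in ("female", "male"):
        fc, hc = sex_counts[("case", sex)], sex_counts[("control", sex)]
        rows.append((sex.capitalize(), fc, round(100 * fc / n_case, 1),
                     hc, round(100 * hc / n_ctrl, 1),
                     sex_p if sex == "female" else np.nan))
    return pd.DataFrame(
        rows,
        columns=["characteristic", "case_mean_or_n", "case_sd_or_pct",
                 "control_mean_or_n", "control_sd_or_pct", "p_value"],
    )
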