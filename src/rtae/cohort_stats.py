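"""mRECIST response classification and cohort group-comparison statistics.

Treatment response of a target lesion is graded on viable (arterially
enhancing) tumor: complete response (CR) when enhancement disappears,
partial response (PR) at >=30% enhancement decrease, progressive disease
(PD) at >=20% size increase, stable disease (SD) otherwise. CR and PR
together form the objective-response endpoint.

Group comparisons mirror a baseline-characteristics table: continuous
variables as median (IQR) with a Mann-Whitney U test; binary variables as
counts (%) with Fisher's exact test when any expected cell is below 5 and
Pearson's chi-squared otherwise. Two-sided Fisher p-values follow the
point-probability summation convention (sum of hypergeometric
probabilities not exceeding the observed table's, with a 1+1e-7 relative
tolerance), which is what scipy.stats.fisher_exact implements.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ResponseLabel:
    """mRECIST category with derived binary endpoints."""

    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown mRECIST category {self.category!r}")

    @property
    def complete_response(self) -> bool:
        return self.category == "CR"

    @property
    def objective_response(self) -> bool:
        return self.category in ("CR", "PR")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = feature present/absent, columns = response group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def mrecist_classify(
    pre_enhancement: float,
    post_enhancement: float,
    pre_size: float,
    post_size: float,
) -> ResponseLabel:
    """Grade one lesion from pre/post enhancement (%) and diameter (mm).

    Precedence CR > PD > PR > SD: disappearance of enhancement always wins;
    otherwise a >=20% size increase marks progression even if enhancement
    also fell; boundaries are inclusive.
    """
    if min(pre_enhancement, post_enhancement, pre_size, post_size) < 0:
        raise ValueError("enhancement and size must be non-negative")
    if pre_enhancement <= 0 or pre_size <= 0:
        raise ValueError("baseline enhancement and size must be positive")
    if post_enhancement == 0:
        return ResponseLabel("CR")
    if (post_size - pre_size) / pre_size >= 0.20:
        return ResponseLabel("PD")
    if (pre_enhancement - post_enhancement) / pre_enhancement >= 0.30:
        return ResponseLabel("PR")
    return ResponseLabel("SD")


def summarize_cohort(labels: list[ResponseLabel]) -> dict:
    """Counts and percentages (1 decimal) per category and endpoint."""
    if not labels:
        raise ValueError("empty cohort")
    n = len(labels)
    out: dict[str, dict] = {"n": n, "categories": {}, "endpoints": {}}
    for cat in CATEGORIES:
        k = sum(lab.category == cat for lab in labels)
        out["categories"][cat] = {"count": k, "pct": round(100.0 * k / n, 1)}
    for name, pred in (
        ("complete_response", lambda lab: lab.complete_response),
        ("objective_response", lambda lab: lab.objective_response),
    ):
        k = sum(pred(lab) for lab in labels)
        out["endpoints"][name] = {"count": k, "pct": round(100.0 * k / n, 1)}
    return out


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (point-probability summation)."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0  # a zero margin carries no information
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-squared statistic and p, no continuity correction."""
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell; use fisher_exact_2x2")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x0, x1) -> tuple[float, float]:
    """Mann-Whitney U (for group 0) with two-sided p.

    Exact enumeration when n0+n1 <= 12 with no ties; otherwise the normal
    approximation with tie correction.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x0, x1])
    exact = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x0, x1, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def compare_groups(
    variables: pd.DataFrame,
    group: np.ndarray,
    binary_threshold: int = 3,
) -> pd.DataFrame:
    """Per-variable two-group comparison report.

    Columns with at most ``binary_threshold`` distinct values are treated
    as categorical (counts and % of the non-zero/indicator level, or an
    r x 2 chi-squared for multi-level), the rest as continuous. Constant
    columns are reported untestable (test "NA").
    """
    group = np.asarray(group).astype(int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    rows = []
    n1, n0 = int(group.sum()), int((1 - group).sum())
    for name in variables.columns:
        x = variables[name].to_numpy(dtype=float)
        levels = np.unique(x)
        if len(levels) == 1:
            rows.append(
                dict(variable=name, summary_pos="-", summary_neg="-",
                     test="NA", p=np.nan, significant=False)
            )
            continue
        if len(levels) <= binary_threshold:
            if set(levels) <= {0.0, 1.0}:
                a = int(x[group == 1].sum())
                b = int(x[group == 0].sum())
                tab = ContingencyTable2x2(a, b, n1 - a, n0 - b)
                arr = tab.as_array()
                expected = stats.contingency.expected_freq(arr)
                if expected.min() < 5:
                    test, p = "fisher", fisher_exact_2x2(tab)
                else:
                    test, (_, p) = "chi2", pearson_chi2(tab)
                s1 = f"{a} ({100 * a / n1:.1f})"
                s0 = f"{b} ({100 * b / n0:.1f})"
            else:
                counts = np.array(
                    [[np.sum((x == lv) & (group == g)) for g in (1, 0)] for lv in levels]
                )
                expected = stats.contingency.expected_freq(counts)
                res = stats.chi2_contingency(counts, correction=False)
                test, p = "chi2", float(res.pvalue)
                s1 = "/".join(str(int(c)) for c in counts[:, 0])
                s0 = "/".join(str(int(c)) for c in counts[:, 1])
        else:
            test = "mannwhitney"
            _, p = mann_whitney_u(x[group == 1], x[group == 0])
            s1 = _median_iqr(x[group == 1])
            s0 = _median_iqr(x[group == 0])
        rows.append(
            dict(variable=name, summary_pos=s1, summary_neg=s0,
                 test=test, p=p, significant=bool(p < 0.05))
        )
    return pd.DataFrame(rows)


def load_printed_tables() -> pd.DataFrame:
    """Packaged fixture of the published baseline-table 2x2 counts.

    Columns: variable, endpoint (cr/or), a..d counts (a/b = feature
    present in responders/non-responders), printed_p, and router_matches
    marking rows where the expected-cell<5 Fisher/chi2 router reproduces
    the printed p-value to 3 decimals.
    """
    ref = importlib.resources.files("rtae.data").joinpath("tables_1_2_counts.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def printed_table_pvalues(verified_only: bool = True) -> pd.DataFrame:
    """Recompute the routed test p-value for every fixture row."""
    df = load_printed_tables().copy()
    recomputed = []
    test_used = []
    for row in df.itertuples():
        tab = ContingencyTable2x2(row.a, row.b, row.c, row.d)
        expected = stats.contingency.expected_freq(tab.as_array())
        if expected.min() < 5:
            recomputed.append(fisher_exact_2x2(tab))
            test_used.append("fisher")
        else:
            recomputed.append(pearson_chi2(tab)[1])
            test_used.append("chi2")
    df["recomputed_p"] = recomputed
    df["test"] = test_used
    if verified_only:
        df = df[df.router_matches == 1].reset_index(drop=True)
    return df
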