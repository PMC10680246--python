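"""Endpoint statistics: two-sample tests, summaries, enrollment arithmetic.

Continuous endpoints are reported as mean +/- SD and compared with an
independent two-sample t-test (Student's pooled-variance test by default,
Welch available); categorical endpoints with a 2x2 chi-square test without
continuity correction.  Censored days-to-target are excluded from means and
reported as separate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import INJECTIONS, MEALS, Period
from .trial import CohortResult, hypo_by_period


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- SD summary of ``n`` observations."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p_value out of range")


def t_test_from_summary(
    a: SummaryStat, b: SummaryStat, method: str = "pooled"
) -> TestResult:
    """Two-sided independent two-sample t-test from summary statistics.

    ``pooled`` is Student's equal-variance test; ``welch`` uses the
    Welch-Satterthwaite degrees of freedom.
    """
    if method not in ("pooled", "welch"):
        raise ValueError(f"unknown method {method!r}")
    res = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(method == "pooled")
    )
    if method == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method=f"t-{method}",
    )


def t_test(a, b, method: str = "pooled") -> TestResult:
    """Two-sided independent t-test from raw samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return t_test_from_summary(
        SummaryStat(float(a.mean()), float(a.std(ddof=1)), a.size),
        SummaryStat(float(b.mean()), float(b.std(ddof=1)), b.size),
        method,
    )


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """2x2 chi-square test of two proportions, no continuity correction.

    A degenerate table (a zero row or column margin) carries no information
    about a difference; it returns p = 1 with the ``degenerate`` flag set.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(0.0, 1.0, 1.0, "chi2", degenerate=True)
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(df), float(p), "chi2")


def sample_size_with_dropout(n_per_group: int, dropout_rate: float) -> int:
    """Total enrollment for two equal groups allowing for dropout.

    Ceiling of ``2 * n_per_group / (1 - dropout_rate)``, with a guard
    against binary-float artifacts at exact quotients.

    >>> sample_size_with_dropout(86, 0.20)
    215
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    exact = 2 * n_per_group / (1 - dropout_rate)
    return int(math.ceil(round(exact, 9)))


def summarize(values) -> dict:
    """Mean +/- SD over the non-censored values, with a censored count."""
    clean = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    out = {"n": len(clean), "n_censored": len(values) - len(clean)}
    if len(clean) >= 1:
        arr = np.asarray(clean, dtype=float)
        out["mean"] = float(arr.mean())
        out["sd"] = float(arr.std(ddof=1)) if len(clean) >= 2 else 0.0
    else:
        out["mean"] = None
        out["sd"] = None
    return out


def _endpoint_columns() -> list[str]:
    return ["fbg", *MEALS]


def arm_report(result: CohortResult, t_method: str = "pooled") -> dict:
    """Tabular per-arm summary mirroring the trial's results structure.

    Per arm: mean +/- SD days-to-target for the four readings (censored
    excluded, counted separately), mean +/- SD final administered doses in
    units/day, and patient-level hypoglycemia percentages per clock period
    and level; plus cross-arm p-values for each comparison.
    """
    arm_labels = [a for a, recs in result.arms.items() if recs]
    if not arm_labels:
        raise ValueError("empty cohort")
    report: dict = {"meta": dict(result.meta), "arms": {}, "comparisons": {}}

    per_arm_raw: dict[str, dict] = {}
    for arm in arm_labels:
        recs = result.arms[arm]
        raw = {
            "days": {
                key: [r.days_to_target[key] for r in recs]
                for key in _endpoint_columns()
            },
            "doses": {
                inj: [r.final_doses[inj] for r in recs] for inj in INJECTIONS
            },
        }
        per_arm_raw[arm] = raw
        hypo = hypo_by_period(recs)
        n = len(recs)
        report["arms"][arm] = {
            "n": n,
            "days_to_target": {k: summarize(v) for k, v in raw["days"].items()},
            "final_doses": {k: summarize(v) for k, v in raw["doses"].items()},
            "hypoglycemia": {
                period: {
                    "levels": {lvl: hypo[period][lvl] for lvl in (1, 2, 3)},
                    "patients": hypo[period]["any"],
                    "percent": round(100.0 * hypo[period]["any"] / n, 1),
                }
                for period in (p.value for p in Period)
            },
        }

    if len(arm_labels) == 2:
        a, b = arm_labels
        comp: dict = {"days_to_target": {}, "final_doses": {}, "hypoglycemia": {}}
        for key in _endpoint_columns():
            xa = [v for v in per_arm_raw[a]["days"][key] if v is not None]
            xb = [v for v in per_arm_raw[b]["days"][key] if v is not None]
            if len(xa) >= 2 and len(xb) >= 2:
                res = t_test(xa, xb, t_method)
                comp["days_to_target"][key] = {"p": res.p_value, "t": res.statistic}
            else:
                comp["days_to_target"][key] = {"p": None, "t": None}
        for inj in INJECTIONS:
            res = t_test(per_arm_raw[a]["doses"][inj], per_arm_raw[b]["doses"][inj], t_method)
            comp["final_doses"][inj] = {"p": res.p_value, "t": res.statistic}
        for period in (p.value for p in Period):
            xa = report["arms"][a]["hypoglycemia"][period]["patients"]
            xb = report["arms"][b]["hypoglycemia"][period]["patients"]
            res = two_proportion_test(
                xa, report["arms"][a]["n"], xb, report["arms"][b]["n"]
            )
            comp["hypoglycemia"][period] = {"p": res.p_value, "chi2": res.statistic}
        report["comparisons"] = comp
    return report


REPORT_SCHEMA_VERSION = 1


def report_from_frame(df: pd.DataFrame, t_method: str = "pooled") -> dict:
    """Build the arm report directly from the tidy per-patient results frame.

    Accepts the CSV schema written by the simulator (one row per patient);
    produces the same report structure as :func:`arm_report`.
    """
    required = {"patient_id", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results frame missing column(s): {', '.join(sorted(missing))}")
    arm_labels = [a for a in df["arm"].unique()]
    report: dict = {
        "meta": {"schema_version": REPORT_SCHEMA_VERSION, "n_analyzed": int(len(df))},
        "arms": {},
        "comparisons": {},
    }
    periods = [p.value for p in Period]
    per_arm: dict[str, pd.DataFrame] = {a: df[df["arm"] == a] for a in arm_labels}
    for arm, sub in per_arm.items():
        n = len(sub)
        days = {
            key: summarize(list(sub[f"days_{key}"])) for key in _endpoint_columns()
        }
        doses = {inj: summarize(list(sub[f"final_{inj}_units"])) for inj in INJECTIONS}
        hypo = {}
        for period in periods:
            level_cols = {lvl: f"hypo_{period}_l{lvl}" for lvl in (1, 2, 3)}
            levels = {lvl: int((sub[col] > 0).sum()) for lvl, col in level_cols.items()}
            any_n = int((sub[list(level_cols.values())].sum(axis=1) > 0).sum())
            hypo[period] = {
                "levels": levels,
                "patients": any_n,
                "percent": round(100.0 * any_n / n, 1),
            }
        report["arms"][arm] = {
            "n": n,
            "days_to_target": days,
            "final_doses": doses,
            "hypoglycemia": hypo,
        }
    if len(arm_labels) == 2:
        a, b = arm_labels
        comp: dict = {"days_to_target": {}, "final_doses": {}, "hypoglycemia": {}}
        for key in _endpoint_columns():
            xa = per_arm[a][f"days_{key}"].dropna()
            xb = per_arm[b][f"days_{key}"].dropna()
            if len(xa) >= 2 and len(xb) >= 2:
                res = t_test(xa, xb, t_method)
                comp["days_to_target"][key] = {"p": res.p_value, "t": res.statistic}
            else:
                comp["days_to_target"][key] = {"p": None, "t": None}
        for inj in INJECTIONS:
            res = t_test(
                per_arm[a][f"final_{inj}_units"], per_arm[b][f"final_{inj}_units"], t_method
            )
            comp["final_doses"][inj] = {"p": res.p_value, "t": res.statistic}
        for period in periods:
            res = two_proportion_test(
                report["arms"][a]["hypoglycemia"][period]["patients"],
                report["arms"][a]["n"],
                report["arms"][b]["hypoglycemia"][period]["patients"],
                report["arms"][b]["n"],
            )
            comp["hypoglycemia"][period] = {"p": res.p_value, "chi2": res.statistic}
        report["comparisons"] = comp
    return report
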