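"""Group-level analyses of regional MISL tables.

Three analyses mirror how regional tissue–CSF flow values are used once
the maps are made: an ordinary least-squares age trend per composite CSF
region, test–retest reliability as a two-way random-effects
absolute-agreement single-measure ICC — ICC(2,1), the standard
test–retest choice; ICC(3,1) available via ``variant`` — and Bland–Altman
agreement (bias and 1.96·SD limits of agreement).  Test–retest pairs are
pooled across all ROIs and subjects rather than averaged per subject
first.  No multiple-testing correction is applied across regions; p
values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "ICCResult",
    "BlandAltmanResult",
    "age_regression",
    "icc_two_session",
    "bland_altman",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # mL/100 mL/min per year for TCF tables
    intercept: float
    p_value: float
    r_squared: float
    stderr: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str
    n_pairs: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def _region_rows(table: pd.DataFrame, region: str | None) -> pd.DataFrame:
    if region is None:
        return table
    col = "region" if "region" in table.columns else "roi_name"
    sub = table[table[col] == region]
    if sub.empty:
        raise ValueError(f"no rows for region {region!r}")
    return sub


def age_regression(
    table: pd.DataFrame, region: str | None = None, metric: str = "mean_tcf"
) -> RegressionResult:
    """OLS of a regional metric on age with a two-sided t-test on the slope.

    Expects columns (subject, age, region|roi_name, metric).  Requires at
    least three subjects with distinct ages.  A constant response is
    flagged degenerate (slope 0, p = 1) instead of propagating NaN.
    """
    sub = _region_rows(table, region)
    age = np.asarray(sub["age"], dtype=float)
    y = np.asarray(sub[metric], dtype=float)
    ok = np.isfinite(age) & np.isfinite(y)
    age, y = age[ok], y[ok]
    if len(np.unique(age)) < 3:
        raise ValueError(
            f"need >= 3 distinct ages for a regression, got {len(np.unique(age))}"
        )
    if np.ptp(y) == 0.0:
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            p_value=1.0,
            r_squared=0.0,
            stderr=0.0,
            n=len(y),
            degenerate=True,
        )
    fit = sps.linregress(age, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        stderr=float(fit.stderr),
        n=len(y),
    )


def _paired_sessions(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Wide (one row per subject×region, columns s1/s2) from the long table."""
    col = "region" if "region" in table.columns else "roi_name"
    need = {"subject", "session", col, metric}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["subject", col], columns="session", values=metric, aggfunc="first"
    )
    if set(wide.columns) != {1, 2}:
        raise ValueError(f"expected sessions {{1, 2}}, got {sorted(wide.columns)}")
    if wide.isna().any().any():
        unpaired = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unpaired rows (present in only one session): {unpaired}")
    return wide.rename(columns={1: "s1", 2: "s2"})


def icc_two_session(
    table: pd.DataFrame, metric: str = "mean_tcf", variant: str = "icc2"
) -> ICCResult:
    """Test–retest ICC over (subject, region) pairs measured in two sessions.

    variant "icc2": two-way random effects, absolute agreement, single
    measure — sensitive to systematic session offsets; "icc3": two-way
    mixed, consistency.  Confidence intervals are the F-distribution-based
    95% intervals.
    """
    if variant not in ("icc2", "icc3"):
        raise ValueError("variant must be 'icc2' or 'icc3'")
    import pingouin as pg  # deferred: heavy import

    wide = _paired_sessions(table, metric)
    long = wide.reset_index(drop=True)
    long["target"] = np.arange(len(long))
    melted = long.melt(id_vars="target", value_vars=["s1", "s2"], var_name="rater")
    res = pg.intraclass_corr(
        data=melted, targets="target", raters="rater", ratings="value"
    )
    # absolute agreement (A,1) is ICC(2,1); consistency (C,1) is ICC(3,1)
    wanted = "ICC(A,1)" if variant == "icc2" else "ICC(C,1)"
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    row = res[res["Type"] == wanted].iloc[0]
    ci_low, ci_high = (float(v) for v in row[ci_col])
    return ICCResult(
        icc=float(row["ICC"]),
        ci_low=ci_low,
        ci_high=ci_high,
        variant=variant,
        n_pairs=len(wide),
    )


def bland_altman(table: pd.DataFrame, metric: str = "mean_tcf") -> BlandAltmanResult:
    """Bland–Altman agreement between the two sessions.

    Differences are session 1 − session 2; bias is their mean and the
    limits of agreement are bias ± 1.96·SD (sample SD, ddof 1).  Requires
    at least two pairs.
    """
    wide = _paired_sessions(table, metric)
    if len(wide) < 2:
        raise ValueError(f"need >= 2 pairs for Bland-Altman, got {len(wide)}")
    diff = np.asarray(wide["s1"] - wide["s2"], dtype=float)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=len(diff),
    )
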