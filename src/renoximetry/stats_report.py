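"""Repeated-measures statistics and cohort summary tables.

One-way within-subject (repeated-measures) ANOVA per metabolic parameter and
imaging site across the breathing conditions, followed by Bonferroni-adjusted
paired t-tests for all condition pairs, and mean +/- SD summary tables with
reporting-layer rounding.  Subjects missing any condition are excluded
listwise from inference but retained in descriptive summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_synth import CONDITIONS
from .fick import round_for_report

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "DegenerateDataError",
    "rm_anova",
    "pairwise_bonferroni",
    "paired_scope_comparison",
    "summarize_cohort",
    "significance_stars",
]


class DegenerateDataError(ValueError):
    """The within-subject design has no usable error variance."""


@dataclass(frozen=True)
class AnovaResult:
    parameter: str
    site: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_subjects_used: int
    gg_epsilon: float | None = None  # set when Greenhouse-Geisser correction applied


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    n_comparisons: int
    note: str = ""


def _select(table: pd.DataFrame, parameter: str | None, site: str | None) -> pd.DataFrame:
    df = table
    if parameter is not None:
        df = df[df["parameter"] == parameter]
    if site is not None:
        df = df[df["site"] == site]
    if df.empty:
        raise ValueError(f"no rows for parameter={parameter!r}, site={site!r}")
    return df


def _complete_pivot(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.pivot_table(index="subject", columns="condition", values="value", aggfunc="mean")
    order = [c for c in CONDITIONS if c in wide.columns] + [
        c for c in wide.columns if c not in CONDITIONS
    ]
    wide = wide[order].dropna(axis=0, how="any")  # listwise deletion
    return wide


def rm_anova(
    table: pd.DataFrame,
    parameter: str | None = None,
    site: str | None = None,
    correction: str = "none",
) -> AnovaResult:
    """One-way repeated-measures ANOVA from the within-subject decomposition.

    ``table`` is long format with columns ``subject, condition, site,
    parameter, value`` (``site``/``parameter`` optional if pre-filtered).
    Sums of squares partition into condition, subject and error terms;
    ``F = MS_condition / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees of
    freedom.  ``correction='gg'`` applies the Greenhouse-Geisser sphericity
    correction to the degrees of freedom and reports the epsilon used.
    """
    df = _select(table, parameter, site)
    wide = _complete_pivot(df)
    n, k = wide.shape
    if k < 2:
        raise ValueError("at least 2 conditions required")
    if n < 3:
        raise ValueError(f"only {n} complete subjects after listwise deletion; >= 3 required")

    y = wide.to_numpy(dtype=float)
    grand = y.mean()
    ss_cond = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_cond - ss_subj
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    if ms_err <= 0:
        raise DegenerateDataError(
            "zero within-subject error variance: F statistic is 0/0 (degenerate design)"
        )
    f_stat = (ss_cond / df_num) / ms_err

    eps = None
    if correction == "gg":
        cov = np.cov(y, rowvar=False, ddof=1)
        dc = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
        eps = float(np.trace(dc) ** 2 / ((k - 1) * (dc**2).sum()))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        p_value = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
    elif correction == "none":
        p_value = float(sps.f.sf(f_stat, df_num, df_den))
    else:
        raise ValueError(f"unknown correction {correction!r}")

    param_label = parameter or (
        str(df["parameter"].iloc[0]) if "parameter" in df.columns else ""
    )
    site_label = site or (str(df["site"].iloc[0]) if "site" in df.columns else "")
    return AnovaResult(
        parameter=param_label,
        site=site_label,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        n_subjects_used=n,
        gg_epsilon=eps,
    )


def pairwise_bonferroni(
    table: pd.DataFrame, parameter: str | None = None, site: str | None = None
) -> list[PairwiseResult]:
    """Paired two-sided t-tests for all condition pairs, Bonferroni adjusted.

    Adjusted p-values are ``min(1, raw_p * n_comparisons)``.  Pairs with zero
    variance of the paired differences are reported as incomparable (NaN
    p-values with a note), never as p = 1.
    """
    df = _select(table, parameter, site)
    wide = _complete_pivot(df)
    if wide.shape[0] < 3:
        raise ValueError("fewer than 3 complete subjects after listwise deletion")
    pairs = list(itertools.combinations(wide.columns, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        diffs = wide[a].to_numpy() - wide[b].to_numpy()
        if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(ddof=0), 0.0):
            results.append(
                PairwiseResult(
                    pair=(a, b),
                    raw_p=float("nan"),
                    adjusted_p=float("nan"),
                    n_comparisons=m,
                    note="incomparable: zero variance of paired differences",
                )
            )
            continue
        t_res = sps.ttest_rel(wide[a], wide[b])
        raw_p = float(t_res.pvalue)
        results.append(
            PairwiseResult(
                pair=(a, b),
                raw_p=raw_p,
                adjusted_p=min(1.0, raw_p * m),
                n_comparisons=m,
            )
        )
    return results


def paired_scope_comparison(
    table: pd.DataFrame,
    parameter: str,
    scope_a: str,
    scope_b: str,
    n_comparisons: int | None = None,
) -> list[PairwiseResult]:
    """Per-condition paired t-tests between two measurement scopes.

    Used to compare the single-kidney rate against the flow-difference
    (bilateral) rate at each breathing condition; Bonferroni multiplier
    defaults to the number of conditions compared.
    """
    df = table[table["parameter"] == parameter]
    a = df[df["site"] == scope_a].pivot_table(index="subject", columns="condition", values="value")
    b = df[df["site"] == scope_b].pivot_table(index="subject", columns="condition", values="value")
    conditions = [c for c in CONDITIONS if c in a.columns and c in b.columns]
    m = n_comparisons or len(conditions)
    results = []
    for cond in conditions:
        joined = pd.concat([a[cond], b[cond]], axis=1, keys=["a", "b"]).dropna()
        diffs = joined["a"].to_numpy() - joined["b"].to_numpy()
        if len(diffs) < 3 or np.isclose(np.std(diffs, ddof=0), 0.0):
            results.append(
                PairwiseResult((scope_a, scope_b), float("nan"), float("nan"), m,
                               note=f"{cond}: incomparable"))
            continue
        raw_p = float(sps.ttest_rel(joined["a"], joined["b"]).pvalue)
        results.append(
            PairwiseResult((f"{scope_a}@{cond}", f"{scope_b}@{cond}"), raw_p,
                           min(1.0, raw_p * m), m)
        )
    return results


_DISPLAY = {  # parameter -> (rounding kind, display scale)
    "sao2": ("sao2", 100.0),
    "svo2": ("svo2", 100.0),
    "avdo2": ("avdo2", 100.0),
    "t2": ("t2", 1.0),
    "bfr": ("bfr", 1.0),
    "delta_bfr": ("delta_bfr", 1.0),
    "rmro2": ("rmro2", 1.0),
}


def summarize_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per (site, parameter, condition) with reporting rounding.

    ``records`` is the long cohort table (``subject, condition, site,
    parameter, value``); rates are already computed per subject, so the cell
    mean is the per-subject-then-averaged quantity.  Saturations are
    displayed in percent; flows and rates are rounded to the tens place.
    """
    rows = []
    for (site, parameter, condition), group in records.groupby(
        ["site", "parameter", "condition"], sort=False
    ):
        values = group["value"].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        kind, scale = _DISPLAY.get(parameter, (None, 1.0))
        if kind is not None:
            mean_r = round_for_report(mean * scale, kind)
            sd_r = round_for_report(sd * scale, kind)
            display = f"{mean_r:g} ± {sd_r:g}"
        else:
            mean_r, sd_r, display = mean, sd, f"{mean:g} ± {sd:g}"
        rows.append(
            {
                "site": site,
                "parameter": parameter,
                "condition": condition,
                "n": len(values),
                "mean": mean,
                "sd": sd,
                "mean_rounded": mean_r,
                "sd_rounded": sd_r,
                "display": display,
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
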