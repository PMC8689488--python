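"""Statistical chain for individual-level ROS percentages.

Proportions are variance-stabilised with the arcsine square-root transform,
assumptions are checked with Shapiro–Wilk (residual normality) and
Brown–Forsythe (homoscedasticity), and the treatment effect is tested with
a two-level nested ANOVA in which replicate containers are a random factor
nested within treatment.  Because the container factor is random, the
treatment mean square is tested over the among-container mean square, and
the Tukey post-hoc uses the same error term.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DesignError(ValueError):
    """The table cannot support the requested analysis."""


class DegenerateDataError(ValueError):
    """Data admit no meaningful test statistic (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# transform


def arcsine_sqrt(p):
    """Variance-stabilising transform arcsin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def back_transform(x):
    """Inverse of :func:`arcsine_sqrt`: sin(x)**2."""
    arr = np.asarray(x, dtype=np.float64)
    out = np.sin(arr) ** 2
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# table validation


def _validate_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    required = {"treatment", "container", response}
    missing = required - set(table.columns)
    if missing:
        raise DesignError(f"table is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table[response].to_numpy(dtype=np.float64))):
        raise DesignError(f"non-finite values in {response!r}")
    nesting = table.groupby("container")["treatment"].nunique()
    bad = nesting[nesting > 1]
    if len(bad):
        raise DesignError(
            f"containers assigned to multiple treatments: {list(bad.index)}; "
            "containers must be nested within treatment"
        )
    return table


# ---------------------------------------------------------------------------
# nested ANOVA


@dataclass(frozen=True)
class NestedAnovaResult:
    ss_treatment: float
    ss_container: float
    ss_residual: float
    df_treatment: int
    df_container: int
    df_residual: int
    ms_treatment: float
    ms_container: float
    ms_residual: float
    F: float
    p_value: float
    degenerate: bool = False
    balanced: bool = True

    @property
    def ss_total(self) -> float:
        return self.ss_treatment + self.ss_container + self.ss_residual

    def to_dict(self) -> dict:
        return {
            "ss_treatment": self.ss_treatment,
            "ss_container": self.ss_container,
            "ss_residual": self.ss_residual,
            "df_treatment": self.df_treatment,
            "df_container": self.df_container,
            "df_residual": self.df_residual,
            "ms_treatment": self.ms_treatment,
            "ms_container": self.ms_container,
            "ms_residual": self.ms_residual,
            "F": self.F,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "balanced": self.balanced,
        }


def nested_anova_components(
    y: np.ndarray, treatment: np.ndarray, container: np.ndarray
) -> NestedAnovaResult:
    """Nested ANOVA on coded arrays.

    ``treatment`` and ``container`` are integer codes; every container code
    must map to a single treatment code.  This is the computational core
    used by :func:`nested_anova` and by simulation loops.
    """
    y = np.asarray(y, dtype=np.float64)
    treatment = np.asarray(treatment)
    container = np.asarray(container)
    n = y.size

    cont_codes, cont_idx = np.unique(container, return_inverse=True)
    trt_codes, trt_idx = np.unique(treatment, return_inverse=True)
    a = len(trt_codes)
    c = len(cont_codes)
    if a < 2:
        raise DesignError("nested ANOVA requires at least two treatments")
    df_treatment = a - 1
    df_container = c - a
    df_residual = n - c
    if df_container < 1:
        raise DesignError(
            "no replicate containers within treatments (df_container = 0); "
            "use a one-way ANOVA instead"
        )

    grand = y.mean()
    # per-container sums and counts
    cont_n = np.bincount(cont_idx, minlength=c).astype(np.float64)
    cont_sum = np.bincount(cont_idx, weights=y, minlength=c)
    cont_mean = cont_sum / cont_n
    # treatment of each container
    cont_trt = np.full(c, -1, dtype=np.int64)
    cont_trt[cont_idx] = trt_idx
    trt_n = np.bincount(cont_trt, weights=cont_n, minlength=a)
    trt_sum = np.bincount(cont_trt, weights=cont_sum, minlength=a)
    trt_mean = trt_sum / trt_n

    ss_treatment = float(np.sum(trt_n * (trt_mean - grand) ** 2))
    ss_container = float(np.sum(cont_n * (cont_mean - trt_mean[cont_trt]) ** 2))
    ss_residual = float(np.sum((y - cont_mean[cont_idx]) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        raise DegenerateDataError("all observations are identical; ANOVA is undefined")

    ms_treatment = ss_treatment / df_treatment
    ms_container = ss_container / df_container
    ms_residual = ss_residual / df_residual if df_residual > 0 else float("nan")

    degenerate = False
    if ms_container == 0:
        if ms_treatment == 0:
            raise DegenerateDataError("zero variance at both treatment and container level")
        F = float("inf")
        p = 0.0
        degenerate = True
    else:
        F = ms_treatment / ms_container
        p = float(sps.f.sf(F, df_treatment, df_container))

    balanced = bool(
        np.all(cont_n == cont_n[0])
        and np.all(np.bincount(cont_trt, minlength=a) == np.bincount(cont_trt, minlength=a)[0])
    )
    return NestedAnovaResult(
        ss_treatment=ss_treatment,
        ss_container=ss_container,
        ss_residual=ss_residual,
        df_treatment=df_treatment,
        df_container=df_container,
        df_residual=df_residual,
        ms_treatment=ms_treatment,
        ms_container=ms_container,
        ms_residual=ms_residual,
        F=float(F),
        p_value=p,
        degenerate=degenerate,
        balanced=balanced,
    )


def nested_anova(table: pd.DataFrame, response: str = "ros_percent_t") -> NestedAnovaResult:
    """Nested one-way ANOVA: treatment fixed, container random nested within.

    The treatment F ratio is ``ms_treatment / ms_container`` with
    ``(df_treatment, df_container)`` degrees of freedom — the expected-mean-
    squares construction for a random nested factor.  A warning flag
    (``balanced=False``) marks unbalanced designs where the SS partition is
    only approximate.
    """
    table = _validate_table(table, response)
    return nested_anova_components(
        table[response].to_numpy(dtype=np.float64),
        table["treatment"].to_numpy(),
        table["container"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# assumption checks


@dataclass(frozen=True)
class AssumptionChecks:
    shapiro_stat: float
    shapiro_p: float
    brown_forsythe_stat: float
    brown_forsythe_p: float
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "brown_forsythe_stat": self.brown_forsythe_stat,
            "brown_forsythe_p": self.brown_forsythe_p,
            "warnings": list(self.warnings),
        }


def check_assumptions(table: pd.DataFrame, response: str = "ros_percent_t") -> AssumptionChecks:
    """Shapiro–Wilk on nested-model residuals; Brown–Forsythe across treatments.

    Residuals are deviations from container means (the finest model cell).
    Brown–Forsythe is Levene's test with group medians as centers.
    """
    table = _validate_table(table, response)
    y = table[response].to_numpy(dtype=np.float64)
    if y.size < 3:
        raise DesignError("need at least 3 observations for assumption checks")
    groups = [g.to_numpy(dtype=np.float64) for _, g in table.groupby("treatment")[response]]
    if len(groups) < 2:
        raise DesignError("need at least 2 treatments for Brown-Forsythe")

    warnings: list[str] = []
    resid = y - table.groupby("container")[response].transform("mean").to_numpy(dtype=np.float64)
    if np.allclose(resid, 0):
        warnings.append("residuals are identically zero; Shapiro-Wilk not meaningful")
        sw_stat, sw_p = float("nan"), float("nan")
    else:
        sw_stat, sw_p = sps.shapiro(resid)

    deviations = [np.abs(g - np.median(g)) for g in groups]
    if all(np.ptp(d) == 0 for d in deviations):
        flat = np.concatenate(deviations)
        if np.ptp(flat) == 0:
            # identical spread in every group: no evidence against homoscedasticity
            bf_stat, bf_p = 0.0, 1.0
        else:
            warnings.append("brown_forsythe_degenerate: zero within-group spread of deviations")
            bf_stat, bf_p = float("nan"), float("nan")
    else:
        bf_stat, bf_p = sps.levene(*groups, center="median")
    return AssumptionChecks(
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        brown_forsythe_stat=float(bf_stat),
        brown_forsythe_p=float(bf_p),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Tukey post-hoc


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise treatment comparisons on the analysis scale."""

    comparisons: pd.DataFrame  # group1, group2, mean_diff, q, p_adj
    ms_error: float
    df_error: int

    def p_adj(self, group1: str, group2: str) -> float:
        cmp = self.comparisons
        hit = cmp[
            ((cmp.group1 == group1) & (cmp.group2 == group2))
            | ((cmp.group1 == group2) & (cmp.group2 == group1))
        ]
        if hit.empty:
            raise KeyError(f"no comparison between {group1!r} and {group2!r}")
        return float(hit.p_adj.iloc[0])

    def to_frame(self) -> pd.DataFrame:
        return self.comparisons.copy()


def tukey_posthoc(
    table: pd.DataFrame,
    anova: NestedAnovaResult,
    response: str = "ros_percent_t",
) -> TukeyResult:
    """Tukey HSD over treatments with the nested error term.

    The error mean square is ``ms_container`` at ``df_container`` degrees of
    freedom, matching the ANOVA F construction.  Unequal treatment sizes use
    the Tukey–Kramer form (harmonic mean of the pair's individual counts).
    """
    table = _validate_table(table, response)
    means = table.groupby("treatment")[response].mean()
    counts = table.groupby("treatment")[response].count()
    k = len(means)
    if k < 2:
        raise DesignError("Tukey post-hoc requires at least 2 treatments")
    if anova.ms_container <= 0:
        raise DegenerateDataError("zero container mean square; Tukey q is undefined")
    rows = []
    for g1, g2 in itertools.combinations(sorted(means.index), 2):
        diff = float(means[g1] - means[g2])
        n_h = 2.0 / (1.0 / counts[g1] + 1.0 / counts[g2])
        se = math.sqrt(anova.ms_container / n_h)
        q = abs(diff) / se if se > 0 else float("inf")
        p = float(sps.studentized_range.sf(q, k, anova.df_container))
        rows.append(
            {"group1": g1, "group2": g2, "mean_diff": diff, "q": q, "p_adj": min(max(p, 0.0), 1.0)}
        )
    return TukeyResult(
        comparisons=pd.DataFrame(rows),
        ms_error=anova.ms_container,
        df_error=anova.df_container,
    )


# ---------------------------------------------------------------------------
# two-sample t


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance Student's t, two-sided."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DesignError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p_value=1.0)
        raise DegenerateDataError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=int(df), p_value=min(p, 1.0))


# ---------------------------------------------------------------------------
# one-call analysis used by the CLI


@dataclass(frozen=True)
class AnalysisReport:
    transform: str
    response: str
    anova: NestedAnovaResult
    assumptions: AssumptionChecks
    tukey: TukeyResult | None
    group_means_percent: pd.DataFrame

    def to_dict(self) -> dict:
        out = {
            "transform": self.transform,
            "response": self.response,
            "anova": self.anova.to_dict(),
            "assumptions": self.assumptions.to_dict(),
            "group_means_percent": self.group_means_percent.to_dict(orient="records"),
        }
        if self.tukey is not None:
            out["tukey"] = self.tukey.comparisons.to_dict(orient="records")
            out["tukey_error_term"] = {
                "ms_error": self.tukey.ms_error,
                "df_error": self.tukey.df_error,
            }
        return out


def analyze_experiment(
    table: pd.DataFrame,
    response: str = "ros_percent",
    transform: str = "arcsine-sqrt",
    posthoc: str = "tukey",
) -> AnalysisReport:
    """Transform, check assumptions, run the nested ANOVA and the post-hoc.

    ``response`` is a percent column in [0, 100]; with the default transform
    it is divided by 100 and arcsine-square-root transformed before any
    inference.  Group means are back-transformed to percent for reporting.
    """
    table = _validate_table(table, response)
    work = table.copy()
    if transform == "arcsine-sqrt":
        work["_y"] = arcsine_sqrt(work[response].to_numpy(dtype=np.float64) / 100.0)
    elif transform in (None, "none", "identity"):
        transform = "none"
        work["_y"] = work[response].to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    anova = nested_anova(work, "_y")
    assumptions = check_assumptions(work, "_y")
    tukey = None
    if posthoc == "tukey":
        tukey = tukey_posthoc(work, anova, "_y")
    elif posthoc not in (None, "none"):
        raise ValueError(f"unknown post-hoc {posthoc!r}")

    grouped = work.groupby("treatment")["_y"].agg(["mean", "count"]).reset_index()
    if transform == "arcsine-sqrt":
        grouped["mean_percent"] = 100.0 * back_transform(grouped.pop("mean").to_numpy())
    else:
        grouped["mean_percent"] = grouped.pop("mean")
    grouped = grouped.rename(columns={"count": "n"})[["treatment", "n", "mean_percent"]]
    return AnalysisReport(
        transform=transform,
        response=response,
        anova=anova,
        assumptions=assumptions,
        tukey=tukey,
        group_means_percent=grouped,
    )
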