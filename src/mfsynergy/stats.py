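"""Group-level inference on per-subject decomposition measures.

The experimental design is fully within-subject: every subject provides
one value of each measure (OMSE, a variance component, a covariance sum)
per feedback condition.  The tools here are the matching classics:

* paired and one-sample t-tests,
* one-way repeated-measures ANOVA with optional Greenhouse-Geisser
  sphericity correction,
* Fisher's LSD post hoc comparisons using the ANOVA error term,
* a per-trial linear trend test (learning effects).

Degenerate inputs (zero variance everywhere) are reported as flagged
degenerate results rather than raised, so that batch pipelines survive
pathological simulated datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.df, self.p))


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaReport:
    """One-way repeated-measures ANOVA report.

    ``df1``/``df2`` are the (possibly epsilon-corrected) degrees of
    freedom actually used for the p-value; ``gg_epsilon`` is 1.0 when no
    correction was requested.
    """

    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    ss_effect: float
    ss_error: float
    ms_error: float
    n_subjects: int
    conditions: tuple[str, ...]
    degenerate: bool = False
    posthoc: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "gg_epsilon": self.gg_epsilon,
            "degenerate": self.degenerate,
            "posthoc": [
                {"pair": f"{a} vs {b}", "t": t, "p": p} for (a, b, t, p) in self.posthoc
            ],
        }


def _as_table(table) -> pd.DataFrame:
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise ValueError("subject x condition table has missing cells")
    if df.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    return df.astype(float)


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test on per-subject values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    df = x.size - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(np.inf * np.sign(d.mean()), df, 0.0, degenerate=True)
    res = sps.ttest_rel(x, y)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def one_sample_t(x, mu: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of mean(x) against a reference value."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-d array of length >= 2")
    df = x.size - 1
    if x.std(ddof=1) == 0.0:
        if x[0] == mu:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(np.inf * np.sign(x[0] - mu), df, 0.0, degenerate=True)
    res = sps.ttest_1samp(x, mu)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the condition covariance matrix."""
    k = values.shape[1]
    cov = np.cov(values, rowvar=False, ddof=1)
    # double-center the covariance matrix
    row = cov.mean(axis=0, keepdims=True)
    dc = cov - row - row.T + cov.mean()
    tr = np.trace(dc)
    denom = (k - 1) * np.sum(dc * dc)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_anova(table, correction: str = "none") -> AnovaReport:
    """One-way within-subject (repeated-measures) ANOVA.

    Parameters
    ----------
    table : DataFrame or 2-d array, subjects x conditions
        One scalar measure per cell; no missing cells.
    correction : {"none", "greenhouse_geisser"}
        With the Greenhouse-Geisser correction both degrees of freedom are
        scaled by the sphericity estimate epsilon before computing p.
    """
    if correction not in ("none", "greenhouse_geisser"):
        raise ValueError(f"unknown correction {correction!r}")
    df_tab = _as_table(table)
    y = df_tab.to_numpy()
    n, k = y.shape

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_cond = float(n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_cond - ss_subj, 0.0)

    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_error = ss_error / df2

    if ss_error <= 1e-12 * max(ss_total, 1.0):
        # no residual variance: identical condition profiles across subjects
        f_stat = 0.0 if ss_cond <= 1e-12 * max(ss_total, 1.0) else np.inf
        return AnovaReport(
            F=f_stat,
            df1=float(df1),
            df2=float(df2),
            p=1.0 if f_stat == 0.0 else 0.0,
            gg_epsilon=1.0,
            ss_effect=ss_cond,
            ss_error=ss_error,
            ms_error=ms_error,
            n_subjects=n,
            conditions=tuple(str(c) for c in df_tab.columns),
            degenerate=True,
        )

    f_stat = (ss_cond / df1) / ms_error
    eps = 1.0
    if correction == "greenhouse_geisser":
        eps = _gg_epsilon(y)
    p = float(sps.f.sf(f_stat, df1 * eps, df2 * eps))

    return AnovaReport(
        F=float(f_stat),
        df1=df1 * eps,
        df2=df2 * eps,
        p=p,
        gg_epsilon=eps,
        ss_effect=ss_cond,
        ss_error=ss_error,
        ms_error=ms_error,
        n_subjects=n,
        conditions=tuple(str(c) for c in df_tab.columns),
    )


def fisher_lsd(table, anova: AnovaReport) -> list[tuple[str, str, float, float]]:
    """Fisher's least-significant-difference pairwise comparisons.

    Each pair of conditions is compared with a t-statistic using the
    pooled ANOVA error term, ``t = (m_a - m_b) / sqrt(2 MSE / n)``, on the
    ANOVA error degrees of freedom; p-values are unadjusted, as the LSD
    convention requires (the omnibus ANOVA is the gatekeeper).

    Returns a list of (label_a, label_b, t, p).
    """
    df_tab = _as_table(table)
    if tuple(str(c) for c in df_tab.columns) != anova.conditions:
        raise ValueError("table conditions do not match the ANOVA report")
    n = df_tab.shape[0]
    means = df_tab.mean(axis=0)
    df_error = (len(anova.conditions) - 1) * (n - 1)
    out = []
    for ia, a in enumerate(anova.conditions):
        for b in anova.conditions[ia + 1 :]:
            diff = float(means[a] - means[b])
            if anova.ms_error <= 0:
                t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / np.sqrt(2.0 * anova.ms_error / n)
                p = float(2.0 * sps.t.sf(abs(t), df_error))
            out.append((a, b, float(t), p))
    return out


def rm_anova_with_posthoc(table, correction: str = "none") -> AnovaReport:
    """Convenience wrapper: omnibus ANOVA plus Fisher LSD pairs attached."""
    report = rm_anova(table, correction=correction)
    pairs = fisher_lsd(table, report)
    return AnovaReport(
        **{**report.__dict__, "posthoc": tuple(pairs)},
    )


def trial_trend(values) -> TrendResult:
    """Linear trend of a per-trial scalar across trial number.

    Ordinary least squares of the value on the 1-based trial index, with
    the F-test of the slope (F = t^2 on 1 and n-2 degrees of freedom).
    Used to screen for learning or fatigue effects across trials.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need at least 3 trials")
    x = np.arange(1, y.size + 1, dtype=float)
    df2 = y.size - 2
    if np.allclose(y, y[0]):
        return TrendResult(0.0, float(y[0]), 0.0, 1, df2, 1.0, degenerate=True)
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, np.abs(y).max())):
        return TrendResult(
            float(res.slope), float(res.intercept), np.inf, 1, df2, 0.0, degenerate=True
        )
    t = res.slope / res.stderr
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        F=float(t * t),
        df1=1,
        df2=df2,
        p=float(res.pvalue),
    )
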