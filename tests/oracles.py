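"""Independent naive reference implementations used only by the tests.

Everything here is deliberately written with explicit Python loops and
textbook formulas, with no shared code or decomposition shortcuts from the
package under test.
"""

from __future__ import annotations

import math

import numpy as np


def naive_vf(forces) -> list[list[float]]:
    """Row sums of each trial's T x 4 force matrix."""
    out = []
    for trial in forces:
        out.append([sum(row) for row in trial])
    return out


def naive_omse(forces, f_t: float) -> float:
    """Mean over trials of the time-averaged squared VF error."""
    vf = naive_vf(forces)
    per_trial = []
    for trial in vf:
        per_trial.append(sum((f_t - v) ** 2 for v in trial) / len(trial))
    return sum(per_trial) / len(per_trial)


def naive_hvd(forces, f_t: float) -> dict:
    """Every decomposition quantity via explicit loops (population norm)."""
    forces = [np.asarray(tr, dtype=float) for tr in forces]
    n_trials = len(forces)
    n_samples = forces[0].shape[0]
    vf = [[sum(row) for row in tr] for tr in forces]

    trial_means = [sum(v) / n_samples for v in vf]
    m = sum(trial_means) / n_trials
    bias = f_t - m

    online_var_vf = 0.0
    for i in range(n_trials):
        mu = trial_means[i]
        online_var_vf += sum((v - mu) ** 2 for v in vf[i]) / n_samples
    online_var_vf /= n_trials

    offline_var_vf = sum((mu - m) ** 2 for mu in trial_means) / n_trials

    # finger-level within-trial covariance, averaged over trials
    online_cov = np.zeros((4, 4))
    for tr in forces:
        mu = tr.mean(axis=0)
        c = np.zeros((4, 4))
        for t in range(tr.shape[0]):
            d = tr[t] - mu
            for a in range(4):
                for b in range(4):
                    c[a, b] += d[a] * d[b]
        online_cov += c / tr.shape[0]
    online_cov /= n_trials

    finger_trial_means = np.array([tr.mean(axis=0) for tr in forces])
    grand = finger_trial_means.mean(axis=0)
    offline_cov = np.zeros((4, 4))
    for i in range(n_trials):
        d = finger_trial_means[i] - grand
        for a in range(4):
            for b in range(4):
                offline_cov[a, b] += d[a] * d[b]
    offline_cov /= n_trials

    def covsum(c):
        return float(sum(c[a, b] for a in range(4) for b in range(4) if a != b))

    u = np.ones(4) / 2.0
    on_rel = float(u @ online_cov @ u)
    off_rel = float(u @ offline_cov @ u)

    return {
        "omse": naive_omse(forces, f_t),
        "grand_mean": m,
        "bias": bias,
        "systematic_error": bias**2,
        "online_var_vf": online_var_vf,
        "offline_var_vf": offline_var_vf,
        "online_finger_vars": np.diag(online_cov).copy(),
        "offline_finger_vars": np.diag(offline_cov).copy(),
        "online_cov_sum": covsum(online_cov),
        "offline_cov_sum": covsum(offline_cov),
        "online_task_relevant": on_rel,
        "online_task_irrelevant": float(np.trace(online_cov)) - on_rel,
        "offline_task_relevant": off_rel,
        "offline_task_irrelevant": float(np.trace(offline_cov)) - off_rel,
    }


def naive_paired_t(x, y) -> tuple[float, float]:
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), two-sided p."""
    from scipy.stats import t as tdist

    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def naive_one_sample_t(x, mu) -> tuple[float, float]:
    from scipy.stats import t as tdist

    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    t = (mean - mu) / (sd / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def naive_rm_anova(y) -> dict:
    """One-way within-subject ANOVA by the sums-of-squares partition."""
    from scipy.stats import f as fdist

    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_cond = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = k * sum((y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    return {
        "F": F,
        "df1": df1,
        "df2": df2,
        "p": float(fdist.sf(F, df1, df2)),
        "ms_error": ss_err / df2,
    }


def naive_lsd(y, labels) -> list[tuple[str, str, float, float]]:
    """Fisher LSD pairwise t-tests via the explicit pooled error term."""
    from scipy.stats import t as tdist

    y = np.asarray(y, dtype=float)
    n, k = y.shape
    ms_error = naive_rm_anova(y)["ms_error"]
    df_err = (k - 1) * (n - 1)
    out = []
    for a in range(k):
        for b in range(a + 1, k):
            t = (y[:, a].mean() - y[:, b].mean()) / math.sqrt(2 * ms_error / n)
            p = 2 * tdist.sf(abs(t), df_err)
            out.append((labels[a], labels[b], t, p))
    return out


def naive_ols_trend(y) -> dict:
    """Closed-form simple OLS of y on the 1-based index, with slope F-test."""
    from scipy.stats import f as fdist

    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(1, n + 1, dtype=float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sse = (resid**2).sum()
    ssr = slope * sxy
    F = ssr / (sse / (n - 2))
    return {
        "slope": slope,
        "intercept": intercept,
        "F": F,
        "p": float(fdist.sf(F, 1, n - 2)),
    }
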