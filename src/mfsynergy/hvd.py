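"""Hierarchical variability decomposition (HVD) of constant-force performance.

The overall mean-squared error (OMSE) of the virtual-finger (VF) force
around the target f_T partitions exactly into three components at the VF
level::

    OMSE = online variance + offline variance + systematic error

* **online variance** -- moment-to-moment variance within a trial,
  averaged over trials ("consistency"),
* **offline variance** -- variance of the trial means across trials
  ("repeatability"),
* **systematic error** -- squared bias (f_T - grand mean)^2 ("accuracy").

Each VF-level variance further decomposes at the individual-finger (IF)
level into the sum of the four finger-force variances plus the summed
between-finger covariance (the synergy index: negative = error
compensation, positive = error amplification), and the summed finger
variance splits into a task-relevant and a task-irrelevant part along the
uncontrolled-manifold (UCM) directions of the force-sum task.

All variances and covariances use the population (divide-by-N) convention;
the additive identities above are exact only under a consistent
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConditionSet

N_FINGERS = 4

# Task Jacobian of the force-sum task: d(VF)/d(f_i) = 1 for every finger.
TASK_JACOBIAN = np.ones(N_FINGERS)


@dataclass(frozen=True)
class TrialComponents:
    """Three-level decomposition of the VF force signals.

    Every trial's VF force y_i(t) is written as ``X_i(t) + E_i + m``:
    the grand mean m over all samples of all trials, the trial-mean
    deviation E_i, and the demeaned within-trial signal X_i(t).
    """

    m: float
    E: np.ndarray          # (n_trials,), mean exactly 0 up to float error
    X: np.ndarray          # (n_trials, T), each row mean 0


def decompose_components(cs: ConditionSet) -> TrialComponents:
    """Split the VF signals into grand mean, trial deviations, and residuals.

    Reconstruction is exact: ``X[i] + E[i] + m`` equals trial i's VF force.
    """
    vf = cs.vf_array()                       # (n_trials, T)
    trial_means = vf.mean(axis=1)
    m = float(trial_means.mean())
    E = trial_means - m
    X = vf - trial_means[:, None]
    return TrialComponents(m=m, E=E, X=X)


def compute_omse(cs: ConditionSet) -> float:
    """Overall mean-squared error of the VF force around the target.

    Mean over trials of the time-averaged squared deviation
    (f_T - y_i(t))^2; the discrete time-average is the mean over samples.
    """
    vf = cs.vf_array()
    return float(((cs.target_force - vf) ** 2).mean(axis=1).mean())


def ucm_split(finger_cov: np.ndarray) -> tuple[float, float]:
    """Split summed finger variance along / against the task direction.

    With task Jacobian J = (1, 1, 1, 1) and unit vector u = J/||J||, the
    task-relevant variance is u' Sigma u -- the per-dimension variance
    along the force-sum direction, which equals Var(VF)/4 -- and the
    task-irrelevant variance is the rest of the trace, i.e. the variance
    inside the null space of J (finger patterns that leave the VF force
    unchanged).

    Parameters
    ----------
    finger_cov : ndarray, shape (4, 4)
        Symmetric positive-semidefinite finger-force covariance matrix.

    Returns
    -------
    (task_relevant, task_irrelevant) : tuple of float
    """
    sigma = np.asarray(finger_cov, dtype=float)
    if sigma.shape != (N_FINGERS, N_FINGERS):
        raise ValueError(f"expected a 4x4 matrix, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, rtol=1e-8, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    u = TASK_JACOBIAN / np.linalg.norm(TASK_JACOBIAN)
    task_relevant = float(u @ sigma @ u)
    task_irrelevant = float(np.trace(sigma) - task_relevant)
    return task_relevant, task_irrelevant


@dataclass(frozen=True)
class HVDResults:
    """Full variance ledger of one subject x condition.

    All quantities are in N^2 except ``grand_mean`` and ``bias`` (N).
    ``bias`` is f_T minus the grand-mean VF force, so a positive bias is an
    undershoot.  Covariance sums count ordered pairs i != j (twice the
    upper triangle), which makes ``Var(VF) = sum(finger vars) + cov sum``
    exact.
    """

    subject_id: str
    condition: str
    target_force: float
    n_trials: int
    n_samples: int

    omse: float
    grand_mean: float
    bias: float
    systematic_error: float
    online_var_vf: float
    offline_var_vf: float
    total_var_vf: float

    online_finger_vars: np.ndarray      # (4,)
    online_cov_sum: float
    offline_finger_vars: np.ndarray     # (4,)
    offline_cov_sum: float
    online_cov_matrix: np.ndarray = field(repr=False, default=None)
    offline_cov_matrix: np.ndarray = field(repr=False, default=None)

    online_task_relevant: float = 0.0
    online_task_irrelevant: float = 0.0
    offline_task_relevant: float = 0.0
    offline_task_irrelevant: float = 0.0

    def to_dict(self) -> dict:
        d = {
            "subject": self.subject_id,
            "condition": self.condition,
            "target_force": self.target_force,
            "n_trials": self.n_trials,
            "n_samples": self.n_samples,
            "omse": self.omse,
            "grand_mean": self.grand_mean,
            "bias": self.bias,
            "systematic_error": self.systematic_error,
            "online_var_vf": self.online_var_vf,
            "offline_var_vf": self.offline_var_vf,
            "total_var_vf": self.total_var_vf,
            "online_cov_sum": self.online_cov_sum,
            "offline_cov_sum": self.offline_cov_sum,
            "online_task_relevant": self.online_task_relevant,
            "online_task_irrelevant": self.online_task_irrelevant,
            "offline_task_relevant": self.offline_task_relevant,
            "offline_task_irrelevant": self.offline_task_irrelevant,
        }
        for k, name in enumerate(("index", "middle", "ring", "little")):
            d[f"online_var_{name}"] = float(self.online_finger_vars[k])
            d[f"offline_var_{name}"] = float(self.offline_finger_vars[k])
        return d

    def summary(self) -> str:
        """Plain-text summary table of the decomposition."""
        lines = [
            "Hierarchical variability decomposition",
            "=" * 54,
            f"subject: {self.subject_id:<12s} condition: {self.condition}",
            f"trials:  {self.n_trials:<12d} samples/trial: {self.n_samples}",
            f"target force       {self.target_force:10.4f} N",
            f"grand mean VF      {self.grand_mean:10.4f} N"
            f"   bias {self.bias:+.4f} N",
            "-" * 54,
            f"OMSE               {self.omse:10.6f} N^2",
            f"  online variance  {self.online_var_vf:10.6f} N^2  (consistency)",
            f"  offline variance {self.offline_var_vf:10.6f} N^2  (repeatability)",
            f"  systematic error {self.systematic_error:10.6f} N^2  (accuracy)",
            "-" * 54,
            "finger level (index, middle, ring, little):",
            "  online vars   "
            + " ".join(f"{v:9.6f}" for v in self.online_finger_vars),
            f"  online cov sum   {self.online_cov_sum:+10.6f} N^2",
            "  offline vars  "
            + " ".join(f"{v:9.6f}" for v in self.offline_finger_vars),
            f"  offline cov sum  {self.offline_cov_sum:+10.6f} N^2",
            "-" * 54,
            "uncontrolled-manifold split (task-relevant / irrelevant):",
            f"  online   {self.online_task_relevant:10.6f} / "
            f"{self.online_task_irrelevant:10.6f} N^2",
            f"  offline  {self.offline_task_relevant:10.6f} / "
            f"{self.offline_task_irrelevant:10.6f} N^2",
        ]
        return "\n".join(lines)

    def plot_components(self, ax=None):
        """Bar chart of the three OMSE components plus the covariance sums."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        labels = ["online", "offline", "systematic", "cov on", "cov off"]
        values = [
            self.online_var_vf,
            self.offline_var_vf,
            self.systematic_error,
            self.online_cov_sum,
            self.offline_cov_sum,
        ]
        ax.bar(labels, values, color=["C0", "C1", "C2", "C3", "C3"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel(r"N$^2$")
        ax.set_title(f"{self.subject_id} / {self.condition}: OMSE = {self.omse:.4g}")
        return ax


class HierarchicalVariability:
    """Model object computing the HVD of one subject x condition.

    Parameters
    ----------
    data : ConditionSet
        Windowed trials of one subject under one feedback condition.

    Examples
    --------
    >>> model = HierarchicalVariability(condition_set)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: ConditionSet):
        self.data = data

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject: str,
        condition: str,
        target_force: float = 18.0,
        sample_rate: float | None = None,
    ) -> "HierarchicalVariability":
        """Build the model from a long-format trial table (see `mfsynergy.io`)."""
        from .io import CSV_COLUMNS, load_trials
        import io as _io

        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = df[(df["subject"].astype(str) == subject) & (df["condition"] == condition)]
        if sub.empty:
            raise ValueError(f"no rows for subject {subject!r}, condition {condition!r}")
        buf = _io.StringIO()
        sub.to_csv(buf, index=False)
        buf.seek(0)
        (cs,) = load_trials(buf, target_force=target_force, sample_rate=sample_rate)
        return cls(cs)

    def fit(self) -> HVDResults:
        """Compute the full variance ledger."""
        return hvd(self.data)


def hvd(cs: ConditionSet) -> HVDResults:
    """Hierarchical variability decomposition of one ConditionSet.

    See :class:`HVDResults` for the fields and conventions.
    """
    forces = cs.force_array()                    # (n_trials, T, 4)
    n_trials, n_samples, _ = forces.shape
    f_t = cs.target_force

    comp = decompose_components(cs)
    m = comp.m
    bias = f_t - m
    systematic_error = bias * bias

    vf = forces.sum(axis=2)
    online_var_vf = float(vf.var(axis=1).mean())         # population, per trial
    offline_var_vf = float(vf.mean(axis=1).var())
    omse = compute_omse(cs)

    # Finger level: within-trial population covariance averaged over trials.
    centered = forces - forces.mean(axis=1, keepdims=True)
    online_cov = np.einsum("nti,ntj->ij", centered, centered) / (n_trials * n_samples)
    # Between-trial covariance of per-finger trial means.
    trial_means = forces.mean(axis=1)                    # (n_trials, 4)
    dm = trial_means - trial_means.mean(axis=0)
    offline_cov = dm.T @ dm / n_trials

    online_finger_vars = np.diag(online_cov).copy()
    offline_finger_vars = np.diag(offline_cov).copy()
    online_cov_sum = float(online_cov.sum() - online_finger_vars.sum())
    offline_cov_sum = float(offline_cov.sum() - offline_finger_vars.sum())

    on_rel, on_irr = ucm_split(online_cov)
    off_rel, off_irr = ucm_split(offline_cov)

    return HVDResults(
        subject_id=cs.subject_id,
        condition=cs.condition,
        target_force=f_t,
        n_trials=n_trials,
        n_samples=n_samples,
        omse=omse,
        grand_mean=m,
        bias=bias,
        systematic_error=systematic_error,
        online_var_vf=online_var_vf,
        offline_var_vf=offline_var_vf,
        total_var_vf=online_var_vf + offline_var_vf,
        online_finger_vars=online_finger_vars,
        online_cov_sum=online_cov_sum,
        offline_finger_vars=offline_finger_vars,
        offline_cov_sum=offline_cov_sum,
        online_cov_matrix=online_cov,
        offline_cov_matrix=offline_cov,
        online_task_relevant=on_rel,
        online_task_irrelevant=on_irr,
        offline_task_relevant=off_rel,
        offline_task_irrelevant=off_irr,
    )


def hvd_table(results: list[HVDResults]) -> pd.DataFrame:
    """Flatten HVDResults into one row per subject x condition."""
    return pd.DataFrame([r.to_dict() for r in results])
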