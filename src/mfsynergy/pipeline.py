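"""End-to-end analysis pipeline: simulate/load -> window -> decompose ->
fuse -> group statistics, with a validated, reproducible report bundle.

The pipeline mirrors the analysis flow of the constant-force experiment:
trials are cut to the steady-state window, each subject x condition is
decomposed with the hierarchical variability model, the F and I conditions
of each subject are fused to predict the FI condition, and the per-subject
measures go into repeated-measures ANOVAs with Fisher LSD post hocs,
a paired t-test of predicted vs observed OMSE_FI, one-sample t-tests of
the covariance sums against zero, and per-trial linear trend tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fusion import CueFusion, FusionResults, fusion_table
from .hvd import HierarchicalVariability, HVDResults, hvd_table
from .io import ConditionSet, load_trials, window_condition_set
from .simulate import SynthConfig, generate_cohort
from .stats import one_sample_t, paired_t, rm_anova_with_posthoc, trial_trend

logger = logging.getLogger("mfsynergy")

#: per-subject measures sent to the repeated-measures ANOVA
ANOVA_MEASURES = (
    "omse",
    "total_var_vf",
    "online_var_vf",
    "offline_var_vf",
    "systematic_error",
    "online_cov_sum",
    "offline_cov_sum",
    "online_task_relevant",
    "online_task_irrelevant",
    "offline_task_relevant",
    "offline_task_irrelevant",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a long-format trial CSV) or
    ``synth_config`` must be provided.
    """

    input_path: str | None = None
    synth_config: SynthConfig | None = None
    window_start_s: float = 6.0
    window_end_s: float = 17.0
    target_force: float = 18.0
    variance_mode: str = "total"
    anova_correction: str = "greenhouse_geisser"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synth_config is None):
            raise ValueError("provide exactly one of input_path or synth_config")
        if not self.window_start_s < self.window_end_s:
            raise ValueError("invalid analysis window")
        if not self.target_force > 0:
            raise ValueError("target_force must be positive")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "synth_config": None
            if self.synth_config is None
            else self.synth_config.to_dict(),
            "window_start_s": self.window_start_s,
            "window_end_s": self.window_end_s,
            "target_force": self.target_force,
            "variance_mode": self.variance_mode,
            "anova_correction": self.anova_correction,
        }


@dataclass
class ReportBundle:
    """All outputs of one pipeline run."""

    config: RunConfig
    hvd_results: list[HVDResults]
    fusion_results: list[FusionResults]
    anova: dict = field(default_factory=dict)           # measure -> AnovaReport
    paired_pred_obs: dict = field(default_factory=dict)  # measure -> TTestResult
    cov_vs_zero: dict = field(default_factory=dict)      # (timescale, cond) -> TTest
    trends: dict = field(default_factory=dict)           # (stat, cond) -> TrendResult
    manifest: dict = field(default_factory=dict)

    @property
    def hvd_frame(self) -> pd.DataFrame:
        return hvd_table(self.hvd_results)

    @property
    def fusion_frame(self) -> pd.DataFrame:
        return fusion_table(self.fusion_results)

    def measure_table(self, measure: str) -> pd.DataFrame:
        """Wide subjects x conditions table of one decomposition measure."""
        return self.hvd_frame.pivot(index="subject", columns="condition", values=measure)[
            ["F", "I", "FI"]
        ]

    def stats_dict(self) -> dict:
        return {
            "anova": {m: r.to_dict() for m, r in self.anova.items()},
            "paired_pred_obs": {
                m: {"t": r.t, "df": r.df, "p": r.p} for m, r in self.paired_pred_obs.items()
            },
            "cov_vs_zero": {
                f"{scale}_{cond}": {"t": r.t, "df": r.df, "p": r.p}
                for (scale, cond), r in self.cov_vs_zero.items()
            },
            "trends": {
                f"{stat}_{cond}": {"slope": r.slope, "F": r.F, "p": r.p}
                for (stat, cond), r in self.trends.items()
            },
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "hvd": out / "hvd.csv",
            "fusion": out / "fusion.csv",
            "stats": out / "stats.json",
            "manifest": out / "manifest.json",
        }
        self.hvd_frame.to_csv(paths["hvd"], index=False)
        self.fusion_frame.to_csv(paths["fusion"], index=False)
        paths["stats"].write_text(json.dumps(self.stats_dict(), indent=2))
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2))
        return paths


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute the full analysis and return a validated report bundle."""
    t_start = _stage("input")
    try:
        if cfg.synth_config is not None:
            sets, _truth = generate_cohort(cfg.synth_config)
        else:
            sets = load_trials(cfg.input_path, target_force=cfg.target_force)
    except Exception:
        logger.exception("pipeline failed in stage 'input'")
        raise
    logger.info("input: %d condition sets (%.2fs)", len(sets), time.perf_counter() - t_start)

    _stage("window")
    windowed = [
        window_condition_set(cs, cfg.window_start_s, cfg.window_end_s) for cs in sets
    ]

    _stage("decompose")
    hvd_results = [HierarchicalVariability(cs).fit() for cs in windowed]
    by_subject: dict[str, dict[str, HVDResults]] = {}
    for r in hvd_results:
        by_subject.setdefault(r.subject_id, {})[r.condition] = r

    _stage("fuse")
    fusion_results = [
        CueFusion(conds, variance_mode=cfg.variance_mode).fit()
        for conds in by_subject.values()
        if set(conds) >= {"F", "I", "FI"}
    ]

    bundle = ReportBundle(
        config=cfg, hvd_results=hvd_results, fusion_results=fusion_results
    )

    _stage("stats")
    n_subjects = len(by_subject)
    have_all = len(fusion_results) == n_subjects and n_subjects >= 2
    if have_all:
        hframe = bundle.hvd_frame
        for measure in ANOVA_MEASURES:
            table = bundle.measure_table(measure)
            bundle.anova[measure] = rm_anova_with_posthoc(
                table, correction=cfg.anova_correction
            )
        fframe = bundle.fusion_frame
        for pred, obs, name in (
            ("omse_fi_pred", "omse_fi_obs", "omse_fi"),
            ("sigma_fi2_pred", "sigma_fi2_obs", "sigma_fi2"),
            ("b_fi_pred", "b_fi_obs", "b_fi"),
        ):
            bundle.paired_pred_obs[name] = paired_t(
                fframe[pred].to_numpy(), fframe[obs].to_numpy()
            )
        for scale in ("online", "offline"):
            for cond in ("F", "I", "FI"):
                vals = hframe.loc[hframe["condition"] == cond, f"{scale}_cov_sum"]
                bundle.cov_vs_zero[(scale, cond)] = one_sample_t(vals.to_numpy(), 0.0)

    # learning-effect screen: per-trial VF mean and variance, averaged over
    # subjects within each condition, regressed on trial number
    trends: dict[tuple[str, str], object] = {}
    for cond in ("F", "I", "FI"):
        cond_sets = [cs for cs in windowed if cs.condition == cond]
        if not cond_sets:
            continue
        n_trials = min(cs.n_trials for cs in cond_sets)
        vf_means = np.mean(
            [cs.vf_array()[:n_trials].mean(axis=1) for cs in cond_sets], axis=0
        )
        vf_vars = np.mean(
            [cs.vf_array()[:n_trials].var(axis=1) for cs in cond_sets], axis=0
        )
        if n_trials >= 3:
            trends[("mean", cond)] = trial_trend(vf_means)
            trends[("variance", cond)] = trial_trend(vf_vars)
    bundle.trends = trends

    bundle.manifest = _manifest(cfg)
    violations = validate_results(bundle)
    if violations:
        logger.warning("validation found %d violations", len(violations))
    if cfg.output_dir is not None:
        bundle.write(cfg.output_dir)
    return bundle


def _manifest(cfg: RunConfig) -> dict:
    import scipy

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    return {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": None if cfg.synth_config is None else cfg.synth_config.seed,
        "versions": {
            "mfsynergy": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def validate_results(bundle: ReportBundle, rtol: float = 1e-8) -> list[str]:
    """Machine-check every additivity/consistency invariant of a run.

    Returns a list of human-readable violation descriptions; an empty list
    means the bundle is internally consistent.
    """
    bad: list[str] = []

    def _close(a, b, scale) -> bool:
        return abs(a - b) <= rtol * max(abs(scale), 1e-12)

    for r in bundle.hvd_results:
        key = f"{r.subject_id}/{r.condition}"
        if not _close(r.omse, r.online_var_vf + r.offline_var_vf + r.systematic_error, r.omse):
            bad.append(f"{key}: OMSE != online + offline + systematic")
        if not _close(r.total_var_vf, r.online_var_vf + r.offline_var_vf, r.total_var_vf):
            bad.append(f"{key}: total VF variance != online + offline")
        for scale_name, var_vf, fvars, cov_sum, rel, irr in (
            ("online", r.online_var_vf, r.online_finger_vars, r.online_cov_sum,
             r.online_task_relevant, r.online_task_irrelevant),
            ("offline", r.offline_var_vf, r.offline_finger_vars, r.offline_cov_sum,
             r.offline_task_relevant, r.offline_task_irrelevant),
        ):
            if not _close(var_vf, fvars.sum() + cov_sum, max(var_vf, abs(cov_sum))):
                bad.append(f"{key}: {scale_name} VF variance != finger vars + cov sum")
            if not _close(rel + irr, fvars.sum(), fvars.sum()):
                bad.append(f"{key}: {scale_name} UCM split != finger variance sum")
            if not _close(rel, var_vf / 4.0, max(var_vf, 1e-12)):
                bad.append(f"{key}: {scale_name} task-relevant != Var(VF)/4")
        if min(r.omse, r.online_var_vf, r.offline_var_vf, r.systematic_error) < 0:
            bad.append(f"{key}: negative variance component")

    for f in bundle.fusion_results:
        key = f.subject_id
        p = f.prediction
        if not _close(p.wF + p.wI, 1.0, 1.0):
            bad.append(f"{key}: fusion weights do not sum to 1")
        if not (0.0 < p.wF < 1.0):
            bad.append(f"{key}: fusion weight outside (0, 1)")
        if p.sigma_fi2 > min(f.f_summary.variance, f.i_summary.variance) * (1 + rtol):
            bad.append(f"{key}: fused variance exceeds a single-cue variance")
        if not _close(p.omse_fi_pred, p.sigma_fi2 + p.b_fi ** 2, p.omse_fi_pred):
            bad.append(f"{key}: predicted OMSE != fused variance + fused bias^2")

    for measure, rep in bundle.anova.items():
        if not (0.0 <= rep.p <= 1.0):
            bad.append(f"anova[{measure}]: p outside [0, 1]")
        if rep.F < 0:
            bad.append(f"anova[{measure}]: negative F")
    return bad
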