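"""Gaussian cue fusion for the two components of auditory feedback.

The observer holds two noisy estimates of the same VF force: one signalled
by tone frequency (F) and one by tone intensity (I).  Under the standard
maximum-likelihood / flat-prior Bayesian model the combined estimate is an
inverse-variance weighted sum::

    w_F = sigma_I^2 / (sigma_F^2 + sigma_I^2),   w_I = 1 - w_F
    s_FI = w_F s_F + w_I s_I
    sigma_FI^2 = sigma_F^2 sigma_I^2 / (sigma_F^2 + sigma_I^2)
    b_FI = w_F b_F + w_I b_I

and the predicted overall mean-squared error in the combined condition is
``OMSE_FI = sigma_FI^2 + b_FI^2``.  The fused variance never exceeds the
smaller single-cue variance -- the fusion benefit that the combined
feedback condition is expected to show behaviorally.

Per-condition variances and biases are read off the HVD results: the VF
variance of a condition is attributed to the estimation variance of its
cue, and the bias is the target force minus the grand-mean VF force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .hvd import HVDResults

VarianceMode = Literal["total", "online_only"]


@dataclass(frozen=True)
class CueSummary:
    """Estimation variance and bias attributed to one feedback cue."""

    variance: float    # N^2
    bias: float        # N

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("cue variance must be positive")
        if not np.isfinite(self.bias):
            raise ValueError("cue bias must be finite")


def fusion_weights(sF2: float, sI2: float) -> tuple[float, float]:
    """Inverse-variance weights (wF, wI); the less noisy cue weighs more."""
    if not (sF2 > 0 and sI2 > 0):
        raise ValueError("variances must be positive")
    total = sF2 + sI2
    return sI2 / total, sF2 / total


def fused_variance(sF2: float, sI2: float) -> float:
    """Variance of the fused estimate; never exceeds min(sF2, sI2)."""
    if not (sF2 > 0 and sI2 > 0):
        raise ValueError("variances must be positive")
    return sF2 * sI2 / (sF2 + sI2)


def fused_bias(bF: float, bI: float, weights: tuple[float, float]) -> float:
    """Bias of the fused estimate: the weighted average of the cue biases."""
    wF, wI = weights
    return wF * bF + wI * bI


def fused_estimate(sF_hat: float, sI_hat: float, weights: tuple[float, float]) -> float:
    """Fused point estimate: the weighted sum of the two cue estimates."""
    wF, wI = weights
    return wF * sF_hat + wI * sI_hat


@dataclass(frozen=True)
class BayesPrediction:
    """Fusion weights and the predicted combined-condition statistics."""

    wF: float
    wI: float
    sigma_fi2: float
    b_fi: float
    omse_fi_pred: float


def predict_omse_fi(f_summary: CueSummary, i_summary: CueSummary) -> BayesPrediction:
    """Predict the combined condition from the two single-cue summaries."""
    weights = fusion_weights(f_summary.variance, i_summary.variance)
    s2 = fused_variance(f_summary.variance, i_summary.variance)
    b = fused_bias(f_summary.bias, i_summary.bias, weights)
    return BayesPrediction(
        wF=weights[0],
        wI=weights[1],
        sigma_fi2=s2,
        b_fi=b,
        omse_fi_pred=s2 + b * b,
    )


def cue_summaries_from_hvd(
    results: Mapping[str, HVDResults],
    variance_mode: VarianceMode = "total",
) -> tuple[CueSummary, CueSummary, HVDResults]:
    """Extract the F and I cue summaries (and the observed FI result).

    ``variance_mode`` selects which timescales of VF variance count as
    estimation variance: the default ``"total"`` uses online + offline;
    ``"online_only"`` restricts to the within-trial part.
    """
    missing = {"F", "I", "FI"} - set(results)
    if missing:
        raise ValueError(f"missing conditions: {sorted(missing)}")

    def _variance(r: HVDResults) -> float:
        if variance_mode == "total":
            return r.total_var_vf
        if variance_mode == "online_only":
            return r.online_var_vf
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    f = CueSummary(variance=_variance(results["F"]), bias=results["F"].bias)
    i = CueSummary(variance=_variance(results["I"]), bias=results["I"].bias)
    return f, i, results["FI"]


@dataclass(frozen=True)
class FusionResults:
    """Per-subject comparison of the fusion prediction with the FI data."""

    subject_id: str
    variance_mode: str
    f_summary: CueSummary
    i_summary: CueSummary
    prediction: BayesPrediction
    observed_sigma_fi2: float
    observed_b_fi: float
    observed_omse_fi: float

    @property
    def omse_fi_pred(self) -> float:
        return self.prediction.omse_fi_pred

    @property
    def omse_error(self) -> float:
        """Predicted minus observed OMSE in the combined condition."""
        return self.prediction.omse_fi_pred - self.observed_omse_fi

    def to_dict(self) -> dict:
        p = self.prediction
        return {
            "subject": self.subject_id,
            "variance_mode": self.variance_mode,
            "sigma_f2": self.f_summary.variance,
            "sigma_i2": self.i_summary.variance,
            "b_f": self.f_summary.bias,
            "b_i": self.i_summary.bias,
            "w_f": p.wF,
            "w_i": p.wI,
            "sigma_fi2_pred": p.sigma_fi2,
            "sigma_fi2_obs": self.observed_sigma_fi2,
            "b_fi_pred": p.b_fi,
            "b_fi_obs": self.observed_b_fi,
            "omse_fi_pred": p.omse_fi_pred,
            "omse_fi_obs": self.observed_omse_fi,
        }

    def summary(self) -> str:
        p = self.prediction
        lines = [
            "Bayesian cue fusion (frequency x intensity)",
            "=" * 50,
            f"subject: {self.subject_id}   variance mode: {self.variance_mode}",
            f"cue F: sigma^2 = {self.f_summary.variance:.6f}  bias = {self.f_summary.bias:+.4f}",
            f"cue I: sigma^2 = {self.i_summary.variance:.6f}  bias = {self.i_summary.bias:+.4f}",
            f"weights: wF = {p.wF:.4f}  wI = {p.wI:.4f}",
            "-" * 50,
            f"{'':18s}{'predicted':>12s}{'observed':>12s}",
            f"{'sigma_FI^2':18s}{p.sigma_fi2:12.6f}{self.observed_sigma_fi2:12.6f}",
            f"{'b_FI':18s}{p.b_fi:12.6f}{self.observed_b_fi:12.6f}",
            f"{'OMSE_FI':18s}{p.omse_fi_pred:12.6f}{self.observed_omse_fi:12.6f}",
        ]
        return "\n".join(lines)


class CueFusion:
    """Model object fusing one subject's F and I conditions to predict FI.

    Parameters
    ----------
    results : mapping condition -> HVDResults
        Decomposition results for the three conditions of one subject.
    variance_mode : {"total", "online_only"}
        Which VF-variance timescales count as estimation variance.

    Examples
    --------
    >>> fusion = CueFusion({"F": rf, "I": ri, "FI": rfi})
    >>> print(fusion.fit().summary())
    """

    def __init__(
        self,
        results: Mapping[str, HVDResults],
        variance_mode: VarianceMode = "total",
    ):
        self.results = dict(results)
        self.variance_mode = variance_mode

    def fit(self) -> FusionResults:
        f, i, fi = cue_summaries_from_hvd(self.results, self.variance_mode)
        pred = predict_omse_fi(f, i)
        obs_var = (
            fi.total_var_vf if self.variance_mode == "total" else fi.online_var_vf
        )
        return FusionResults(
            subject_id=fi.subject_id,
            variance_mode=self.variance_mode,
            f_summary=f,
            i_summary=i,
            prediction=pred,
            observed_sigma_fi2=obs_var,
            observed_b_fi=fi.bias,
            observed_omse_fi=fi.omse,
        )


def fusion_table(results: list[FusionResults]) -> pd.DataFrame:
    """Flatten FusionResults into one row per subject."""
    return pd.DataFrame([r.to_dict() for r in results])
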