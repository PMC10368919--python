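"""Reliability and calibration metrics for disconnection predictions.

Internal reliability: leave-one-out Pearson correlation of each database
subject's visitation map against the mean of all others, Fisher-z averaged.
External reliability: correlation of the database-mean prediction with a
map derived from a patient's own tractogram. Deviation-score: RMS of
per-voxel patient-minus-prediction differences normalized by the predicted
per-voxel deviation, with a theoretical value of 1 for perfectly calibrated
uncertainty. An exponential curve r(V) = a - b*exp(-c*V) describes how
these metrics depend on lesion volume V (cm^3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import PredictionResult
from .io import VolumeGrid

__all__ = [
    "ReliabilityReport",
    "DeviationScore",
    "CurveFit",
    "UndefinedCorrelationError",
    "fisher_mean",
    "masked_correlation",
    "internal_reliability",
    "external_reliability",
    "deviation_score",
    "fit_reliability_curve",
]

logger = logging.getLogger(__name__)

# clamp before atanh: identical maps give r = 1 exactly, whose z is infinite
_R_CLAMP = 1.0 - 1e-7


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation is undefined (zero variance)."""


@dataclass
class ReliabilityReport:
    per_subject_r: list[float]
    mean_r: float
    lesion_included: bool
    kind: str  # "internal" | "external"
    n_voxels_used: int
    dropped_subjects: list[int] = field(default_factory=list)


@dataclass
class DeviationScore:
    score: float
    n_voxels_used: int
    lesion_volume_ml: float


@dataclass
class CurveFit:
    """Parameters of r(V) = a - b*exp(-c*V) with adjusted R^2."""

    a: float
    b: float
    c: float
    adjusted_r2: float
    converged: bool = True

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def predict(self, volumes_ml) -> np.ndarray:
        v = np.asarray(volumes_ml, dtype=float)
        return self.a - self.b * np.exp(-self.c * v)


def fisher_mean(r_list) -> float:
    """Average correlations on the Fisher-z scale and back-transform.

    Values are clamped to +/-(1 - 1e-7) before atanh so degenerate
    perfect correlations do not produce infinite z.
    """
    r = np.asarray(list(r_list), dtype=float)
    if r.size == 0:
        raise ValueError("fisher_mean of an empty list")
    if np.any(np.isnan(r)):
        raise ValueError("NaN correlation in fisher_mean input")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    return float(np.tanh(z.mean()))


def _used_voxels(
    brain_mask: VolumeGrid,
    lesion_mask: VolumeGrid | None,
    include_lesion: bool,
    fov_mask: VolumeGrid | None = None,
) -> np.ndarray:
    used = brain_mask.data.astype(bool)
    if fov_mask is not None:
        used = used & fov_mask.data.astype(bool)
    if not include_lesion and lesion_mask is not None:
        used = used & ~lesion_mask.data.astype(bool)
    return used


def masked_correlation(
    map_a: VolumeGrid,
    map_b: VolumeGrid,
    brain_mask: VolumeGrid,
    lesion_mask: VolumeGrid | None = None,
    include_lesion: bool = True,
    fov_mask: VolumeGrid | None = None,
) -> tuple[float, int]:
    """Pearson r between two maps over brain-mask voxels.

    Lesion voxels are excluded when ``include_lesion`` is False; an optional
    field-of-view mask is intersected with the brain mask. Returns
    ``(r, n_voxels_used)``.
    """
    used = _used_voxels(brain_mask, lesion_mask, include_lesion, fov_mask)
    a = map_a.data[used].astype(float)
    b = map_b.data[used].astype(float)
    if a.size < 2:
        raise UndefinedCorrelationError("fewer than 2 usable voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance over the used voxels")
    r = stats.pearsonr(a, b).statistic
    return float(r), int(a.size)


def internal_reliability(
    per_subject_maps: list[VolumeGrid],
    brain_mask: VolumeGrid,
    lesion_mask: VolumeGrid | None = None,
    include_lesion: bool = True,
) -> ReliabilityReport:
    """Leave-one-out reliability of a prediction database.

    Each subject's map is correlated with the mean of all other subjects'
    maps over the brain mask; the per-subject r values are Fisher-averaged.
    A subject whose masked map has zero variance is dropped with a warning
    rather than aborting the group analysis.
    """
    n = len(per_subject_maps)
    if n < 3:
        raise ValueError("internal reliability requires >= 3 subjects")
    stack = np.stack([m.data.astype(np.float64) for m in per_subject_maps])
    total = stack.sum(axis=0)
    rs, dropped, n_used = [], [], 0
    ref = per_subject_maps[0]
    for i in range(n):
        loo_mean = ref.like((total - stack[i]) / (n - 1))
        try:
            r, n_used = masked_correlation(
                per_subject_maps[i], loo_mean, brain_mask, lesion_mask, include_lesion
            )
            rs.append(r)
        except UndefinedCorrelationError as exc:
            warnings.warn(f"subject {i} dropped from internal reliability: {exc}")
            dropped.append(i)
    if not rs:
        raise UndefinedCorrelationError("every subject had undefined correlation")
    return ReliabilityReport(
        per_subject_r=rs, mean_r=fisher_mean(rs), lesion_included=include_lesion,
        kind="internal", n_voxels_used=n_used, dropped_subjects=dropped,
    )


def external_reliability(
    prediction: PredictionResult,
    patient_map: VolumeGrid,
    brain_mask: VolumeGrid,
    lesion_mask: VolumeGrid | None = None,
    include_lesion: bool = True,
    fov_mask: VolumeGrid | None = None,
) -> ReliabilityReport:
    """Correlation of the prediction mean with a patient-derived map.

    No smoothing is applied to either map: the score reflects prediction
    accuracy relative to an individual tractography.
    """
    r, n_used = masked_correlation(
        prediction.mean, patient_map, brain_mask, lesion_mask, include_lesion, fov_mask
    )
    return ReliabilityReport(
        per_subject_r=[r], mean_r=r, lesion_included=include_lesion,
        kind="external", n_voxels_used=n_used,
    )


def deviation_score(
    prediction: PredictionResult,
    patient_map: VolumeGrid,
    brain_mask: VolumeGrid,
    lesion_mask: VolumeGrid | None = None,
    deviation_scale: str = "sd_plus_se",
) -> DeviationScore:
    """Calibration of the prediction's uncertainty against a patient map.

    d_v = (patient_v - mean_v) / s_v over brain voxels with s_v > 0, where
    s_v is the predicted per-voxel deviation (default sqrt(sd^2 + se^2));
    the score is the standard deviation of d about ZERO, i.e. the RMS
    sqrt(mean(d^2)). A score of 1 means the patient's map fluctuates
    exactly within the predicted range; voxels with s_v = 0 (never visited
    by any streamline) are 0/0 cases and are excluded.
    """
    s = prediction.total_deviation(deviation_scale)
    used = brain_mask.data.astype(bool) & (s > 0)
    n_used = int(used.sum())
    n_zero = int((brain_mask.data.astype(bool) & (s == 0)).sum())
    logger.info("deviation_score: %d voxels used, %d zero-deviation voxels excluded",
                n_used, n_zero)
    if n_used < 2:
        raise ValueError("no voxels with positive predicted deviation in the brain mask")
    d = (patient_map.data[used].astype(float) - prediction.mean.data[used]) / s[used]
    vol_ml = 0.0
    if lesion_mask is not None:
        vol_ml = float(lesion_mask.data.astype(bool).sum()
                       * lesion_mask.voxel_volume_mm3 / 1000.0)
    return DeviationScore(score=float(np.sqrt(np.mean(d**2))),
                          n_voxels_used=n_used, lesion_volume_ml=vol_ml)


def fit_reliability_curve(lesion_volumes_ml, scores) -> CurveFit:
    """Nonlinear least squares of r(V) = a - b*exp(-c*V), V in cm^3.

    The saturating 3-parameter exponential captures lower reliability for
    small lesions with a plateau at large volumes. Adjusted R^2 uses
    p = 3 parameters. Non-convergence returns the best-found parameters
    flagged ``converged=False``.
    """
    v = np.asarray(lesion_volumes_ml, dtype=float)
    y = np.asarray(scores, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 points to fit a 3-parameter curve")
    if np.any(v <= 0):
        raise ValueError("lesion volumes must be positive")

    def model(V, a, b, c):
        return a - b * np.exp(-c * V)

    a0 = float(y[np.argsort(v)[-max(1, v.size // 4):]].mean())
    b0 = max(a0 - float(y[np.argsort(v)[: max(1, v.size // 4)]].mean()), 1e-3)
    c0 = 1.0 / max(np.median(v), 1e-6)
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, v, y, p0=(a0, b0, c0),
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        converged = False
        popt = (a0, b0, c0)
    resid = y - model(v, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n, p = v.size, 3
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return CurveFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                    adjusted_r2=float(adj), converged=converged)
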