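"""Frame-wise head-motion summaries and subject-level exclusion rules.

Rigid-body realignment of an fMRI run yields six parameters per frame:
three rotations (radians) and three translations (mm). This module turns
those traces into the standard frame-wise motion indices —

* **FD** (framewise displacement): per frame, the sum of absolute
  differentials of the six parameters, rotations converted to arc length
  on a sphere (default radius 50 mm, the Power convention);
* **Diff**: the per-parameter absolute differentials themselves;
* **Mean Motion**: the mean frame-to-frame translational displacement of
  the head (Van Dijk convention, Euclidean norm of the translation
  differential) —

and applies the cohort exclusion rule: a subject is dropped when any
converted parameter excursion exceeds 1.0 mm or Mean Motion exceeds
0.25 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RealignmentTrace",
    "MotionSummary",
    "framewise_displacement",
    "diff_series",
    "mean_motion",
    "apply_exclusion",
    "motion_connectivity_check",
]

#: Default head-radius (mm) used to convert rotations to arc length.
DEFAULT_ROTATION_RADIUS_MM = 50.0

#: Exclusion thresholds: any parameter excursion > 1.0 mm, Mean Motion > 0.25 mm.
PARAMETER_LIMIT_MM = 1.0
MEAN_MOTION_LIMIT_MM = 0.25


@dataclass
class RealignmentTrace:
    """Six rigid-body realignment parameters per frame.

    Parameters
    ----------
    rotations
        Array of shape ``(n_frames, 3)``, radians.
    translations
        Array of shape ``(n_frames, 3)``, mm.
    subject_id
        Optional subject identifier carried through QC reports.
    """

    rotations: np.ndarray
    translations: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 2 or self.rotations.shape[1] != 3:
            raise ValueError("rotations must have shape (n_frames, 3)")
        if self.translations.shape != self.rotations.shape:
            raise ValueError("translations must match rotations in shape")

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    @property
    def parameters(self) -> np.ndarray:
        """Frames x 6 array in the MCFLIRT column order (rotations, translations)."""
        return np.hstack([self.rotations, self.translations])


@dataclass
class MotionSummary:
    """Per-subject motion QC result."""

    fd_series: np.ndarray
    diff_series: np.ndarray  # (n_frames - 1, 6) absolute differentials, mm-converted
    mean_motion: float
    max_parameter_excursion: float
    excluded: bool = False
    exclusion_reason: str | None = None
    subject_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_motion_mm": float(self.mean_motion),
            "max_fd_mm": float(np.max(self.fd_series)) if self.fd_series.size else 0.0,
            "max_parameter_excursion_mm": float(self.max_parameter_excursion),
            "excluded": bool(self.excluded),
            "exclusion_reason": self.exclusion_reason,
        }


def _require_frames(trace: RealignmentTrace) -> None:
    if trace.n_frames < 2:
        raise ValueError(
            f"need at least 2 frames for frame-wise differentials, got {trace.n_frames}"
        )


def _converted_parameters(
    trace: RealignmentTrace, rotation_radius: float
) -> np.ndarray:
    """All six parameters on a common mm scale (rotations as arc length)."""
    return np.hstack([trace.rotations * rotation_radius, trace.translations])


def diff_series(
    trace: RealignmentTrace, rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Absolute differentials of the six parameters (mm), shape ``(n_frames-1, 6)``."""
    _require_frames(trace)
    return np.abs(np.diff(_converted_parameters(trace, rotation_radius), axis=0))


def framewise_displacement(
    trace: RealignmentTrace, rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement FD_t, one value per frame transition.

    FD_t = sum |Delta translation| + radius * sum |Delta rotation|; the
    rotation term is the arc swept on a sphere of ``rotation_radius`` mm.
    Output has length ``n_frames - 1``.
    """
    return diff_series(trace, rotation_radius).sum(axis=1)


def mean_motion(trace: RealignmentTrace, method: str = "norm") -> float:
    """Mean frame-to-frame translational displacement (mm).

    ``method="norm"`` (default): mean over frames of the Euclidean norm of
    the translation differential — the Van Dijk head-displacement index.
    ``method="per_axis"``: mean of the three per-axis mean absolute
    differentials, an alternative literal reading offered without
    endorsement.
    """
    _require_frames(trace)
    d = np.diff(trace.translations, axis=0)
    if method == "norm":
        return float(np.mean(np.linalg.norm(d, axis=1)))
    if method == "per_axis":
        return float(np.mean(np.abs(d)))
    raise ValueError(f"unknown method {method!r}")


def summarize_motion(
    trace: RealignmentTrace,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM,
) -> MotionSummary:
    """Compute FD, Diff and Mean Motion and apply the exclusion rule."""
    diffs = diff_series(trace, rotation_radius)
    summary = MotionSummary(
        fd_series=diffs.sum(axis=1),
        diff_series=diffs,
        mean_motion=mean_motion(trace),
        max_parameter_excursion=float(
            np.max(np.abs(_converted_parameters(trace, rotation_radius)))
        ),
        subject_id=trace.subject_id,
    )
    return apply_exclusion(summary, trace)


def apply_exclusion(
    summary: MotionSummary,
    trace: RealignmentTrace,
    parameter_limit: float = PARAMETER_LIMIT_MM,
    mean_motion_limit: float = MEAN_MOTION_LIMIT_MM,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM,
) -> MotionSummary:
    """Flag a subject for exclusion.

    Excluded when any of the six parameters (rotations converted to mm at
    ``rotation_radius``) deviates by more than ``parameter_limit`` mm, or
    when Mean Motion exceeds ``mean_motion_limit`` mm. The first matching
    reason is recorded; thresholds are strict (>).
    """
    excursion = float(np.max(np.abs(_converted_parameters(trace, rotation_radius))))
    summary.max_parameter_excursion = excursion
    if excursion > parameter_limit:
        summary.excluded = True
        summary.exclusion_reason = "parameter_deviation"
    elif summary.mean_motion > mean_motion_limit:
        summary.excluded = True
        summary.exclusion_reason = "mean_motion"
    else:
        summary.excluded = False
        summary.exclusion_reason = None
    return summary


def motion_connectivity_check(
    mean_motions: np.ndarray, connectivity_values: np.ndarray
) -> dict:
    """Association between per-subject Mean Motion and a connectivity value.

    Returns Pearson (linear) and Spearman (rank, the monotone/non-linear
    check) correlations with p-values. With fewer than 3 subjects or a
    zero-variance input the correlations are undefined and flagged.
    """
    x = np.asarray(mean_motions, dtype=float)
    y = np.asarray(connectivity_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    report: dict = {"n": int(x.size), "undefined": False}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        report["undefined"] = True
        report.update(
            pearson_r=np.nan, pearson_p=np.nan, spearman_r=np.nan, spearman_p=np.nan
        )
        return report
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    report.update(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
    return report
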