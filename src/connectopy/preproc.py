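"""Temporal preprocessing and subject-level quality control.

Covers the stages that happen between raw (already registered) BOLD data and
gradient estimation: nuisance regression against confound time series, a
discrete-cosine high-pass filter for slow drifts, Power-style framewise
displacement, rule-based subject exclusion and ROI-mask erosion for
edge-effect sensitivity analyses.

Stage order convention: apply :func:`highpass_filter` to the data *and* the
confounds first, then :func:`regress_nuisance`.  With both series filtered by
the same drift basis, the sequential result equals the single projection onto
the concatenated [drift | confound] design (the two operations commute).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MotionSummary",
    "QCResult",
    "ExclusionThresholds",
    "regress_nuisance",
    "highpass_filter",
    "dct_drift_basis",
    "framewise_displacement",
    "apply_exclusions",
    "erode_mask",
]


@dataclass
class MotionSummary:
    """Framewise displacement series (mm) and its summary statistics."""

    fd_series: np.ndarray
    fd_mean: float
    fd_max: float


@dataclass
class QCResult:
    """Outcome of the exclusion rules for one subject.

    ``passed`` is True iff ``reasons`` is empty; each reason is one of
    "motion_mean", "motion_max", "roi_variance", "reference_correlation".
    """

    subject_id: str
    passed: bool
    reasons: list = field(default_factory=list)
    reference_r: float | None = None


@dataclass(frozen=True)
class ExclusionThresholds:
    """Exclusion rules (all strict comparisons).

    Defaults follow the conventional cut-offs for multi-site clinical rfMRI:
    mean FD above 0.7 mm, max FD above 3.8 mm (about one voxel), an ROI
    variance floor of 1e-6 (on standardized data "insufficient variance"
    means numerically zero) and a reference-map correlation of at least 0.5.
    """

    fd_mean_max: float = 0.7
    fd_max_max: float = 3.8
    variance_floor: float = 1e-6
    min_reference_r: float = 0.5


def _augment_intercept(confounds, n):
    if confounds is None or np.size(confounds) == 0:
        return np.ones((n, 1)), ["intercept"]
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValueError(f"confounds have {C.shape[0]} rows, data has {n} timepoints")
    names = ["intercept"] + [f"confound_{j}" for j in range(C.shape[1])]
    return np.column_stack([np.ones(n), C]), names


def regress_nuisance(data, confounds=None):
    """OLS residuals of each voxel's series after regressing out confounds.

    An intercept is always included, so with no confounds the output is the
    demeaned input.  Residuals are orthogonal to every confound column.
    Raises on rank-deficient designs, naming the collinear column.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a time x voxel matrix")
    C, names = _augment_intercept(confounds, Y.shape[0])
    # detect collinearity column by column for a useful error message
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        for j in range(1, C.shape[1]):
            if np.linalg.matrix_rank(C[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"confound design is rank-deficient: column {names[j]!r} is "
                    "collinear with the preceding columns"
                )
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ beta


def dct_drift_basis(n_timepoints, tr_seconds, cutoff_hz):
    """Discrete-cosine drift basis: all DCT-II regressors with frequency below
    the cut-off, plus the constant.

    Basis function j (j >= 1) is ``cos(pi j (2t + 1) / (2T))`` with frequency
    ``j / (2 T TR)`` Hz.
    """
    T = int(n_timepoints)
    if T < 2:
        raise ValueError("need at least 2 frames to build a drift basis")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist} Hz")
    n_funcs = int(np.floor(2.0 * T * tr_seconds * cutoff_hz))
    t = np.arange(T)
    cols = [np.ones(T)]
    for j in range(1, n_funcs + 1):
        cols.append(np.cos(np.pi * j * (2 * t + 1) / (2.0 * T)))
    return np.column_stack(cols)


def highpass_filter(data, cutoff_hz, tr_seconds):
    """High-pass filter by regressing out a low-frequency discrete-cosine basis.

    Removes the constant and every cosine drift regressor with frequency
    below `cutoff_hz`; oscillations well above the cut-off pass essentially
    unattenuated.  Regression-based filtering (rather than an IIR filter)
    avoids edge transients on short runs.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a time x voxel matrix")
    B = dct_drift_basis(Y.shape[0], tr_seconds, cutoff_hz)
    beta, *_ = np.linalg.lstsq(B, Y, rcond=None)
    return Y - B @ beta


def framewise_displacement(motion_params, head_radius_mm=50.0, rotations_first=True):
    """Power framewise displacement from six rigid-body motion parameters.

    ``FD_t = sum |delta translations| + r * sum |delta rotations|`` with
    rotations in radians converted to arc length on a `head_radius_mm` sphere;
    the first frame has FD 0 by convention.  Column order defaults to three
    rotations then three translations (set ``rotations_first=False`` for the
    opposite convention).
    """
    P = np.asarray(motion_params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError("motion parameters must be a time x 6 matrix")
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite motion parameters")
    rot, trans = (P[:, :3], P[:, 3:]) if rotations_first else (P[:, 3:], P[:, :3])
    d_rot = np.abs(np.diff(rot, axis=0)).sum(axis=1) * head_radius_mm
    d_trans = np.abs(np.diff(trans, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], d_rot + d_trans])
    return MotionSummary(fd_series=fd, fd_mean=float(fd.mean()), fd_max=float(fd.max()))


def apply_exclusions(cohort, motion, roi_variances, thresholds=None, reference_r=None):
    """Apply the subject exclusion rules and report per-subject outcomes.

    Parameters
    ----------
    cohort : DataFrame with a ``subject_id`` column.
    motion : dict subject_id -> :class:`MotionSummary`.
    roi_variances : dict subject_id -> minimum voxel variance within the ROI.
    thresholds : :class:`ExclusionThresholds`
    reference_r : dict subject_id -> post-alignment reference correlation, optional.

    A subject is excluded iff any rule fires (all comparisons strict); every
    exclusion carries its reasons.  Returns ``(retained_cohort, qc_results)``.
    The operation is idempotent: re-applying it to the retained table removes
    nobody.
    """
    thr = thresholds or ExclusionThresholds()
    results = []
    keep = []
    for sid in cohort["subject_id"]:
        if sid not in motion:
            raise KeyError(f"missing motion summary for subject {sid!r}")
        if sid not in roi_variances:
            raise KeyError(f"missing ROI variance for subject {sid!r}")
        reasons = []
        m = motion[sid]
        if m.fd_mean > thr.fd_mean_max:
            reasons.append("motion_mean")
        if m.fd_max > thr.fd_max_max:
            reasons.append("motion_max")
        if roi_variances[sid] < thr.variance_floor:
            reasons.append("roi_variance")
        r = None if reference_r is None else reference_r.get(sid)
        if r is not None and r < thr.min_reference_r:
            reasons.append("reference_correlation")
        passed = len(reasons) == 0
        results.append(QCResult(subject_id=sid, passed=passed, reasons=reasons, reference_r=r))
        keep.append(passed)
    retained = cohort.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return retained, results


def erode_mask(mask, iterations=1):
    """Binary erosion with the 6-connected (face-neighbour) structuring element.

    The output is a subset of the input; erosion that would empty the mask
    raises instead of silently returning nothing.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3:
        raise ValueError("mask must be 3-D")
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m, structure=structure, iterations=iterations)
    if not eroded.any():
        raise ValueError(f"erosion with {iterations} iteration(s) empties the mask")
    return eroded


def qc_results_to_frame(results):
    """Tabulate a list of :class:`QCResult` for TSV/JSON reporting."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "passed": r.passed,
                "reasons": ";".join(r.reasons),
                "reference_r": r.reference_r,
            }
            for r in results
        ]
    )
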