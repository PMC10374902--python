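"""Dual regression: project ROI gradients onto the whole brain.

Stage 1 regresses each timepoint's ROI pattern onto the (demeaned) spatial
gradient map(s) across voxels, yielding one time course per map; stage 2
regresses every brain voxel's time series onto those (variance-normalized)
time courses, yielding one whole-brain coefficient image per map.  The result
shows which brain regions co-vary with the subtle connectivity variation the
gradient encodes inside the ROI.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["DualRegression", "dual_regression"]


def dual_regression(brain_data, roi_maps, roi_columns, normalize_timecourses=True):
    """Two-stage OLS from spatial map(s) to whole-brain projection image(s).

    Parameters
    ----------
    brain_data : ndarray (T, V_brain)
        Standardized brain time series.
    roi_maps : ndarray (V_roi,) or (V_roi, M)
        Spatial design: one or more gradient maps over ROI voxels.  Maps are
        demeaned across voxels before stage 1, and an intercept is included
        in both stages, so the result is invariant to positive rescaling of
        the maps.
    roi_columns : integer or boolean index
        Which columns of `brain_data` are the ROI voxels.

    Returns
    -------
    timecourses : ndarray (T, M)
        Stage-1 time courses (unit variance unless a map is orthogonal to
        the data, in which case its time course is identically zero).
    projections : ndarray (M, V_brain)
        Stage-2 coefficient maps.
    """
    Y = np.asarray(brain_data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("brain_data must be a time x voxel matrix")
    S = np.asarray(roi_maps, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    roi = Y[:, roi_columns]
    if roi.shape[1] != S.shape[0]:
        raise ValueError(
            f"roi_maps have {S.shape[0]} voxels but roi_columns select {roi.shape[1]}"
        )
    Sd = S - S.mean(axis=0)
    if np.linalg.matrix_rank(Sd) < Sd.shape[1]:
        raise ValueError("spatial design is rank-deficient after demeaning")
    M = Sd.shape[1]
    design1 = np.column_stack([np.ones(Sd.shape[0]), Sd])
    # stage 1: per-timepoint spatial regression (solved jointly via lstsq)
    beta1, *_ = np.linalg.lstsq(design1, roi.T, rcond=None)
    tc = beta1[1:].T.copy()  # T x M
    # a numerically null time course (map orthogonal to the data) stays zero
    # instead of being blown up by the variance normalization
    scale = np.abs(tc).max(axis=0)
    null_tc = scale <= 1e-10 * max(1.0, np.abs(roi).max())
    tc[:, null_tc] = 0.0
    if normalize_timecourses:
        sd = tc.std(axis=0, ddof=1)
        nz = sd > 0
        tc[:, nz] = (tc[:, nz] - tc[:, nz].mean(axis=0)) / sd[nz]
    # stage 2: per-voxel temporal regression
    design2 = np.column_stack([np.ones(Y.shape[0]), tc])
    beta2, *_ = np.linalg.lstsq(design2, Y, rcond=None)
    projections = beta2[1:]
    return tc, projections


class DualRegression(BaseEstimator):
    """Estimator wrapper around :func:`dual_regression`.

    Parameters
    ----------
    roi_columns : index into the brain-voxel axis marking ROI voxels.
    normalize_timecourses : bool, default True
        Scale stage-1 time courses to unit variance before stage 2 (makes
        the projections comparable across subjects and absorbs any map scale).

    Attributes
    ----------
    timecourses_ : ndarray (T, M)
    projections_ : ndarray (M, V_brain)
    """

    def __init__(self, roi_columns=None, normalize_timecourses=True):
        self.roi_columns = roi_columns
        self.normalize_timecourses = normalize_timecourses

    def fit(self, X, y=None, roi_maps=None):
        if self.roi_columns is None:
            raise ValueError("roi_columns must be provided")
        if roi_maps is None:
            raise ValueError("roi_maps must be provided to fit")
        self.timecourses_, self.projections_ = dual_regression(
            X, roi_maps, self.roi_columns, self.normalize_timecourses
        )
        return self

    def fit_transform(self, X, y=None, roi_maps=None):
        """Fit and return the projection maps, shape (M, V_brain)."""
        return self.fit(X, roi_maps=roi_maps).projections_
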