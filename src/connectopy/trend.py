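"""Trend-surface models (TSM): polynomial summaries of spatial gradient maps.

A connectopy is a scalar field over ROI voxels.  Fitting it with per-axis
polynomial terms of the (standardized) voxel coordinates — columns
(1, x, y, z, x^2, y^2, z^2, ..., x^k, y^k, z^k), no cross-terms — compresses
the map into 3k coefficients that can be compared across subjects.  The
polynomial order is selected by minimizing the Bayesian information
criterion, with explained variance reported alongside so the fit/parsimony
trade-off can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TSMBasis",
    "TSMModel",
    "TrendSurfaceModel",
    "build_basis",
    "fit_tsm",
    "select_order",
    "reconstruct",
    "rmse_coefficients",
]

_AXIS_NAMES = ("x", "y", "z")


@dataclass
class TSMBasis:
    """Design matrix of per-axis monomials over standardized voxel coordinates.

    `terms` names the non-intercept columns ("x1", "y1", "z1", "x2", ...,
    grouped by power); axes whose coordinate is constant within the ROI are
    dropped (`dropped_axes`) so thin ROIs still fit.
    """

    order: int
    coords: np.ndarray          # raw voxel (or world) coordinates, V x 3
    design: np.ndarray          # V x (1 + n_terms), first column is the intercept
    terms: list
    axis_means: np.ndarray
    axis_sds: np.ndarray
    dropped_axes: tuple = ()


@dataclass
class TSMModel:
    """A fitted trend surface: order, intercept, per-term coefficients, BIC,
    explained variance and residual sum of squares."""

    order: int
    intercept: float
    coefficients: np.ndarray
    terms: list
    bic: float
    explained_variance: float
    residual_ss: float


def build_basis(voxel_coords, order):
    """Build the TSM design for `voxel_coords` (V x 3) at a given order.

    Coordinates are standardized per axis (mean 0, sd 1) before powering so
    the coefficients are unit-free and comparable across subjects regardless
    of ROI size or whether voxel or world (mm) coordinates are supplied.
    Constant axes are dropped with a warning; an error is raised if fewer
    voxels than design columns remain.
    """
    C = np.asarray(voxel_coords, dtype=float)
    if C.ndim != 2 or C.shape[1] != 3:
        raise ValueError("voxel_coords must be a V x 3 matrix")
    if order < 1:
        raise ValueError("order must be >= 1")
    means = C.mean(axis=0)
    sds = C.std(axis=0, ddof=0)
    dropped = tuple(_AXIS_NAMES[a] for a in range(3) if sds[a] == 0)
    if dropped:
        warnings.warn(
            f"axis/axes {dropped} constant within the ROI; their terms are dropped",
            RuntimeWarning,
        )
    kept = [a for a in range(3) if sds[a] > 0]
    Z = (C[:, kept] - means[kept]) / sds[kept]
    cols = [np.ones(C.shape[0])]
    terms = []
    for p in range(1, order + 1):
        for idx, a in enumerate(kept):
            cols.append(Z[:, idx] ** p)
            terms.append(f"{_AXIS_NAMES[a]}{p}")
    design = np.column_stack(cols)
    if design.shape[0] < design.shape[1]:
        raise ValueError(
            f"{design.shape[0]} voxels cannot support {design.shape[1]} design columns "
            f"at order {order}"
        )
    return TSMBasis(
        order=order, coords=C, design=design, terms=terms,
        axis_means=means, axis_sds=sds, dropped_axes=dropped,
    )


# Relative floor applied to RSS inside the BIC likelihood term.  Noise-free
# surfaces fit to machine precision give RSS ~ 1e-30 whose logarithm swamps
# the parsimony penalty with meaningless rounding noise; flooring at 1e-15 of
# the total SS keeps BIC finite and lets the penalty decide between models
# that both fit exactly.
_RSS_FLOOR_REL = 1e-15


def _ols_fit(y, basis, ridge=1e-8):
    design = basis.design
    n, p_cols = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < p_cols:
        raise ValueError(f"rank-deficient TSM design (rank {rank} < {p_cols} columns)")
    cond = np.linalg.cond(design)
    if cond > 1e10:
        # ridge fallback for ill-conditioned high orders; bias is negligible
        # at this regularization but keeps the solve stable
        A = design.T @ design + ridge * np.eye(p_cols)
        beta = np.linalg.solve(A, design.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    ev = 1.0 - rss / tss if tss > 0 else 1.0
    # BIC of the Gaussian model; parameter count includes intercept,
    # coefficients and the noise variance
    p = p_cols + 1
    rss_floor = max(rss, _RSS_FLOOR_REL * max(tss, 1.0))
    bic = n * np.log(rss_floor / n) + p * np.log(n)
    return beta, rss, ev, float(bic)


def _map_values(connectopy):
    return np.asarray(getattr(connectopy, "values", connectopy), dtype=float).ravel()


def fit_tsm(connectopy, basis):
    """Ordinary-least-squares fit of a gradient map onto a TSM basis.

    Accepts a :class:`~connectopy.mapping.Connectopy` or a plain value array.
    """
    y = _map_values(connectopy)
    if y.size != basis.design.shape[0]:
        raise ValueError("map length does not match basis voxel count")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite map values")
    beta, rss, ev, bic = _ols_fit(y, basis)
    return TSMModel(
        order=basis.order, intercept=float(beta[0]), coefficients=beta[1:].copy(),
        terms=list(basis.terms), bic=bic, explained_variance=ev, residual_ss=rss,
    )


def select_order(connectopy, voxel_coords, max_order=6):
    """Choose the TSM polynomial order by global BIC minimum over 1..max_order.

    Returns ``(chosen_order, table)`` where `table` lists BIC and explained
    variance for every candidate order, so the fit/parsimony trade-off is
    auditable.  Ties break toward the lower order.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    y = _map_values(connectopy)
    rows = []
    for k in range(1, max_order + 1):
        try:
            basis = build_basis(voxel_coords, k)
            model = fit_tsm(y, basis)
        except ValueError as err:
            # an ROI with few distinct coordinate levels cannot support high
            # per-axis powers; mark the order infeasible instead of aborting
            warnings.warn(f"order {k} infeasible on this ROI geometry: {err}", RuntimeWarning)
            rows.append({"order": k, "bic": np.inf, "explained_variance": np.nan})
            continue
        rows.append({"order": k, "bic": model.bic, "explained_variance": model.explained_variance})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["bic"]).any():
        raise ValueError("no feasible order on this ROI geometry")
    chosen = int(table.loc[table["bic"].idxmin(), "order"])  # idxmin takes the first = lowest order
    return chosen, table


def reconstruct(model, basis):
    """Evaluate a fitted trend surface on a basis: ``design @ (intercept, coefs)``."""
    if model.order != basis.order:
        raise ValueError(f"model order {model.order} does not match basis order {basis.order}")
    if len(model.coefficients) != basis.design.shape[1] - 1:
        raise ValueError("coefficient count does not match basis columns")
    return basis.design @ np.concatenate([[model.intercept], model.coefficients])


def term_axis_filter(terms, axis):
    """Indices of the terms belonging to one coordinate axis ('x', 'y' or 'z')."""
    idx = [i for i, t in enumerate(terms) if t.startswith(axis)]
    return np.asarray(idx, dtype=int)


def rmse_coefficients(c1, c2, terms=None, axis=None):
    """Root-mean-square difference between two TSM coefficient vectors,
    optionally restricted to the terms of one axis (e.g. the z-direction)."""
    a = np.asarray(c1, dtype=float).ravel()
    b = np.asarray(c2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("coefficient vectors differ in length")
    if axis is not None:
        if terms is None:
            raise ValueError("axis filtering requires the term names")
        idx = term_axis_filter(terms, axis)
        if idx.size == 0:
            raise ValueError(f"no terms on axis {axis!r}")
        a, b = a[idx], b[idx]
    if a.size == 0:
        raise ValueError("empty coefficient selection")
    return float(np.sqrt(np.mean((a - b) ** 2)))


class TrendSurfaceModel(RegressorMixin, BaseEstimator):
    """sklearn-style trend-surface regressor over 3-D voxel coordinates.

    ``fit(coords, values)`` standardizes the coordinates, builds the per-axis
    monomial design of the requested `order` and solves by OLS.  ``predict``
    reuses the standardization fitted on the training ROI, so a model fitted
    on one map can be evaluated on the same geometry.

    Attributes (after fit): ``intercept_``, ``coef_``, ``terms_``, ``bic_``,
    ``explained_variance_``, ``residual_ss_``, ``basis_``.
    """

    def __init__(self, order=6):
        self.order = order

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _map_values(y)
        self.basis_ = build_basis(X, self.order)
        model = fit_tsm(y, self.basis_)
        self.model_ = model
        self.intercept_ = model.intercept
        self.coef_ = model.coefficients
        self.terms_ = model.terms
        self.bic_ = model.bic
        self.explained_variance_ = model.explained_variance
        self.residual_ss_ = model.residual_ss
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        b = self.basis_
        kept = [a for a in range(3) if _AXIS_NAMES[a] not in b.dropped_axes]
        Z = (X[:, kept] - b.axis_means[kept]) / b.axis_sds[kept]
        cols = [np.ones(X.shape[0])]
        for p in range(1, b.order + 1):
            for idx in range(len(kept)):
                cols.append(Z[:, idx] ** p)
        design = np.column_stack(cols)
        return design @ np.concatenate([[self.intercept_], self.coef_])
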