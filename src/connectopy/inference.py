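"""Association and comparison statistics for trend-surface coefficients.

The inference layer asks whether the spatial summary of a gradient relates
to behaviour: partial correlations between TSM coefficients and scores with
OLS covariate adjustment and Holm (step-down Bonferroni) family-wise error
control; independent and paired t-tests for group and condition contrasts;
a mass-univariate GLM on the raw per-voxel gradients with max-T permutation
FWE control; and score-conditioned reconstruction of the gradient with an
RMSE profile against the cohort-average surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trend import TSMBasis, TSMModel, reconstruct, rmse_coefficients

logger = logging.getLogger(__name__)

__all__ = [
    "StatsConfig",
    "holm_correct",
    "associate_coefficients",
    "group_ttest",
    "paired_ttest",
    "glm_voxelwise",
    "fit_coefficient_score_model",
    "reconstruct_at_score",
]


@dataclass(frozen=True)
class StatsConfig:
    """Inference options.

    alpha : family-wise error rate (default 0.05).
    family : label describing the correction family; the default is all
        terms supplied in one call, i.e. one (score, ROI, condition) family.
    ttest_variant : "pooled" or "welch" for independent-sample comparisons.
    n_permutations / seed : max-T permutation settings for the voxel-wise GLM.
    """

    alpha: float = 0.05
    family: str = "terms"
    ttest_variant: str = "pooled"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.ttest_variant not in ("pooled", "welch"):
            raise ValueError("ttest_variant must be 'pooled' or 'welch'")


def holm_correct(pvals, alpha=0.05):
    """Holm step-down correction.

    Sorts the p-values ascending, compares p_(i) to alpha / (m - i + 1) and
    stops at the first failure; adjusted p-values are the running maximum of
    (m - i + 1) p_(i), capped at 1.  Returns ``(adjusted, rejected)`` in the
    original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, *_ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, rejected


def _covariate_design(covariates, index=None):
    """Numeric covariate design: categorical columns dummy-coded with the
    alphabetically first level as reference; returns (matrix, column names)."""
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        df = covariates if index is None else covariates.loc[index]
        parts = []
        for col in df.columns:
            s = df[col]
            if s.dtype.kind in "biufc":
                parts.append(s.astype(float).rename(col))
            else:
                levels = sorted(s.astype(str).unique())
                for lev in levels[1:]:
                    parts.append((s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]"))
        if not parts:
            return np.empty((len(df), 0)), []
        out = pd.concat(parts, axis=1)
        return out.to_numpy(dtype=float), list(out.columns)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == 1 and C.shape[1] > 1 and index is not None:
        C = C.T
    names = [f"cov_{j}" for j in range(C.shape[1])]
    return C, names


def _residualize(v, Caug):
    beta, *_ = np.linalg.lstsq(Caug, v, rcond=None)
    return v - Caug @ beta


def associate_coefficients(coeffs, score, covariates=None, config=None, terms=None):
    """Partial correlations between TSM coefficients and a behavioural score.

    Per term, both the coefficient and the score are residualized on
    [intercept | covariates] by OLS; the partial r is the Pearson correlation
    of the residuals, with ``t = r sqrt((n - 2 - q) / (1 - r^2))`` against a
    Student-t with n - 2 - q degrees of freedom (q = covariate columns).
    Subjects with a missing score or covariate are dropped listwise (count
    logged).  Holm correction is applied across the supplied terms.

    Returns a DataFrame with columns term, partial_r, p, p_holm, rejected, n.
    """
    cfg = config or StatsConfig()
    X = np.asarray(coeffs, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if terms is None:
        terms = list(coeffs.columns) if isinstance(coeffs, pd.DataFrame) else [
            f"term_{j}" for j in range(X.shape[1])
        ]
    s = np.asarray(score, dtype=float).ravel()
    if s.size != X.shape[0]:
        raise ValueError("score length does not match coefficient rows")
    C, cov_names = _covariate_design(covariates)
    if C.size and C.shape[0] != X.shape[0]:
        raise ValueError("covariate rows do not match coefficient rows")

    ok = np.isfinite(s) & np.all(np.isfinite(X), axis=1)
    if C.size:
        ok &= np.all(np.isfinite(C), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("associate_coefficients: dropped %d subject(s) listwise", n_dropped)
    X, s = X[ok], s[ok]
    C = C[ok] if C.size else np.empty((X.shape[0], 0))
    n, q = X.shape[0], C.shape[1]
    if n <= q + 3:
        raise ValueError(f"too few subjects (n={n}) for q={q} covariates")
    if np.ptp(s) == 0:
        raise ValueError("constant score")
    Caug = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Caug) < Caug.shape[1]:
        raise ValueError(f"collinear covariates among {cov_names}")

    s_res = _residualize(s, Caug)
    df = n - 2 - q
    rows = []
    for j, term in enumerate(terms):
        x_res = _residualize(X[:, j], Caug)
        denom = np.sqrt((x_res @ x_res) * (s_res @ s_res))
        r = float(x_res @ s_res / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r**2))
            p = float(2 * stats.t.sf(abs(t), df))
        rows.append({"term": term, "partial_r": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    adj, rej = holm_correct(out["p"].to_numpy(), alpha=cfg.alpha)
    out["p_holm"] = adj
    out["rejected"] = rej
    return out


def _holm_frame(frame, alpha):
    adj, rej = holm_correct(frame["p"].to_numpy(), alpha=alpha)
    frame["p_holm"] = adj
    frame["rejected"] = rej
    return frame


def group_ttest(coeffs_a, coeffs_b, config=None, terms=None):
    """Independent two-sample t-test per coefficient term (pooled variance by
    default, Welch optional), Holm-corrected across terms."""
    cfg = config or StatsConfig()
    A = np.atleast_2d(np.asarray(coeffs_a, dtype=float))
    B = np.atleast_2d(np.asarray(coeffs_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different term counts")
    if terms is None:
        terms = list(coeffs_a.columns) if isinstance(coeffs_a, pd.DataFrame) else [
            f"term_{j}" for j in range(A.shape[1])
        ]
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=(cfg.ttest_variant == "pooled"))
    out = pd.DataFrame({"term": terms, "t": t, "p": p})
    return _holm_frame(out, cfg.alpha)


def paired_ttest(coeffs_rest, coeffs_task, config=None, terms=None, subject_ids=None):
    """Paired t-test (one-sample t on within-subject differences) per term.

    Rows must be matched subjects; pass `subject_ids` as (ids_rest, ids_task)
    to have the matching verified.  A term whose differences have zero
    variance raises (a silently infinite t would be meaningless).
    """
    cfg = config or StatsConfig()
    A = np.atleast_2d(np.asarray(coeffs_rest, dtype=float))
    B = np.atleast_2d(np.asarray(coeffs_task, dtype=float))
    if subject_ids is not None:
        ids_a, ids_b = (list(x) for x in subject_ids)
        if ids_a != ids_b:
            raise ValueError("subject sets of the two conditions do not match")
    if A.shape != B.shape:
        raise ValueError("paired matrices must have identical shape")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if terms is None:
        terms = list(coeffs_rest.columns) if isinstance(coeffs_rest, pd.DataFrame) else [
            f"term_{j}" for j in range(A.shape[1])
        ]
    D = A - B
    sd = D.std(axis=0, ddof=1)
    sd = np.where(sd <= 1e-12 * (np.abs(D.mean(axis=0)) + 1.0), 0.0, sd)
    degenerate = np.flatnonzero(sd == 0)
    nonzero_shift = degenerate[np.abs(D.mean(axis=0)[degenerate]) > 0]
    if nonzero_shift.size:
        raise ValueError(
            "zero variance of within-subject differences with non-zero shift for "
            f"term(s) {[terms[i] for i in nonzero_shift]}; t is undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(A, B, axis=0)
    t = np.where(sd == 0, 0.0, t)
    p = np.where(sd == 0, 1.0, p)
    out = pd.DataFrame({"term": terms, "t": t, "p": p})
    return _holm_frame(out, cfg.alpha)


def glm_voxelwise(raw_maps, design, contrast, config=None, method="max-t"):
    """Mass-univariate GLM on raw per-voxel gradients with FWE control.

    Parameters
    ----------
    raw_maps : ndarray (n_subjects, V)
        One gradient value per subject per ROI voxel.
    design : DataFrame (n_subjects x p)
        Explanatory variables (e.g. intercept, diagnosis, sex, age, score);
        an intercept column is added if absent.
    contrast : str
        Name of the design column whose effect is tested.
    method : "max-t" (default) or "holm"
        Family-wise control: sign/label permutation of the contrast column
        with the max-T null distribution, or Holm on the parametric p-values.
        Max-T respects the spatial correlation among voxels that makes Holm
        conservative.

    Returns a dict with t (V,), p_fwe (V,), significant (V,) and df.
    """
    cfg = config or StatsConfig()
    Y = np.asarray(raw_maps, dtype=float)
    if not isinstance(design, pd.DataFrame):
        raise TypeError("design must be a DataFrame with named columns")
    X_df = design.copy()
    if "intercept" not in X_df.columns:
        X_df.insert(0, "intercept", 1.0)
    Xmat, names = _covariate_design(X_df)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError(f"rank-deficient design: columns {names}")
    if Y.shape[0] < Xmat.shape[1] + 2:
        raise ValueError("too few subjects for the design")
    try:
        c_idx = names.index(contrast)
    except ValueError as err:
        raise KeyError(f"contrast column {contrast!r} not in design ({names})") from err

    def tmap(Xm):
        pinv = np.linalg.pinv(Xm)
        beta = pinv @ Y
        resid = Y - Xm @ beta
        dof = Y.shape[0] - Xm.shape[1]
        sigma2 = np.sum(resid**2, axis=0) / dof
        XtX_inv_cc = (pinv @ pinv.T)[c_idx, c_idx]
        se = np.sqrt(sigma2 * XtX_inv_cc)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(se > 0, beta[c_idx] / se, 0.0), dof

    t_obs, dof = tmap(Xmat)
    if method == "holm":
        p_raw = 2 * stats.t.sf(np.abs(t_obs), dof)
        p_fwe, sig = holm_correct(p_raw, alpha=cfg.alpha)
    elif method == "max-t":
        rng = np.random.default_rng(cfg.seed)
        n_perm = int(cfg.n_permutations)
        max_null = np.empty(n_perm)
        Xp = Xmat.copy()
        for b in range(n_perm):
            Xp[:, c_idx] = rng.permutation(Xmat[:, c_idx])
            t_b, _ = tmap(Xp)
            max_null[b] = np.max(np.abs(t_b))
        p_fwe = (1 + np.sum(max_null[None, :] >= np.abs(t_obs)[:, None], axis=1)) / (n_perm + 1)
        sig = p_fwe <= cfg.alpha
    else:
        raise ValueError("method must be 'max-t' or 'holm'")
    return {"t": t_obs, "p_fwe": np.asarray(p_fwe), "significant": np.asarray(sig), "df": dof}


@dataclass
class CoefficientScoreModel:
    """Per-term linear models of TSM coefficients on a behavioural score."""

    slopes: np.ndarray          # per term (including the intercept term, index 0)
    intercepts: np.ndarray
    terms: list
    score_range: tuple
    score_mean: float


def fit_coefficient_score_model(coeffs, scores, intercepts=None):
    """Fit, per TSM term, an OLS line of coefficient on score.

    `coeffs` is the subjects x terms matrix of TSM coefficients; if the
    per-subject model intercepts are supplied they are modelled as an extra
    leading term so full maps can be reconstructed at a score point.
    """
    X = np.atleast_2d(np.asarray(coeffs, dtype=float))
    s = np.asarray(scores, dtype=float).ravel()
    if s.size != X.shape[0]:
        raise ValueError("score length does not match coefficient rows")
    terms = list(coeffs.columns) if isinstance(coeffs, pd.DataFrame) else [
        f"term_{j}" for j in range(X.shape[1])
    ]
    if intercepts is not None:
        X = np.column_stack([np.asarray(intercepts, dtype=float), X])
        terms = ["intercept"] + terms
    D = np.column_stack([np.ones(s.size), s])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return CoefficientScoreModel(
        slopes=beta[1], intercepts=beta[0], terms=terms,
        score_range=(float(s.min()), float(s.max())), score_mean=float(s.mean()),
    )


def reconstruct_at_score(model, score_points, basis, average_model, axis="z"):
    """Reconstruct the gradient surface predicted at given score points and
    profile its RMSE against the cohort-average surface.

    For each score point the per-term linear models predict a full TSM
    coefficient vector, the surface is evaluated on `basis`, and the RMSE to
    `average_model`'s coefficients is computed over the terms of the selected
    axis (default z, the canonical gradient direction).  Score points outside
    the observed range trigger an extrapolation warning, not an error.

    Returns a DataFrame with columns score, rmse and a list of reconstructed
    maps aligned with the rows.
    """
    pts = np.asarray(score_points, dtype=float).ravel()
    lo, hi = model.score_range
    outside = (pts < lo) | (pts > hi)
    if outside.any():
        warnings.warn(
            f"score point(s) {pts[outside].tolist()} outside the observed range "
            f"[{lo:.3g}, {hi:.3g}]; extrapolating",
            RuntimeWarning,
        )
    has_intercept = model.terms and model.terms[0] == "intercept"
    body_terms = model.terms[1:] if has_intercept else model.terms
    if body_terms != list(basis.terms):
        raise ValueError("score model terms do not match the basis term layout")
    maps, rows = [], []
    for s in pts:
        pred = model.intercepts + model.slopes * s
        if has_intercept:
            intercept, coefs = pred[0], pred[1:]
        else:
            intercept, coefs = average_model.intercept, pred
        tsm = TSMModel(
            order=basis.order, intercept=float(intercept), coefficients=coefs,
            terms=list(basis.terms), bic=np.nan, explained_variance=np.nan, residual_ss=np.nan,
        )
        maps.append(reconstruct(tsm, basis))
        rmse = rmse_coefficients(
            coefs, average_model.coefficients, terms=basis.terms, axis=axis
        )
        rows.append({"score": float(s), "rmse": rmse})
    return pd.DataFrame(rows), maps
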