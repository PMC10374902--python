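"""Connection-topography ("connectopy") estimation.

The central idea: each voxel inside a region of interest (ROI) has a
*connectivity fingerprint* — the vector of Pearson correlations between its
time series and a set of signals summarising the rest of the brain.  Voxels
whose fingerprints are similar are placed at nearby positions on a
one-dimensional coordinate by spectral embedding (Laplacian eigenmaps) of an
eta-squared similarity graph.  The resulting per-voxel coordinate, scaled to
[0, 1], is the connectopy: a smoothly varying map of how connectivity to the
rest of the brain changes across the ROI.

The computation pipeline is

    standardize -> svd_reduce (rest of brain) -> compute_fingerprints
                -> eta2_similarity -> laplacian_eigenmaps -> align_connectopy

and is wrapped by the :class:`ConnectopicMapping` estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

__all__ = [
    "Connectopy",
    "ConnectopicMapping",
    "standardize",
    "svd_reduce",
    "compute_fingerprints",
    "eta2_similarity",
    "laplacian_eigenmaps",
    "align_connectopy",
    "spatial_correlation",
]


@dataclass
class Connectopy:
    """A per-ROI-voxel gradient map scaled to [0, 1].

    Attributes
    ----------
    values : ndarray, shape (V_roi,)
        Min-max scaled eigenvector; 0 and 1 are attained.
    eigenvalue : float
        Generalized eigenvalue of the graph Laplacian (ascending order,
        trivial eigenvector excluded).
    rank : int
        Which non-trivial eigenvector this is (1 = primary).
    roi : str or None
        Optional ROI / hemisphere tag.
    condition : str or None
        Optional acquisition condition tag (e.g. "rest" or "task").
    qc_passed : bool or None
        Set by :func:`align_connectopy`; None until reference QC is run.
    reference_r : float or None
        Pearson correlation with the reference map after sign alignment.
    warnings : list of str
        Numerical warnings recorded during estimation (e.g. near-degenerate
        eigenvalues).
    """

    values: np.ndarray
    eigenvalue: float
    rank: int = 1
    roi: str | None = None
    condition: str | None = None
    qc_passed: bool | None = None
    reference_r: float | None = None
    warnings: list = field(default_factory=list)


def standardize(data, ddof=1):
    """Standardize each column (voxel) of a time x voxel matrix to mean 0, unit variance.

    Raises ``ValueError`` listing the offending voxel indices if any column
    has zero variance (those voxels must be handled by QC upstream).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D time x voxel matrix")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance voxel column(s) at indices {bad.tolist()}; "
            "exclude them before standardizing (insufficient variance)"
        )
    return (data - mean) / sd


def svd_reduce(data, tol=1e-10, return_basis=False):
    """Lossless SVD reduction of the out-of-ROI data.

    Computes the economy SVD ``X = U S V^T`` of the standardized
    time x voxel matrix and returns ``U S`` (time x C), keeping components with
    singular value ``s_c > tol * s_max``.  Because ``U S = X V`` with V
    orthonormal, all inner products among voxel-wise covariance fingerprints
    are preserved exactly; with ``return_basis=True`` the basis ``V`` is also
    returned so voxel-space fingerprints can be reconstructed
    (``F_vox = F_comp @ V.T``).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("expected a time x voxel matrix with T >= 2, N >= 1")
    if not np.any(X):
        raise ValueError("all-zero input has no SVD components")
    U, s, Vt = linalg.svd(X, full_matrices=False)
    keep = s > tol * s[0]
    components = U[:, keep] * s[keep]
    if return_basis:
        return components, Vt[keep].T
    return components


def compute_fingerprints(roi_data, components):
    """Pearson-correlation fingerprints of ROI voxels against reference signals.

    Entry (i, c) is the correlation between ROI voxel i's time series and
    component c's time series.  Both inputs are time x columns with equal T.
    """
    roi = np.asarray(roi_data, dtype=float)
    comp = np.asarray(components, dtype=float)
    if roi.shape[0] != comp.shape[0]:
        raise ValueError(
            f"time dimensions differ: roi T={roi.shape[0]}, components T={comp.shape[0]}"
        )
    comp_sd = comp.std(axis=0, ddof=1)
    if np.any(comp_sd == 0):
        raise ValueError("zero-variance component")
    rz = roi - roi.mean(axis=0)
    cz = comp - comp.mean(axis=0)
    roi_sd = rz.std(axis=0, ddof=1)
    if np.any(roi_sd == 0):
        raise ValueError("zero-variance ROI voxel")
    T = roi.shape[0]
    fp = (rz.T @ cz) / ((T - 1) * np.outer(roi_sd, comp_sd))
    return np.clip(fp, -1.0, 1.0)


def eta2_similarity(fp):
    """Eta-squared similarity between all pairs of fingerprint profiles.

    For profiles a, b over C coordinates, with per-coordinate pair means
    ``m_c = (a_c + b_c) / 2`` and grand mean ``M = mean(m)``::

        eta2(a, b) = 1 - sum_c[(a_c - m_c)^2 + (b_c - m_c)^2]
                       / sum_c[(a_c - M)^2 + (b_c - M)^2]

    i.e. one minus the within-pair fraction of the total variance.  The result
    is symmetric, has unit diagonal and entries in [0, 1].
    """
    F = np.asarray(fp, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least 2 fingerprint rows")
    V, C = F.shape
    sq = np.einsum("ij,ij->i", F, F)  # ||a||^2
    mu = F.mean(axis=1)  # per-profile means
    gram = F @ F.T
    # numerator: ||a - b||^2 / 2
    num = 0.5 * (sq[:, None] + sq[None, :] - 2 * gram)
    # denominator: ||a||^2 + ||b||^2 - 2 C Mbar^2, Mbar = (mu_a + mu_b) / 2
    mbar = 0.5 * (mu[:, None] + mu[None, :])
    den = sq[:, None] + sq[None, :] - 2 * C * mbar**2
    if np.any((den <= 0) & (num > 0)) or np.any(den == 0):
        raise ValueError("degenerate profile pair: zero total variance (constant identical profiles)")
    eta = 1.0 - num / den
    eta = np.clip(eta, 0.0, 1.0)
    np.fill_diagonal(eta, 1.0)
    return 0.5 * (eta + eta.T)


def _knn_sparsify(W, k):
    """Symmetrized k-nearest-neighbour sparsification of a dense affinity."""
    V = W.shape[0]
    keep = np.zeros_like(W, dtype=bool)
    order = np.argsort(W, axis=1)[:, ::-1]
    for i in range(V):
        keep[i, order[i, :k]] = True
    keep |= keep.T
    return np.where(keep, W, 0.0)


def laplacian_eigenmaps(sim, n_maps=1, knn=None, residual_tol=1e-8):
    """Spectral embedding of an eta-squared similarity graph.

    The similarity matrix (diagonal zeroed) is treated as a weighted graph
    adjacency W; with degree matrix ``D = diag(row sums)`` and Laplacian
    ``L = D - W``, the generalized eigenproblem ``L v = lambda D v`` is solved.
    Eigenvalues are sorted ascending, the trivial (lambda ~ 0, constant)
    eigenvector is discarded and the next `n_maps` eigenvectors are returned
    min-max scaled to [0, 1].

    Parameters
    ----------
    sim : ndarray (V, V)
        Symmetric similarity matrix with unit diagonal.
    n_maps : int
        Number of non-trivial gradients to return (1 = primary only).
    knn : int or None
        If given, symmetrized k-nearest-neighbour sparsification is applied
        before building the graph (useful for large ROIs); default dense.

    Returns
    -------
    list of :class:`Connectopy`
    """
    S = np.asarray(sim, dtype=float)
    V = S.shape[0]
    if S.ndim != 2 or S.shape[1] != V:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    W = S.copy()
    np.fill_diagonal(W, 0.0)
    if knn is not None:
        W = _knn_sparsify(W, int(knn))
    n_comp, labels = connected_components(sparse.csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"similarity graph is disconnected: component sizes {sizes}")
    d = W.sum(axis=1)
    # random-walk normalization via the symmetric form:
    # D^-1/2 L D^-1/2 u = lambda u, v = D^-1/2 u
    dinv_sqrt = 1.0 / np.sqrt(d)
    Lsym = -(W * dinv_sqrt[:, None]) * dinv_sqrt[None, :]
    np.fill_diagonal(Lsym, 1.0 + Lsym.diagonal())
    Lsym = 0.5 * (Lsym + Lsym.T)
    evals, evecs = linalg.eigh(Lsym, subset_by_index=[0, min(n_maps + 1, V - 1)])
    vecs = evecs * dinv_sqrt[:, None]

    # identify and discard the trivial eigenvector
    lam0, v0 = evals[0], vecs[:, 0]
    cv0 = np.std(v0) / max(abs(np.mean(v0)), np.finfo(float).tiny)
    if not (lam0 < 1e-10 and cv0 < 1e-6):
        warnings.warn(
            "smallest eigenvector does not look trivial "
            f"(lambda={lam0:.3g}, cv={cv0:.3g}); returning it anyway as trivial",
            RuntimeWarning,
        )
    if evals.size < n_maps + 1:
        raise ValueError(f"requested {n_maps} maps but only {evals.size - 1} non-trivial eigenvectors exist")

    L = np.diag(d) - W
    out = []
    for r in range(1, n_maps + 1):
        lam, v = float(evals[r]), vecs[:, r]
        resid = np.max(np.abs(L @ v - lam * d * v)) / max(np.max(np.abs(v)), 1.0)
        if resid > residual_tol:
            warnings.warn(f"eigenpair residual {resid:.3g} exceeds {residual_tol}", RuntimeWarning)
        notes = []
        if r < evals.size - 1 and evals[r + 1] - lam < 1e-8 * max(lam, 1e-30):
            notes.append("near-degenerate eigenvalue: map orientation unstable")
        vmin, vmax = v.min(), v.max()
        scaled = (v - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(v)
        out.append(Connectopy(values=scaled, eigenvalue=lam, rank=r, warnings=notes))
    return out


def align_connectopy(connectopy, reference):
    """Sign-align a connectopy to a reference map and QC it.

    The eigenvector sign is arbitrary, so if the Pearson correlation with the
    reference is negative the map is flipped (``v -> 1 - v``).  Returns the
    (possibly flipped) connectopy with ``reference_r`` and ``qc_passed`` set:
    QC passes iff the post-flip correlation is at least 0.5, the conventional
    cut-off for a well-estimated individual gradient.
    """
    ref = np.asarray(reference, dtype=float)
    v = np.asarray(connectopy.values, dtype=float)
    if ref.shape != v.shape:
        raise ValueError("connectopy and reference have different voxel support")
    if np.ptp(ref) == 0:
        raise ValueError("constant reference map")
    r = float(np.corrcoef(v, ref)[0, 1])
    flipped = connectopy
    if r < 0:
        flipped = replace(connectopy, values=1.0 - v)
        r = -r
    flipped = replace(flipped, reference_r=r, qc_passed=bool(r >= 0.5))
    return flipped, r


def spatial_correlation(map_a, map_b, mask=None):
    """Voxel-wise Pearson correlation between two spatial maps.

    `mask` (boolean, same shape) restricts the comparison; both maps must be
    non-constant within it.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps have different shapes")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != a.shape:
            raise ValueError("mask shape differs from map shape")
        a, b = a[m], b[m]
    a, b = a.ravel(), b.ravel()
    if a.size == 0:
        raise ValueError("empty mask")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map within mask")
    return float(np.corrcoef(a, b)[0, 1])


class ConnectopicMapping(BaseEstimator):
    """Estimate connection topographies of an ROI from a 4-D time series matrix.

    Parameters
    ----------
    roi_mask : boolean array, shape (n_voxels,)
        Marks which columns of the fitted matrix belong to the ROI; the
        remaining columns are the "rest of brain" whose SVD components serve
        as fingerprint targets.
    n_maps : int, default 1
        Number of gradients to estimate (1 = primary connectopy only).
    similarity : {"eta2", "correlation"}, default "eta2"
        Fingerprint similarity kernel.  "correlation" uses the plain Pearson
        correlation between fingerprint profiles (shifted to [0, 1]).
    knn : int or None, default None
        Optional k-nearest-neighbour sparsification of the similarity graph.
    svd_tol : float, default 1e-10
        Relative singular-value cut-off of the lossless reduction.

    Attributes
    ----------
    connectopies_ : list of :class:`Connectopy`
    maps_ : ndarray (V_roi, n_maps)
        Min-max scaled gradient values, primary first.
    eigenvalues_ : ndarray (n_maps,)
    fingerprints_ : ndarray (V_roi, C)
    similarity_ : ndarray (V_roi, V_roi)
    components_ : ndarray (T, C)
    svd_basis_ : ndarray (N_out, C)
        Right-singular basis of the reduction (voxel-space reconstruction).
    """

    def __init__(self, roi_mask=None, n_maps=1, similarity="eta2", knn=None, svd_tol=1e-10):
        self.roi_mask = roi_mask
        self.n_maps = n_maps
        self.similarity = similarity
        self.knn = knn
        self.svd_tol = svd_tol

    def fit(self, X, y=None):
        """Fit on a time x voxel matrix containing both ROI and out-of-ROI columns."""
        X = np.asarray(X, dtype=float)
        if self.roi_mask is None:
            raise ValueError("roi_mask must be provided")
        roi = np.asarray(self.roi_mask, dtype=bool)
        if roi.size != X.shape[1]:
            raise ValueError(
                f"roi_mask length {roi.size} does not match n_voxels {X.shape[1]}"
            )
        if roi.sum() < 2:
            raise ValueError("degenerate ROI: need at least 2 ROI voxels")
        if (~roi).sum() < 1:
            raise ValueError("no out-of-ROI voxels to fingerprint against")
        roi_z = standardize(X[:, roi])
        out_z = standardize(X[:, ~roi])
        self.components_, self.svd_basis_ = svd_reduce(out_z, tol=self.svd_tol, return_basis=True)
        self.fingerprints_ = compute_fingerprints(roi_z, self.components_)
        if self.similarity == "eta2":
            self.similarity_ = eta2_similarity(self.fingerprints_)
        elif self.similarity == "correlation":
            self.similarity_ = (np.corrcoef(self.fingerprints_) + 1.0) / 2.0
        else:
            raise ValueError(f"unknown similarity kernel {self.similarity!r}")
        self.connectopies_ = laplacian_eigenmaps(self.similarity_, n_maps=self.n_maps, knn=self.knn)
        self.maps_ = np.column_stack([c.values for c in self.connectopies_])
        self.eigenvalues_ = np.array([c.eigenvalue for c in self.connectopies_])
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the ROI gradient coordinates, shape (V_roi, n_maps)."""
        return self.fit(X).maps_
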