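"""Synthetic fMRI phantoms with a planted connection topography.

Real connectopic-mapping inputs (multi-site clinical resting-state cohorts)
are access-controlled, so validation runs on phantoms built to exercise every
downstream stage against a known ground truth:

* ROI voxels mix K "network" time courses with Gaussian-bump weights whose
  centres move smoothly along one spatial axis — so the ROI's connectivity to
  the rest of the (phantom) brain varies smoothly along that axis, exactly
  the structure a connectopy should recover.
* The out-of-ROI "brain" consists of K contiguous slabs, one per network.
* A per-subject flatness parameter theta in (0, 1] compresses the planted
  gradient coordinate around 0.5 (theta = 1: full gradient; theta -> 0: flat),
  emulating reduced functional differentiation of the ROI.
* Simulated cohorts couple flatness linearly to a behavioural score and add
  age / sex / site nuisance covariates and case-control labels.

Everything is reproducible from integer seeds; each subject draws from an
independent stream derived from (seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BoldVolume, voxel_index_table

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "SubjectPhantom",
    "generate_phantom",
    "generate_cohort",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of a single phantom.

    The default geometry (12 x 8 x 12 grid, 6 x 6 x 10 ROI, 4 networks,
    200 volumes, noise sd 0.5) is the standard validation condition used
    throughout the test-bench: at this noise level the gradient is clearly
    present but far from noise-free.
    """

    grid_dims: tuple = (12, 8, 12)
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    roi_extent: tuple = ((1, 7), (1, 7), (1, 11))  # half-open voxel box per axis
    n_networks: int = 4
    gradient_axis: str = "z"
    flatness: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_dims) != 3 or any(int(d) < 1 for d in self.grid_dims):
            raise ValueError("grid_dims must be three positive integers")
        if self.n_timepoints < 30:
            raise ValueError("need at least 30 timepoints")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.gradient_axis not in _AXES:
            raise ValueError("gradient_axis must be one of 'x', 'y', 'z'")
        if not (0 < self.flatness <= 1):
            raise ValueError("flatness must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        for ax, (lo, hi) in enumerate(self.roi_extent):
            if not (0 <= lo < hi <= self.grid_dims[ax]):
                raise ValueError(f"roi_extent on axis {ax} not inside the grid")
        n_roi = np.prod([hi - lo for lo, hi in self.roi_extent])
        if n_roi < 2:
            raise ValueError("degenerate ROI: a single voxel cannot carry a gradient")
        if self.roi_extent[0][1] >= self.grid_dims[0]:
            raise ValueError("no room for out-of-ROI network slabs beyond the ROI along x")
        if self.grid_dims[2] < self.n_networks:
            raise ValueError("grid too short along z to host one slab per network")

    @property
    def roi_shape(self):
        return tuple(hi - lo for lo, hi in self.roi_extent)


@dataclass
class PhantomTruth:
    """Ground truth of a phantom: planted gradient coordinate per ROI voxel
    (canonical voxel order), network slab assignment per out-of-ROI voxel and
    the realized flatness."""

    gradient_coord: np.ndarray
    network_assignment: np.ndarray
    flatness: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    ``score = score_intercept + effect_slope * theta_s + N(0, score_noise_sd)``
    with per-subject flatness theta_s drawn uniformly from ``flatness_range``
    (shifted by ``group_flatness_shift`` for the case group, clipped to (0, 1]).
    Score scale and covariate defaults are patterned on adaptive-behaviour
    standard scores and an adolescent multi-site cohort (score intercept 70,
    age 17 +- 5 years, two-thirds male, 3 sites).
    """

    n_subjects: int = 20
    effect_slope: float = 0.0
    score_intercept: float = 70.0
    score_noise_sd: float = 2.0
    group_flatness_shift: float = 0.0
    flatness_range: tuple = (0.3, 1.0)
    age_mean: float = 17.0
    age_sd: float = 5.0
    sex_p_male: float = 0.66
    n_sites: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        lo, hi = self.flatness_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("flatness_range must satisfy 0 < lo <= hi <= 1")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")
        if not (0 <= self.sex_p_male <= 1):
            raise ValueError("sex_p_male must be a probability")
        if self.n_sites < 1:
            raise ValueError("need at least one site")


@dataclass
class SubjectPhantom:
    """One simulated subject: volume, masks and ground truth."""

    subject_id: str
    spec: PhantomSpec
    bold: BoldVolume | None
    roi_mask: np.ndarray
    brain_mask: np.ndarray
    truth: PhantomTruth


def _network_timecourses(rng, K, T):
    """K band-limited network signals: white noise smoothed with a width-3
    moving average, sample-orthonormalized (QR) and standardized.

    Orthonormalization makes the planted fingerprint geometry exactly
    identifiable: with only a handful of networks, random sample correlations
    among the raw courses would warp the gradient the downstream stages are
    supposed to recover.
    """
    kernel = np.ones(3) / 3.0
    tau = np.array([np.convolve(rng.standard_normal(T + 2), kernel, mode="valid") for _ in range(K)])
    tau -= tau.mean(axis=1, keepdims=True)
    Q, R = np.linalg.qr(tau.T)
    tau = Q.T * np.sign(np.diag(R))[:, None]
    tau -= tau.mean(axis=1, keepdims=True)
    tau /= tau.std(axis=1, keepdims=True)
    return tau


def phantom_masks(spec):
    """ROI mask, brain mask and per-voxel network labels of a phantom geometry.

    The out-of-ROI region sits beyond the ROI along x and is split into K
    contiguous slabs along z (network k occupies slab k, ascending z, matching
    the ordering of the gradient bump centres).  Voxels outside ROI and slabs
    are not part of the brain.
    """
    X, Y, Z = spec.grid_dims
    (x0, x1), (y0, y1), (z0, z1) = spec.roi_extent
    roi = np.zeros(spec.grid_dims, dtype=bool)
    roi[x0:x1, y0:y1, z0:z1] = True
    labels = np.full(spec.grid_dims, -1, dtype=int)
    z_slabs = np.array_split(np.arange(Z), spec.n_networks)
    for k, zz in enumerate(z_slabs):
        labels[x1:X, :, zz.min() : zz.max() + 1] = k
    brain = roi | (labels >= 0)
    labels[roi] = -1
    return roi, brain, labels


def generate_phantom(spec):
    """Generate one phantom volume with a planted smooth gradient.

    Returns ``(bold, roi_mask, brain_mask, truth)``.  ROI voxel i's series is
    ``sum_k w_k(g_i) tau_k(t) + sigma eps`` with g_i = 0.5 + theta (p_i - 0.5)
    for normalized position p_i along the gradient axis; bump weights
    ``w_k(g) = exp(-(g - c_k)^2 / (2 (1/K)^2))`` with centres c_k equally
    spaced on [0, 1] make the topography smooth rather than parcellated.
    Out-of-ROI voxel in slab k carries ``tau_k(t) + sigma eps``.
    Deterministic given the spec (bit-identical on repeated calls).
    """
    rng = np.random.default_rng(np.random.SeedSequence([2**16 + int(spec.seed)]))
    K, T = spec.n_networks, spec.n_timepoints
    roi, brain, labels = phantom_masks(spec)
    tau = _network_timecourses(rng, K, T)

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    roi_table = voxel_index_table(roi, affine)
    ax = _AXES[spec.gradient_axis]
    pos = roi_table[["i", "j", "k"]].to_numpy()[:, ax].astype(float)
    span = pos.max() - pos.min()
    if span == 0:
        raise ValueError("ROI is a single plane along the gradient axis; no gradient possible")
    p = (pos - pos.min()) / span
    g = 0.5 + spec.flatness * (p - 0.5)

    # Bump SD = 1/K places adjacent centres (spacing 1/(K-1)) about 1.3 SD
    # apart, so neighbouring networks genuinely overlap and the planted
    # topography is smooth rather than parcellated.
    centres = np.linspace(0.0, 1.0, K)
    sd_bump = 1.0 / K
    W = np.exp(-((g[:, None] - centres[None, :]) ** 2) / (2.0 * sd_bump**2))

    data = np.zeros(spec.grid_dims + (T,))
    ii, jj, kk = roi_table["i"].to_numpy(), roi_table["j"].to_numpy(), roi_table["k"].to_numpy()
    data[ii, jj, kk, :] = W @ tau

    out_table = voxel_index_table(brain & ~roi, affine)
    oi, oj, ok = out_table["i"].to_numpy(), out_table["j"].to_numpy(), out_table["k"].to_numpy()
    assignment = labels[oi, oj, ok]
    data[oi, oj, ok, :] = tau[assignment]

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(int(brain.sum()), T))
        bi, bj, bk = np.nonzero(brain)
        data[bi, bj, bk, :] += noise

    bold = BoldVolume(data=data, affine=affine, tr_seconds=spec.tr_seconds)
    truth = PhantomTruth(gradient_coord=g, network_assignment=assignment, flatness=spec.flatness)
    return bold, roi, brain, truth


def _subject_seed(seed, index):
    """Independent, reproducible per-subject seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(pspec, cspec, volumes=True):
    """Simulate a cohort of phantoms plus its behavioural table.

    Each subject s draws flatness theta_s ~ U(flatness_range) (cases shifted
    by ``group_flatness_shift``), receives its own phantom with that flatness
    (independent random stream per subject) and a score linearly coupled to
    theta_s.  ``volumes=False`` skips the (relatively expensive) 4-D volume
    synthesis when only the table / ground truth is needed.

    Returns ``(subjects, table)`` where `subjects` is a list of
    :class:`SubjectPhantom` and `table` a DataFrame with columns
    subject_id, group, score, age, sex, site.
    """
    if cspec.n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([3**7, int(cspec.seed)]))
    n = cspec.n_subjects
    groups = np.array(["control"] * (n - n // 2) + ["case"] * (n // 2))
    rng.shuffle(groups)

    lo, hi = cspec.flatness_range
    theta = rng.uniform(lo, hi, size=n)
    theta = np.where(groups == "case", theta + cspec.group_flatness_shift, theta)
    theta = np.clip(theta, 1e-3, 1.0)

    score = (
        cspec.score_intercept
        + cspec.effect_slope * theta
        + rng.normal(0.0, cspec.score_noise_sd, size=n)
    )
    age = rng.normal(cspec.age_mean, cspec.age_sd, size=n).clip(6, 45)
    sex = np.where(rng.random(n) < cspec.sex_p_male, "M", "F")
    site = np.array([f"site{1 + i}" for i in rng.integers(0, cspec.n_sites, size=n)])

    subjects = []
    rows = []
    for s in range(n):
        sid = f"sub-{s + 1:03d}"
        sspec = replace(pspec, flatness=float(theta[s]), seed=_subject_seed(cspec.seed, s))
        if volumes:
            bold, roi, brain, truth = generate_phantom(sspec)
        else:
            roi, brain, labels = phantom_masks(sspec)
            bold = None
            truth = PhantomTruth(
                gradient_coord=np.empty(0), network_assignment=np.empty(0, dtype=int),
                flatness=float(theta[s]),
            )
        subjects.append(SubjectPhantom(sid, sspec, bold, roi, brain, truth))
        rows.append(
            {"subject_id": sid, "group": groups[s], "score": score[s],
             "age": age[s], "sex": sex[s], "site": site[s]}
        )
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table["score"])):
        raise ValueError("non-finite scores generated")
    return subjects, table
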