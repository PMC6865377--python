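"""Smoothing, absolute-volume accounting, and voxelwise statistics.

The single-case map compares one subject against a control group with the
two-group GLM t for group sizes 1 and n,

    t = (x_subject - mean_controls) / (s_controls * sqrt(1 + 1/n)),  df = n - 1,

algebraically identical to the Crawford-Howell statistic for a single case.
Group comparisons use the paired t on per-subject differences with a
Bonferroni family-wise-error threshold over in-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from ._util import _FWHM_TO_SIGMA, as_volume, check_same_grid

__all__ = [
    "SmoothingSpec",
    "TMap",
    "VolumeReport",
    "SingleCaseTTest",
    "smooth_volume",
    "tissue_volume",
    "compute_tiv",
    "analysis_mask",
    "individual_tmap",
    "paired_tmap",
    "DEFAULT_FWHM_GRID",
]

#: smoothing grid in mm FWHM
DEFAULT_FWHM_GRID = (4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0)


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian kernel: FWHM in mm, isotropic voxels, truncated at
    ``truncation`` sigmas and renormalized (scipy normalizes the truncated
    kernel to sum 1)."""

    fwhm: float
    voxel_size: float
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def sigma_voxels(self) -> float:
        return self.fwhm / (self.voxel_size * _FWHM_TO_SIGMA)


@dataclass
class TMap:
    t: np.ndarray
    df: int
    mask: np.ndarray
    direction: str  # "increase" | "decrease"


@dataclass(frozen=True)
class VolumeReport:
    gm_ml: float
    wm_ml: float
    csf_ml: float
    tiv_ml: float


def smooth_volume(vol, spec: SmoothingSpec) -> np.ndarray:
    """Separable 3-D Gaussian convolution with replicate ("nearest") padding."""
    vol = as_volume(vol)
    return ndimage.gaussian_filter(vol, sigma=spec.sigma_voxels, mode="nearest",
                                   truncate=spec.truncation)


def tissue_volume(prob_map, voxel_size: float) -> float:
    """Sum of probabilities times voxel volume, in milliliters."""
    p = np.asarray(prob_map, dtype=float)
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError("probability map values outside [0, 1]")
    return float(p.sum() * voxel_size**3 / 1000.0)


def compute_tiv(gm_ml: float, wm_ml: float, csf_ml: float) -> VolumeReport:
    if min(gm_ml, wm_ml, csf_ml) < 0:
        raise ValueError("tissue volumes must be nonnegative")
    return VolumeReport(gm_ml=gm_ml, wm_ml=wm_ml, csf_ml=csf_ml,
                        tiv_ml=gm_ml + wm_ml + csf_ml)


def analysis_mask(control_maps, threshold: float = 0.1) -> np.ndarray:
    """Voxels with mean control signal above ``threshold`` and nonzero
    between-control variance."""
    stack = np.stack([as_volume(m, "control map") for m in control_maps])
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 control maps")
    mask = (stack.mean(axis=0) > threshold) & (stack.var(axis=0) > 0)
    if not mask.any():
        raise ValueError("analysis mask is empty at this threshold")
    return mask


class SingleCaseTTest(BaseEstimator):
    """Single-subject-versus-group voxelwise t, sklearn style.

    ``fit(X)`` with X = (n_controls, n_voxels) stores the control mean and
    SD; ``transform(X)`` maps subject rows to t rows with
    df_ = n_controls - 1. Zero-variance voxels yield 0 and are reported in
    ``valid_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be (n_controls >= 2, n_voxels)")
        self.n_controls_ = X.shape[0]
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.valid_ = self.sd_ > 0
        self.df_ = self.n_controls_ - 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scale = np.where(self.valid_, self.sd_, 1.0) * np.sqrt(1.0 + 1.0 / self.n_controls_)
        t = (X - self.mean_[None, :]) / scale[None, :]
        t[:, ~self.valid_] = 0.0
        return t


def individual_tmap(subject_map, control_maps, mask, direction: str = "increase") -> TMap:
    """Crawford-Howell t-map of one subject against a control group.

    The subject must not be a member of the control set (leave-one-out
    contract for control-vs-rest comparisons). ``direction='decrease'``
    negates the map so that supra-threshold voxels always mean evidence in
    the requested direction. Zero-variance voxels are dropped from the mask.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    subject = as_volume(subject_map, "subject map")
    controls = [as_volume(c, "control map") for c in control_maps]
    for c in controls:
        check_same_grid(subject, c)
        if np.array_equal(subject, c):
            raise ValueError("subject map is included in the control set")
    mask = np.asarray(mask, dtype=bool)
    check_same_grid(subject, mask, "mask")

    est = SingleCaseTTest().fit(np.stack([c[mask] for c in controls]))
    t_flat = est.transform(subject[mask][None, :])[0]
    if direction == "decrease":
        t_flat = -t_flat
    t = np.zeros_like(subject)
    t[mask] = t_flat
    out_mask = mask.copy()
    out_mask[mask] = est.valid_
    t[~out_mask] = 0.0
    return TMap(t=t, df=est.df_, mask=out_mask, direction=direction)


def paired_tmap(maps_a, maps_b, mask, fwe_alpha: float = 0.05) -> tuple[TMap, float]:
    """Voxelwise paired t of matched map lists, plus a Bonferroni threshold.

    Returns the t-map (df = n - 1, direction 'increase' meaning A > B) and
    the critical t whose two-sided tail probability equals
    ``fwe_alpha / n_in_mask_voxels``. Voxels with zero difference variance
    (including A == B everywhere) are masked out.
    """
    a = [as_volume(m) for m in maps_a]
    b = [as_volume(m) for m in maps_b]
    if len(a) != len(b):
        raise ValueError("paired map lists must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mask = np.asarray(mask, dtype=bool)
    diffs = np.stack([x - y for x, y in zip(a, b)])
    mean_d = diffs.mean(axis=0)
    sd_d = diffs.std(axis=0, ddof=1)
    valid = mask & (sd_d > 0)
    t = np.zeros_like(mean_d)
    t[valid] = mean_d[valid] / (sd_d[valid] / np.sqrt(n))
    df = n - 1
    m_voxels = int(valid.sum())
    if m_voxels == 0:
        raise ValueError("no voxels with nonzero difference variance in mask")
    t_fwe = float(stats.t.isf(fwe_alpha / (2 * m_voxels), df))
    return TMap(t=t, df=df, mask=valid, direction="increase"), t_fwe
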