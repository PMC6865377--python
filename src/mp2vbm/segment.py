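"""Multispectral tissue segmentation via a full-covariance Gaussian mixture.

A deliberately simple, fully specified stand-in for unified segmentation:
voxel intensity vectors from 1-3 co-registered channels are modeled as a
mixture of multivariate Gaussians fit by EM (seeded k-means initialization,
optional per-voxel spatial prior multiplication in the E-step), and the
per-class posteriors become the GM/WM/CSF probability maps. There is no
bias-field estimation inside the segmentation (handled upstream by the
uniform-image reconstruction, or absent by design), no prior warping, and no
Markov-random-field cleanup.

Class-to-tissue assignment: when spatial priors are supplied, classes are
matched to prior columns by maximum posterior/prior agreement; otherwise the
first three classes are ordered by ascending mean on the first channel, which
yields (CSF, GM, WM) for T1-like, MP2 and INV1/INV2 first channels. Put a
channel with that ordering first, or pass priors, when using FLAIR-like
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .phantom import MultiContrastVolume, TissueProbabilityMaps

__all__ = [
    "MultispectralSegmenter",
    "SegmentationModel",
    "fit_segmentation",
    "misclassification_fraction",
]

TISSUE_ORDER = ("csf", "gm", "wm")


@dataclass
class SegmentationModel:
    """Fitted mixture summary: one row per class in tissue order."""

    class_names: tuple[str, ...]
    means: np.ndarray  # (n_classes, n_channels)
    covariances: np.ndarray  # (n_classes, n_channels, n_channels)
    weights: np.ndarray  # (n_classes,)
    converged: bool
    log_likelihood_trace: np.ndarray = field(repr=False)


class MultispectralSegmenter(BaseEstimator):
    """Full-covariance GMM-EM over voxel intensity vectors.

    scikit-learn estimator interface: ``fit(X)`` on an (n_voxels, n_channels)
    matrix (1-3 channels), ``predict_proba(X)`` for posteriors,
    ``predict(X)`` for hard labels. Spatial priors, if any, are passed as an
    (n_voxels, n_classes) matrix via the ``priors`` fit/predict keyword and
    multiply the likelihood voxelwise (posterior ∝ prior × weight ×
    likelihood).

    Parameters
    ----------
    n_classes : int, default 3
        Mixture components; must be >= 3 (CSF, GM, WM, then extras).
    max_iter, tol : EM stopping rule — relative log-likelihood change < tol.
    reg_covar : diagonal loading added to every covariance; increased with a
        warning if a covariance turns singular.
    init_subsample : voxel cap for the seeded k-means initialization.
    random_state : seed for subsampling and k-means.
    """

    def __init__(self, n_classes: int = 3, max_iter: int = 200, tol: float = 1e-5,
                 reg_covar: float = 1e-6, init_subsample: int = 50_000,
                 random_state: int = 0):
        self.n_classes = n_classes
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.init_subsample = init_subsample
        self.random_state = random_state

    # ---- internals ---------------------------------------------------
    def _log_prob(self, X: np.ndarray) -> np.ndarray:
        lp = np.empty((X.shape[0], self.n_classes))
        for k in range(self.n_classes):
            lp[:, k] = multivariate_normal.logpdf(
                X, mean=self.means_[k], cov=self.covariances_[k], allow_singular=True
            )
        return lp

    def _responsibilities(self, X, priors):
        lp = self._log_prob(X) + np.log(self.weights_)[None, :]
        if priors is not None:
            with np.errstate(divide="ignore"):
                lp = lp + np.log(np.asarray(priors, dtype=float))
        norm = logsumexp(lp, axis=1)
        resp = np.exp(lp - norm[:, None])
        return resp, float(norm.mean())

    def _init_parameters(self, X: np.ndarray, priors=None) -> None:
        n_ch = X.shape[1]
        if priors is not None:
            # prior-weighted moments: keeps class k aligned with prior column
            # k from the first E-step onward
            resp = priors / priors.sum(axis=1, keepdims=True).clip(min=1e-12)
            nk = resp.sum(axis=0) + 1e-12
            self.means_ = (resp.T @ X) / nk[:, None]
            covs = []
            for k in range(self.n_classes):
                diff = X - self.means_[k]
                covs.append((resp[:, k][:, None] * diff).T @ diff / nk[k]
                            + self.reg_covar * np.eye(n_ch))
            self.covariances_ = np.asarray(covs)
            self.weights_ = nk / nk.sum()
            return
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        idx = rng.choice(n, size=min(n, self.init_subsample), replace=False)
        km = KMeans(n_clusters=self.n_classes, n_init=1,
                    random_state=int(rng.integers(2**31 - 1))).fit(X[idx])
        self.means_ = km.cluster_centers_.copy()
        covs, weights = [], []
        global_cov = np.atleast_2d(np.cov(X[idx].T)) + self.reg_covar * np.eye(n_ch)
        for k in range(self.n_classes):
            members = X[idx][km.labels_ == k]
            if len(members) > n_ch + 1:
                c = np.atleast_2d(np.cov(members.T))
            else:
                c = global_cov.copy()
            covs.append(c + self.reg_covar * np.eye(n_ch))
            weights.append(max(len(members), 1))
        self.covariances_ = np.asarray(covs)
        self.weights_ = np.asarray(weights, dtype=float)
        self.weights_ /= self.weights_.sum()

    def _regularize(self) -> None:
        eye = np.eye(self.covariances_.shape[1])
        for k in range(self.n_classes):
            cov = self.covariances_[k] + self.reg_covar * eye
            tries = 0
            while tries < 8:
                try:
                    np.linalg.cholesky(cov)
                    break
                except np.linalg.LinAlgError:
                    load = self.reg_covar * 10 ** (tries + 1)
                    cov = cov + load * eye
                    tries += 1
            if tries:
                warnings.warn(
                    f"singular covariance for class {k}; applied diagonal loading",
                    RuntimeWarning, stacklevel=3,
                )
            self.covariances_[k] = cov

    def _reorder(self, order) -> None:
        self.means_ = self.means_[order]
        self.covariances_ = self.covariances_[order]
        self.weights_ = self.weights_[order]

    # ---- estimator API -----------------------------------------------
    def fit(self, X, y=None, priors=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_voxels, n_channels)")
        if not (1 <= X.shape[1] <= 3):
            raise ValueError("between 1 and 3 channels are supported")
        if X.shape[0] == 0:
            raise ValueError("mask is empty: no voxels to segment")
        if self.n_classes < 3:
            raise ValueError("n_classes must be >= 3 (CSF, GM, WM)")
        if priors is not None:
            priors = np.asarray(priors, dtype=float)
            if priors.shape != (X.shape[0], self.n_classes):
                raise ValueError("priors must be (n_voxels, n_classes)")

        self._init_parameters(X, priors)
        self._regularize()
        trace: list[float] = []
        self.converged_ = False
        for _ in range(self.max_iter):
            resp, ll = self._responsibilities(X, priors)
            if trace and ll + 1e-12 < trace[-1] - 1e-8 * abs(trace[-1]):
                # EM is monotone up to numerics; anything beyond that is a bug
                warnings.warn("log-likelihood decreased beyond tolerance",
                              RuntimeWarning, stacklevel=2)
            if trace and abs(ll - trace[-1]) < self.tol * max(abs(trace[-1]), 1e-12):
                trace.append(ll)
                self.converged_ = True
                break
            trace.append(ll)
            # M-step
            nk = resp.sum(axis=0) + 1e-12
            self.weights_ = nk / nk.sum()
            self.means_ = (resp.T @ X) / nk[:, None]
            for k in range(self.n_classes):
                diff = X - self.means_[k]
                self.covariances_[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            self._regularize()

        self.log_likelihood_trace_ = np.asarray(trace)
        # relabel classes to the tissue order
        if priors is not None:
            resp, _ = self._responsibilities(X, priors)
            agreement = resp.T @ priors  # (class, prior-column) co-assignment mass
            rows, cols = linear_sum_assignment(-agreement)
            order = np.empty(self.n_classes, dtype=int)
            order[cols] = rows
        else:
            order = np.argsort(self.means_[:, 0], kind="stable")
        self._reorder(order)
        names = list(TISSUE_ORDER) + [f"class{j}" for j in range(3, self.n_classes)]
        self.class_names_ = tuple(names[: self.n_classes])
        return self

    def predict_proba(self, X, priors=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        resp, _ = self._responsibilities(X, priors)
        return resp

    def predict(self, X, priors=None) -> np.ndarray:
        return np.argmax(self.predict_proba(X, priors), axis=1)

    def to_model(self) -> SegmentationModel:
        return SegmentationModel(
            class_names=self.class_names_, means=self.means_.copy(),
            covariances=self.covariances_.copy(), weights=self.weights_.copy(),
            converged=self.converged_,
            log_likelihood_trace=self.log_likelihood_trace_.copy(),
        )


def _stack_channels(channels, mask):
    vols = []
    if isinstance(channels, MultiContrastVolume):
        channels = list(channels.channels.values())
    for vol in channels:
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.shape:
            raise ValueError("channel grid does not match mask")
        vols.append(vol[mask])
    return np.column_stack(vols)


def fit_segmentation(
    channels,
    mask,
    n_classes: int = 3,
    priors=None,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
    voxel_size: float = 1.0,
):
    """Segment 1-3 channel volumes inside ``mask``.

    ``channels`` is a list of 3-D arrays (or a ``MultiContrastVolume``);
    ``priors``, if given, a list of ``n_classes`` prior probability volumes.
    Returns ``(SegmentationModel, TissueProbabilityMaps, posteriors)`` where
    posteriors is the full (n_classes, *grid) posterior stack (zero outside
    the mask) and the tissue maps hold its CSF/GM/WM slices.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    X = _stack_channels(channels, mask)
    prior_mat = None
    if priors is not None:
        prior_mat = np.column_stack([np.asarray(p, dtype=float)[mask] for p in priors])
    seg = MultispectralSegmenter(n_classes=n_classes, max_iter=max_iter, tol=tol,
                                 random_state=seed)
    seg.fit(X, priors=prior_mat)
    resp = seg.predict_proba(X, priors=prior_mat)

    grid = mask.shape
    posteriors = np.zeros((n_classes,) + grid)
    for k in range(n_classes):
        posteriors[k][mask] = resp[:, k]
    tpm = TissueProbabilityMaps(gm=posteriors[1], wm=posteriors[2], csf=posteriors[0],
                                mask=mask.copy(), voxel_size=voxel_size)
    return seg.to_model(), tpm, posteriors


def misclassification_fraction(posteriors, reference_mask, tissue: str = "gm") -> float:
    """Fraction of reference-mask voxels whose argmax class is ``tissue``.

    ``posteriors`` may be the (n_classes, *grid) stack from
    :func:`fit_segmentation` or a :class:`TissueProbabilityMaps`.
    """
    ref = np.asarray(reference_mask, dtype=bool)
    if not ref.any():
        raise ValueError("reference mask is empty")
    if isinstance(posteriors, TissueProbabilityMaps):
        stack = np.stack([posteriors.csf, posteriors.gm, posteriors.wm])
        names = list(TISSUE_ORDER)
    else:
        stack = np.asarray(posteriors, dtype=float)
        names = list(TISSUE_ORDER) + [f"class{j}" for j in range(3, stack.shape[0])]
    if tissue not in names:
        raise ValueError(f"unknown tissue {tissue!r}; have {names}")
    target = names.index(tissue)
    argmax = np.argmax(stack[:, ref], axis=0)
    return float(np.mean(argmax == target))
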