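"""Gaussian-mixture clustering of texture / Gabor feature vectors.

Features are z-scored per dimension before EM: GLCM mean lives in [0, G-1]
while GLCM contrast lives in [0, (G-1)^2], and EM on those raw scales
collapses onto the high-variance axis.  Fits use full covariance matrices,
five seeded restarts, a 1e-6 diagonal regularization floor, and run to a
relative log-likelihood tolerance of 1e-6 (at most 500 iterations), so a
fit is deterministic given the data and the seed.

The "lesion cluster" is selected either in oracle mode (the label of the
point nearest a known lesion center — reproducing evaluation against ground
truth) or heuristically (the non-background cluster with the highest mean
GLCM-mean feature, background being the most populous cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import ParameterError

__all__ = [
    "GMMFit",
    "Mask",
    "fit_gmm",
    "em_loglik_trace",
    "select_lesion_cluster",
    "mask_from_labels",
]


@dataclass(frozen=True)
class GMMFit:
    """A fitted mixture: parameters are in the z-scored feature space."""

    K: int
    weights: np.ndarray          # (K,), simplex
    means: np.ndarray            # (K, d), z-scored space
    covariances: np.ndarray      # (K, d, d)
    labels: np.ndarray           # (n,), argmax responsibilities
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    log_likelihood: float        # total log-likelihood of the training data
    seed: int
    feature_mean: np.ndarray     # (d,) standardization offset
    feature_scale: np.ndarray    # (d,) standardization scale

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.K)


@dataclass(frozen=True)
class Mask:
    """Boolean pixel field marking every pixel of the selected cluster's patches."""

    values: np.ndarray
    cluster_id: int
    row_starts: np.ndarray
    col_starts: np.ndarray
    window: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature dims pass through
    return (features - mu) / sd, mu, sd


def fit_gmm(features: np.ndarray, K: int, seed: int = 0, n_restarts: int = 5) -> GMMFit:
    """Fit a K-component full-covariance GMM by EM, best of seeded restarts."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("features must be an (n, d) array")
    if not np.all(np.isfinite(X)):
        raise ParameterError("features must be finite")
    n = X.shape[0]
    if K < 1 or K > n:
        raise ParameterError(f"K={K} must be in [1, n={n}]")

    Z, mu, sd = _standardize(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=K,
            covariance_type="full",
            tol=1e-6,
            max_iter=500,
            n_init=n_restarts,
            reg_covar=1e-6,
            random_state=seed,
        ).fit(Z)
    resp = gm.predict_proba(Z)
    labels = resp.argmax(axis=1)
    return GMMFit(
        K=K,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        labels=labels,
        responsibilities=resp,
        log_likelihood=float(gm.score(Z) * n),
        seed=seed,
        feature_mean=mu,
        feature_scale=sd,
    )


def em_loglik_trace(features: np.ndarray, K: int, seed: int = 0, n_iter: int = 50) -> np.ndarray:
    """Per-iteration log-likelihood of a single EM run (debug / diagnostics).

    Runs EM one iteration at a time from a seeded k-means init and records
    the total log-likelihood after each step; EM guarantees this sequence is
    non-decreasing.
    """
    X = np.asarray(features, dtype=np.float64)
    Z, _, _ = _standardize(X)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        tol=1e-12,
        max_iter=1,
        n_init=1,
        reg_covar=1e-6,
        warm_start=True,
        random_state=seed,
    )
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_iter):
            gm.fit(Z)
            trace.append(float(gm.score(Z) * Z.shape[0]))
    return np.array(trace)


def select_lesion_cluster(
    fit: GMMFit,
    point_locations: np.ndarray,
    lesion_center: tuple[float, float] | None = None,
    mode: str = "oracle",
    mean_feature_index: int = 0,
) -> int:
    """Pick the cluster taken to contain the lesion.

    oracle    — label of the point whose location is nearest ``lesion_center``.
    heuristic — background is the most populous cluster; among the rest,
                the cluster whose (z-scored) mean along
                ``mean_feature_index`` (the GLCM-mean dimension) is highest.
    """
    if mode == "oracle":
        if lesion_center is None:
            raise ParameterError("oracle mode requires lesion_center")
        locs = np.asarray(point_locations, dtype=np.float64)
        d2 = ((locs - np.asarray(lesion_center, dtype=np.float64)) ** 2).sum(axis=1)
        return int(fit.labels[np.argmin(d2)])
    if mode == "heuristic":
        sizes = fit.cluster_sizes()
        background = int(np.argmax(sizes))
        if fit.K == 1:
            return 0
        scores = fit.means[:, mean_feature_index].copy()
        scores[background] = -np.inf
        return int(np.argmax(scores))
    raise ParameterError(f"unknown mode {mode!r}")


def mask_from_labels(
    fit: GMMFit,
    cluster_id: int,
    row_starts: np.ndarray,
    col_starts: np.ndarray,
    window: int,
    image_shape: tuple[int, int],
) -> Mask:
    """Expand a patch-lattice labeling to a pixel mask of one cluster.

    ``fit.labels`` must be indexed row-major over the (row_starts x
    col_starts) patch lattice; every pixel of every patch carrying
    ``cluster_id`` becomes true.
    """
    if not 0 <= cluster_id < fit.K:
        raise ParameterError(f"cluster id {cluster_id} outside [0, {fit.K})")
    n_rows, n_cols = len(row_starts), len(col_starts)
    if fit.labels.size != n_rows * n_cols:
        raise ParameterError("labels do not index the patch lattice")
    grid = fit.labels.reshape(n_rows, n_cols)
    values = np.zeros(image_shape, dtype=bool)
    for a, r0 in enumerate(row_starts):
        for b, c0 in enumerate(col_starts):
            if grid[a, b] == cluster_id:
                values[r0 : r0 + window, c0 : c0 + window] = True
    return Mask(
        values=values,
        cluster_id=int(cluster_id),
        row_starts=np.asarray(row_starts),
        col_starts=np.asarray(col_starts),
        window=window,
    )
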