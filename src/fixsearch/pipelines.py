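"""Fixation-prediction pipelines and the feature-relation analyses.

Three runners produce fixation-candidate estimates from a single image:

* pipeline A (texture first) — GLCM mean/contrast on the patch lattice,
  5-component GMM, a pixel mask from the lesion cluster, then
  reversed-watershed maxima of the four Gabor maps screened by the mask;
* pipeline B (Gabor first) — regional maxima of the four Gabor maps,
  GLCM features on windows centered at each candidate, then a GMM over the
  six features (four Gabor responses + two texture features) retaining the
  lesion cluster;
* thresholded comparator — Gabor maxima kept above a response quantile.

`feature_correlation` quantifies the relation between GLCM mean and the
Gabor channel magnitudes; `gaze_overlap` scores recorded gaze points against
a candidate set.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import pearsonr

from .candidates import (
    CandidateSet,
    collect_candidates,
    regional_maxima,
    reversed_watershed_maxima,
    screen_by_mask,
    threshold_candidates,
)
from .clustering import fit_gmm, mask_from_labels, select_lesion_cluster
from .errors import InsufficientDataError, ParameterError
from .gabor import GaborBank, ResponseMaps, default_bank, response_maps
from .phantom import Image2D
from .texture import GLCMParams, TextureMaps, texture_at_locations, texture_maps

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "CorrelationReport",
    "run_pipeline_a",
    "run_pipeline_b",
    "run_thresholded",
    "feature_correlation",
    "gaze_overlap",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameter surface of the three runners.

    ``K_a`` / ``K_b`` are the mixture sizes of the texture-first and
    Gabor-first pipelines (defaults 5 and 3).  ``dedupe_radius`` defaults to
    half the target radius used to build the bank.  ``cluster_mode`` is
    ``"oracle"`` (requires a lesion center) or ``"heuristic"``.
    """

    glcm: GLCMParams = field(default_factory=GLCMParams)
    bank: GaborBank = field(default_factory=lambda: default_bank(100.0))
    target_radius_px: float = 100.0
    K_a: int = 5
    K_b: int = 3
    dedupe_radius: float | None = None
    threshold_quantile: float = 0.75
    cluster_mode: str = "oracle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_mode not in ("oracle", "heuristic"):
            raise ParameterError(f"unknown cluster_mode {self.cluster_mode!r}")
        if not 0 <= self.threshold_quantile < 1:
            raise ParameterError("threshold_quantile must be in [0, 1)")
        if self.K_a < 1 or self.K_b < 1:
            raise ParameterError("mixture sizes must be at least 1")

    @property
    def effective_dedupe_radius(self) -> float:
        if self.dedupe_radius is not None:
            return self.dedupe_radius
        return self.target_radius_px / 2.0

    def to_dict(self) -> dict:
        qr = self.glcm.quantization_range
        return {
            "glcm": {
                "G": self.glcm.G,
                "window": self.glcm.window,
                "stride": self.glcm.stride,
                "offsets": [list(o) for o in self.glcm.offsets],
                "quantization_range": list(qr) if isinstance(qr, tuple) else qr,
            },
            "bank": self.bank.to_dicts(),
            "target_radius_px": self.target_radius_px,
            "K_a": self.K_a,
            "K_b": self.K_b,
            "dedupe_radius": self.dedupe_radius,
            "threshold_quantile": self.threshold_quantile,
            "cluster_mode": self.cluster_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        g = dict(d.get("glcm", {}))
        if "offsets" in g:
            g["offsets"] = tuple(tuple(o) for o in g["offsets"])
        if isinstance(g.get("quantization_range"), list):
            tag, lo, hi = g["quantization_range"]
            g["quantization_range"] = (tag, lo, hi)
        kwargs = {k: v for k, v in d.items() if k not in ("glcm", "bank")}
        return cls(
            glcm=GLCMParams(**g),
            bank=GaborBank.from_dicts(d["bank"]) if "bank" in d else default_bank(
                d.get("target_radius_px", 100.0)
            ),
            **kwargs,
        )


@dataclass(frozen=True)
class PipelineResult:
    """Final candidate set plus every intermediate stage artifact."""

    final: CandidateSet
    intermediates: dict
    config: PipelineConfig
    timings: dict


def _timed(timings: dict, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    timings[name] = time.perf_counter() - t0
    return out


def run_pipeline_a(
    image: Image2D,
    config: PipelineConfig,
    lesion_center: tuple[float, float] | None = None,
) -> PipelineResult:
    """Texture-first pipeline: GLCM maps -> GMM mask -> screened Gabor maxima."""
    if config.cluster_mode == "oracle" and lesion_center is None:
        raise ParameterError("oracle cluster_mode requires lesion_center")
    timings: dict = {}
    tmaps = _timed(timings, "texture_maps", texture_maps, image, config.glcm)
    features = np.column_stack([tmaps.mean_map.ravel(), tmaps.contrast_map.ravel()])
    centers = tmaps.patch_centers.reshape(-1, 2)
    K = min(config.K_a, features.shape[0])
    if K < config.K_a:
        warnings.warn(f"only {features.shape[0]} patches; using K={K}", stacklevel=2)
    fit = _timed(timings, "fit_gmm", fit_gmm, features, K, config.seed)
    cluster = select_lesion_cluster(
        fit, centers, lesion_center, config.cluster_mode, mean_feature_index=0
    )
    mask = mask_from_labels(
        fit, cluster, tmaps.row_starts, tmaps.col_starts, config.glcm.window, image.shape
    )
    responses = _timed(timings, "response_maps", response_maps, image, config.bank)
    initial = _timed(
        timings,
        "collect_candidates",
        collect_candidates,
        responses,
        config.effective_dedupe_radius,
        reversed_watershed_maxima,
    )
    final = screen_by_mask(initial, mask)
    return PipelineResult(
        final=final,
        intermediates={
            "texture_maps": tmaps,
            "gmm_fit": fit,
            "lesion_cluster": cluster,
            "mask": mask,
            "response_maps": responses,
            "watershed_candidates": initial,
        },
        config=config,
        timings=timings,
    )


def run_pipeline_b(
    image: Image2D,
    config: PipelineConfig,
    lesion_center: tuple[float, float] | None = None,
) -> PipelineResult:
    """Gabor-first pipeline: regional maxima -> per-candidate features -> GMM."""
    if config.cluster_mode == "oracle" and lesion_center is None:
        raise ParameterError("oracle cluster_mode requires lesion_center")
    timings: dict = {}
    responses = _timed(timings, "response_maps", response_maps, image, config.bank)
    initial = _timed(
        timings,
        "collect_candidates",
        collect_candidates,
        responses,
        config.effective_dedupe_radius,
        regional_maxima,
    )
    locs = initial.locations
    texture = _timed(
        timings, "texture_at_locations", texture_at_locations, image, locs, config.glcm
    )
    annotated = tuple(
        replace(c, texture_values=(float(texture[k, 0]), float(texture[k, 1])))
        for k, c in enumerate(initial.candidates)
    )
    initial = replace(initial, candidates=annotated)

    n = len(initial)
    if n == 0:
        final = initial.with_provenance("clustered")
        return PipelineResult(final, {"response_maps": responses, "initial_candidates": initial}, config, timings)
    K = min(config.K_b, n)
    if K < config.K_b:
        warnings.warn(f"only {n} candidates; using K={K}", stacklevel=2)
    gabor_features = np.array([c.channel_values for c in initial.candidates])
    features = np.column_stack([gabor_features, texture])
    fit = _timed(timings, "fit_gmm", fit_gmm, features, K, config.seed)
    cluster = select_lesion_cluster(
        fit,
        locs,
        lesion_center,
        config.cluster_mode,
        mean_feature_index=gabor_features.shape[1],  # GLCM-mean dimension
    )
    survivors = tuple(
        c for c, lab in zip(initial.candidates, fit.labels) if lab == cluster
    )
    final = CandidateSet(
        candidates=survivors, image_shape=initial.image_shape, provenance="clustered"
    )
    return PipelineResult(
        final=final,
        intermediates={
            "response_maps": responses,
            "initial_candidates": initial,
            "gmm_fit": fit,
            "lesion_cluster": cluster,
        },
        config=config,
        timings=timings,
    )


def run_thresholded(image: Image2D, config: PipelineConfig) -> PipelineResult:
    """Comparator: Gabor maxima kept above the response quantile."""
    timings: dict = {}
    responses = _timed(timings, "response_maps", response_maps, image, config.bank)
    initial = _timed(
        timings,
        "collect_candidates",
        collect_candidates,
        responses,
        config.effective_dedupe_radius,
        reversed_watershed_maxima,
    )
    final = threshold_candidates(initial, config.threshold_quantile)
    return PipelineResult(
        final=final,
        intermediates={"response_maps": responses, "initial_candidates": initial},
        config=config,
        timings=timings,
    )


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlations between GLCM mean and Gabor response magnitudes.

    ``per_channel`` holds r for GLCM mean vs |response| of each channel;
    ``vs_mean_over_channels`` is r against the mean magnitude across
    channels.  ``pairing`` records how observations were paired
    (``"per_candidate"`` or ``"per_patch"``).
    """

    per_channel: tuple[float, ...]
    vs_mean_over_channels: float
    n: int
    pairing: str


def feature_correlation(
    glcm_mean_values: np.ndarray,
    gabor_responses: np.ndarray,
    pairing: str = "per_candidate",
) -> CorrelationReport:
    """Correlate GLCM mean with per-channel Gabor response magnitudes.

    ``gabor_responses`` is (n, N) of signed responses; the magnitude
    (absolute value) is used, since the sign of an even-phase filter response
    encodes contrast polarity rather than salience.
    """
    x = np.asarray(glcm_mean_values, dtype=np.float64).ravel()
    R = np.atleast_2d(np.asarray(gabor_responses, dtype=np.float64))
    if R.shape[0] != x.size:
        R = R.T
    if R.shape[0] != x.size:
        raise ParameterError("glcm_mean_values and gabor_responses must pair up")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    mags = np.abs(R)
    per_channel = tuple(float(pearsonr(x, mags[:, k]).statistic) for k in range(mags.shape[1]))
    overall = float(pearsonr(x, mags.mean(axis=1)).statistic)
    return CorrelationReport(
        per_channel=per_channel, vs_mean_over_channels=overall, n=x.size, pairing=pairing
    )


def gaze_overlap(
    gaze_points: np.ndarray,
    final: CandidateSet,
    radius: float,
) -> tuple[float, float]:
    """Fraction of gaze points within ``radius`` of any candidate.

    ``gaze_points`` are (row, col) pixel coordinates.  Returns
    ``(fraction, mean_nearest_distance)``; an empty candidate set yields
    fraction 0 (with a warning) and an infinite mean distance.
    """
    gaze = np.asarray(gaze_points, dtype=np.float64).reshape(-1, 2)
    if gaze.shape[0] == 0:
        return 0.0, float("nan")
    locs = final.locations.astype(np.float64)
    if locs.shape[0] == 0:
        warnings.warn("empty candidate set: gaze overlap is 0", stacklevel=2)
        return 0.0, float("inf")
    d = np.sqrt(((gaze[:, None, :] - locs[None, :, :]) ** 2).sum(axis=2))
    nearest = d.min(axis=1)
    return float((nearest <= radius).mean()), float(nearest.mean())
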