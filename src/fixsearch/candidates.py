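"""Fixation-candidate extraction from feature maps.

Three selectors are provided:

* reversed-watershed maxima — watershed flooding of the negated map; each
  catchment basin contributes the argmax of the original map, which on maps
  with all-distinct values coincides with the 8-neighbourhood regional
  maxima;
* regional maxima — 8-connected maxima, plateau-aware (a plateau emits its
  rounded centroid; a plateau covering the whole map emits nothing);
* threshold screening — keep candidates whose strongest channel response
  reaches a quantile of that statistic over the set.

Candidate sets can additionally be screened against a boolean pixel mask
(the texture-cluster mask of the texture-first pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import GeometryError, ParameterError
from .gabor import ResponseMaps

__all__ = [
    "Candidate",
    "CandidateSet",
    "reversed_watershed_maxima",
    "regional_maxima",
    "collect_candidates",
    "threshold_candidates",
    "screen_by_mask",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Candidate:
    """One fixation candidate: location plus the feature values attached to it."""

    location: tuple[int, int]
    channel_values: tuple[float, ...]
    source_channel: int
    texture_values: tuple[float, float] | None = None

    @property
    def max_channel_value(self) -> float:
        return max(self.channel_values)


@dataclass(frozen=True)
class CandidateSet:
    """An ordered (row-major) list of candidates with its provenance tag."""

    candidates: tuple[Candidate, ...]
    image_shape: tuple[int, int]
    provenance: str

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.candidates, key=lambda c: c.location))
        object.__setattr__(self, "candidates", ordered)
        if self.provenance not in (
            "watershed",
            "regional_maxima",
            "screened",
            "thresholded",
            "clustered",
        ):
            raise ParameterError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def locations(self) -> np.ndarray:
        """(n, 2) integer array of candidate (row, col) locations."""
        if not self.candidates:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([c.location for c in self.candidates], dtype=np.int64)

    def with_provenance(self, provenance: str) -> "CandidateSet":
        return replace(self, provenance=provenance)


def reversed_watershed_maxima(feature_map: np.ndarray) -> list[tuple[int, int]]:
    """Basin-wise argmax of the map under watershed flooding of its negation.

    A constant map has no basins with distinct maxima; it yields an empty
    list with a warning rather than an error.
    """
    m = np.asarray(feature_map, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ParameterError("feature map must be finite")
    if m.max() == m.min():
        warnings.warn("constant feature map: no watershed maxima", stacklevel=2)
        return []
    labels = watershed(-m, connectivity=2)
    positions = ndimage.maximum_position(m, labels, np.arange(1, labels.max() + 1))
    return sorted((int(r), int(c)) for r, c in positions)


def regional_maxima(feature_map: np.ndarray) -> list[tuple[int, int]]:
    """8-connected regional maxima; plateaus emit their rounded centroid.

    A plateau covering the entire map is excluded (a constant map yields an
    empty list).
    """
    m = np.asarray(feature_map, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ParameterError("feature map must be finite")
    if m.max() == m.min():
        return []
    # group equal-valued 8-connected plateaus, then test plateau borders
    dilated = ndimage.grey_dilation(m, footprint=_EIGHT, mode="nearest")
    flat_max = m >= dilated  # pixels not dominated by any neighbour
    labels, n = ndimage.label(flat_max, structure=_EIGHT)
    out = []
    for lab in range(1, n + 1):
        mask = labels == lab
        # a plateau is a regional max only if no neighbouring pixel exceeds it
        ring = ndimage.binary_dilation(mask, structure=_EIGHT) & ~mask
        if ring.any() and m[ring].max() >= m[mask].max():
            continue
        rows, cols = np.nonzero(mask)
        out.append((int(round(rows.mean())), int(round(cols.mean()))))
    return sorted(out)


def collect_candidates(
    responses: ResponseMaps,
    dedupe_radius: float,
    finder=reversed_watershed_maxima,
) -> CandidateSet:
    """Union of per-channel maxima, merged within ``dedupe_radius``.

    When two candidates fall closer than the dedupe radius, the one whose
    producing channel responded more strongly survives; each survivor is
    annotated with the responses of *all* channels at its location.
    """
    n_channels = len(responses.bank)
    raw: list[tuple[float, int, int, int]] = []  # (-strength, row, col, channel)
    for k in range(n_channels):
        for row, col in finder(responses.maps[k]):
            raw.append((-responses.maps[k][row, col], row, col, k))
    raw.sort()  # strongest first; deterministic tie-break by location/channel

    kept: list[Candidate] = []
    kept_locs: list[tuple[int, int]] = []
    for neg_strength, row, col, k in raw:
        if any((row - r) ** 2 + (col - c) ** 2 <= dedupe_radius**2 for r, c in kept_locs):
            continue
        values = tuple(float(responses.maps[j][row, col]) for j in range(n_channels))
        kept.append(Candidate(location=(row, col), channel_values=values, source_channel=k))
        kept_locs.append((row, col))

    provenance = "watershed" if finder is reversed_watershed_maxima else "regional_maxima"
    return CandidateSet(candidates=tuple(kept), image_shape=responses.image_shape, provenance=provenance)


def threshold_candidates(cands: CandidateSet, quantile: float) -> CandidateSet:
    """Keep candidates whose max channel value reaches the given quantile.

    The threshold is the ``quantile`` of the max-channel statistic over the
    input set; survivors are a subset of the input and nested across
    increasing quantiles.
    """
    if not 0 <= quantile < 1:
        raise ParameterError("quantile must be in [0, 1)")
    if not cands.candidates:
        return replace(cands, provenance="thresholded")
    stats = np.array([c.max_channel_value for c in cands.candidates])
    cut = np.quantile(stats, quantile)
    survivors = tuple(c for c in cands.candidates if c.max_channel_value >= cut)
    return CandidateSet(candidates=survivors, image_shape=cands.image_shape, provenance="thresholded")


def screen_by_mask(cands: CandidateSet, mask) -> CandidateSet:
    """Keep exactly the candidates whose location falls on a true mask pixel."""
    mask_values = np.asarray(mask.values if hasattr(mask, "values") else mask, dtype=bool)
    if mask_values.shape != tuple(cands.image_shape):
        raise GeometryError(
            f"mask shape {mask_values.shape} != image shape {tuple(cands.image_shape)}"
        )
    survivors = tuple(c for c in cands.candidates if mask_values[c.location])
    return CandidateSet(candidates=survivors, image_shape=cands.image_shape, provenance="screened")
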