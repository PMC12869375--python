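"""Gray-level co-occurrence matrix (GLCM) texture features.

The GLCM of an image patch is the normalized joint histogram of gray-level
pairs (i, j) observed at fixed spatial offsets delta:

    P(i, j | delta) = N(i, j | delta) / sum_ij N(i, j | delta)

Two second-order statistics are derived from it:

* GLCM mean     — sum_ij i * P(i, j), the expected gray level of the
  reference pixel, in [0, G-1];
* GLCM contrast — sum_ij (i - j)^2 * P(i, j), the expected squared
  gray-level difference between offset neighbours, in [0, (G-1)^2].

Counts are directional (each listed offset delta counted once, not also
-delta); pass both delta and -delta for symmetric accumulation.  The default
offset set pools the four unit displacements at 0, 45, 90 and 135 degrees
into a single matrix, the standard orientation-pooled Haralick practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegeneratePatchError, GeometryError, ParameterError
from .phantom import Image2D

__all__ = [
    "DEFAULT_OFFSETS",
    "GLCMParams",
    "GLCMatrix",
    "TextureMaps",
    "quantize",
    "compute_glcm",
    "glcm_mean",
    "glcm_contrast",
    "texture_maps",
    "texture_at_locations",
]

#: Unit displacements at 0, 45, 90, 135 degrees (row, col), pooled by default.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMParams:
    """GLCM computation parameters.

    ``G`` gray levels and ``window`` size default to 128 and 100.  The
    stride defaults to the window (tiled, non-overlapping patches).
    ``quantization_range`` is one of ``"per_image"`` (global min-max, the
    default, so all patches share one gray scale), ``"per_patch"``, or a
    ``("fixed", lo, hi)`` tuple.
    """

    G: int = 128
    window: int = 100
    stride: int | None = None
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    quantization_range: object = "per_image"

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ParameterError("G must be at least 2")
        if self.window < 2:
            raise ParameterError("window must be at least 2")
        stride = self.window if self.stride is None else self.stride
        if stride < 1:
            raise ParameterError("stride must be at least 1")
        offsets = tuple((int(dr), int(dc)) for dr, dc in self.offsets)
        if not offsets or any(o == (0, 0) for o in offsets):
            raise ParameterError("offsets must be non-empty and exclude (0, 0)")
        object.__setattr__(self, "offsets", offsets)
        mode = self.quantization_range
        if isinstance(mode, str):
            if mode not in ("per_image", "per_patch"):
                raise ParameterError(f"unknown quantization_range {mode!r}")
        else:
            tag, lo, hi = mode
            if tag != "fixed" or not lo < hi:
                raise ParameterError("fixed quantization_range must be ('fixed', lo, hi) with lo < hi")

    @property
    def effective_stride(self) -> int:
        return self.window if self.stride is None else self.stride


@dataclass(frozen=True)
class GLCMatrix:
    """A normalized G x G joint gray-level probability table for one patch."""

    P: np.ndarray
    offsets: tuple[tuple[int, int], ...]
    patch_bounds: tuple[int, int, int, int] | None = None  # (r0, r1, c0, c1)

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=np.float64)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ContractError("GLCM must be a square matrix")
        if np.any(P < 0):
            raise ContractError("GLCM entries must be non-negative")
        object.__setattr__(self, "P", P)

    @property
    def G(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class TextureMaps:
    """Patch-lattice maps of GLCM mean and contrast.

    ``row_starts``/``col_starts`` give the top-left corner of each patch row/
    column of the lattice; patch (a, b) covers
    ``[row_starts[a], row_starts[a]+window) x [col_starts[b], ...)``.
    """

    mean_map: np.ndarray
    contrast_map: np.ndarray
    row_starts: np.ndarray
    col_starts: np.ndarray
    params: GLCMParams
    image_shape: tuple[int, int]

    @property
    def patch_centers(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of patch center (row, col) coordinates."""
        half = self.params.window / 2.0
        rr = self.row_starts + half
        cc = self.col_starts + half
        grid = np.empty((rr.size, cc.size, 2))
        grid[..., 0] = rr[:, None]
        grid[..., 1] = cc[None, :]
        return grid


def _resolve_range(values: np.ndarray, mode: object) -> tuple[float, float]:
    if isinstance(mode, tuple):
        _, lo, hi = mode
        return float(lo), float(hi)
    return float(values.min()), float(values.max())


def quantize(image: Image2D | np.ndarray, G: int, range_mode: object = "per_image") -> np.ndarray:
    """Linearly bin intensities into integer levels {0..G-1}.

    The range [lo, hi] is split into G equal bins, top edge inclusive.  A
    constant image (lo == hi) maps entirely to level 0.  Under a fixed range,
    values outside [lo, hi] are clipped.
    """
    if G < 2:
        raise ParameterError("G must be at least 2")
    values = image.values if isinstance(image, Image2D) else np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ParameterError("cannot quantize non-finite values")
    lo, hi = _resolve_range(values, range_mode)
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * G).astype(np.int64)
    return np.clip(q, 0, G - 1)


def compute_glcm(
    q_patch: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    G: int | None = None,
    patch_bounds: tuple[int, int, int, int] | None = None,
) -> GLCMatrix:
    """Accumulate directional pair counts over all offsets and normalize.

    ``G`` defaults to ``q_patch.max() + 1``.  Raises
    :class:`DegeneratePatchError` when no offset yields a valid pixel pair.
    """
    q = np.asarray(q_patch)
    if not np.issubdtype(q.dtype, np.integer):
        raise ParameterError("compute_glcm expects an integer gray-level grid")
    if G is None:
        G = int(q.max()) + 1
    if q.size and int(q.max()) >= G:
        raise ParameterError(f"patch contains level {int(q.max())} >= G={G}")

    h, w = q.shape
    counts = np.zeros(G * G, dtype=np.int64)
    total = 0
    for dr, dc in offsets:
        if abs(dr) >= h or abs(dc) >= w:
            continue
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        ref = q[r0:r1, c0:c1]
        nbr = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        idx = ref.ravel() * G + nbr.ravel()
        counts += np.bincount(idx, minlength=G * G)
        total += idx.size
    if total == 0:
        raise DegeneratePatchError("no valid pixel pair for any offset in this patch")
    P = counts.reshape(G, G).astype(np.float64) / total
    return GLCMatrix(P=P, offsets=tuple(offsets), patch_bounds=patch_bounds)


def _check_normalized(P: np.ndarray) -> None:
    s = P.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        raise ContractError(f"GLCM is not normalized (sum={s!r})")


def glcm_mean(glcm: GLCMatrix | np.ndarray) -> float:
    """Expected gray level of the reference pixel: sum_ij i * P(i, j)."""
    P = glcm.P if isinstance(glcm, GLCMatrix) else np.asarray(glcm, dtype=np.float64)
    _check_normalized(P)
    i = np.arange(P.shape[0], dtype=np.float64)
    return float(i @ P.sum(axis=1))


def glcm_contrast(glcm: GLCMatrix | np.ndarray) -> float:
    """Expected squared gray-level difference: sum_ij (i - j)^2 * P(i, j)."""
    P = glcm.P if isinstance(glcm, GLCMatrix) else np.asarray(glcm, dtype=np.float64)
    _check_normalized(P)
    i = np.arange(P.shape[0], dtype=np.float64)
    diff2 = (i[:, None] - i[None, :]) ** 2
    return float((diff2 * P).sum())


def _lattice(extent: int, window: int, stride: int) -> np.ndarray:
    if extent < window:
        return np.array([], dtype=np.int64)
    return np.arange(0, extent - window + 1, stride, dtype=np.int64)


def texture_maps(image: Image2D, params: GLCMParams = GLCMParams()) -> TextureMaps:
    """Compute GLCM mean and contrast on the patch lattice of the image.

    Patches of ``params.window`` pixels are placed on a stride lattice; any
    partial patch at the right/bottom border is dropped so every cell's
    statistics come from the same patch area.
    """
    h, w = image.shape
    window, stride = params.window, params.effective_stride
    if window > h or window > w:
        raise GeometryError(f"window {window} exceeds image shape {image.shape}")
    row_starts = _lattice(h, window, stride)
    col_starts = _lattice(w, window, stride)

    q_full = None
    if params.quantization_range != "per_patch":
        q_full = quantize(image, params.G, params.quantization_range)

    mean_map = np.empty((row_starts.size, col_starts.size))
    contrast_map = np.empty_like(mean_map)
    for a, r0 in enumerate(row_starts):
        for b, c0 in enumerate(col_starts):
            if q_full is not None:
                q = q_full[r0 : r0 + window, c0 : c0 + window]
            else:
                q = quantize(image.values[r0 : r0 + window, c0 : c0 + window], params.G, "per_image")
            glcm = compute_glcm(q, params.offsets, params.G, (r0, r0 + window, c0, c0 + window))
            mean_map[a, b] = glcm_mean(glcm)
            contrast_map[a, b] = glcm_contrast(glcm)
    return TextureMaps(
        mean_map=mean_map,
        contrast_map=contrast_map,
        row_starts=row_starts,
        col_starts=col_starts,
        params=params,
        image_shape=(h, w),
    )


def texture_at_locations(
    image: Image2D,
    locations: list[tuple[int, int]] | np.ndarray,
    params: GLCMParams = GLCMParams(),
) -> np.ndarray:
    """GLCM (mean, contrast) on a window centered at each location.

    Windows overhanging the image border are clamped to the image bounds, so
    candidates near borders still receive features.  Returns an (n, 2) array
    ordered like ``locations``; an empty location list yields shape (0, 2).
    """
    h, w = image.shape
    window = params.window
    if window > h or window > w:
        raise GeometryError(f"window {window} exceeds image shape {image.shape}")

    q_full = None
    if params.quantization_range != "per_patch":
        q_full = quantize(image, params.G, params.quantization_range)

    out = np.empty((len(locations), 2))
    half = window // 2
    for k, (row, col) in enumerate(locations):
        r0 = int(np.clip(int(row) - half, 0, h - window))
        c0 = int(np.clip(int(col) - half, 0, w - window))
        if q_full is not None:
            q = q_full[r0 : r0 + window, c0 : c0 + window]
        else:
            q = quantize(image.values[r0 : r0 + window, c0 : c0 + window], params.G, "per_image")
        glcm = compute_glcm(q, params.offsets, params.G)
        out[k, 0] = glcm_mean(glcm)
        out[k, 1] = glcm_contrast(glcm)
    return out
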