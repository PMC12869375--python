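"""Seeded synthetic phantoms: clustered lumpy backgrounds with an optional spiculated mass.

The generator emulates 2D tomosynthesis-slice-like textured backgrounds at
three mammographic density regimes.  Texture is a clustered lumpy background:
Gaussian blobs scattered around Poisson-distributed cluster centers, plus
white Gaussian noise.  A spiculated mass (disk core with radial taper and
radiating linear spicules) can be added as a purely additive profile, so the
lesion term is independent of the background it is inserted into.

Intensities are arbitrary float units; quantization to gray levels happens
only in :mod:`fixsearch.texture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "Image2D",
    "REGIME_FACTORS",
    "generate_background",
    "insert_spiculated_mass",
    "lesion_profile",
]

#: Per-regime (cluster density multiplier, blob amplitude multiplier).
#: Chosen so the spatial variance strictly increases fatty < scattered <
#: heterogeneous for matched seeds: variance scales roughly with
#: density * amplitude**2, i.e. 0.38 : 1.0 : 2.7.
REGIME_FACTORS = {
    "fatty": (0.6, 0.8),
    "scattered": (1.0, 1.0),
    "heterogeneous": (1.6, 1.3),
}


@dataclass(frozen=True)
class Image2D:
    """A 2D float intensity grid with its physical pixel pitch in mm/pixel."""

    values: np.ndarray
    pixel_pitch: float = 0.1

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ParameterError(f"Image2D requires a 2D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ParameterError("Image2D values must be finite")
        if self.pixel_pitch <= 0:
            raise ParameterError("pixel_pitch must be positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a clustered-lumpy-background phantom.

    ``lump_count`` is the expected number of blob clusters; each cluster
    spawns a Poisson number of Gaussian blobs of scale ``lump_radius_mean``
    (pixels).  ``background_regime`` scales cluster density and blob
    amplitude per :data:`REGIME_FACTORS`.
    """

    height: int = 600
    width: int = 600
    pixel_pitch: float = 0.1
    background_regime: str = "scattered"
    lump_count: int = 80
    lump_radius_mean: float = 10.0
    lump_amplitude: float = 1.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ParameterError("phantom dimensions must be at least 64x64")
        if self.background_regime not in REGIME_FACTORS:
            raise ParameterError(
                f"unknown background_regime {self.background_regime!r}; "
                f"expected one of {sorted(REGIME_FACTORS)}"
            )
        if self.lump_count < 0:
            raise ParameterError("lump_count must be non-negative")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if self.lump_radius_mean <= 0:
            raise ParameterError("lump_radius_mean must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """A spiculated mass: disk core plus radiating spicules, additive contrast.

    ``radius`` is in millimetres (default 10 mm); it is converted to pixels
    with the image's pixel pitch at insertion time.  ``contrast`` is the peak
    additive intensity above the local background.
    """

    center: tuple[int, int] = (300, 300)
    radius: float = 10.0
    contrast: float = 1.0
    n_spicules: int = 8
    spicule_length_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("lesion radius must be positive")
        if self.n_spicules < 0:
            raise ParameterError("n_spicules must be non-negative")
        if self.spicule_length_factor < 0:
            raise ParameterError("spicule_length_factor must be non-negative")


def generate_background(spec: PhantomSpec) -> Image2D:
    """Generate a clustered lumpy background, bit-deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    density_factor, amp_factor = REGIME_FACTORS[spec.background_regime]
    img = np.zeros((spec.height, spec.width), dtype=np.float64)

    n_clusters = rng.poisson(spec.lump_count * density_factor)
    for _ in range(n_clusters):
        cr = rng.uniform(0, spec.height)
        cc = rng.uniform(0, spec.width)
        n_blobs = rng.poisson(5)
        spread = 4.0 * spec.lump_radius_mean
        for _ in range(n_blobs):
            br = cr + rng.normal(0, spread)
            bc = cc + rng.normal(0, spread)
            sigma = spec.lump_radius_mean * rng.uniform(0.6, 1.4)
            amp = spec.lump_amplitude * amp_factor * rng.uniform(0.5, 1.5)
            _add_gaussian_blob(img, br, bc, sigma, amp)

    if spec.noise_sigma > 0:
        img += rng.normal(0, spec.noise_sigma, size=img.shape)
    return Image2D(values=img, pixel_pitch=spec.pixel_pitch)


def _add_gaussian_blob(
    img: np.ndarray, row: float, col: float, sigma: float, amplitude: float
) -> None:
    """Accumulate one Gaussian blob in-place, rendered on a 3-sigma window."""
    h, w = img.shape
    half = int(np.ceil(3 * sigma))
    r0 = max(int(np.floor(row)) - half, 0)
    r1 = min(int(np.ceil(row)) + half + 1, h)
    c0 = max(int(np.floor(col)) - half, 0)
    c1 = min(int(np.ceil(col)) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1, dtype=np.float64)[:, None] - row
    cc = np.arange(c0, c1, dtype=np.float64)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def lesion_profile(
    shape: tuple[int, int],
    lesion: LesionSpec,
    pixel_pitch: float,
    seed: int,
) -> np.ndarray:
    """Render the additive intensity profile of a spiculated mass.

    The core is a hemispheric taper ``contrast * sqrt(1 - (d/r)^2)`` on the
    disk of radius r = radius/pixel_pitch pixels; each of ``n_spicules``
    spicules is a linear ramp from the center to radius r*(1+length_factor),
    with a Gaussian cross-profile of width r/20 truncated at 3 widths, at
    equally spaced angles with seeded jitter.  Core and spicules combine by
    pointwise maximum, so the peak stays at ``contrast``.
    """
    h, w = shape
    r_px = lesion.radius / pixel_pitch
    cr, cc = lesion.center
    tip = r_px * (1.0 + lesion.spicule_length_factor)
    if cr - tip < 0 or cr + tip > h - 1 or cc - tip < 0 or cc + tip > w - 1:
        raise GeometryError(
            f"lesion at {lesion.center} with extent {tip:.1f} px does not fit "
            f"inside a {h}x{w} image"
        )

    rng = np.random.default_rng(seed)
    half = int(np.ceil(tip)) + 1
    r0, r1 = int(cr) - half, int(cr) + half + 1
    c0, c1 = int(cc) - half, int(cc) + half + 1
    rr = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cc_ = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    d = np.hypot(rr, cc_)

    core = np.sqrt(np.clip(1.0 - (d / r_px) ** 2, 0.0, None))
    local = core

    width = max(2.0, r_px / 20.0)
    n = lesion.n_spicules
    for k in range(n):
        angle = 2 * np.pi * k / n + rng.uniform(-0.5, 0.5) * (2 * np.pi / max(n, 1)) * 0.4
        ux, uy = np.cos(angle), np.sin(angle)
        # along-ray coordinate t and perpendicular offset p
        t = rr * uy + cc_ * ux
        p = -rr * ux + cc_ * uy
        ramp = np.clip(1.0 - t / tip, 0.0, 1.0) * (t >= 0)
        cross = np.exp(-(p**2) / (2 * width**2)) * (np.abs(p) <= 3 * width)
        local = np.maximum(local, ramp * cross * (t <= tip))

    profile = np.zeros(shape, dtype=np.float64)
    pr0, pr1 = max(r0, 0), min(r1, h)
    pc0, pc1 = max(c0, 0), min(c1, w)
    profile[pr0:pr1, pc0:pc1] = (lesion.contrast * local)[
        pr0 - r0 : pr1 - r0, pc0 - c0 : pc1 - c0
    ]
    return profile


def insert_spiculated_mass(image: Image2D, lesion: LesionSpec, seed: int = 0) -> Image2D:
    """Return a new image with the lesion's additive profile superimposed."""
    profile = lesion_profile(image.shape, lesion, image.pixel_pitch, seed)
    return Image2D(values=image.values + profile, pixel_pitch=image.pixel_pitch)
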