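"""Four-channel Gabor filter bank and per-pixel response maps.

The kernel is a cosine carrier under an isotropic Gaussian envelope whose
full width at half maximum is Ws:

    g(x, y) = exp(-4 ln2 ((x-x0)^2 + (y-y0)^2) / Ws^2)
              * cos(2 pi fc (x cos(theta) + y sin(theta)) + phi)

so the envelope attains exactly 1/2 at radius Ws/2 from the kernel center
(x0, y0).  Response maps are the cross-correlation of the image with the
kernel (no kernel flip) — observable with odd-phase channels — with reflect
padding at the borders, so output shape equals input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .errors import GeometryError, ParameterError
from .phantom import Image2D

__all__ = [
    "GaborParams",
    "GaborBank",
    "ResponseMaps",
    "gabor_kernel",
    "response_maps",
    "default_bank",
]


@dataclass(frozen=True)
class GaborParams:
    """One Gabor channel: envelope FWHM Ws (px), central frequency fc
    (cycles/px), orientation theta and phase phi (radians), and the kernel
    half-size ``support`` (px; defaults to ceil(2*Ws), where the envelope
    tail is 2^-16 of peak)."""

    Ws: float
    fc: float
    theta: float = 0.0
    phi: float = 0.0
    support: int | None = None

    def __post_init__(self) -> None:
        if self.Ws <= 0:
            raise ParameterError("Ws must be positive")
        if self.fc < 0:
            raise ParameterError("fc must be non-negative")
        support = self.support
        if support is None:
            support = int(np.ceil(2 * self.Ws))
        if support < 2 * self.Ws:
            raise ParameterError("support must be at least 2*Ws")
        object.__setattr__(self, "support", int(support))


@dataclass(frozen=True)
class GaborBank:
    """An ordered, indexed list of Gabor channels (default bank size 4)."""

    channels: tuple[GaborParams, ...]

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        if not channels:
            raise ParameterError("bank must contain at least one channel")
        object.__setattr__(self, "channels", channels)

    def __len__(self) -> int:
        return len(self.channels)

    def to_dicts(self) -> list[dict]:
        return [
            {"Ws": c.Ws, "fc": c.fc, "theta": c.theta, "phi": c.phi, "support": c.support}
            for c in self.channels
        ]

    @classmethod
    def from_dicts(cls, dicts: list[dict]) -> "GaborBank":
        return cls(channels=tuple(GaborParams(**d) for d in dicts))


@dataclass(frozen=True)
class ResponseMaps:
    """Per-pixel response of every bank channel; shape equals the image's."""

    maps: np.ndarray  # (N, H, W)
    bank: GaborBank

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=np.float64)
        if maps.ndim != 3 or maps.shape[0] != len(self.bank):
            raise ParameterError("maps must be (n_channels, H, W) matching the bank")
        if not np.all(np.isfinite(maps)):
            raise ParameterError("response maps must be finite")
        object.__setattr__(self, "maps", maps)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]

    def values_at(self, locations: np.ndarray) -> np.ndarray:
        """(n, N) channel values at integer (row, col) locations."""
        locations = np.asarray(locations, dtype=np.int64)
        return self.maps[:, locations[:, 0], locations[:, 1]].T


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Evaluate the kernel on the (2*support+1)^2 integer grid.

    The value at the center pixel is cos(phi); the envelope factor alone is
    0.5 at radius Ws/2.
    """
    s = params.support
    y = np.arange(-s, s + 1, dtype=np.float64)[:, None]  # row offset
    x = np.arange(-s, s + 1, dtype=np.float64)[None, :]  # col offset
    envelope = np.exp(-4 * np.log(2) * (x**2 + y**2) / params.Ws**2)
    carrier = np.cos(
        2 * np.pi * params.fc * (x * np.cos(params.theta) + y * np.sin(params.theta))
        + params.phi
    )
    return envelope * carrier


def response_maps(image: Image2D, bank: GaborBank) -> ResponseMaps:
    """Cross-correlate the image with every channel kernel (reflect borders).

    Cross-correlation applies the kernel unflipped; the image is reflect-
    padded by each kernel's support so the output grid matches the input.
    """
    values = image.values
    h, w = values.shape
    maps = np.empty((len(bank), h, w))
    for k, params in enumerate(bank.channels):
        kernel = gabor_kernel(params)
        s = params.support
        if 2 * s + 1 > h or 2 * s + 1 > w:
            raise GeometryError(
                f"channel {k}: kernel size {2 * s + 1} exceeds image shape {values.shape}"
            )
        padded = np.pad(values, s, mode="reflect")
        # correlation == convolution with the doubly flipped kernel
        maps[k] = fftconvolve(padded, kernel[::-1, ::-1], mode="valid")
    return ResponseMaps(maps=maps, bank=bank)


def default_bank(target_radius_px: float) -> GaborBank:
    """Four-channel multiscale bank matched to a target of the given radius.

    Central frequencies are octave-spaced, fc in {1/(8r), 1/(4r), 1/(2r),
    1/r}; the envelope FWHM is one carrier wavelength capped at the target
    radius, Ws = min(1/fc, r), which keeps kernels no larger than 4r+1 pixels
    while the lowest channels act as blob detectors matched to the target
    scale.  theta = phi = 0 throughout; every parameter is overridable by
    constructing a :class:`GaborBank` directly or via a config file.
    """
    if target_radius_px <= 0:
        raise ParameterError("target_radius_px must be positive")
    r = float(target_radius_px)
    channels = []
    for m in (8, 4, 2, 1):
        fc = 1.0 / (m * r)
        ws = min(1.0 / fc, r)
        channels.append(GaborParams(Ws=ws, fc=fc))
    return GaborBank(channels=tuple(channels))
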