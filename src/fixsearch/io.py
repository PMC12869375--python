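"""Readers, writers, config round-tripping, fixtures and run manifests.

Conventions: coordinates are (row, col), 0-based, row-major everywhere in
the package; gaze CSVs use image-style (x, y) columns and are converted to
(row=y, col=x) at this boundary.  The candidate CSV (columns row, col,
source_channel, ch1..chN, glcm_mean, glcm_contrast, provenance) is the
single interchange format between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .candidates import Candidate, CandidateSet
from .errors import ParameterError
from .phantom import Image2D, LesionSpec, PhantomSpec, generate_background, insert_spiculated_mass

logger = logging.getLogger("fixsearch")

__all__ = [
    "read_image",
    "write_image",
    "write_ground_truth",
    "read_ground_truth",
    "write_candidates",
    "read_candidates",
    "read_gaze",
    "save_config",
    "load_config",
    "RunManifest",
    "write_manifest",
    "read_manifest",
    "make_fixture",
    "FIXTURE_NAMES",
]


def read_image(path: str | os.PathLike, pixel_pitch: float = 0.1) -> Image2D:
    """Load a single-channel TIFF or PNG as a float grid, without rescaling.

    Multichannel inputs are reduced to luminance with a logged warning;
    integer samples are cast to float with their raw values preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        values = tifffile.imread(path)
    elif suffix == ".png":
        values = iio.imread(path)
    else:
        raise ParameterError(f"unsupported image format {suffix!r} (expected TIFF or PNG)")
    values = np.asarray(values)
    if values.ndim == 3:
        logger.warning("multichannel image %s reduced to luminance", path)
        values = values[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    return Image2D(values=values.astype(np.float64), pixel_pitch=pixel_pitch)


def write_image(path: str | os.PathLike, image: Image2D) -> None:
    """Write 32-bit float TIFF, or 16-bit min-max-scaled PNG, by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32))
    elif suffix == ".png":
        v = image.values
        lo, hi = v.min(), v.max()
        scaled = np.zeros(v.shape) if hi <= lo else (v - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))
    else:
        raise ParameterError(f"unsupported image format {suffix!r}")


def write_ground_truth(path: str | os.PathLike, center: tuple[float, float], radius_px: float) -> None:
    pd.DataFrame(
        [{"center_row": center[0], "center_col": center[1], "radius_px": radius_px}]
    ).to_csv(path, index=False)


def read_ground_truth(path: str | os.PathLike) -> tuple[tuple[float, float], float]:
    row = pd.read_csv(path).iloc[0]
    return (float(row.center_row), float(row.center_col)), float(row.radius_px)


def write_candidates(path: str | os.PathLike, cands: CandidateSet) -> None:
    n_ch = len(cands.candidates[0].channel_values) if cands.candidates else 0
    rows = []
    for c in cands.candidates:
        row = {"row": c.location[0], "col": c.location[1], "source_channel": c.source_channel}
        for k, v in enumerate(c.channel_values, start=1):
            row[f"ch{k}"] = v
        row["glcm_mean"] = c.texture_values[0] if c.texture_values else np.nan
        row["glcm_contrast"] = c.texture_values[1] if c.texture_values else np.nan
        row["provenance"] = cands.provenance
        rows.append(row)
    columns = ["row", "col", "source_channel"] + [f"ch{k}" for k in range(1, n_ch + 1)] + [
        "glcm_mean", "glcm_contrast", "provenance",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.attrs["image_shape"] = cands.image_shape
    with open(path, "w") as fh:
        fh.write(f"# image_shape={cands.image_shape[0]}x{cands.image_shape[1]}\n")
        df.to_csv(fh, index=False)


def read_candidates(path: str | os.PathLike) -> CandidateSet:
    with open(path) as fh:
        header = fh.readline().strip()
        shape = tuple(int(t) for t in header.split("=")[1].split("x"))
        df = pd.read_csv(fh)
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    cands = []
    provenance = "watershed"
    for _, row in df.iterrows():
        tex = None
        if not np.isnan(row["glcm_mean"]):
            tex = (float(row["glcm_mean"]), float(row["glcm_contrast"]))
        cands.append(
            Candidate(
                location=(int(row["row"]), int(row["col"])),
                channel_values=tuple(float(row[c]) for c in ch_cols),
                source_channel=int(row["source_channel"]),
                texture_values=tex,
            )
        )
        provenance = row["provenance"]
    return CandidateSet(candidates=tuple(cands), image_shape=shape, provenance=provenance)


def read_gaze(path: str | os.PathLike, t_max_ms: float | None = None) -> np.ndarray:
    """Load a gaze CSV (columns x, y, t_ms) as (row, col) points.

    ``t_max_ms`` optionally keeps only the first T milliseconds (early-stage
    gaze).  The (x, y) convention of eye trackers maps to (col, row).
    """
    df = pd.read_csv(path)
    if t_max_ms is not None and "t_ms" in df.columns:
        df = df[df["t_ms"] <= t_max_ms]
    return np.column_stack([df["y"].to_numpy(float), df["x"].to_numpy(float)])


def save_config(path: str | os.PathLike, config) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str | os.PathLike):
    from .pipelines import PipelineConfig

    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Run manifests

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest(dict):
    """A JSON-serializable record sufficient to re-run a pipeline bit-identically."""


def write_manifest(
    out_dir: str | os.PathLike,
    config,
    pipeline: str,
    input_image: str | os.PathLike,
    lesion_center: tuple[float, float] | None,
    artifacts: list[str],
    timings: dict,
) -> Path:
    """Write run.manifest.json atomically into ``out_dir``."""
    out_dir = Path(out_dir)
    manifest = RunManifest(
        tool="fixsearch",
        version=__version__,
        pipeline=pipeline,
        input_image=str(Path(input_image).resolve()),
        lesion_center=list(lesion_center) if lesion_center is not None else None,
        config=config.to_dict(),
        seed=config.seed,
        artifacts={name: _sha256(out_dir / name) for name in artifacts},
        timings={k: float(v) for k, v in timings.items()},
    )
    path = out_dir / "run.manifest.json"
    fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(manifest, fh, indent=2)
    os.replace(tmp, path)
    return path


def read_manifest(path: str | os.PathLike) -> RunManifest:
    with open(path) as fh:
        return RunManifest(json.load(fh))


def rerun_from_manifest(path: str | os.PathLike, out_dir: str | os.PathLike):
    """Re-execute the pipeline a manifest records, writing to ``out_dir``.

    Returns the new manifest path; the artifact checksums it contains can be
    compared with the original's to confirm bit-identical reproduction.
    """
    from .cli import _run_and_export

    m = read_manifest(path)
    from .pipelines import PipelineConfig

    config = PipelineConfig.from_dict(m["config"])
    image = read_image(m["input_image"])
    center = tuple(m["lesion_center"]) if m["lesion_center"] is not None else None
    return _run_and_export(m["pipeline"], image, config, center, Path(out_dir), m["input_image"])


# ---------------------------------------------------------------------------
# Fixture catalogue

FIXTURE_NAMES = ("constant", "checkerboard", "two-bumps", "lumpy-with-lesion", "lumpy-no-lesion")


def make_fixture(name: str, seed: int = 0) -> dict:
    """Build a deterministic named test fixture.

    Returns a dict with the image, any ground truth, and the constructed
    properties the fixture guarantees (e.g. known peak locations).
    """
    if name == "constant":
        return {"image": Image2D(np.full((64, 64), 5.0)), "expected": {"constant_value": 5.0}}
    if name == "checkerboard":
        rr, cc = np.indices((64, 64))
        values = ((rr + cc) % 2).astype(np.float64)
        return {"image": Image2D(values), "expected": {"period": 2, "levels": (0.0, 1.0)}}
    if name == "two-bumps":
        rr, cc = np.indices((128, 128), dtype=np.float64)
        peaks = [(40.0, 40.0), (90.0, 95.0)]
        sigma = 6.0
        values = sum(
            np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * sigma**2)) for pr, pc in peaks
        )
        return {
            "image": Image2D(values),
            "expected": {"peaks": [(int(r), int(c)) for r, c in peaks], "sigma": sigma},
        }
    if name in ("lumpy-with-lesion", "lumpy-no-lesion"):
        spec = PhantomSpec(height=320, width=320, lump_count=30, seed=seed)
        image = generate_background(spec)
        if name == "lumpy-no-lesion":
            return {"image": image, "spec": spec}
        rng = np.random.default_rng(seed + 1)
        margin = 80
        center = (
            int(rng.integers(margin, spec.height - margin)),
            int(rng.integers(margin, spec.width - margin)),
        )
        lesion = LesionSpec(center=center, radius=5.0, contrast=5 * float(image.values.std()))
        with_lesion = insert_spiculated_mass(image, lesion, seed=seed + 2)
        return {
            "image": with_lesion,
            "spec": spec,
            "lesion": lesion,
            "expected": {"center": center, "radius_px": lesion.radius / spec.pixel_pitch},
        }
    raise ParameterError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
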