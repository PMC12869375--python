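import numpy as np
import pytest

from fixsearch import Image2D, LesionSpec, PhantomSpec, generate_background, insert_spiculated_mass


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 320x320 lumpy background with a centered spiculated mass (radius 50 px)."""
    spec = PhantomSpec(height=320, width=320, lump_count=30, seed=7)
    background = generate_background(spec)
    center = (160, 170)
    lesion = LesionSpec(center=center, radius=5.0, contrast=5 * float(background.values.std()))
    image = insert_spiculated_mass(background, lesion, seed=7)
    return {"image": image, "background": background, "center": center, "radius_px": 50.0}


def brute_force_glcm(q_patch, offsets, G):
    """Pair-enumeration oracle for the co-occurrence matrix (pure double loop)."""
    q = np.asarray(q_patch)
    h, w = q.shape
    counts = np.zeros((G, G), dtype=np.int64)
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[q[r, c], q[r2, c2]] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def brute_force_regional_maxima(feature_map):
    """8-neighbourhood maxima oracle for maps with all-distinct values."""
    m = np.asarray(feature_map)
    h, w = m.shape
    out = []
    for r in range(h):
        for c in range(w):
            neighbours = [
                m[r2, c2]
                for r2 in range(max(0, r - 1), min(h, r + 2))
                for c2 in range(max(0, c - 1), min(w, c + 2))
                if (r2, c2) != (r, c)
            ]
            if all(m[r, c] > v for v in neighbours):
                out.append((r, c))
    return sorted(out)
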