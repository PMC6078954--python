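"""Shared fixtures: small synthetic cohorts, phantoms and atlases."""

from __future__ import annotations

import numpy as np
import pytest

from gliomics import CohortSpec, make_toy_atlas, simulate_cohort
from gliomics.pipeline import cohort_feature_table

GRID32 = (32, 32, 32)


def small_spec(**overrides) -> CohortSpec:
    """A fast desk-scale cohort spec used throughout the unit tests."""
    params = dict(
        n_cases=30, n_institutions=3, grid_shape=GRID32,
        spacing_mm=(4.0, 4.0, 4.0), lesion_radius_mm=(8.0, 16.0), seed=0,
    )
    params.update(overrides)
    return CohortSpec(**params)


@pytest.fixture(scope="session")
def small_cohort():
    spec = small_spec(seed=5)
    cases, manifest = simulate_cohort(spec)
    return spec, cases, manifest


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, cases, _ = small_cohort
    return cohort_feature_table(cases)


@pytest.fixture(scope="session")
def atlas10():
    return make_toy_atlas(GRID32, "mni10")


@pytest.fixture(scope="session")
def atlas49():
    return make_toy_atlas(GRID32, "ho49")


def gaussian_blob_phantom(shape=GRID32, n_blobs: int = 8, seed: int = 0) -> np.ndarray:
    """Smooth anisotropic-blob head phantom for registration tests."""
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vol = np.zeros(shape)
    lo, hi = 0.25 * shape[0], 0.75 * shape[0]
    for _ in range(n_blobs):
        c = rng.uniform(lo, hi, 3)
        amp = rng.uniform(50, 150)
        s = rng.uniform(2, 5, 3)
        vol += amp * np.exp(
            -(((x - c[0]) / s[0]) ** 2 + ((y - c[1]) / s[1]) ** 2
              + ((z - c[2]) / s[2]) ** 2) / 2
        )
    return vol


def random_sphere_masks(rng, n: int, shape=GRID32, radius=(3.0, 6.0),
                        center_bias=None) -> list[np.ndarray]:
    """Random spherical lesions inside a central brain ball (null structure)."""
    x, y, z = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c0 = (np.asarray(shape) - 1) / 2
    brain = ((x - c0[0]) ** 2 + (y - c0[1]) ** 2 + (z - c0[2]) ** 2) <= (0.45 * shape[0]) ** 2
    masks = []
    for _ in range(n):
        while True:
            if center_bias is not None:
                c = rng.normal(center_bias, 2.0)
            else:
                c = rng.uniform(6, np.asarray(shape) - 7)
            r = rng.uniform(*radius)
            m = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r * r
            m &= brain
            if m.any():
                masks.append(m)
                break
    return masks
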