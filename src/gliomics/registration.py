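"""Affine mutual-information registration, resampling and laterality handling.

A lightweight intra-modality/inter-modality affine registration: histogram
mutual information (32 bins) maximized by a derivative-free Powell search over
a coarse-to-fine pyramid.  Degrees of freedom follow the usual convention:
6 = rigid (translation + rotation), 9 = + anisotropic scale, 12 = + shear.
It matches the contract of standard neuroimaging tools (MI cost, 12 DOF) but
is exercised on synthetic phantoms only — it is not a numerical replica of
any external registration package.

Transforms are stored as 4x4 homogeneous matrices mapping *fixed* (atlas)
voxel coordinates to *moving* (native) voxel coordinates, i.e. in the
resampling direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import NormalizedVolume, VOIMask, Volume

__all__ = ["AffineTransform", "register_affine_mi", "resample_to_atlas", "flip_lr",
           "save_transform", "load_transform"]

_N_BINS = 32


@dataclass
class AffineTransform:
    """Homogeneous voxel-to-voxel affine (fixed -> moving) with its MI cost."""

    matrix: np.ndarray
    dof: int = 12
    cost: float = float("nan")  # mutual information at the optimum (bits-like, nats)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("non-invertible transform")
        if self.dof not in (6, 9, 12):
            raise ValueError("dof must be one of 6, 9, 12")

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), dof=self.dof, cost=self.cost)


def _rotation(deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def params_to_matrix(params: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Build the 4x4 fixed->moving voxel matrix from a parameter vector.

    Layout: [tx, ty, tz, rx, ry, rz, log_sx, log_sy, log_sz, kxy, kxz, kyz];
    rotations in degrees, translations in (full-resolution) voxels.  The
    linear part acts about the grid center.
    """
    p = np.zeros(12)
    p[: len(params)] = params
    rot = _rotation(p[3:6])
    scale = np.diag(np.exp(p[6:9]))
    shear = np.array([[1, p[9], p[10]], [0, 1, p[11]], [0, 0, 1]], dtype=float)
    lin = rot @ scale @ shear
    center = (np.asarray(shape) - 1) / 2.0
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = center - lin @ center + p[:3]
    return mat


def matrix_to_params(mat: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Recover [t, rot(deg)] of a (near-)rigid matrix built by params_to_matrix."""
    lin = mat[:3, :3]
    center = (np.asarray(shape) - 1) / 2.0
    t = mat[:3, 3] - center + lin @ center
    # inverse of the Rx @ Ry @ Rz composition used in params_to_matrix
    ry = np.arcsin(np.clip(lin[0, 2], -1, 1))
    rx = np.arctan2(-lin[1, 2], lin[2, 2])
    rz = np.arctan2(-lin[0, 1], lin[0, 0])
    return np.concatenate([t, np.rad2deg([rx, ry, rz])])


def mutual_information(fixed: np.ndarray, moved: np.ndarray, bins: int | None = None) -> float:
    """Histogram mutual information (nats) over voxels where both are defined."""
    valid = np.isfinite(moved)
    if valid.sum() < 32:
        return 0.0
    f = fixed[valid]
    m = moved[valid]
    if bins is None:
        # keep the joint histogram reasonably populated on coarse grids
        bins = int(np.clip(np.sqrt(f.size) / 4, 8, _N_BINS))
    hist, _, _ = np.histogram2d(f, m, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _pyramid(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    smoothed = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return smoothed[::factor, ::factor, ::factor]


def _neg_mi(params, fixed_c, moving_c, shape_full, factor):
    mat = params_to_matrix(np.asarray(params), shape_full)
    scale = np.diag([factor, factor, factor, 1.0]).astype(float)
    mat_c = np.linalg.inv(scale) @ mat @ scale
    moved = ndimage.affine_transform(
        moving_c, mat_c[:3, :3], mat_c[:3, 3], output_shape=fixed_c.shape,
        order=1, mode="constant", cval=np.nan,
    )
    return -mutual_information(fixed_c, moved)


def register_affine_mi(moving: Volume, fixed: Volume, dof: int = 12,
                       seed: int = 0, levels: tuple[int, ...] = (4, 2, 1),
                       maxiter: tuple[int, ...] | None = None) -> AffineTransform:
    """Affine registration of ``moving`` onto ``fixed`` by maximizing MI.

    Runs Powell over a multi-resolution pyramid (downsampling factors given in
    ``levels``).  The starting point is the identity plus a tiny seeded jitter,
    so results are deterministic for a given seed.  Returns the fixed->moving
    voxel transform suitable for :func:`resample_to_atlas`.
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9 or 12")
    fdat = np.asarray(fixed.data, dtype=float)
    mdat = np.asarray(moving.data, dtype=float)
    if fdat.std() == 0 or mdat.std() == 0:
        raise ValueError("degenerate image: constant intensity, MI undefined")

    n_params = {6: 6, 9: 9, 12: 12}[dof]
    rng = np.random.default_rng(seed)
    params = rng.normal(0.0, 0.01, n_params)
    if maxiter is None:
        maxiter = tuple(10 if f > 1 else 6 for f in levels)

    cost = np.nan
    for factor, it in zip(levels, maxiter):
        fixed_c = _pyramid(fdat, factor)
        moving_c = _pyramid(mdat, factor)
        if any(n < 12 for n in fixed_c.shape):
            continue  # too coarse for a stable histogram MI estimate
        res = optimize.minimize(
            _neg_mi, params, args=(fixed_c, moving_c, fdat.shape, factor),
            method="Powell",
            options={"maxiter": it, "xtol": 1e-4, "ftol": 1e-7},
        )
        params = res.x
        cost = -res.fun
    mat = params_to_matrix(params, fdat.shape)
    return AffineTransform(matrix=mat, dof=dof, cost=float(cost))


def resample_to_atlas(vol, transform: AffineTransform,
                      target_grid: tuple[int, int, int],
                      target_spacing: tuple[float, float, float] | None = None):
    """Resample a volume or mask into atlas space.

    Intensity volumes use trilinear interpolation; binary masks use nearest
    neighbor so they stay binary.  ``transform`` maps atlas voxels to the
    input's voxels.
    """
    mat = transform.matrix
    spacing = target_spacing or vol.spacing
    if isinstance(vol, VOIMask):
        out = ndimage.affine_transform(
            vol.data.astype(np.uint8), mat[:3, :3], mat[:3, 3],
            output_shape=tuple(target_grid), order=0, mode="constant", cval=0,
        )
        return VOIMask(data=out.astype(bool), spacing=spacing, space="atlas")
    data = np.asarray(vol.data, dtype=float)
    out = ndimage.affine_transform(
        data, mat[:3, :3], mat[:3, 3], output_shape=tuple(target_grid),
        order=1, mode="constant", cval=0.0,
    )
    if isinstance(vol, NormalizedVolume):
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        return NormalizedVolume(data=out, spacing=spacing, provenance=vol.provenance)
    return Volume(data=out, spacing=spacing)


def flip_lr(mask: VOIMask) -> VOIMask:
    """Mirror an atlas-space mask about the mid-sagittal (x midline) plane."""
    if mask.space != "atlas":
        raise ValueError("laterality flip is defined in atlas space only")
    return VOIMask(
        data=np.flip(mask.data, axis=0).copy(),
        spacing=mask.spacing, affine=mask.affine.copy(), space="atlas",
    )


def save_transform(transform: AffineTransform, path) -> None:
    """Serialize as a plain-text 4x4 row-major matrix."""
    np.savetxt(path, transform.matrix, header=f"dof={transform.dof} cost={transform.cost}")


def load_transform(path, dof: int = 12) -> AffineTransform:
    return AffineTransform(np.loadtxt(path), dof=dof)
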