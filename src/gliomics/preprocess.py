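"""Intensity normalization and derived channels.

Channels acquired on heterogeneous scanners are made comparable by mapping
each volume onto 256 gray levels.  T1, FLAIR and gadolinium-enhanced T1 are
winsorized at the 99.9th percentile first (the top 0.1% of voxels are mostly
high-signal noise); T2 keeps its full range.  Two derived channels are built:
a 3D Prewitt gradient-magnitude map of the T2 image (``T2Edge``) and a
voxel-wise z-scored enhancement map from the T1/Gd pair (``Gdzscore``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import NormalizedVolume, RawVolume, VOIMask, Volume, ZScoreVolume

__all__ = ["normalize_channel", "prewitt_edge", "gd_zscore", "derive_channels"]

_MODES = ("t2_fullrange", "clip999")


def normalize_channel(vol: Volume, mode: str) -> NormalizedVolume:
    """Map a raw channel onto integer gray levels 0..255.

    ``clip999`` caps values strictly above the 99.9th percentile at that
    percentile, then maps the retained range linearly onto 0..255;
    ``t2_fullrange`` maps min..max linearly.  A constant volume maps to all
    zeros.  The gray-level rule is floor(255 * (x - lo) / (hi - lo)) with the
    maximum mapped to 255, so the mapping is monotone non-decreasing and
    invariant to positive affine rescaling of the input.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    data = np.asarray(vol.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty volume")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input")

    if mode == "clip999":
        cap = np.percentile(data, 99.9)
        data = np.minimum(data, cap)
    lo, hi = data.min(), data.max()
    if hi == lo:
        levels = np.zeros(data.shape, dtype=np.uint8)
    else:
        levels = np.floor(255.0 * (data - lo) / (hi - lo))
        # floor sends only exact maxima to 255; everything else is already <255
        levels = np.clip(levels, 0, 255).astype(np.uint8)
    return NormalizedVolume(
        data=levels, spacing=vol.spacing, affine=vol.affine.copy(), provenance=mode
    )


# 1D Prewitt components: derivative [-1, 0, 1], smoothing [1, 1, 1]
def _prewitt_axis(data: np.ndarray, axis: int) -> np.ndarray:
    return ndimage.prewitt(data, axis=axis, mode="nearest")


def prewitt_edge(t2: NormalizedVolume) -> NormalizedVolume:
    """3D Prewitt gradient magnitude of a normalized T2 volume, re-scaled 0..255.

    The magnitude is the Euclidean norm of the three axis responses; the result
    is mapped back onto 256 gray levels with the full-range rule.
    """
    if any(n < 3 for n in t2.shape):
        raise ValueError(f"kernel larger than volume: shape {t2.shape}")
    data = np.asarray(t2.data, dtype=float)
    mag = np.sqrt(sum(_prewitt_axis(data, ax) ** 2 for ax in range(3)))
    out = normalize_channel(
        Volume(data=mag, spacing=t2.spacing, affine=t2.affine.copy()), "t2_fullrange"
    )
    out.provenance = "t2_fullrange"
    return out


def gd_zscore(t1: NormalizedVolume, gd: NormalizedVolume,
              reference_mask: VOIMask | np.ndarray) -> ZScoreVolume:
    """Voxel-wise z-scored contrast enhancement.

    The difference image d = Gd - T1 is standardized against its distribution
    over the reference mask (normal-appearing brain: brain minus lesion):
    z = (d - mean_ref) / sd_ref.  If the reference SD is zero the map is all
    zeros by convention.
    """
    ref = reference_mask.data if isinstance(reference_mask, VOIMask) else np.asarray(reference_mask)
    ref = ref.astype(bool)
    if not t1.same_grid(gd) or ref.shape != t1.shape:
        raise ValueError("grid mismatch between T1, Gd and reference mask")
    if not ref.any():
        raise ValueError("empty reference mask")
    d = np.asarray(gd.data, dtype=float) - np.asarray(t1.data, dtype=float)
    mean = float(d[ref].mean())
    sd = float(d[ref].std())  # population SD
    z = np.zeros_like(d) if sd == 0 else (d - mean) / sd
    return ZScoreVolume(
        data=z, spacing=t1.spacing, affine=t1.affine.copy(),
        reference_mean=mean, reference_sd=sd,
    )


def derive_channels(raw: dict, voi: VOIMask, brain_mask: np.ndarray | None = None) -> dict:
    """Normalize the four acquired channels and append T2Edge and Gdzscore.

    ``raw`` maps channel name -> RawVolume for T1, T2, FLAIR, Gd.  The Gd
    z-score reference is the brain mask minus the lesion; when no brain mask
    is given, positive-intensity T1 voxels stand in for the brain.
    """
    norm = {}
    for name, vol in raw.items():
        mode = "t2_fullrange" if name == "T2" else "clip999"
        norm[name] = normalize_channel(vol, mode)
    out = dict(norm)
    out["T2Edge"] = prewitt_edge(norm["T2"])
    if brain_mask is None:
        brain_mask = np.asarray(raw["T1"].data) > 0
    ref = brain_mask & ~voi.data
    out["Gdzscore"] = gd_zscore(norm["T1"], norm["Gd"], ref)
    return out
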