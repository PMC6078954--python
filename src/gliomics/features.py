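"""The 109-feature radiomic vector and cohort-level feature screens.

Per case, three aspects of the lesion are quantified:

* histogram-based first-order texture of the voxels inside the VOI, for each
  of six channels (T1, T2, FLAIR, Gd, T2Edge, Gdzscore);
* shape of the VOI (volume, sphericity);
* location, encoded as the occupancy ratio of the VOI over each label of two
  brain parcellations (10-label structural, 49-label cortical).

The default inventory is pinned at 109 features: 5 channels x 8 first-order
statistics + a Gdzscore block of 7 statistics plus the enhancing-area
fraction (``Gdzscore_ara.of.Gd.``) + 2 shape + 10 + 49 occupancies.  Column
names follow the ``MNI_str_loc.04`` / ``HrvdOxf_loc.01`` convention where
``loc.k`` refers to atlas label k-1 (so ``loc.01`` is the label-0 white
matter compartment).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .core import AtlasLabelMap, NormalizedVolume, VOIMask, ZScoreVolume

__all__ = [
    "FIRST_ORDER_STATS",
    "build_default_inventory",
    "first_order_features",
    "shape_features",
    "enhancement_area",
    "occupancy_features",
    "extract_case_features",
    "assemble_feature_table",
    "feature_columns",
    "anova_screen",
    "correlation_matrix",
]

logger = logging.getLogger(__name__)

FIRST_ORDER_STATS = (
    "mean", "sd", "skewness", "kurtosis", "median", "p10", "p90", "entropy",
)
TEXTURE_CHANNELS = ("T1", "T2", "FLAIR", "Gd", "T2Edge")
METADATA_COLUMNS = ("subtype", "institution")


def build_default_inventory() -> list[str]:
    """Ordered list of the 109 default feature names."""
    names: list[str] = []
    for ch in TEXTURE_CHANNELS:
        names += [f"{ch}_{s}" for s in FIRST_ORDER_STATS]
    names += [f"Gdzscore_{s}" for s in FIRST_ORDER_STATS if s != "entropy"]
    names += ["Gdzscore_ara.of.Gd."]
    names += ["shape_volume_mm3", "shape_sphericity"]
    names += [f"MNI_str_loc.{k + 1:02d}" for k in range(10)]
    names += [f"HrvdOxf_loc.{k + 1:02d}" for k in range(49)]
    assert len(names) == 109
    return names


def first_order_features(channel, voi: VOIMask, with_entropy: bool = True) -> dict:
    """Eight first-order statistics of the within-VOI intensity histogram.

    Mean, population SD, skewness, excess (Fisher) kurtosis, median, 10th and
    90th percentiles, and the Shannon entropy (bits) of the 256-level
    histogram.  A zero-variance region returns skewness and kurtosis 0 by
    convention (with a warning).  Entropy assumes 8-bit gray levels and is
    omitted for continuous channels via ``with_entropy=False``.
    """
    if not voi.data.any():
        raise ValueError("empty VOI")
    if channel.shape != voi.shape:
        raise ValueError("grid mismatch between channel and VOI")
    x = np.asarray(channel.data, dtype=float)[voi.data]
    out = {
        "mean": float(x.mean()),
        "sd": float(x.std()),
        "median": float(np.median(x)),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }
    if out["sd"] == 0:
        warnings.warn("zero-variance VOI: skewness/kurtosis set to 0", stacklevel=2)
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    else:
        out["skewness"] = float(stats.skew(x, bias=True))
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
    if with_entropy:
        hist, _ = np.histogram(x, bins=256, range=(-0.5, 255.5))
        p = hist[hist > 0] / hist.sum()
        out["entropy"] = float(-(p * np.log2(p)).sum())
    return {k: out[k] for k in FIRST_ORDER_STATS if k in out}


def shape_features(voi: VOIMask) -> dict:
    """Lesion volume (mm^3) and sphericity.

    Sphericity = pi^(1/3) (6V)^(2/3) / A, with A the surface area of the
    marching-cubes isosurface of the mask (1 for a perfect ball, smaller for
    elongated or irregular shapes).
    """
    if not voi.data.any():
        raise ValueError("empty VOI")
    volume = voi.n_voxels * voi.voxel_volume_mm3
    padded = np.pad(voi.data.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=voi.spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    return {"volume_mm3": float(volume), "sphericity": sphericity}


def enhancement_area(z: ZScoreVolume, voi: VOIMask, z_thresh: float = 2.0) -> float:
    """Fraction of VOI voxels whose enhancement z-score exceeds ``z_thresh``."""
    if not voi.data.any():
        raise ValueError("empty VOI")
    if z.shape != voi.shape:
        raise ValueError("grid mismatch between z map and VOI")
    zz = np.asarray(z.data, dtype=float)[voi.data]
    return float((zz > z_thresh).mean())


def occupancy_features(voi_atlas: VOIMask, atlas: AtlasLabelMap) -> dict:
    """Occupancy ratio of the VOI over every atlas label.

    Entry ``loc.k`` is the fraction of lesion voxels carrying atlas value
    k-1, so ``loc.01`` corresponds to label 0 (white matter / background).
    When the atlas labels every voxel the entries sum to 1.
    """
    if voi_atlas.shape != atlas.shape:
        raise ValueError("grid mismatch between VOI and atlas")
    if not voi_atlas.data.any():
        raise ValueError("empty VOI")
    values = atlas.data[voi_atlas.data]
    n = values.size
    label_vals = atlas.label_values()
    counts = {k: 0 for k in label_vals}
    uniq, cnt = np.unique(values, return_counts=True)
    for u, c in zip(uniq, cnt):
        counts[int(u)] = int(c)
    return {f"loc.{k + 1:02d}": counts[k] / n for k in label_vals}


def extract_case_features(channels: dict, voi: VOIMask, voi_atlas: VOIMask,
                          atlas10: AtlasLabelMap, atlas49: AtlasLabelMap,
                          z_thresh: float = 2.0) -> dict:
    """The full 109-entry feature dict for one case.

    ``channels`` must contain the six channels (four acquired plus T2Edge and
    Gdzscore); texture is measured in native space on ``voi``; occupancies in
    atlas space on ``voi_atlas``.
    """
    required = set(TEXTURE_CHANNELS) | {"Gdzscore"}
    missing = required - set(channels)
    if missing:
        raise KeyError(f"missing channels: {sorted(missing)}")
    feats: dict[str, float] = {}
    for ch in TEXTURE_CHANNELS:
        fo = first_order_features(channels[ch], voi)
        feats.update({f"{ch}_{k}": v for k, v in fo.items()})
    zvol = channels["Gdzscore"]
    fo = first_order_features(zvol, voi, with_entropy=False)
    feats.update({f"Gdzscore_{k}": v for k, v in fo.items()})
    feats["Gdzscore_ara.of.Gd."] = enhancement_area(zvol, voi, z_thresh)
    shp = shape_features(voi)
    feats["shape_volume_mm3"] = shp["volume_mm3"]
    feats["shape_sphericity"] = shp["sphericity"]
    occ10 = occupancy_features(voi_atlas, atlas10)
    feats.update({f"MNI_str_{k}": v for k, v in occ10.items()})
    occ49 = occupancy_features(voi_atlas, atlas49)
    feats.update({f"HrvdOxf_{k}": v for k, v in occ49.items()})
    return feats


def assemble_feature_table(case_records: list, inventory: list[str] | None = None) -> pd.DataFrame:
    """Assemble per-case feature dicts into a cases x features table.

    ``case_records`` holds (case_id, subtype, institution, features-or-None)
    tuples; cases with missing channels (features None or incomplete) are
    excluded with a logged warning, mirroring a complete-datasets-only
    analysis.  Columns follow the inventory order; metadata columns
    ``subtype`` and ``institution`` are appended.
    """
    inventory = inventory or build_default_inventory()
    rows, index, excluded = [], [], 0
    for case_id, subtype, institution, feats in case_records:
        if feats is None or any(name not in feats for name in inventory):
            excluded += 1
            continue
        rows.append([feats[name] for name in inventory] + [subtype, institution])
        index.append(case_id)
    if excluded:
        logger.warning("excluded %d case(s) with incomplete channels", excluded)
    table = pd.DataFrame(
        rows, index=pd.Index(index, name="case_id"),
        columns=list(inventory) + list(METADATA_COLUMNS),
    )
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-metadata) column names of a feature table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def anova_screen(table: pd.DataFrame, group_col: str = "subtype") -> pd.DataFrame:
    """One-way ANOVA of every feature across subtype groups.

    Returns a DataFrame with F, p and the significance bin
    (<0.001, [0.001,0.01), [0.01,0.05), >=0.05).  A feature with zero
    variance everywhere gets p = 1 by convention.
    """
    groups = table.groupby(group_col, observed=True)
    if groups.ngroups < 2:
        raise ValueError("need at least 2 groups for ANOVA")
    sizes = groups.size()
    if (sizes < 2).any():
        raise ValueError(f"each group needs >= 2 cases, got {sizes.to_dict()}")
    out = []
    for col in feature_columns(table):
        samples = [g[col].to_numpy(dtype=float) for _, g in groups]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            warnings.warn(f"feature {col!r} is constant; ANOVA p set to 1", stacklevel=2)
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
            if not np.isfinite(p):
                f_stat, p = 0.0, 1.0
        out.append((col, float(f_stat), float(p), _p_bin(p)))
    return pd.DataFrame(out, columns=["feature", "F", "p", "bin"]).set_index("feature")


def _p_bin(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "[0.001,0.01)"
    if p < 0.05:
        return "[0.01,0.05)"
    return ">=0.05"


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of all features.

    Constant columns get correlation 0 (with a warning); the diagonal is 1
    for non-constant columns.
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cases for correlations")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return pd.DataFrame(corr, index=cols, columns=cols)
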