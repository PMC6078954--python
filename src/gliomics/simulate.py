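"""Seeded synthetic glioma cohorts: toy atlases, lesion masks, MR-like channels.

The generator emulates the statistical structure that the downstream analysis
assumes for WHO grade II/III gliomas:

* three molecular subtypes — IDH-mutant astrocytoma, IDH+TERT co-mutated
  oligodendroglioma, IDH-wildtype astrocytoma — with subtype-biased lesion
  locations (frontal / frontotemporal / white-matter + parietal);
* subtype-dependent lesion intensity on four acquired channels
  (T1, T2, FLAIR, gadolinium-enhanced T1);
* a contrast-enhancing core strongly enriched in IDH-wildtype tumors;
* a multi-institution cohort manifest.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AtlasLabelMap, RawVolume, VOIMask, affine_from_spacing, save_volume

__all__ = [
    "SUBTYPES",
    "CHANNELS",
    "CohortSpec",
    "SyntheticCase",
    "make_toy_atlas",
    "simulate_cohort",
    "write_cohort",
]

SUBTYPES = ("IDHmt_astro", "IDHmt_TERTmt_oligo", "IDHwt")
CHANNELS = ("T1", "T2", "FLAIR", "Gd")

# Label tables.  The 10-label scheme mirrors a coarse whole-brain structural
# parcellation where label 0 is the deep white matter and label 3 the frontal
# lobe; the 49-label scheme mirrors a detailed cortical parcellation whose
# label 0 is everything non-cortical (white matter included).
MNI10_LABELS = {
    0: "White Matter",
    1: "Caudate",
    2: "Cerebellum",
    3: "Frontal Lobe",
    4: "Insula",
    5: "Occipital Lobe",
    6: "Parietal Lobe",
    7: "Putamen",
    8: "Temporal Lobe",
    9: "Thalamus",
}

_HO48_NAMES = [
    "Frontal Pole", "Insular Cortex", "Superior Frontal Gyrus",
    "Middle Frontal Gyrus", "Inferior Frontal Gyrus, pars triangularis",
    "Inferior Frontal Gyrus, pars opercularis", "Precentral Gyrus",
    "Temporal Pole", "Superior Temporal Gyrus, anterior division",
    "Superior Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, anterior division",
    "Middle Temporal Gyrus, posterior division",
    "Middle Temporal Gyrus, temporooccipital part",
    "Inferior Temporal Gyrus, anterior division",
    "Inferior Temporal Gyrus, posterior division",
    "Inferior Temporal Gyrus, temporooccipital part", "Postcentral Gyrus",
    "Superior Parietal Lobule", "Supramarginal Gyrus, anterior division",
    "Supramarginal Gyrus, posterior division", "Angular Gyrus",
    "Lateral Occipital Cortex, superior division",
    "Lateral Occipital Cortex, inferior division", "Intracalcarine Cortex",
    "Frontal Medial Cortex", "Juxtapositional Lobule Cortex",
    "Subcallosal Cortex", "Paracingulate Gyrus",
    "Cingulate Gyrus, anterior division", "Cingulate Gyrus, posterior division",
    "Precuneous Cortex", "Cuneal Cortex", "Frontal Orbital Cortex",
    "Parahippocampal Gyrus, anterior division",
    "Parahippocampal Gyrus, posterior division", "Lingual Gyrus",
    "Temporal Fusiform Cortex, anterior division",
    "Temporal Fusiform Cortex, posterior division",
    "Temporal Occipital Fusiform Cortex", "Occipital Fusiform Gyrus",
    "Frontal Operculum Cortex", "Central Opercular Cortex",
    "Parietal Operculum Cortex", "Planum Polare", "Heschl's Gyrus",
    "Planum Temporale", "Supracalcarine Cortex", "Occipital Pole",
]
HO49_LABELS = {0: "Non-cortical / White Matter"}
HO49_LABELS.update({i + 1: name for i, name in enumerate(_HO48_NAMES)})

# Default per-subtype lesion-center distribution over the 10 structural labels
# (order: WM, caudate, cerebellum, frontal, insula, occipital, parietal,
# putamen, temporal, thalamus).  Qualitative choices: IDH-mutant astrocytomas
# frontotemporal, oligodendrogliomas frontal-dominant, IDH-wildtype tumors in
# deep white matter and parietal lobe with little frontal involvement.
DEFAULT_LOCATION_WEIGHTS = {
    "IDHmt_astro":        (0.04, 0.01, 0.01, 0.34, 0.12, 0.01, 0.03, 0.01, 0.42, 0.01),
    "IDHmt_TERTmt_oligo": (0.03, 0.01, 0.01, 0.66, 0.05, 0.01, 0.02, 0.01, 0.19, 0.01),
    "IDHwt":              (0.62, 0.01, 0.01, 0.01, 0.03, 0.03, 0.24, 0.02, 0.02, 0.01),
}

# Lesion intensity offsets added to the brain baseline, per subtype/channel.
# Subtype deltas are modest (about one between-case SD, see
# DEFAULT_CASE_EFFECT_SD) so texture is informative but imperfect, the regime
# lower-grade glioma radiomics operates in.
DEFAULT_CHANNEL_MEANS = {
    "IDHmt_astro":        {"T1": -25.0, "T2": 62.0, "FLAIR": 55.0, "Gd": -10.0},
    "IDHmt_TERTmt_oligo": {"T1": -21.0, "T2": 68.0, "FLAIR": 59.0, "Gd": -6.0},
    "IDHwt":              {"T1": -29.0, "T2": 56.0, "FLAIR": 50.0, "Gd": 0.0},
}
DEFAULT_CHANNEL_SDS = {s: {c: 12.0 for c in CHANNELS} for s in SUBTYPES}
DEFAULT_CASE_EFFECT_SD = 12.0  # between-case spread of the lesion offset

BASELINE = {"T1": 120.0, "T2": 100.0, "FLAIR": 110.0, "Gd": 120.0}
BRAIN_NOISE_SD = 10.0
ENHANCING_CORE_OFFSET = 80.0  # added to Gd inside the enhancing core


def make_toy_atlas(grid_shape: tuple[int, int, int], scheme: str) -> AtlasLabelMap:
    """Build a deterministic toy brain parcellation.

    ``mni10``: an ellipsoidal brain whose deep core is label 0 (white matter)
    and whose shell is divided into 9 angular sectors, with label 3 placed
    anteriorly (the "frontal lobe").  ``ho49``: the same shell divided into
    48 cortical parcels (8 axial bands x 6 azimuthal sectors), label 0
    elsewhere.  Every voxel is labeled.
    """
    if scheme not in ("mni10", "ho49"):
        raise ValueError(f"unknown atlas scheme {scheme!r}")
    if any(n < 16 for n in grid_shape):
        raise ValueError(f"grid too small for a toy atlas: {grid_shape} (need >= 16 per axis)")

    ux, uy, uz = np.meshgrid(
        *(np.linspace(-1.0, 1.0, n) for n in grid_shape), indexing="ij"
    )
    r = np.sqrt((ux / 0.95) ** 2 + (uy / 0.95) ** 2 + (uz / 0.95) ** 2)
    brain = r <= 1.0
    shell = brain & (r > 0.55)
    theta = np.arctan2(uy, ux)  # +y is the anterior direction

    labels = np.zeros(grid_shape, dtype=np.int32)
    if scheme == "mni10":
        # 9 azimuthal sectors; the sector centered on +y receives label 3.
        b = np.floor(((theta - np.pi / 2 + np.pi / 9) % (2 * np.pi)) / (2 * np.pi / 9))
        sector_order = np.array([3, 4, 5, 6, 7, 8, 9, 1, 2])
        labels[shell] = sector_order[b[shell].astype(int)]
        table = dict(MNI10_LABELS)
    else:
        zband = np.clip(((uz + 1.0) / 2.0 * 8).astype(int), 0, 7)
        azbin = np.floor(((theta + np.pi) % (2 * np.pi)) / (2 * np.pi / 6)).astype(int)
        labels[shell] = (zband * 6 + azbin + 1)[shell]
        table = dict(HO49_LABELS)
    return AtlasLabelMap(data=labels, labels=table)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the modeled study population: 169 complete-imaging cases
    from 11 institutions, subtype mix close to the observed one, and the
    contrast-enhancement probability concentrated in IDH-wildtype tumors.
    """

    n_cases: int = 169
    n_institutions: int = 11
    subtype_proportions: tuple[float, float, float] = (0.32, 0.33, 0.35)
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    location_weights: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_LOCATION_WEIGHTS.items()}
    )
    channel_means: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANNEL_MEANS.items()}
    )
    channel_sds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHANNEL_SDS.items()}
    )
    enhancement_prob: dict = field(
        default_factory=lambda: {"IDHmt_astro": 0.1, "IDHmt_TERTmt_oligo": 0.1, "IDHwt": 0.6}
    )
    lesion_radius_mm: tuple[float, float] = (10.0, 25.0)
    case_effect_sd: float = DEFAULT_CASE_EFFECT_SD
    misalign: bool = False  # apply a small random rigid offset per case
    seed: int = 0

    def validate(self) -> None:
        if not np.isclose(sum(self.subtype_proportions), 1.0):
            raise ValueError("subtype_proportions must sum to 1")
        for s, row in self.location_weights.items():
            if not np.isclose(sum(row), 1.0):
                raise ValueError(f"location_weights[{s}] must sum to 1")
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.n_cases > 0 and not (self.n_cases >= self.n_institutions >= 1):
            raise ValueError("need n_cases >= n_institutions >= 1")
        lo, hi = self.lesion_radius_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion radius range must be positive and ordered")
        extent = min(n * s for n, s in zip(self.grid_shape, self.spacing_mm))
        if 2 * hi > extent:
            raise ValueError(
                f"impossible lesion radius {hi} mm for grid extent {extent} mm"
            )


@dataclass
class SyntheticCase:
    """One simulated patient: four raw channels plus the T2-space lesion mask."""

    case_id: str
    institution: int
    subtype: str
    channels: dict
    voi: VOIMask
    true_affine: np.ndarray | None = None  # voxel map applied when misaligned


def _largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Integer class counts summing to n, closest to n * proportions."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1
    return counts


def _interior_center(label_mask: np.ndarray, radius_vox: float, rng) -> np.ndarray:
    """Pick a lesion center inside a label region, preferring deep voxels.

    Voxels at least one lesion radius from the region boundary are preferred
    so that the seeded label dominates the lesion's occupancy vector; if the
    region is too thin, the deepest available voxels are used.
    """
    edt = ndimage.distance_transform_edt(label_mask)
    deep = edt >= radius_vox
    pool = np.argwhere(deep) if deep.any() else np.argwhere(edt >= 0.8 * edt.max())
    return pool[rng.integers(len(pool))]


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort; returns ``(cases, manifest)``.

    The manifest is a DataFrame with columns case_id, institution, subtype.
    Reproducible: identical spec (including seed) gives identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    manifest_cols = ["case_id", "institution", "subtype"]
    if spec.n_cases == 0:
        return [], pd.DataFrame(columns=manifest_cols)

    atlas = make_toy_atlas(spec.grid_shape, "mni10")
    # recompute the brain ellipsoid used by the atlas
    ux, uy, uz = np.meshgrid(
        *(np.linspace(-1.0, 1.0, n) for n in spec.grid_shape), indexing="ij"
    )
    r_grid = np.sqrt((ux / 0.95) ** 2 + (uy / 0.95) ** 2 + (uz / 0.95) ** 2)
    brain = r_grid <= 1.0

    # fixed cohort composition via largest remainder, then shuffled
    counts = _largest_remainder_counts(spec.n_cases, spec.subtype_proportions)
    subtypes = np.repeat(np.arange(3), counts)
    rng.shuffle(subtypes)
    institutions = np.arange(spec.n_cases) % spec.n_institutions
    rng.shuffle(institutions)

    # per-subtype lesion-seed labels are quota-allocated (largest remainder)
    # so the planted location distribution is matched exactly up to rounding;
    # only the within-label placement is random
    case_labels = np.zeros(spec.n_cases, dtype=int)
    for s_idx, subtype in enumerate(SUBTYPES):
        idxs = np.where(subtypes == s_idx)[0]
        lab_counts = _largest_remainder_counts(
            len(idxs), np.asarray(spec.location_weights[subtype], dtype=float)
        )
        labels_s = np.repeat(np.arange(10), lab_counts)
        rng.shuffle(labels_s)
        case_labels[idxs] = labels_s

    spacing = tuple(spec.spacing_mm)
    affine = affine_from_spacing(spacing)
    coords_mm = [np.arange(n) * s for n, s in zip(spec.grid_shape, spacing)]
    # centers are drawn inside the brain only: label 0 otherwise also covers
    # the outside-background, which shares its atlas value with white matter
    label_pools = {k: (atlas.data == k) & brain for k in range(10)}

    cases: list[SyntheticCase] = []
    rows = []
    for i in range(spec.n_cases):
        subtype = SUBTYPES[subtypes[i]]
        case_id = f"case_{i:04d}"
        base_r = rng.uniform(*spec.lesion_radius_mm)

        label = int(case_labels[i])
        center = _interior_center(
            label_pools[label], base_r / float(np.mean(spacing)), rng
        ).astype(float)

        def _axis(a):
            idx = [None, None, None]
            idx[a] = slice(None)
            return coords_mm[a][tuple(idx)] - center[a] * spacing[a]

        # axis-aligned ellipsoid with mild anisotropy (axis ratio <= 2)
        aniso = rng.uniform(1 / np.sqrt(2), np.sqrt(2), size=3)
        semi = base_r * aniso
        dist2 = sum((_axis(a) / semi[a]) ** 2 for a in range(3))
        lesion = dist2 <= 1.0
        lesion &= brain
        cidx = tuple(center.astype(int))
        lesion[cidx] = True  # never empty

        enhancing = None
        if rng.uniform() < spec.enhancement_prob[subtype]:
            core2 = sum((_axis(a) / (0.5 * base_r)) ** 2 for a in range(3))
            enhancing = (core2 <= 1.0) & lesion
            enhancing[cidx] = True

        channels = {}
        for ch in CHANNELS:
            vol = np.zeros(spec.grid_shape, dtype=float)
            vol[brain] = BASELINE[ch] + rng.normal(0.0, BRAIN_NOISE_SD, brain.sum())
            # case-level random effect: tumors of one subtype vary around the
            # subtype mean, so cohort-level texture contrasts stay imperfect
            case_mu = spec.channel_means[subtype][ch] + rng.normal(0.0, spec.case_effect_sd)
            offset = rng.normal(
                case_mu, spec.channel_sds[subtype][ch], int(lesion.sum())
            )
            vol[lesion] += offset
            if ch == "Gd" and enhancing is not None:
                vol[enhancing] += ENHANCING_CORE_OFFSET
            channels[ch] = vol

        voi = lesion
        true_affine = None
        if spec.misalign:
            true_affine = _small_rigid(spec.grid_shape, rng)
            mat, off = true_affine[:3, :3], true_affine[:3, 3]
            for ch in CHANNELS:
                channels[ch] = ndimage.affine_transform(
                    channels[ch], mat, off, order=1, mode="constant"
                )
            voi = ndimage.affine_transform(
                voi.astype(float), mat, off, order=0, mode="constant"
            ) > 0.5

        cases.append(
            SyntheticCase(
                case_id=case_id,
                institution=int(institutions[i]),
                subtype=subtype,
                channels={
                    ch: RawVolume(data=v, spacing=spacing, affine=affine.copy())
                    for ch, v in channels.items()
                },
                voi=VOIMask(data=voi, spacing=spacing, affine=affine.copy(),
                            space="native" if spec.misalign else "atlas"),
                true_affine=true_affine,
            )
        )
        rows.append((case_id, int(institutions[i]), subtype))

    manifest = pd.DataFrame(rows, columns=manifest_cols)
    return cases, manifest


def _small_rigid(shape, rng) -> np.ndarray:
    """Random small rigid voxel transform: <=5 deg rotation, <=3 mm-ish shift."""
    ang = np.deg2rad(rng.uniform(-5, 5, 3))
    cx, cy, cz = np.cos(ang)
    sx, sy, sz = np.sin(ang)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rx @ ry @ rz
    center = (np.asarray(shape) - 1) / 2.0
    t = rng.uniform(-0.75, 0.75, 3)  # voxels (3 mm at 4 mm spacing)
    aff = np.eye(4)
    aff[:3, :3] = rot
    aff[:3, 3] = center - rot @ center + t
    return aff


def write_cohort(cases, manifest: pd.DataFrame, outdir, spec: CohortSpec | None = None):
    """Write per-case NIfTI volumes, a manifest CSV and the spec as JSON.

    Returns the manifest augmented with file-path columns (paths relative to
    ``outdir``, so identical cohorts are byte-identical on disk regardless of
    where they are written).  Volumes are stored uncompressed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    path_cols: dict[str, list[str]] = {f"path_{c}": [] for c in CHANNELS}
    path_cols["path_voi"] = []
    for case in cases:
        for ch in CHANNELS:
            name = f"{case.case_id}_{ch}.nii"
            save_volume(case.channels[ch], outdir / name)
            path_cols[f"path_{ch}"].append(name)
        name = f"{case.case_id}_voi.nii"
        save_volume(case.voi, outdir / name)
        path_cols["path_voi"].append(name)
    for col, vals in path_cols.items():
        manifest[col] = vals
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if spec is not None:
        d = asdict(spec)
        (outdir / "cohort_spec.json").write_text(json.dumps(d, indent=2, default=list))
    return manifest
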