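"""Voxel-wise lesion-frequency statistics across molecular subtypes.

At every atlas voxel touched by at least one lesion, a 3x2 contingency table
(subtype x lesion-positive/negative) is tested with a two-tailed exact
conditional test; family-wise error over voxels is controlled by cluster-based
permutation: subtype labels are shuffled across cases, the suprathreshold
cluster landscape recomputed, and observed clusters compared against the
permutation distribution of the maximum cluster size.

The two-tailed definition is the probability-ordering rule: the p-value sums
the hypergeometric probabilities of all fixed-margin tables no more probable
than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln

__all__ = [
    "fisher_3x2_p",
    "voxelwise_fisher_map",
    "lesion_frequency_maps",
    "cluster_permutation_correct",
    "FrequencyMap",
    "ClusterResult",
]

_TOL = 1.0 + 1e-7  # relative slack when comparing table probabilities


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


@lru_cache(maxsize=1_000_000)
def _fisher_sorted(rows: tuple) -> float:
    """Exact two-tailed p for sorted ((k, n), ...) rows of a 3x2 table."""
    (k1, n1), (k2, n2), (k3, n3) = rows
    c1 = k1 + k2 + k3
    n = n1 + n2 + n3
    if c1 == 0 or c1 == n:
        return 1.0
    denom = _log_binom(n, c1)
    logp_obs = (
        _log_binom(n1, k1) + _log_binom(n2, k2) + _log_binom(n3, k3) - denom
    )
    p_obs = np.exp(logp_obs)

    total = 0.0
    x1 = np.arange(max(0, c1 - n2 - n3), min(n1, c1) + 1)
    lb1 = _log_binom(n1, x1)
    for i, a in enumerate(x1):
        rest = c1 - a
        x2 = np.arange(max(0, rest - n3), min(n2, rest) + 1)
        if x2.size == 0:
            continue
        x3 = rest - x2
        logp = lb1[i] + _log_binom(n2, x2) + _log_binom(n3, x3) - denom
        p = np.exp(logp)
        total += p[p <= p_obs * _TOL].sum()
    return float(min(total, 1.0))


def fisher_3x2_p(table) -> float:
    """Two-tailed exact conditional test of a 3x2 contingency table.

    Rows are (lesion-positive, lesion-negative) counts per subtype.  Exhaustive
    over all tables with the observed margins; invariant under row permutation.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (3, 2):
        raise ValueError("expected a 3x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    rows = tuple(sorted((int(k), int(k + m)) for k, m in t))
    return _fisher_sorted(rows)


def _stack_masks(masks) -> np.ndarray:
    arrs = [np.asarray(getattr(m, "data", m)).astype(bool) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all masks must share one atlas grid")
    return np.stack(arrs)


def _group_indices(subtypes, groups=None):
    subtypes = list(subtypes)
    if groups is None:
        groups = sorted(set(subtypes))
    missing = [g for g in groups if g not in subtypes]
    if missing:
        raise ValueError(f"subtype(s) missing from cohort: {missing}")
    labels = np.array([groups.index(s) for s in subtypes])
    return labels, list(groups)


class _PTable:
    """Lazy lookup of exact p-values for per-group lesion counts."""

    def __init__(self, group_sizes: np.ndarray):
        self.n = tuple(int(x) for x in group_sizes)
        size = int(np.prod([x + 1 for x in self.n]))
        self.flat = np.full(size, np.nan)

    def encode(self, counts: np.ndarray) -> np.ndarray:
        n1, n2, n3 = self.n
        return (counts[:, 0] * (n2 + 1) + counts[:, 1]) * (n3 + 1) + counts[:, 2]

    def lookup(self, counts: np.ndarray) -> np.ndarray:
        codes = self.encode(counts)
        miss = np.isnan(self.flat[codes])
        if miss.any():
            for row in np.unique(counts[miss], axis=0):
                k1, k2, k3 = (int(v) for v in row)
                key = tuple(sorted(((k1, self.n[0]), (k2, self.n[1]), (k3, self.n[2]))))
                code = (k1 * (self.n[1] + 1) + k2) * (self.n[2] + 1) + k3
                self.flat[code] = _fisher_sorted(key)
        return self.flat[codes]


@dataclass
class FrequencyMap:
    """Per-subtype lesion occurrence counts and frequencies in atlas space."""

    groups: list
    counts: dict      # group -> 3D int array
    frequencies: dict  # group -> 3D float array in [0, 1]
    group_sizes: dict


def lesion_frequency_maps(masks, subtypes, groups=None) -> FrequencyMap:
    """Voxel-wise lesion occurrence count / frequency for each subtype."""
    stack = _stack_masks(masks)
    labels, groups = _group_indices(subtypes, groups)
    counts, freqs, sizes = {}, {}, {}
    for gi, g in enumerate(groups):
        sel = stack[labels == gi]
        counts[g] = sel.sum(axis=0)
        sizes[g] = int(sel.shape[0])
        freqs[g] = counts[g] / max(sizes[g], 1)
    return FrequencyMap(groups=groups, counts=counts, frequencies=freqs,
                        group_sizes=sizes)


def voxelwise_fisher_map(masks, subtypes, groups=None) -> np.ndarray:
    """Exact-test p-value at every voxel with at least one lesion occurrence.

    Returns a float array shaped like the atlas grid with NaN at voxels no
    lesion touches (those voxels receive no test).
    """
    stack = _stack_masks(masks)
    labels, groups = _group_indices(subtypes, groups)
    if len(groups) != 3:
        raise ValueError("expected exactly 3 subtype groups")
    shape = stack.shape[1:]
    flat = stack.reshape(stack.shape[0], -1)
    active = flat.any(axis=0)
    group_sizes = np.bincount(labels, minlength=3)
    onehot = np.eye(3)[labels].T  # 3 x cases
    counts = (onehot @ flat[:, active]).T.astype(int)  # active-voxels x 3
    ptab = _PTable(group_sizes)
    pvals = ptab.lookup(counts)
    out = np.full(shape, np.nan).reshape(-1)
    out[active] = pvals
    return out.reshape(shape)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterResult:
    """Observed suprathreshold clusters with permutation-corrected significance."""

    sig_mask: np.ndarray          # observed suprathreshold voxels (p < alpha)
    corrected_mask: np.ndarray    # union of corrected-significant clusters
    clusters: pd.DataFrame        # cluster_id, size, peak_p, corrected_p, significant
    null_max_sizes: np.ndarray    # length n_permutations
    size_threshold: float         # 95th percentile of the null max-size distribution
    p_map: np.ndarray


def cluster_permutation_correct(
    masks, subtypes, n_permutations: int = 500, alpha: float = 0.05,
    connectivity: int = 26, seed: int = 0, groups=None,
    ignore_laterality: bool = False,
) -> ClusterResult:
    """Cluster-based permutation correction of the voxel-wise exact-test map.

    Observed clusters are connected components (``connectivity`` in
    {6, 18, 26}) of voxels with p < ``alpha``.  For each permutation the
    subtype labels are reshuffled across cases (group sizes preserved), the
    p-map recomputed, and the maximum suprathreshold cluster size recorded.
    Each cluster's corrected p is the add-one Monte-Carlo estimate
    (1 + #{null max >= size}) / (n_permutations + 1); a cluster is
    corrected-significant when that p is <= ``alpha`` (equivalently, its size
    exceeds the alpha-tail of the null max-size distribution).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    stack = _stack_masks(masks)
    if ignore_laterality:
        stack = stack | np.flip(stack, axis=1)  # union with left-right mirror
    labels, groups = _group_indices(subtypes, groups)
    if len(groups) != 3:
        raise ValueError("expected exactly 3 subtype groups")
    rng = np.random.default_rng(seed)
    structure = _STRUCTURES[connectivity]

    shape = stack.shape[1:]
    flat = stack.reshape(stack.shape[0], -1)
    active = flat.any(axis=0)
    occ = flat[:, active].astype(float)
    group_sizes = np.bincount(labels, minlength=3)
    ptab = _PTable(group_sizes)

    def pmap_for(lab: np.ndarray) -> np.ndarray:
        onehot = np.eye(3)[lab].T
        counts = (onehot @ occ).T.astype(int)
        return ptab.lookup(counts)

    def max_cluster(pvals: np.ndarray) -> tuple[int, np.ndarray, int]:
        supra = np.zeros(active.size, dtype=bool)
        supra[active] = pvals < alpha
        supra = supra.reshape(shape)
        lab_img, n_clust = ndimage.label(supra, structure=structure)
        if n_clust == 0:
            return 0, lab_img, 0
        sizes = np.bincount(lab_img.reshape(-1))[1:]
        return int(sizes.max()), lab_img, n_clust

    obs_p = pmap_for(labels)
    _, obs_lab, n_clust = max_cluster(obs_p)

    null_max = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        null_max[i], _, _ = max_cluster(pmap_for(rng.permutation(labels)))

    threshold = float(np.percentile(null_max, 95))
    p_map_full = np.full(active.size, np.nan)
    p_map_full[active] = obs_p
    p_map_full = p_map_full.reshape(shape)

    rows = []
    corrected = np.zeros(shape, dtype=bool)
    for cid in range(1, n_clust + 1):
        members = obs_lab == cid
        size = int(members.sum())
        peak_p = float(np.nanmin(p_map_full[members]))
        corr_p = float((1 + (null_max >= size).sum()) / (n_permutations + 1))
        significant = corr_p <= alpha
        if significant:
            corrected |= members
        rows.append((cid, size, peak_p, corr_p, significant))
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_p", "corrected_p", "significant"]
    )
    return ClusterResult(
        sig_mask=obs_lab > 0, corrected_mask=corrected, clusters=clusters,
        null_max_sizes=null_max, size_threshold=threshold, p_map=p_map_full,
    )
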