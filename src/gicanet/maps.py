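"""Group-level component significance maps with permutation cluster correction.

Each component's subject maps (z-scored intensities) enter a voxel-wise
one-sample t-test against zero.  Voxels beyond the voxel-level threshold
(default p < .001, one-sided positive tail: component "involvement" is
positive under the sign convention) form clusters by 26-connectivity; the
family-wise error of cluster extents is controlled by a subject-wise
sign-flipping permutation null of the maximum cluster size.  Surviving
clusters are binarised into the mask used for template matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

__all__ = ["GroupComponentMap", "group_tmap", "threshold_and_correct"]


@dataclass
class GroupComponentMap:
    """One component's group t-map, cluster table and binarised mask."""

    t_map: np.ndarray                 # grid-shaped
    df: int
    voxel_p: float
    cluster_alpha: float
    binary_mask: np.ndarray           # grid-shaped bool
    surviving_clusters: list[tuple[int, float, tuple[int, ...]]]
    critical_extent: int
    zero_variance_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def group_tmap(
    subject_maps: np.ndarray, t_cap: float = 1e4
) -> tuple[np.ndarray, int, np.ndarray]:
    """Voxel-wise one-sample t against 0 across subjects.

    Parameters
    ----------
    subject_maps:
        (n_subjects, ...) stack of per-subject maps (any trailing shape).
    t_cap:
        Cap for the otherwise unbounded t at zero-variance voxels with a
        nonzero mean.

    Returns
    -------
    (t_map, df, zero_variance_flags):
        ``df = n_subjects - 1``; zero-variance voxels get t = 0 (zero mean)
        or +/- ``t_cap`` (nonzero mean) and are flagged.
    """
    x = np.asarray(subject_maps, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("group t-map requires >= 3 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero_var, np.sign(mean) * t_cap, t)
    t = np.clip(t, -t_cap, t_cap)
    return t, n - 1, zero_var


def _cluster_sizes(
    supra: np.ndarray, structure: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n_clusters = ndimage.label(supra, structure=structure)
    if n_clusters == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n_clusters, sizes


def threshold_and_correct(
    subject_maps: np.ndarray,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    tail: str = "positive",
    connectivity: int = 26,
    t_cap: float = 1e4,
) -> GroupComponentMap:
    """Threshold a component's group t-map and apply cluster-extent FWE correction.

    Parameters
    ----------
    subject_maps:
        (n_subjects, nx, ny, nz) stack of per-subject component maps.
    voxel_p:
        Cluster-forming voxel-level p threshold (default .001).
    cluster_alpha:
        Family-wise error level for cluster extents (default .05).
    n_permutations:
        Number of subject-wise sign-flip permutations (>= 100).
    tail:
        "positive" (default, one-sided involvement test) or "two-sided".
    connectivity:
        6, 18 or 26 (default) neighbourhood for cluster forming.

    Notes
    -----
    The null distribution of the maximum cluster extent is built by randomly
    flipping each subject's map sign and re-thresholding; a cluster survives
    when its permutation p-value (1 + #{null max >= size}) / (n_permutations
    + 1) is at most ``cluster_alpha``.
    """
    if not 0 < voxel_p <= 1:
        raise ValueError("voxel_p must be in (0, 1]")
    if not 0 < cluster_alpha < 1:
        raise ValueError("cluster_alpha must be in (0, 1)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")

    x = np.asarray(subject_maps, dtype=float)
    n = x.shape[0]
    grid_shape = x.shape[1:]
    flat = x.reshape(n, -1)
    t_map, df, zero_var = group_tmap(flat, t_cap=t_cap)

    if tail == "positive":
        t_thresh = stats.t.isf(voxel_p, df)
    elif tail == "two-sided":
        t_thresh = stats.t.isf(voxel_p / 2.0, df)
    else:
        raise ValueError("tail must be 'positive' or 'two-sided'")

    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    def supra_of(tvals: np.ndarray) -> np.ndarray:
        if tail == "positive":
            return (tvals >= t_thresh).reshape(grid_shape)
        return (np.abs(tvals) >= t_thresh).reshape(grid_shape)

    # permutation null of the max cluster extent; sign flips leave sum(x^2)
    # per voxel unchanged, so the t statistics vectorise over permutations
    rng = np.random.default_rng(seed)
    sumsq = (flat**2).sum(axis=0)
    null_max = np.empty(n_permutations, dtype=int)
    chunk = max(1, min(n_permutations, 64))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n))
        means = (signs @ flat) / n
        var = (sumsq[None, :] - n * means**2) / (n - 1)
        var = np.clip(var, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=t_cap, neginf=-t_cap)
        for row in t_perm:
            _, n_cl, sizes = _cluster_sizes(supra_of(row), structure)
            null_max[done] = int(sizes.max()) if n_cl else 0
            done += 1
        del signs, means, var, t_perm

    supra = supra_of(t_map)
    labels, n_clusters, sizes = _cluster_sizes(supra, structure)

    null_sorted = np.sort(null_max)
    # smallest extent whose permutation p-value is <= cluster_alpha
    critical = None
    for size_candidate in np.unique(np.concatenate([sizes, [1]])):
        p = (1 + np.count_nonzero(null_max >= size_candidate)) / (n_permutations + 1)
        if p <= cluster_alpha and (critical is None or size_candidate < critical):
            critical = int(size_candidate)
    if critical is None:
        # no candidate survives: report the extent that would have been needed
        critical = int(null_sorted[-1]) + 1 if n_permutations else 1

    t_grid = t_map.reshape(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    surviving: list[tuple[int, float, tuple[int, ...]]] = []
    for c in range(1, n_clusters + 1):
        in_cluster = labels == c
        size = int(in_cluster.sum())
        p_cluster = (1 + np.count_nonzero(null_max >= size)) / (n_permutations + 1)
        if p_cluster <= cluster_alpha:
            mask |= in_cluster
            tvals = np.where(in_cluster, np.abs(t_grid), -np.inf)
            peak_flat = int(np.argmax(tvals))
            peak = tuple(int(i) for i in np.unravel_index(peak_flat, grid_shape))
            surviving.append((size, float(t_grid[peak]), peak))
    surviving.sort(key=lambda c: -c[0])

    return GroupComponentMap(
        t_map=t_grid,
        df=df,
        voxel_p=voxel_p,
        cluster_alpha=cluster_alpha,
        binary_mask=mask,
        surviving_clusters=surviving,
        critical_extent=critical,
        zero_variance_voxels=zero_var.reshape(grid_shape),
    )
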