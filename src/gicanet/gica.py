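"""Group spatial ICA with MDL order selection and back-reconstruction.

The decomposition follows the temporal-concatenation scheme standard in
group ICA of fMRI: each subject's (time x voxel) data are reduced along the
time dimension by PCA, the reduced data are concatenated across subjects and
reduced again to the model order, and the group matrix is unmixed by
fixed-point spatial ICA (sources are spatial maps, the mixing matrix holds
time courses).  Subject-specific maps and time courses are recovered by
back-projection through the stored reduction operators.

The model order is estimated per subject from the eigenvalue spectrum of the
time-demeaned data covariance with the classical information-theoretic
minimum-description-length criterion, then averaged across subjects and
minimised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "OrderEstimate",
    "SubjectReduction",
    "GroupDecomposition",
    "mdl_criterion",
    "estimate_order_mdl",
    "subject_reduce",
    "group_decompose",
    "back_reconstruct",
]


# ---------------------------------------------------------------------------
# MDL model-order selection
# ---------------------------------------------------------------------------

@dataclass
class OrderEstimate:
    """MDL criterion values per subject and the group-mean selection."""

    candidate_orders: np.ndarray
    per_subject_mdl: np.ndarray  # (n_subjects, n_candidates)
    group_mean_mdl: np.ndarray
    selected_order: int


def mdl_criterion(
    eigenvalues: np.ndarray, n_samples: int, candidate_orders: np.ndarray
) -> np.ndarray:
    """Classical MDL criterion over candidate signal ranks.

    For eigenvalues lambda_1 >= ... >= lambda_p of the data covariance and
    N observed samples,

        MDL(k) = -N (p - k) log( gm(lambda_{k+1..p}) / am(lambda_{k+1..p}) )
                 + 1/2 k (2p - k) log N

    where gm/am are the geometric and arithmetic means of the trailing
    eigenvalues.  The first term is the log-likelihood cost of modelling the
    tail as isotropic; the second penalises model complexity.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    p = lam.size
    lam = np.clip(lam, 1e-300, None)
    candidate_orders = np.asarray(candidate_orders, dtype=int)
    if candidate_orders.max() >= p:
        raise ValueError("candidate order must be < number of eigenvalues")
    # suffix cumulative sums for O(p) evaluation of tail means
    csum = np.cumsum(lam[::-1])[::-1]          # csum[k] = sum lam[k:]
    clog = np.cumsum(np.log(lam)[::-1])[::-1]  # clog[k] = sum log lam[k:]
    out = np.empty(candidate_orders.size)
    for i, k in enumerate(candidate_orders):
        m = p - k
        log_gm = clog[k] / m
        log_am = np.log(csum[k] / m)
        out[i] = -n_samples * m * (log_gm - log_am) + 0.5 * k * (2 * p - k) * np.log(
            n_samples
        )
    return out


def estimate_order_mdl(
    subject_data: list[np.ndarray],
    candidate_orders: np.ndarray | None = None,
    demean: bool = True,
) -> OrderEstimate:
    """Estimate the group model order by group-mean MDL.

    Parameters
    ----------
    subject_data:
        One (time, voxel) array per subject (runs already concatenated in
        time).  All subjects need the same number of volumes.
    candidate_orders:
        Candidate signal ranks; default 0 .. T-2.  The selection is floored
        at 1 (with a warning) if the criterion is minimised at 0.
    demean:
        Remove each voxel's temporal mean before the covariance (default).
    """
    if len(subject_data) < 2:
        raise ValueError("MDL order estimation needs >= 2 subjects")
    p = subject_data[0].shape[0]
    if any(d.shape[0] != p for d in subject_data):
        raise ValueError("all subjects must have the same number of volumes")
    if candidate_orders is None:
        candidate_orders = np.arange(0, p - 1)
    candidate_orders = np.asarray(candidate_orders, dtype=int)
    if candidate_orders.max() >= p:
        raise ValueError("candidate orders must be below the number of volumes")

    per_subject = np.empty((len(subject_data), candidate_orders.size))
    for s, data in enumerate(subject_data):
        y = np.asarray(data, dtype=float)
        if demean:
            y = y - y.mean(axis=0, keepdims=True)
        n_vox = y.shape[1]
        if not (y != 0).any():
            raise ValueError(f"subject {s}: data have zero variance")
        cov = (y @ y.T) / n_vox
        lam = np.linalg.eigvalsh(cov)[::-1]
        per_subject[s] = mdl_criterion(lam, n_vox, candidate_orders)

    group_mean = per_subject.mean(axis=0)
    selected = int(candidate_orders[int(np.argmin(group_mean))])
    if selected < 1:
        warnings.warn(
            "MDL minimised at order 0 (no detectable signal subspace); "
            "flooring selected order at 1",
            stacklevel=2,
        )
        selected = 1
    return OrderEstimate(
        candidate_orders=candidate_orders,
        per_subject_mdl=per_subject,
        group_mean_mdl=group_mean,
        selected_order=selected,
    )


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class SubjectReduction:
    """Time-dimension principal-subspace projection of one subject's data.

    ``data`` (d, voxel) are the reduced data; ``basis`` (time, d) holds the
    retained left singular vectors so that ``basis @ data`` reconstructs the
    retained part of the (demeaned) input.  ``voxel_means`` are the removed
    temporal means.
    """

    data: np.ndarray
    basis: np.ndarray
    voxel_means: np.ndarray
    singular_values: np.ndarray

    @property
    def target_dim(self) -> int:
        return self.basis.shape[1]


def subject_reduce(run_data: np.ndarray, target_dim: int) -> SubjectReduction:
    """Project one subject's (time, voxel) data onto its principal temporal subspace.

    Retains ``target_dim`` directions of the time dimension; the projection
    basis is stored for back-reconstruction.
    """
    y = np.asarray(run_data, dtype=float)
    if y.ndim != 2:
        raise ValueError("run_data must be a (time, voxel) array")
    t, v = y.shape
    if target_dim > min(t, v):
        raise ValueError(
            f"target_dim {target_dim} exceeds min(volumes={t}, voxels={v})"
        )
    if target_dim < 1:
        raise ValueError("target_dim must be >= 1")
    means = y.mean(axis=0, keepdims=True)
    yc = y - means
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    basis = u[:, :target_dim]
    reduced = basis.T @ yc
    return SubjectReduction(
        data=reduced,
        basis=basis,
        voxel_means=means.ravel(),
        singular_values=s[:target_dim],
    )


# ---------------------------------------------------------------------------
# Group decomposition
# ---------------------------------------------------------------------------

@dataclass
class GroupDecomposition:
    """Group spatial ICA result with stored back-reconstruction operators.

    ``group_maps`` are z-scaled (component, voxel) spatial maps with
    nonnegative skewness; ``subject_timecourses[s]`` is (time, component) and
    ``subject_maps[s]`` is (component, voxel) for subject ``s``.
    """

    n_components: int
    group_maps: np.ndarray
    group_maps_raw: np.ndarray
    mixing: np.ndarray                      # (group dim C, C)
    group_basis: np.ndarray                 # (n_subjects * d, C)
    subject_ids: list[str]
    reductions: dict[str, SubjectReduction]
    subject_timecourses: dict[str, np.ndarray]
    subject_maps: dict[str, np.ndarray]
    seed: int
    negentropy: float = field(default=np.nan)

    def subject_maps_z(self) -> dict[str, np.ndarray]:
        """Subject maps z-scored across voxels per component (for group stats)."""
        out = {}
        for s, m in self.subject_maps.items():
            mu = m.mean(axis=1, keepdims=True)
            sd = m.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            out[s] = (m - mu) / sd
        return out


def _negentropy_score(sources: np.ndarray) -> float:
    """Sum of squared logcosh-negentropy gaps to a standard Gaussian."""
    s = sources - sources.mean(axis=0, keepdims=True)
    sd = s.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    s = s / sd
    # E[log cosh nu] for nu ~ N(0,1)
    gauss = 0.3745672075
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=0) - gauss) ** 2))


def group_decompose(
    reduced_subjects: dict[str, SubjectReduction],
    n_components: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> GroupDecomposition:
    """Temporal-concatenation group spatial ICA on PCA-reduced subjects.

    Subject-reduced data are stacked along the (reduced) time axis, reduced
    again to ``n_components`` by PCA, and unmixed by fixed-point ICA with the
    logcosh nonlinearity.  The best of ``n_restarts`` seeded restarts by the
    negentropy score is kept; each group map's sign is fixed so its skewness
    is nonnegative, and maps are z-scaled.  Subject time courses and maps are
    recovered through the stored projection operators.
    """
    if not reduced_subjects:
        raise ValueError("no reduced subjects supplied")
    subject_ids = list(reduced_subjects)
    dims = [reduced_subjects[s].target_dim for s in subject_ids]
    if len(set(dims)) != 1:
        raise ValueError("all subjects must be reduced to a common dimension")
    d = dims[0]
    if d < n_components:
        raise ValueError(
            f"common reduced dimension {d} is below n_components {n_components}"
        )

    x = np.vstack([reduced_subjects[s].data for s in subject_ids])  # (N*d, V)
    # group-level PCA of the concatenated reduced data
    u, s_vals, vt = np.linalg.svd(x, full_matrices=False)
    group_basis = u[:, :n_components]                # (N*d, C)
    g = group_basis.T @ x                            # (C, V)

    ss = np.random.SeedSequence(seed)
    best = None
    any_converged = False
    for child in ss.spawn(n_restarts):
        restart_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=restart_seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(g.T)  # (V, C)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        score = _negentropy_score(sources)
        if converged:
            any_converged = True
        if best is None or (converged, score) > (best[0], best[1]):
            best = (converged, score, sources, ica)
    if not any_converged:
        raise RuntimeError(
            f"group ICA failed to converge in {n_restarts} restarts (seed={seed})"
        )

    _, score, sources, ica = best
    maps = sources.T                        # (C, V): spatial sources
    mixing = ica.mixing_                    # (C, C): g.T ~ sources @ mixing.T + mean
    source_mean = ica.mean_                 # per-row mean of g

    # sign convention: nonnegative skewness of each group map
    for c in range(n_components):
        if skew(maps[c]) < 0:
            maps[c] *= -1.0
            mixing[:, c] *= -1.0

    # deterministic component order: by descending variance contribution
    order = np.argsort(-np.linalg.norm(mixing, axis=0) * np.linalg.norm(maps, axis=1))
    maps = maps[order]
    mixing = mixing[:, order]

    # back-reconstruction through the stored operators
    subject_tcs: dict[str, np.ndarray] = {}
    subject_maps: dict[str, np.ndarray] = {}
    for i, sid in enumerate(subject_ids):
        red = reduced_subjects[sid]
        block = group_basis[i * d : (i + 1) * d, :]          # (d, C)
        m_i = block @ mixing                                  # (d, C)
        subject_tcs[sid] = red.basis @ m_i                    # (time, C)
        subject_maps[sid] = np.linalg.pinv(m_i) @ red.data    # (C, V)

    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return GroupDecomposition(
        n_components=n_components,
        group_maps=(maps - mu) / sd,
        group_maps_raw=maps,
        mixing=mixing,
        group_basis=group_basis,
        subject_ids=subject_ids,
        reductions=dict(reduced_subjects),
        subject_timecourses=subject_tcs,
        subject_maps=subject_maps,
        seed=seed,
        negentropy=score,
    )


def back_reconstruct(
    decomposition: GroupDecomposition, subject_id: str
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute one subject's (maps, time courses) from the stored operators.

    Returns the (component, voxel) subject map and (time, component) time
    course; deterministic given the decomposition.
    """
    if subject_id not in decomposition.reductions:
        raise ValueError(f"unknown subject {subject_id!r}")
    idx = decomposition.subject_ids.index(subject_id)
    red = decomposition.reductions[subject_id]
    d = red.target_dim
    block = decomposition.group_basis[idx * d : (idx + 1) * d, :]
    m_i = block @ decomposition.mixing
    tc = red.basis @ m_i
    maps = np.linalg.pinv(m_i) @ red.data
    return maps, tc
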