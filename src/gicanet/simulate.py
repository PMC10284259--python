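"""Synthetic multi-subject BOLD data with known planted networks.

Every downstream stage of the pipeline is testable without any download:
this module plants spatially smooth networks (Gaussian blobs, optionally
multi-cluster) on a common voxel grid, gives each network a time course that
mixes slow baseline fluctuations with HRF-convolved condition responses of
configurable sign and magnitude (so task-negative profiles are expressible),
and adds i.i.d. Gaussian voxel noise.  Each planted weight field comes with a
matching binary template (weight above half peak), mirroring the
template/component duality used for network identification.

All randomness flows through integer seeds; identical seeds and parameters
regenerate bit-identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .design import TaskDesign, build_design_matrix

__all__ = [
    "Grid",
    "GroundTruth",
    "BoldRun",
    "GeometryError",
    "make_templates",
    "simulate_dataset",
    "simulate_motion_trace",
]


class GeometryError(ValueError):
    """Requested network masks cannot be placed on the grid."""


@dataclass(frozen=True)
class Grid:
    """Voxel grid geometry: 3D shape plus a NIfTI affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(
        default_factory=lambda: np.eye(4), compare=False, repr=False
    )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def flatten(self, vol: np.ndarray) -> np.ndarray:
        return np.asarray(vol).reshape(self.n_voxels)

    def unflatten(self, flat: np.ndarray) -> np.ndarray:
        return np.asarray(flat).reshape(self.shape)


@dataclass
class BoldRun:
    """One subject/run of simulated (or loaded) BOLD data.

    ``data`` is (time, voxel) with voxels in C order of the grid shape.
    """

    data: np.ndarray
    tr: float
    grid: Grid
    subject_id: str
    run_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.grid.n_voxels:
            raise ValueError("data must be (time, n_voxels) matching the grid")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


@dataclass
class GroundTruth:
    """Planted networks and their condition responses.

    Attributes
    ----------
    planted_maps:
        One spatial weight field per network, flattened to (n_voxels,),
        nonnegative and peak-normalised to 1.
    template_masks:
        Matching binary masks (weight above half peak), same shapes.
    condition_weights:
        (n_networks, n_conditions) signed response amplitudes; columns follow
        ``condition_labels``.
    condition_labels:
        Condition labels matching the task design.
    noise_sd:
        Standard deviation of additive i.i.d. Gaussian voxel noise.
    seed:
        Master seed for dataset generation.
    baseline_timecourses:
        Filled by :func:`simulate_dataset`: subject_id -> (time, n_networks)
        baseline fluctuation series (before adding condition responses).
    """

    planted_maps: list[np.ndarray]
    template_masks: list[np.ndarray]
    condition_weights: np.ndarray
    condition_labels: list[str]
    noise_sd: float
    seed: int
    baseline_timecourses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition_weights = np.atleast_2d(
            np.asarray(self.condition_weights, dtype=float)
        )
        if len(self.planted_maps) != self.condition_weights.shape[0]:
            raise ValueError("one row of condition_weights per planted map required")
        if self.condition_weights.shape[1] != len(self.condition_labels):
            raise ValueError("one column of condition_weights per condition required")
        for m in self.planted_maps:
            if not (np.asarray(m) != 0).any():
                raise ValueError("every planted map needs at least one nonzero voxel")

    @property
    def n_networks(self) -> int:
        return len(self.planted_maps)


def _gaussian_field(
    shape: tuple[int, int, int], centers: np.ndarray, sigma: float
) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).astype(float)
    f = np.zeros(shape)
    for c in centers:
        d2 = ((coords - c) ** 2).sum(axis=-1)
        f += np.exp(-d2 / (2.0 * sigma**2))
    return f / f.max()


def make_templates(
    grid: Grid,
    n_networks: int,
    clusters_per_network: int = 1,
    smoothness: float = 2.0,
    seed: int = 0,
    max_overlap: float = 0.10,
    mask_level: float = 0.5,
    max_attempts: int = 500,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Place smooth network weight fields and matching binary templates.

    Each network is a sum of ``clusters_per_network`` Gaussian bumps of width
    ``smoothness`` voxels, peak-normalised to 1; its binary template is the
    set of voxels above ``mask_level`` of the peak.  Placement is rejected and
    resampled until the pairwise voxel overlap between any two networks is at
    most ``max_overlap`` of the smaller mask.

    Returns
    -------
    (masks, fields):
        Lists of flattened boolean masks and float weight fields.

    Raises
    ------
    GeometryError
        If the requested masks cannot be placed within ``max_attempts``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    margin = max(1.5 * smoothness, 1.0)
    lo = np.full(3, margin)
    hi = np.asarray(grid.shape, dtype=float) - 1.0 - margin
    if np.any(hi <= lo):
        raise GeometryError(
            f"grid {grid.shape} too small for blobs of smoothness {smoothness}"
        )

    masks: list[np.ndarray] = []
    fields: list[np.ndarray] = []
    for _ in range(n_networks):
        placed = False
        for _attempt in range(max_attempts):
            centers = rng.uniform(lo, hi, size=(clusters_per_network, 3))
            fld = _gaussian_field(grid.shape, centers, smoothness)
            msk = fld > mask_level
            if not msk.any():
                continue
            ok = True
            for prev in masks:
                inter = np.logical_and(prev, msk.ravel()).sum()
                if inter > max_overlap * min(prev.sum(), msk.sum()):
                    ok = False
                    break
            if ok:
                masks.append(msk.ravel())
                fields.append(fld.ravel())
                placed = True
                break
        if not placed:
            raise GeometryError(
                f"could not place {n_networks} networks with overlap <= "
                f"{max_overlap:.0%} on grid {grid.shape} after {max_attempts} attempts"
            )
    return masks, fields


def _lowpass_baseline(
    rng: np.random.Generator, n_volumes: int, tr: float, cutoff_hz: float, sd: float
) -> np.ndarray:
    """Low-pass-filtered Gaussian series, standardised to the requested SD."""
    x = rng.standard_normal(n_volumes)
    nyquist = 0.5 / tr
    if 0 < cutoff_hz < nyquist and n_volumes > 18:
        b, a = butter(4, cutoff_hz / nyquist, btype="low")
        x = filtfilt(b, a, x)
    s = x.std()
    if s > 0:
        x = x / s
    return sd * x


def simulate_dataset(
    ground_truth: GroundTruth,
    task_design: TaskDesign,
    n_subjects: int,
    n_runs: int,
    n_volumes: int,
    tr: float,
    baseline_sd: float = 1.0,
    baseline_cutoff_hz: float = 0.1,
    weight_jitter_sd: float = 0.0,
    grid: Grid | None = None,
) -> tuple[list[BoldRun], dict[str, np.ndarray]]:
    """Simulate a multi-subject, multi-run BOLD dataset from planted networks.

    Each network's time course is ``baseline fluctuation + sum over
    conditions of weight x HRF-convolved condition regressor`` (regressors
    from :mod:`gicanet.design`, shared across subjects).  The voxel signal is
    the outer-product sum of planted maps and network time courses plus
    Gaussian noise of SD ``ground_truth.noise_sd``.

    ``weight_jitter_sd`` adds independent Gaussian variation to every
    (network, condition) response amplitude per subject, emulating
    between-subject variability in response magnitude.  The default 0 keeps
    the condition weights exact (closed-form regression oracles hold to
    numerical precision); group-level fixtures set it positive so that
    between-subject variance is realistic rather than degenerate.

    Returns
    -------
    (runs, true_timecourses):
        ``runs`` holds one :class:`BoldRun` per subject x run;
        ``true_timecourses`` maps subject_id to the (total time, n_networks)
        ground-truth network time courses over concatenated runs.
    """
    if grid is None:
        side = round(len(ground_truth.planted_maps[0]) ** (1 / 3))
        grid = Grid((side, side, side))
    if list(task_design.condition_set) != list(ground_truth.condition_labels):
        raise ValueError(
            "condition labels of ground truth and task design do not match"
        )
    if len(task_design.run_lengths) != n_runs or any(
        v != n_volumes for v in task_design.run_lengths.values()
    ):
        raise ValueError(
            f"task design runs {task_design.run_lengths} inconsistent with "
            f"n_runs={n_runs}, n_volumes={n_volumes}"
        )

    dm = build_design_matrix(task_design, tr)
    regressors = dm.conditions()  # (total time, n_conditions)
    maps = np.stack([np.asarray(m, dtype=float) for m in ground_truth.planted_maps])

    ss = np.random.SeedSequence(ground_truth.seed)
    children = ss.spawn(n_subjects)
    runs: list[BoldRun] = []
    true_tcs: dict[str, np.ndarray] = {}
    run_ids = task_design.run_ids
    for si in range(n_subjects):
        subject_id = f"sub-{si + 1:02d}"
        rng = np.random.default_rng(children[si])
        weights = ground_truth.condition_weights
        if weight_jitter_sd > 0:
            weights = weights + rng.normal(0.0, weight_jitter_sd, size=weights.shape)
        task_part = regressors @ weights.T  # (time, n_networks)
        baseline = np.column_stack(
            [
                np.concatenate(
                    [
                        _lowpass_baseline(rng, n_volumes, tr, baseline_cutoff_hz, baseline_sd)
                        for _ in run_ids
                    ]
                )
                for _n in range(ground_truth.n_networks)
            ]
        )
        tc = baseline + task_part
        ground_truth.baseline_timecourses[subject_id] = baseline
        true_tcs[subject_id] = tc
        signal = tc @ maps  # (time, voxels)
        for ri, run_id in enumerate(run_ids):
            sl = dm.run_slices[run_id]
            data = signal[sl]
            if ground_truth.noise_sd > 0:
                data = data + rng.normal(
                    0.0, ground_truth.noise_sd, size=data.shape
                )
            else:
                data = data.copy()
            runs.append(
                BoldRun(
                    data=data, tr=tr, grid=grid, subject_id=subject_id, run_id=run_id
                )
            )
    return runs, true_tcs


def simulate_motion_trace(
    n_volumes: int,
    spike_positions: set[int] | list[int] = (),
    spike_magnitude: float = 2.0,
    seed: int = 0,
    baseline_max_mm: float = 0.3,
    intensity_spikes: dict[int, float] | None = None,
) -> "MotionTrace":
    """Per-volume relative-movement and mean-intensity traces with injected spikes.

    The baseline relative movement is uniform on (0, ``baseline_max_mm``) so
    that without spikes no volume approaches the 1 mm flagging threshold; at
    each spike position the movement is set to 1.25 x ``spike_magnitude`` so
    exactly those indices exceed the magnitude.  ``intensity_spikes`` maps
    volume index -> offset in baseline-SD units added to the intensity series.
    """
    from .motion import MotionTrace  # local import to avoid a cycle

    spike_positions = set(int(p) for p in spike_positions)
    if any(p < 0 or p >= n_volumes for p in spike_positions):
        raise ValueError("spike positions must lie in [0, n_volumes)")
    rng = np.random.default_rng(seed)
    movement = rng.uniform(0.02, baseline_max_mm, size=n_volumes)
    for p in spike_positions:
        movement[p] = 1.25 * spike_magnitude
    intensity = 1000.0 + rng.normal(0.0, 5.0, size=n_volumes)
    if intensity_spikes:
        base_sd = 5.0
        for p, z in intensity_spikes.items():
            if p < 0 or p >= n_volumes:
                raise ValueError("intensity spike positions must lie in [0, n_volumes)")
            intensity[p] = 1000.0 + z * base_sd
    return MotionTrace(relative_movement=movement, intensity=intensity)
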