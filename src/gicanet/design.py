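"""Task design matrices: canonical HRF and condition-regressor construction.

A task is specified as a table of events (run, condition, onset, duration).
Each condition becomes one regressor per analysis: a boxcar on an oversampled
time grid convolved with the canonical double-gamma hemodynamic response
function, then downsampled to volume acquisition times.  Rest is never
modelled as a column — it is the implicit baseline of the regression.  Runs
are concatenated with run-wise intercepts and no drift terms (the pipeline
assumes unfiltered data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "Event",
    "TaskDesign",
    "DesignMatrix",
    "canonical_hrf",
    "build_design_matrix",
    "read_events",
    "write_events",
]

#: double-gamma shape parameters: response peaks at 6 s, undershoot at 16 s,
#: undershoot amplitude 1/6 of the peak lobe (both scale parameters are 1 s).
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class Event:
    """One task event: a condition occupying [onset, onset + duration) in a run."""

    run_id: str
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class TaskDesign:
    """Event table plus run geometry for one task.

    Parameters
    ----------
    events:
        All events of all runs.  Rest is whatever time no event covers.
    run_lengths:
        Mapping run_id -> number of volumes; insertion order is the
        concatenation order of the runs.
    condition_set:
        Ordered unique condition labels.  Every event's condition must be a
        member; a member with no events yields an all-zero regressor.
    """

    events: list[Event]
    run_lengths: dict[str, int]
    condition_set: list[str]

    def __post_init__(self) -> None:
        if len(set(self.condition_set)) != len(self.condition_set):
            raise ValueError("condition_set contains duplicate labels")
        for ev in self.events:
            if ev.condition not in self.condition_set:
                raise ValueError(
                    f"event condition {ev.condition!r} not in condition_set"
                )
            if ev.run_id not in self.run_lengths:
                raise ValueError(f"event run {ev.run_id!r} not in run_lengths")
            if ev.onset_s < 0 or ev.duration_s < 0:
                raise ValueError("event onsets and durations must be >= 0")

    @property
    def run_ids(self) -> list[str]:
        return list(self.run_lengths)

    @property
    def n_volumes_total(self) -> int:
        return int(sum(self.run_lengths.values()))

    def validate_against_tr(self, tr: float) -> None:
        """Check every event fits inside its run at repetition time ``tr``."""
        for ev in self.events:
            limit = self.run_lengths[ev.run_id] * tr
            if ev.onset_s + ev.duration_s > limit + 1e-9:
                raise ValueError(
                    f"event ({ev.run_id}, {ev.condition}, onset={ev.onset_s}, "
                    f"duration={ev.duration_s}) exceeds run length {limit} s"
                )

    def events_of(self, run_id: str) -> list[Event]:
        return [ev for ev in self.events if ev.run_id == run_id]

    def shifted(self, shift_s: float) -> "TaskDesign":
        """Return a copy with every onset shifted by ``shift_s`` seconds."""
        evs = [
            Event(e.run_id, e.condition, e.onset_s + shift_s, e.duration_s)
            for e in self.events
        ]
        return TaskDesign(evs, dict(self.run_lengths), list(self.condition_set))


@dataclass
class DesignMatrix:
    """Volume-sampled design: condition regressors plus run-wise intercepts."""

    values: np.ndarray  # (total volumes, n_regressors)
    columns: list[str]
    tr: float
    run_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def condition_columns(self) -> list[str]:
        return [c for c in self.columns if not c.startswith("intercept:")]

    def conditions(self) -> np.ndarray:
        """The condition regressors only, as a (time, n_conditions) array."""
        idx = [self.columns.index(c) for c in self.condition_columns]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def canonical_hrf(tr: float, kernel_length_s: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    The kernel is the difference of two gamma densities — a positive response
    lobe peaking at 6 s and an undershoot peaking at 16 s with amplitude
    ratio 1/6 — sampled at t = 0, tr, 2*tr, ... <= kernel_length_s and scaled
    to unit peak.

    Parameters
    ----------
    tr:
        Sampling interval in seconds (> 0).
    kernel_length_s:
        Window length in seconds (>= 16, so the undershoot is represented).

    Returns
    -------
    ndarray of shape (floor(kernel_length_s / tr) + 1,)
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if kernel_length_s < 16:
        raise ValueError("kernel_length_s must be >= 16 s")
    n = int(math.floor(kernel_length_s / tr)) + 1
    t = np.arange(n) * tr
    # gamma densities with scale 1: mode at shape-1, so shape = delay + 1
    h = _gamma_dist.pdf(t, HRF_PEAK_DELAY_S) - HRF_UNDERSHOOT_RATIO * _gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY_S
    )
    return h / h.max()


def _run_condition_columns(
    events: list[Event],
    n_volumes: int,
    tr: float,
    condition_set: list[str],
    oversampling: int,
    kernel_length_s: float,
) -> np.ndarray:
    """Condition regressors for one run, sampled at volume times i*tr."""
    dt = tr / oversampling
    n_os = n_volumes * oversampling
    hrf = canonical_hrf(dt, kernel_length_s)
    cols = np.zeros((n_volumes, len(condition_set)))
    for j, cond in enumerate(condition_set):
        box = np.zeros(n_os)
        for ev in events:
            if ev.condition != cond:
                continue
            i0 = int(round(ev.onset_s / dt))
            if ev.duration_s == 0:
                # zero-duration event = unit impulse
                if i0 < n_os:
                    box[i0] += 1.0
            else:
                i1 = int(round((ev.onset_s + ev.duration_s) / dt))
                box[i0 : max(i1, i0 + 1)] += 1.0
        conv = np.convolve(box, hrf)[:n_os]
        cols[:, j] = conv[::oversampling]
    return cols


def build_design_matrix(
    task_design: TaskDesign,
    tr: float,
    oversampling: int = 16,
    kernel_length_s: float = 32.0,
) -> DesignMatrix:
    """Build the concatenated-run design matrix for a task.

    Each condition column is the boxcar of its events convolved with the
    canonical HRF on a grid oversampled by ``oversampling`` (to place
    off-grid onsets such as jittered rests accurately), then downsampled to
    volume times.  Runs are concatenated in ``run_lengths`` order with one
    intercept column per run; rest contributes no column.
    """
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    task_design.validate_against_tr(tr)

    active = {ev.condition for ev in task_design.events}
    for cond in task_design.condition_set:
        if cond not in active:
            warnings.warn(
                f"condition {cond!r} has no events; its regressor is all zero",
                stacklevel=2,
            )

    blocks = []
    run_slices: dict[str, slice] = {}
    start = 0
    for run_id, n_vol in task_design.run_lengths.items():
        blocks.append(
            _run_condition_columns(
                task_design.events_of(run_id),
                n_vol,
                tr,
                task_design.condition_set,
                oversampling,
                kernel_length_s,
            )
        )
        run_slices[run_id] = slice(start, start + n_vol)
        start += n_vol

    n_total = start
    n_cond = len(task_design.condition_set)
    run_ids = task_design.run_ids
    values = np.zeros((n_total, n_cond + len(run_ids)))
    values[:, :n_cond] = np.vstack(blocks)
    for k, run_id in enumerate(run_ids):
        values[run_slices[run_id], n_cond + k] = 1.0
    columns = list(task_design.condition_set) + [f"intercept:{r}" for r in run_ids]
    return DesignMatrix(values=values, columns=columns, tr=tr, run_slices=run_slices)


_EVENT_COLUMNS = ["run", "condition", "onset_s", "duration_s"]


def write_events(task_design: TaskDesign, path) -> None:
    """Write the event table as CSV with columns run, condition, onset_s, duration_s."""
    df = pd.DataFrame(
        [(e.run_id, e.condition, e.onset_s, e.duration_s) for e in task_design.events],
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_events(
    path, run_lengths: dict[str, int], condition_set: list[str] | None = None
) -> TaskDesign:
    """Read an event table written by :func:`write_events`.

    ``run_lengths`` must be supplied (volumes per run are not stored in the
    event table).  If ``condition_set`` is omitted it is taken as the sorted
    unique conditions of the table.
    """
    df = pd.read_csv(path)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    events = [
        Event(str(r.run), str(r.condition), float(r.onset_s), float(r.duration_s))
        for r in df.itertuples()
    ]
    if condition_set is None:
        condition_set = sorted({e.condition for e in events})
    return TaskDesign(events, dict(run_lengths), list(condition_set))
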