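"""Motion quality control: high-motion volume flagging and participant exclusion.

A volume is flagged when its relative movement exceeds 1 mm or its global
mean intensity deviates from the trace mean by more than 2.5 SD; a
participant is excluded when more than a quarter of their volumes are
flagged (strictly more — exactly one quarter keeps the participant).
Flagged volumes are dropped from both the BOLD data and the design-matrix
rows before decomposition, keeping time alignment exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "flag_high_motion",
    "exclude_participant",
    "drop_flagged_rows",
    "read_motion_trace",
    "write_motion_trace",
    "qc_report",
]


@dataclass
class MotionTrace:
    """Per-volume relative movement (mm) and global mean intensity."""

    relative_movement: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.relative_movement = np.asarray(self.relative_movement, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.relative_movement.shape != self.intensity.shape:
            raise ValueError("movement and intensity series must have equal length")
        if (self.relative_movement < 0).any():
            raise ValueError("relative movement must be >= 0")

    @property
    def n_volumes(self) -> int:
        return self.relative_movement.size


def flag_high_motion(
    trace: MotionTrace, movement_mm: float = 1.0, intensity_z: float = 2.5
) -> set[int]:
    """Indices of high-motion volumes.

    A volume is flagged iff its relative movement exceeds ``movement_mm`` or
    the absolute z-score of its intensity (mean/SD of the trace itself)
    exceeds ``intensity_z``.  A constant intensity series yields z-scores of
    0 everywhere (no intensity flags) with a warning.
    """
    mv = trace.relative_movement
    inten = trace.intensity
    sd = inten.std()
    if sd == 0:
        warnings.warn(
            "intensity series is constant; no intensity-based flags", stacklevel=2
        )
        z = np.zeros_like(inten)
    else:
        z = (inten - inten.mean()) / sd
    flagged = (mv > movement_mm) | (np.abs(z) > intensity_z)
    return set(np.flatnonzero(flagged).tolist())


def exclude_participant(
    flags: set[int], n_volumes: int, fraction: float = 0.25
) -> bool:
    """True iff strictly more than ``fraction`` of the volumes are flagged."""
    if any(f < 0 or f >= n_volumes for f in flags):
        raise ValueError("flags must lie in [0, n_volumes)")
    return len(flags) / n_volumes > fraction


def drop_flagged_rows(array: np.ndarray, flags: set[int]) -> np.ndarray:
    """Remove flagged time points (rows) from a (time, ...) array."""
    keep = np.setdiff1d(np.arange(array.shape[0]), np.fromiter(flags, dtype=int))
    return array[keep]


def write_motion_trace(trace: MotionTrace, path) -> None:
    pd.DataFrame(
        {
            "volume": np.arange(trace.n_volumes),
            "relative_movement_mm": trace.relative_movement,
            "intensity": trace.intensity,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_motion_trace(path) -> MotionTrace:
    df = pd.read_csv(path)
    return MotionTrace(
        relative_movement=df["relative_movement_mm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
    )


def qc_report(
    traces: dict[str, MotionTrace],
    movement_mm: float = 1.0,
    intensity_z: float = 2.5,
    fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-subject QC table: flag count, flagged fraction, exclusion decision."""
    rows = []
    for subject_id, trace in traces.items():
        flags = flag_high_motion(trace, movement_mm, intensity_z)
        rows.append(
            {
                "subject": subject_id,
                "n_volumes": trace.n_volumes,
                "n_flagged": len(flags),
                "flagged_fraction": len(flags) / trace.n_volumes,
                "excluded": exclude_participant(flags, trace.n_volumes, fraction),
                "flagged_volumes": ";".join(str(i) for i in sorted(flags)),
            }
        )
    return pd.DataFrame(rows)
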