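"""Functional profiling of a component: condition betas, ANOVA and contrasts.

A component's relation to the task model is tested in three steps.  Each
subject's component time course is regressed on the HRF-convolved design
matrix (rest is the implicit baseline), yielding one beta per condition per
subject.  A one-way ANOVA with condition as the factor — treating each
subject x condition cell as an observation, so df = (k - 1, N*k - k) —
gates interpretation.  Planned contrasts are paired t-tests on beta
differences between two conditions (or one-sample t-tests against zero for
condition-vs-rest), Bonferroni-adjusted over the declared family; they are
computed even when the ANOVA gate fails, and flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "ConditionBetas",
    "ContrastResult",
    "extract_condition_betas",
    "betas_table",
    "condition_anova",
    "planned_contrasts",
]

REST = None  # sentinel: contrast against the implicit rest baseline


@dataclass
class ConditionBetas:
    """Subject x condition beta table for one component."""

    component_id: int
    table: pd.DataFrame  # index: subject ids; columns: condition labels

    def __post_init__(self) -> None:
        if not np.isfinite(self.table.to_numpy()).all():
            raise ValueError("betas must be finite")

    @property
    def conditions(self) -> list[str]:
        return list(self.table.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.table)


@dataclass
class ContrastResult:
    """Omnibus ANOVA plus Bonferroni-adjusted planned contrasts."""

    anova_f: float
    anova_df1: int
    anova_df2: int
    anova_p: float
    contrasts: list[dict] = field(default_factory=list)
    m: int = 0
    gate_passed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contrasts)


def extract_condition_betas(
    subject_timecourse: np.ndarray, design_matrix: DesignMatrix
) -> dict[str, float]:
    """OLS fit of one component time course on the design matrix.

    Returns the condition-regressor coefficients (run intercepts are fitted
    but not returned); rest is the implicit baseline.  A rank-deficient
    design fails with the collinear columns named.
    """
    y = np.asarray(subject_timecourse, dtype=float).ravel()
    x = design_matrix.values
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"time course has {y.shape[0]} rows but design has {x.shape[0]}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns with (near-)zero pivots in the QR factorisation
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [
            design_matrix.columns[i]
            for i in np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return {
        c: float(beta[design_matrix.columns.index(c)])
        for c in design_matrix.condition_columns
    }


def betas_table(
    timecourses: dict[str, np.ndarray],
    design_matrix: DesignMatrix,
    component_id: int = 0,
) -> ConditionBetas:
    """Fit every subject's time course and assemble the subject x condition table."""
    rows = {
        sid: extract_condition_betas(tc, design_matrix)
        for sid, tc in timecourses.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[design_matrix.condition_columns]
    return ConditionBetas(component_id=component_id, table=table)


def condition_anova(betas: ConditionBetas) -> tuple[float, int, int, float]:
    """One-way ANOVA with condition as the factor over subject x condition cells.

    Each beta is one observation, so with k conditions and N subjects
    df1 = k - 1 and df2 = N*k - k.

    Returns (F, df1, df2, p).
    """
    k = len(betas.conditions)
    n = betas.n_subjects
    if k < 2:
        raise ValueError("ANOVA needs >= 2 conditions")
    if n < 2:
        raise ValueError("ANOVA needs >= 2 subjects")
    groups = [betas.table[c].to_numpy() for c in betas.conditions]
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within_ss == 0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    grand = np.concatenate(groups).mean()
    between_ss = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df1 = k - 1
    df2 = n * k - k
    f = (between_ss / df1) / (within_ss / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def planned_contrasts(
    betas: ConditionBetas,
    contrast_pairs: list[tuple[str, str, str | None]],
    m: int | None = None,
    alpha: float = 0.05,
    anova: tuple[float, int, int, float] | None = None,
) -> ContrastResult:
    """Bonferroni-adjusted planned contrasts on condition betas.

    Parameters
    ----------
    contrast_pairs:
        Triples ``(label, condition_a, condition_b)``; ``condition_b=None``
        tests ``condition_a`` against the implicit rest baseline (betas
        against zero).  Each contrast is a paired (or one-sample) t-test
        across subjects with df = n - 1.
    m:
        Bonferroni family size; default the number of contrasts.
        ``adjusted_p = min(1, raw_p * m)``.
    anova:
        Optional precomputed (F, df1, df2, p); computed here if omitted.
        The gate (ANOVA p < ``alpha``) is recorded but contrasts are always
        computed and reported.
    """
    if anova is None:
        anova = condition_anova(betas)
    f, df1, df2, p_anova = anova
    if m is None:
        m = len(contrast_pairs)
    n = betas.n_subjects
    results = []
    for label, cond_a, cond_b in contrast_pairs:
        if cond_a not in betas.conditions:
            raise ValueError(f"contrast {label!r}: unknown condition {cond_a!r}")
        a = betas.table[cond_a].to_numpy()
        if cond_b is None:
            diff = a
        else:
            if cond_b not in betas.conditions:
                raise ValueError(f"contrast {label!r}: unknown condition {cond_b!r}")
            diff = a - betas.table[cond_b].to_numpy()
        sd = diff.std(ddof=1)
        if sd == 0:
            t = 0.0
            raw_p = 1.0
        else:
            t = float(diff.mean() / (sd / np.sqrt(n)))
            raw_p = float(2.0 * stats.t.sf(abs(t), n - 1))
        results.append(
            {
                "label": label,
                "condition_a": cond_a,
                "condition_b": "rest" if cond_b is None else cond_b,
                "t": t,
                "df": n - 1,
                "raw_p": raw_p,
                "adjusted_p": min(1.0, raw_p * m),
            }
        )
    return ContrastResult(
        anova_f=f,
        anova_df1=df1,
        anova_df2=df2,
        anova_p=p_anova,
        contrasts=results,
        m=m,
        gate_passed=p_anova < alpha,
    )


def condition_profile_figure(betas: ConditionBetas, result: ContrastResult, path) -> None:
    """Bar chart of mean beta per condition vs rest with significance markers.

    Writes a PNG; requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = betas.table.mean(axis=0)
    sems = betas.table.sem(axis=0)
    sig = {
        c["condition_a"]: c["adjusted_p"] < 0.05
        for c in result.contrasts
        if c["condition_b"] == "rest"
    }
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(means.index, means.to_numpy(), yerr=sems.to_numpy(), color="#888")
    for i, c in enumerate(means.index):
        if sig.get(c):
            y = means[c] + np.sign(means[c]) * (sems[c] + 0.05 * abs(means).max())
            ax.text(i, y, "*", ha="center", fontsize=14)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("beta vs rest (a.u.)")
    ax.set_title(f"component {betas.component_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
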