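"""Network-of-interest identification by Jaccard template matching.

Each component's binarised group map is compared with an a priori binary
network template using the Jaccard coefficient J = |A n B| / |A u B| on
active voxels.  Identification is two-step: (1) every component with J at or
above a threshold (default .15) becomes a candidate; (2) if several
candidates exist, a greedy forward search over unions of candidate masks
keeps adding the candidate that most increases J with the template and stops
when no addition strictly improves the fit — so a split network is captured
by multiple components while a merely overlapping distinct network is
rejected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MatchReport", "jaccard", "identify_network", "compare_templates"]

_TIE_TOL = 1e-12


@dataclass
class MatchReport:
    """Outcome of matching one template against a set of component masks."""

    template_id: str
    per_component_j: dict[int, float]
    candidate_threshold: float
    candidates: list[int]
    selected: list[int]
    selected_j: float
    best_single: tuple[int, float]
    search_log: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(self.per_component_j),
                "jaccard": [self.per_component_j[c] for c in self.per_component_j],
                "candidate": [
                    c in self.candidates for c in self.per_component_j
                ],
                "selected": [c in self.selected for c in self.per_component_j],
            }
        )


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard similarity |A n B| / |A u B| of two binary masks.

    Ranges from 0 (no overlap of active voxels) to 1 (identical active
    sets).  Both masks empty is defined as 0 with a warning.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks are empty; Jaccard defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _union_j(
    masks: dict[int, np.ndarray], members: tuple[int, ...], template: np.ndarray
) -> float:
    u = np.zeros(template.shape, dtype=bool)
    for m in members:
        u |= masks[m].astype(bool)
    union = np.logical_or(u, template).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(u, template).sum() / union)


def identify_network(
    component_masks: dict[int, np.ndarray] | list[np.ndarray],
    template: np.ndarray,
    threshold: float = 0.15,
    template_id: str = "template",
    strict: bool = True,
) -> MatchReport:
    """Two-step identification of the component(s) matching a template.

    Step 1 computes J for every component; components with J >= ``threshold``
    are candidates.  Step 2, with two or more candidates, runs a greedy
    forward search seeded at the best single candidate, at each step adding
    the candidate whose mask union most increases J and stopping when no
    addition strictly increases it.  With exactly one candidate that
    component is selected; with none, the selection is empty (``strict``,
    default) or the single best component (``strict=False``), and the best
    single J is always reported.

    Ties in J within 1e-12 are broken toward the lower component index.
    """
    if isinstance(component_masks, list):
        component_masks = {i: m for i, m in enumerate(component_masks)}
    if not component_masks:
        raise ValueError("empty component list")
    template = np.asarray(template).astype(bool)
    for cid, m in component_masks.items():
        if np.asarray(m).shape != template.shape:
            raise ValueError(f"component {cid}: grid mismatch with template")

    per_j = {cid: jaccard(m, template) for cid, m in component_masks.items()}
    order = sorted(per_j, key=lambda c: (-per_j[c], c))
    best_single = (order[0], per_j[order[0]])
    candidates = [c for c in order if per_j[c] >= threshold - _TIE_TOL]

    log: list[tuple[tuple[int, ...], float]] = [
        ((c,), per_j[c]) for c in order
    ]

    if not candidates:
        selected = [] if strict else [best_single[0]]
        selected_j = 0.0 if strict else best_single[1]
        return MatchReport(
            template_id=template_id,
            per_component_j=per_j,
            candidate_threshold=threshold,
            candidates=candidates,
            selected=selected,
            selected_j=selected_j,
            best_single=best_single,
            search_log=log,
        )

    current = [candidates[0]]
    current_j = per_j[candidates[0]]
    remaining = [c for c in candidates[1:]]
    while remaining:
        trial_j = []
        for c in remaining:
            members = tuple(sorted(current + [c]))
            jv = _union_j(component_masks, members, template)
            log.append((members, jv))
            trial_j.append((jv, c))
        # best addition; ties toward lower component index
        trial_j.sort(key=lambda t: (-t[0], t[1]))
        best_j, best_c = trial_j[0]
        if best_j > current_j + _TIE_TOL:
            current.append(best_c)
            current_j = best_j
            remaining.remove(best_c)
        else:
            break

    return MatchReport(
        template_id=template_id,
        per_component_j=per_j,
        candidate_threshold=threshold,
        candidates=candidates,
        selected=sorted(current),
        selected_j=current_j,
        best_single=best_single,
        search_log=log,
    )


def exhaustive_best_subset(
    component_masks: dict[int, np.ndarray],
    template: np.ndarray,
    candidates: list[int],
) -> tuple[tuple[int, ...], float]:
    """Best nonempty candidate subset by union Jaccard (test oracle for the greedy search)."""
    template = np.asarray(template).astype(bool)
    best: tuple[tuple[int, ...], float] | None = None
    for r in range(1, len(candidates) + 1):
        for combo in itertools.combinations(sorted(candidates), r):
            jv = _union_j(component_masks, combo, template)
            if best is None or jv > best[1] + _TIE_TOL:
                best = (combo, jv)
    if best is None:
        raise ValueError("no candidates supplied")
    return best


def compare_templates(
    component_masks: dict[int, np.ndarray],
    templates: dict[str, np.ndarray],
    threshold: float = 0.15,
    strict: bool = True,
) -> tuple[dict[str, MatchReport], bool]:
    """Identify the network with each template and flag selection disagreement.

    Mirrors the cross-check of two independent a priori templates: reports
    are produced per template and ``agree`` is False when their selected
    component sets differ (the disagreement is flagged, not resolved).
    """
    reports = {
        tid: identify_network(
            component_masks, tpl, threshold=threshold, template_id=tid, strict=strict
        )
        for tid, tpl in templates.items()
    }
    selections = {tuple(r.selected) for r in reports.values()}
    agree = len(selections) <= 1
    if not agree:
        warnings.warn(
            "templates disagree on the selected component set: "
            + "; ".join(f"{tid}: {r.selected}" for tid, r in reports.items()),
            stacklevel=2,
        )
    return reports, agree
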