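"""Jaccard coefficient and two-step network identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gicanet.match import (
    compare_templates,
    exhaustive_best_subset,
    identify_network,
    jaccard,
)


def _mask(shape, true_idx):
    m = np.zeros(shape, dtype=bool)
    m.ravel()[list(true_idx)] = True
    return m


class TestJaccard:
    def test_identical_nonempty_masks_give_one(self):
        m = _mask((4, 4, 4), range(10))
        assert jaccard(m, m.copy()) == 1.0

    def test_disjoint_nonempty_masks_give_zero(self):
        a = _mask((4, 4, 4), range(5))
        b = _mask((4, 4, 4), range(5, 12))
        assert jaccard(a, b) == 0.0

    def test_explicit_set_enumeration_example(self):
        # |A|=3, |B|=4, |A n B|=2 -> 2/5
        a = _mask((3, 3, 3), {0, 1, 2})
        b = _mask((3, 3, 3), {1, 2, 5, 7})
        assert jaccard(a, b) == pytest.approx(0.4)

    def test_both_empty_defined_as_zero_with_warning(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard(e, e.copy()) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            jaccard(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 63), max_size=40),
        b=st.sets(st.integers(0, 63), min_size=1, max_size=40),
    )
    def test_symmetry_and_bounds(self, a, b):
        ma, mb = _mask((4, 4, 4), a), _mask((4, 4, 4), b)
        j = jaccard(ma, mb)
        assert j == jaccard(mb, ma)
        assert 0.0 <= j <= 1.0
        # set-enumeration oracle
        assert j == pytest.approx(len(a & b) / len(a | b))


def _split_network_case(rng, shape=(10, 10, 10)):
    """Template randomly split across 2-3 components plus a distractor."""
    n_vox = int(np.prod(shape))

    def mk(idx):
        m = np.zeros(n_vox, dtype=bool)
        m[np.asarray(list(idx), dtype=int)] = True
        return m.reshape(shape)

    template_idx = rng.choice(n_vox, 120, replace=False)
    outside_pool = np.setdiff1d(np.arange(n_vox), template_idx)
    k = int(rng.integers(2, 4))
    parts = np.array_split(rng.permutation(template_idx), k)
    comps = {}
    for i, part in enumerate(parts):
        keep = part[rng.random(part.size) >= 0.15]
        extra = rng.choice(outside_pool, int(rng.integers(5, 30)), replace=False)
        comps[i] = mk(np.concatenate([keep, extra]))
    overlap = rng.choice(template_idx, 25, replace=False)
    outside = rng.choice(outside_pool, 150, replace=False)
    comps[k] = mk(np.concatenate([overlap, outside]))
    return mk(template_idx), comps


def _split_template_case():
    """Template split across two components plus a distractor."""
    shape = (8, 8, 8)
    template = _mask(shape, range(0, 64))
    left = _mask(shape, range(0, 32))
    right = _mask(shape, range(32, 64))
    distractor = _mask(shape, range(300, 340))
    return shape, template, {0: left, 1: right, 2: distractor}


class TestIdentifyNetwork:
    def test_single_candidate_selected(self):
        shape = (6, 6, 6)
        template = _mask(shape, range(30))
        comps = {
            0: _mask(shape, range(25)),          # J = 25/35
            1: _mask(shape, range(100, 110)),    # J = 0
        }
        rep = identify_network(comps, template)
        assert rep.candidates == [0]
        assert rep.selected == [0]
        assert rep.selected_j == pytest.approx(25 / 30)

    def test_split_template_selects_both_halves(self):
        _, template, comps = _split_template_case()
        rep = identify_network(comps, template)
        assert rep.selected == [0, 1]
        assert rep.selected_j > rep.per_component_j[0]
        assert rep.selected_j > rep.per_component_j[1]
        assert rep.selected_j == pytest.approx(1.0)

    def test_spurious_candidate_lowering_j_rejected(self):
        # a second candidate overlaps the template but lies mostly outside
        # it, so adding it reduces the union fit and only the best single
        # component is kept
        shape = (8, 8, 8)
        template = _mask(shape, range(0, 60))
        best = _mask(shape, range(0, 55))
        spurious = _mask(shape, list(range(35, 60)) + list(range(200, 280)))
        rep = identify_network({0: best, 1: spurious}, template)
        assert rep.candidates == [0, 1]
        assert rep.selected == [0]
        assert rep.selected_j == rep.per_component_j[0]

    def test_no_candidate_strict_gives_empty_selection(self):
        shape = (6, 6, 6)
        template = _mask(shape, range(40))
        comps = {0: _mask(shape, range(38, 60))}  # small J
        rep = identify_network(comps, template, threshold=0.5)
        assert rep.candidates == []
        assert rep.selected == []
        assert rep.best_single == (0, rep.per_component_j[0])

    def test_no_candidate_non_strict_selects_best_single(self):
        shape = (6, 6, 6)
        template = _mask(shape, range(40))
        comps = {
            0: _mask(shape, range(38, 60)),
            1: _mask(shape, range(100, 120)),
        }
        rep = identify_network(comps, template, threshold=0.5, strict=False)
        assert rep.selected == [0]

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            identify_network({}, np.zeros((3, 3, 3), bool))

    def test_raising_threshold_never_enlarges_candidates(self):
        rng = np.random.default_rng(5)
        shape = (6, 6, 6)
        template = rng.random(shape) > 0.7
        comps = {i: rng.random(shape) > 0.8 for i in range(5)}
        prev = None
        for thr in (0.05, 0.1, 0.2, 0.4):
            cands = set(identify_network(comps, template, threshold=thr).candidates)
            if prev is not None:
                assert cands <= prev
            prev = cands

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive_on_split_network_cases(self, seed):
        # the scientific scenario: template split across components plus a
        # partially overlapping distractor
        rng = np.random.default_rng(seed)
        template, comps = _split_network_case(rng)
        rep = identify_network(comps, template, threshold=0.05)
        if not rep.candidates:
            pytest.skip("no candidates under this draw")
        _, best_j = exhaustive_best_subset(comps, template, rep.candidates)
        assert rep.selected_j == pytest.approx(best_j, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_bounded_on_unstructured_random_cases(self, seed):
        # on arbitrary masks greedy must sit between the best single
        # candidate and the exhaustive optimum (it may fall short of the
        # latter; the search log exposes the evaluated path for review)
        rng = np.random.default_rng(seed)
        shape = (7, 7, 7)
        template = rng.random(shape) > 0.75
        comps = {i: rng.random(shape) > 0.85 for i in range(6)}
        rep = identify_network(comps, template, threshold=0.01)
        if not rep.candidates:
            pytest.skip("no candidates under this draw")
        _, best_j = exhaustive_best_subset(comps, template, rep.candidates)
        assert rep.selected_j >= max(
            rep.per_component_j[c] for c in rep.candidates
        ) - 1e-12
        assert rep.selected_j <= best_j + 1e-12

    def test_selected_j_dominates_strict_subsets_on_accepted_path(self):
        _, template, comps = _split_template_case()
        rep = identify_network(comps, template)
        for members, j in rep.search_log:
            if set(members) < set(rep.selected):
                assert rep.selected_j >= j - 1e-12


class TestCompareTemplates:
    def test_agreement_flagged(self):
        shape = (6, 6, 6)
        comps = {0: _mask(shape, range(30)), 1: _mask(shape, range(120, 150))}
        t1 = _mask(shape, range(28))
        t2 = _mask(shape, range(2, 32))
        reports, agree = compare_templates(comps, {"a": t1, "b": t2})
        assert agree
        assert reports["a"].selected == reports["b"].selected == [0]

    def test_disagreement_warned(self):
        shape = (6, 6, 6)
        comps = {0: _mask(shape, range(30)), 1: _mask(shape, range(120, 150))}
        t1 = _mask(shape, range(28))
        t2 = _mask(shape, range(118, 152))
        with pytest.warns(UserWarning, match="disagree"):
            reports, agree = compare_templates(comps, {"a": t1, "b": t2})
        assert not agree
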