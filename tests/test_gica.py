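"""MDL order selection, PCA reduction, group ICA and back-reconstruction."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from gicanet.gica import (
    back_reconstruct,
    estimate_order_mdl,
    group_decompose,
    mdl_criterion,
    subject_reduce,
)
from gicanet.simulate import Grid, GroundTruth, make_templates, simulate_dataset


def _rank_k_subjects(rank, n_subjects, t=120, v=800, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        u = rng.standard_normal((t, rank))
        w = rng.standard_normal((rank, v))
        out.append(u @ w + noise * rng.standard_normal((t, v)))
    return out


class TestMdl:
    def test_equal_eigenvalues_minimise_at_zero(self):
        # geometric mean = arithmetic mean makes the data term vanish for all
        # k, so the complexity penalty picks k = 0
        vals = mdl_criterion(np.ones(50), 1000, np.arange(50))
        assert int(np.argmin(vals)) == 0

    def test_isotropic_data_floor_at_one_with_warning(self):
        # rows scaled from an orthonormal frame give an exactly flat spectrum
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((400, 50)))
        y = q[:, :30].T * 2.0
        with pytest.warns(UserWarning, match="floor"):
            est = estimate_order_mdl([y, y.copy()], demean=False)
        assert est.selected_order == 1

    @pytest.mark.parametrize("rank", [3, 8])
    def test_planted_rank_recovered(self, rank):
        est = estimate_order_mdl(_rank_k_subjects(rank, 4, seed=rank))
        assert est.selected_order == rank

    def test_group_mean_is_mean_of_subject_criteria(self):
        data = _rank_k_subjects(4, 3, seed=5)
        est = estimate_order_mdl(data)
        np.testing.assert_allclose(
            est.group_mean_mdl, est.per_subject_mdl.mean(axis=0)
        )
        assert est.selected_order == int(
            est.candidate_orders[np.argmin(est.group_mean_mdl)]
        )

    def test_deterministic_given_identical_data(self):
        data = _rank_k_subjects(5, 3, seed=2)
        a = estimate_order_mdl(data)
        b = estimate_order_mdl([d.copy() for d in data])
        np.testing.assert_array_equal(a.group_mean_mdl, b.group_mean_mdl)
        assert a.selected_order == b.selected_order

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            estimate_order_mdl([np.zeros((50, 100)), np.zeros((50, 100))])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            estimate_order_mdl([np.random.default_rng(0).standard_normal((20, 50))])


class TestSubjectReduce:
    def test_full_dimension_is_lossless(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((20, 200))
        red = subject_reduce(y, 20)
        recon = red.basis @ red.data + red.voxel_means
        np.testing.assert_allclose(recon, y, atol=1e-9)

    def test_rank_three_data_exact_at_target_three(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 300))
        y -= y.mean(axis=0)
        red = subject_reduce(y, 3)
        np.testing.assert_allclose(red.basis @ red.data, y, atol=1e-8)

    def test_retained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((30, 400))
        red = subject_reduce(y, 30)
        var = red.singular_values**2
        assert (np.diff(var) <= 1e-9).all()

    def test_excessive_target_dim_rejected(self):
        with pytest.raises(ValueError, match="target_dim"):
            subject_reduce(np.zeros((10, 50)), 11)


@pytest.fixture(scope="module")
def noiseless_decomposition(noiseless_dataset):
    truth, runs, tcs = noiseless_dataset
    subjects = sorted({r.subject_id for r in runs})
    data = {s: np.vstack([r.data for r in runs if r.subject_id == s]) for s in subjects}
    reductions = {s: subject_reduce(data[s], 6) for s in subjects}
    decomp = group_decompose(reductions, 4, seed=33, n_restarts=3)
    return truth, tcs, decomp


def _match_components(group_maps, planted):
    corr = np.corrcoef(np.vstack([group_maps, planted]))[
        : len(group_maps), len(group_maps) :
    ]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    return cols, np.abs(corr[rows, cols])


class TestGroupDecompose:
    def test_noiseless_planted_maps_recovered(self, noiseless_decomposition):
        truth, _, decomp = noiseless_decomposition
        _, corrs = _match_components(
            decomp.group_maps, np.stack(truth.planted_maps)
        )
        assert (corrs >= 0.95).all()

    def test_noiseless_timecourses_recovered(self, noiseless_decomposition):
        truth, tcs, decomp = noiseless_decomposition
        perm, _ = _match_components(decomp.group_maps, np.stack(truth.planted_maps))
        sid = decomp.subject_ids[0]
        rec = decomp.subject_timecourses[sid]
        true = tcs[sid]
        for c, n in enumerate(perm):
            r = np.corrcoef(rec[:, c], true[:, n])[0, 1]
            assert abs(r) >= 0.95

    def test_group_maps_have_nonnegative_skewness(self, noiseless_decomposition):
        from scipy.stats import skew

        _, _, decomp = noiseless_decomposition
        assert (skew(decomp.group_maps_raw, axis=1) >= -1e-9).all()

    def test_same_seed_identical_decomposition(self, noiseless_dataset):
        truth, runs, _ = noiseless_dataset
        subjects = sorted({r.subject_id for r in runs})
        data = {
            s: np.vstack([r.data for r in runs if r.subject_id == s])
            for s in subjects
        }
        reds = {s: subject_reduce(data[s], 6) for s in subjects}
        a = group_decompose(reds, 4, seed=33, n_restarts=2)
        b = group_decompose(reds, 4, seed=33, n_restarts=2)
        np.testing.assert_array_equal(a.group_maps, b.group_maps)
        for s in subjects:
            np.testing.assert_array_equal(
                a.subject_timecourses[s], b.subject_timecourses[s]
            )

    def test_variance_accounting(self, noiseless_dataset):
        # group-PCA projection + residual account for all concatenated variance
        truth, runs, _ = noiseless_dataset
        subjects = sorted({r.subject_id for r in runs})
        data = {
            s: np.vstack([r.data for r in runs if r.subject_id == s])
            for s in subjects
        }
        reds = {s: subject_reduce(data[s], 6) for s in subjects}
        decomp = group_decompose(reds, 4, seed=33, n_restarts=2)
        x = np.vstack([reds[s].data for s in subjects])
        g = decomp.group_basis.T @ x
        resid = x - decomp.group_basis @ g
        total = np.sum(x**2)
        np.testing.assert_allclose(
            np.sum(g**2) + np.sum(resid**2), total, rtol=1e-8
        )

    def test_mismatched_reduction_dims_rejected(self):
        rng = np.random.default_rng(0)
        reds = {
            "a": subject_reduce(rng.standard_normal((20, 100)), 5),
            "b": subject_reduce(rng.standard_normal((20, 100)), 6),
        }
        with pytest.raises(ValueError, match="common dimension"):
            group_decompose(reds, 4, seed=0)


class TestBackReconstruct:
    def test_matches_stored_subject_results(self, noiseless_decomposition):
        _, _, decomp = noiseless_decomposition
        sid = decomp.subject_ids[1]
        maps, tc = back_reconstruct(decomp, sid)
        np.testing.assert_allclose(maps, decomp.subject_maps[sid], atol=1e-10)
        np.testing.assert_allclose(tc, decomp.subject_timecourses[sid], atol=1e-10)

    def test_reconstruction_residual_bounded_by_pca_residual(
        self, noiseless_dataset
    ):
        # with order = planted rank the component model must explain the
        # reduced data as well as the PCA projection itself
        truth, runs, _ = noiseless_dataset
        subjects = sorted({r.subject_id for r in runs})
        data = {
            s: np.vstack([r.data for r in runs if r.subject_id == s])
            for s in subjects
        }
        reds = {s: subject_reduce(data[s], 4) for s in subjects}
        decomp = group_decompose(reds, 4, seed=33, n_restarts=2)
        for s in subjects:
            y = data[s] - data[s].mean(axis=0)
            pca_resid = np.linalg.norm(y - reds[s].basis @ reds[s].data)
            tc = decomp.subject_timecourses[s]
            sm = decomp.subject_maps[s]
            model_resid = np.linalg.norm(y - tc @ sm)
            assert model_resid <= pca_resid + 1e-6 * np.linalg.norm(y)

    def test_unknown_subject_rejected(self, noiseless_decomposition):
        _, _, decomp = noiseless_decomposition
        with pytest.raises(ValueError, match="unknown subject"):
            back_reconstruct(decomp, "sub-99")

    def test_subject_order_permutation_invariance(self, noiseless_dataset):
        truth, runs, _ = noiseless_dataset
        subjects = sorted({r.subject_id for r in runs})
        data = {
            s: np.vstack([r.data for r in runs if r.subject_id == s])
            for s in subjects
        }
        reds = {s: subject_reduce(data[s], 6) for s in subjects}
        fwd = group_decompose(reds, 4, seed=33, n_restarts=2)
        rev = group_decompose(
            {s: reds[s] for s in reversed(subjects)}, 4, seed=33, n_restarts=2
        )
        sid = subjects[0]
        # reconstructions (time-course x map products) must agree up to the
        # decomposition's inherent component permutation/sign freedom
        recon_f = fwd.subject_timecourses[sid] @ fwd.subject_maps[sid]
        recon_r = rev.subject_timecourses[sid] @ rev.subject_maps[sid]
        scale = np.linalg.norm(recon_f)
        assert np.linalg.norm(recon_f - recon_r) <= 1e-4 * scale
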