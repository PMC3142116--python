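"""Parental PCA, member projection, and residualization properties."""

import numpy as np
import pytest

from famjoint.stratification import (PCModel, adjust_cohort,
                                     choose_genomic_markers, fit_parental_pca,
                                     project_members, residualize)

from conftest import manual_cohort


class TestChooseGenomicMarkers:
    def test_sorted_unique_and_deterministic(self, small_null_cohort):
        idx = choose_genomic_markers(small_null_cohort, 100, seed=5)
        assert idx.shape == (100,)
        assert np.all(np.diff(idx) > 0)           # sorted, no repeats
        np.testing.assert_array_equal(
            idx, choose_genomic_markers(small_null_cohort, 100, seed=5))
        assert not np.array_equal(
            idx, choose_genomic_markers(small_null_cohort, 100, seed=6))

    def test_requesting_more_than_panel_errors(self, small_null_cohort):
        with pytest.raises(ValueError, match="l=10000"):
            choose_genomic_markers(small_null_cohort, 10000, seed=0)


class TestFitParentalPCA:
    def test_pc1_separates_subpopulations(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 200, seed=0)
        model = fit_parental_pca(structured_cohort, idx, K=5)
        scores = project_members(structured_cohort, model)
        par_scores = scores[structured_cohort.member_is_parent, 0]
        labels = np.repeat([f.subpop for f in structured_cohort.families], 2)
        r = np.corrcoef(par_scores, labels)[0, 1]
        assert abs(r) > 0.9

    def test_eigenvalues_nonincreasing_and_vectors_orthonormal(
            self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 200, seed=0)
        model = fit_parental_pca(structured_cohort, idx, K=5)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)
        np.testing.assert_allclose(model.eigenvectors.T @ model.eigenvectors,
                                   np.eye(5), atol=1e-10)

    def test_small_problem_matches_full_svd_path(self, structured_cohort):
        # l = 40 forces the exact-SVD branch; top eigenvalue must match the
        # covariance eigendecomposition computed independently here
        idx = choose_genomic_markers(structured_cohort, 40, seed=1)
        model = fit_parental_pca(structured_cohort, idx, K=3)
        Gp = structured_cohort.genotype_matrix[
            structured_cohort.member_is_parent][:, idx]
        Gc = Gp - Gp.mean(axis=0)
        w = np.linalg.eigvalsh(Gc.T @ Gc / (Gp.shape[0] - 1))[::-1]
        np.testing.assert_allclose(model.eigenvalues, w[:3], rtol=1e-8)

    def test_k_exceeding_rank_errors(self):
        # every parent carries one of two genotype vectors -> centered rank 1
        a = np.array([0.0, 1, 2, 0, 1, 2])
        b = np.array([2.0, 1, 0, 2, 1, 0])
        cohort = manual_cohort(
            father=[a, a, b], mother=[b, a, b],
            children=[[(a + b) / 2], [a], [b]],
            traits=[(0.1, 0.2, 0.3), (0.4, 0.5, 0.6), (0.7, 0.8, 0.9)])
        with pytest.raises(ValueError, match="rank"):
            fit_parental_pca(cohort, np.arange(6), K=2)

    def test_too_few_parents_errors(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(3, 30)).astype(float)
        cohort = manual_cohort(father=[g[0]], mother=[g[1]],
                               children=[[g[2]]], traits=[(0, 1, 2)])
        with pytest.raises(ValueError, match="parents"):
            fit_parental_pca(cohort, np.arange(30), K=5)

    def test_missing_genotypes_mean_imputed(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 100, seed=2)
        model = fit_parental_pca(structured_cohort, idx, K=2)
        # knocking out a handful of entries perturbs, not destroys, the fit
        import copy
        fams = copy.deepcopy(structured_cohort.families)
        fams[0].father_genotypes[idx[0]] = np.nan
        fams[1].mother_genotypes[idx[1]] = np.nan
        from famjoint.datamodel import FamilyCohort
        holey = FamilyCohort(fams, structured_cohort.markers)
        model2 = fit_parental_pca(holey, idx, K=2)
        assert abs(np.corrcoef(model.eigenvectors[:, 0],
                               model2.eigenvectors[:, 0])[0, 1]) > 0.99


class TestProjection:
    def test_child_pc1_tracks_midparent(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 200, seed=0)
        model = fit_parental_pca(structured_cohort, idx, K=1)
        scores = project_members(structured_cohort, model)[:, 0]
        fa = scores[structured_cohort.member_is_father]
        par = structured_cohort.member_is_parent
        mo = scores[par & ~structured_cohort.member_is_father]
        ch = scores[~par]
        mid = (fa + mo) / 2.0
        slope = np.polyfit(mid, ch, 1)[0]
        assert 0.8 < slope < 1.2

    def test_parent_scores_are_centered(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 150, seed=3)
        model = fit_parental_pca(structured_cohort, idx, K=3)
        scores = project_members(structured_cohort, model)
        par_scores = scores[structured_cohort.member_is_parent]
        np.testing.assert_allclose(par_scores.mean(axis=0), 0.0, atol=1e-9)


class TestResidualize:
    def test_parental_residuals_orthogonal_to_design(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 200, seed=0)
        model = fit_parental_pca(structured_cohort, idx, K=4)
        pcs = project_members(structured_cohort, model)
        adj = residualize(structured_cohort, pcs,
                          candidate_indices=np.arange(20))
        par = structured_cohort.member_is_parent
        D = np.column_stack([np.ones(par.sum()), pcs[par]])
        np.testing.assert_allclose(D.T @ adj.residual_traits[par], 0.0,
                                   atol=1e-7)
        np.testing.assert_allclose(D.T @ adj.residual_scores[par], 0.0,
                                   atol=1e-6)

    def test_residualization_is_idempotent(self, structured_cohort):
        idx = choose_genomic_markers(structured_cohort, 200, seed=0)
        model = fit_parental_pca(structured_cohort, idx, K=4)
        pcs = project_members(structured_cohort, model)
        adj = residualize(structured_cohort, pcs,
                          candidate_indices=np.arange(5))
        again = residualize(structured_cohort.with_traits(adj.residual_traits),
                            pcs, candidate_indices=np.arange(5))
        np.testing.assert_allclose(again.residual_traits, adj.residual_traits,
                                   atol=1e-8)

    def test_k0_is_intercept_only(self, small_null_cohort):
        adj = adjust_cohort(small_null_cohort, K=0,
                            candidate_indices=np.arange(10))
        par = small_null_cohort.member_is_parent
        y = small_null_cohort.trait_vector
        np.testing.assert_allclose(adj.residual_traits, y - y[par].mean(),
                                   atol=1e-10)
        G = small_null_cohort.genotype_matrix[:, :10]
        np.testing.assert_allclose(adj.residual_scores,
                                   G - G[par].mean(axis=0), atol=1e-10)

    def test_missing_candidate_genotype_keeps_residual_missing(
            self, structured_cohort):
        import copy
        from famjoint.datamodel import FamilyCohort
        fams = copy.deepcopy(structured_cohort.families)
        fams[3].father_genotypes[7] = np.nan
        holey = FamilyCohort(fams, structured_cohort.markers)
        adj = adjust_cohort(holey, K=2, l=100, seed=0,
                            candidate_indices=[7])
        row = np.nonzero(holey.member_is_father)[0][3]
        assert np.isnan(adj.residual_scores[row, 0])
        assert np.isfinite(np.delete(adj.residual_scores[:, 0], row)).all()

    def test_wrong_pc_row_count_errors(self, small_null_cohort):
        with pytest.raises(ValueError, match="rows"):
            residualize(small_null_cohort, np.zeros((5, 2)))


class TestPCModelSerialization:
    def test_tsv_round_trip(self, structured_cohort, tmp_path):
        idx = choose_genomic_markers(structured_cohort, 80, seed=4)
        model = fit_parental_pca(structured_cohort, idx, K=3)
        model.to_tsv(tmp_path / "pc")
        back = PCModel.from_tsv(tmp_path / "pc")
        np.testing.assert_array_equal(back.genomic_marker_indices,
                                      model.genomic_marker_indices)
        np.testing.assert_allclose(back.parental_means, model.parental_means,
                                   atol=1e-9)
        np.testing.assert_allclose(back.eigenvectors, model.eigenvectors,
                                   atol=1e-9)
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues,
                                   rtol=1e-9)
        assert back.K == 3
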