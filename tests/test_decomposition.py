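"""Shape PCA, symmetry-subspace classification, variance fractions, scores."""

import numpy as np
import pytest

import florasym as fs
from florasym import align, decomposition, symmetry
from florasym.align import AlignmentResult
from conftest import tiny_params


def pipeline_to_decomposition(params, sliders=True, classify=True):
    data, truth = fs.generate_population(params)
    expanded = symmetry.expand_symmetry_group(data)
    spec = align.default_slider_spec() if sliders else None
    alignment = align.gpa(expanded, sliders=spec)
    dec = decomposition.shape_pca(alignment)
    if classify:
        dec = decomposition.classify_components(dec)
    return data, expanded, alignment, dec


@pytest.fixture(scope="module")
def mixed_decomposition(mixed_aligned):
    _, expanded, alignment = mixed_aligned
    dec = decomposition.classify_components(decomposition.shape_pca(alignment))
    return expanded, dec


class TestShapePca:
    def test_identical_configurations_have_no_variance(self):
        data, _ = fs.generate_population(tiny_params(seed=2))
        expanded = symmetry.expand_symmetry_group(data)
        alignment = align.gpa(expanded)
        dec = decomposition.shape_pca(alignment)
        assert dec.eigenvalues.sum() < 1e-12

    def test_eigenvalue_sum_equals_total_variance(self, mixed_decomposition):
        _, dec = mixed_decomposition
        assert dec.eigenvalues.sum() == pytest.approx(dec.total_variance,
                                                      rel=1e-8)

    def test_matches_covariance_eigensolve_oracle(self):
        """Scores agree (up to sign) with a direct eigendecomposition of the
        coordinate covariance matrix on a small toy alignment."""
        rng = np.random.default_rng(8)
        aligned = rng.normal(size=(10, 6, 2)) * 0.01
        aligned -= aligned.mean(axis=1, keepdims=True)
        aligned /= np.sqrt(np.sum(aligned ** 2, axis=(1, 2)))[:, None, None]
        res = AlignmentResult(aligned=aligned, consensus=aligned.mean(axis=0),
                              centroid_sizes=np.ones(10), iterations=0,
                              slide_iterations=0)
        dec = decomposition.shape_pca(res, n_petals=1, points_per_petal=6,
                                      canonicalize=False)
        flat = aligned.reshape(10, -1)
        cov = np.cov(flat, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        keep = len(dec.eigenvalues)
        assert np.allclose(dec.eigenvalues, vals[:keep], atol=1e-12)
        oracle_scores = (flat - flat.mean(axis=0)) @ vecs[:, :keep]
        for j in range(keep):
            assert (np.allclose(dec.scores[:, j], oracle_scores[:, j], atol=1e-9)
                    or np.allclose(dec.scores[:, j], -oracle_scores[:, j],
                                   atol=1e-9))

    def test_too_few_configurations_rejected(self):
        one = np.zeros((1, 8, 2))
        res = AlignmentResult(aligned=one, consensus=one[0],
                              centroid_sizes=np.ones(1), iterations=0,
                              slide_iterations=0)
        with pytest.raises(ValueError):
            decomposition.shape_pca(res, n_petals=1, points_per_petal=8)


class TestClassification:
    @pytest.mark.parametrize("sigma_field,expected", [
        ("sigma_sym", "symmetric"),
        ("sigma_lat", "lateral"),
        ("sigma_trans", "transversal"),
    ])
    def test_pure_subspace_generators_recovered(self, sigma_field, expected):
        params = tiny_params(flowers_per_tree=4, seed=7,
                             **{sigma_field: 0.04})
        *_, dec = pipeline_to_decomposition(params)
        fractions = decomposition.variance_fractions(dec)
        assert fractions[expected] >= 95.0

    def test_agrees_with_copy_projection_oracle(self, mixed_decomposition):
        expanded, dec = mixed_decomposition
        oracle = decomposition.classify_by_copy_scores(dec, expanded)
        gaps_ok = np.concatenate([
            [True], np.diff(dec.eigenvalues) / dec.eigenvalues[:-1] < -1e-3])
        checked = 0
        for mine, theirs, sharp, lam in zip(dec.labels, oracle, gaps_ok,
                                            dec.eigenvalues):
            if sharp and lam > 1e-6 * dec.eigenvalues[0] \
                    and theirs != "ambiguous":
                assert mine == theirs
                checked += 1
        assert checked >= 5

    def test_characters_match_labels(self, mixed_decomposition):
        _, dec = mixed_decomposition
        for label, (sv, sh) in zip(dec.labels, dec.characters):
            if label == "symmetric":
                assert sv > 0.9 and sh > 0.9
            elif label == "transversal":
                assert sv < -0.9 and sh < -0.9
            elif label == "lateral":
                assert sv * sh < 0


class TestVarianceFractions:
    def test_fractions_partition_total(self, mixed_decomposition):
        _, dec = mixed_decomposition
        fr = decomposition.variance_fractions(dec)
        assert sum(fr.values()) == pytest.approx(100.0, abs=1e-6)

    def test_unclassified_decomposition_rejected(self, mixed_aligned):
        _, _, alignment = mixed_aligned
        dec = decomposition.shape_pca(alignment)
        with pytest.raises(ValueError):
            decomposition.variance_fractions(dec)


class TestAsymmetryScores:
    def test_symmetric_flowers_have_zero_scores(self):
        params = tiny_params(flowers_per_tree=4, sigma_sym=0.05, seed=9)
        _, expanded, _, dec = pipeline_to_decomposition(params)
        scores = decomposition.asymmetry_scores(dec, expanded)
        assert np.abs(scores.table["lateral_score"]).max() < 1e-9
        assert np.abs(scores.table["transversal_score"]).max() < 1e-9

    def test_symmetry_copies_share_subspace_norms(self, mixed_decomposition):
        expanded, dec = mixed_decomposition
        scores = decomposition.asymmetry_scores(dec, expanded,
                                                mode="per_configuration")
        t = scores.table
        for col in ("lateral_score", "transversal_score"):
            spread = t.groupby("object_id")[col].agg(np.ptp)
            assert spread.max() < 1e-8

    def test_scores_invariant_to_rigid_motion_of_input(self):
        params = tiny_params(flowers_per_tree=4, sigma_lat=0.03,
                             sigma_trans=0.02, seed=10)
        data, _ = fs.generate_population(params)

        def run(dataset):
            expanded = symmetry.expand_symmetry_group(dataset)
            alignment = align.gpa(expanded, sliders=align.default_slider_spec())
            dec = decomposition.classify_components(
                decomposition.shape_pca(alignment))
            return decomposition.asymmetry_scores(dec, expanded)

        s1 = run(data)
        a = 0.8
        rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        moved = fs.Dataset([c.copy(points=c.points @ rot * 2.5 + [40.0, -7.0])
                            for c in data.configurations])
        s2 = run(moved)
        assert np.allclose(s1.table["lateral_score"],
                           s2.table["lateral_score"], atol=1e-6)
        assert np.allclose(s1.table["transversal_score"],
                           s2.table["transversal_score"], atol=1e-6)

    def test_abs_sum_mode_bounds_norm(self, mixed_decomposition):
        expanded, dec = mixed_decomposition
        norm = decomposition.asymmetry_scores(dec, expanded, score_kind="norm")
        abss = decomposition.asymmetry_scores(dec, expanded,
                                              score_kind="abs_sum")
        assert (abss.table["lateral_score"] + 1e-12
                >= norm.table["lateral_score"]).all()

    def test_transform_equivariance_of_fractions(self):
        """Feeding the half-turn copies as the raw data leaves the variance
        fractions unchanged: the expanded set is the same."""
        params = tiny_params(flowers_per_tree=3, sigma_sym=0.04,
                             sigma_lat=0.02, sigma_trans=0.015, seed=11)
        data, _ = fs.generate_population(params)

        def decompose(dataset):
            expanded = symmetry.expand_symmetry_group(dataset)
            alignment = align.gpa(expanded, tol=1e-10)
            return decomposition.classify_components(
                decomposition.shape_pca(alignment))

        dec1 = decompose(data)
        rotated = fs.Dataset([
            fs.apply_transform(c, "reflectHV").copy(transform_id="identity")
            for c in data.configurations
        ])
        dec2 = decompose(rotated)
        f1 = decomposition.variance_fractions(dec1)
        f2 = decomposition.variance_fractions(dec2)
        for key in ("symmetric", "lateral", "transversal"):
            assert f1[key] == pytest.approx(f2[key], abs=1e-6)

    def test_transversal_score_increases_with_injected_sd(self):
        """Mean transversal score grows strictly with sigma_trans (20 seeds)."""
        levels = (0.01, 0.02, 0.04)
        means = []
        for sigma in levels:
            vals = []
            for seed in range(20):
                params = tiny_params(n_trees_per_sex=1, flowers_per_tree=3,
                                     sigma_trans=sigma, sigma_lat=0.01,
                                     sigma_sym=0.02, seed=100 + seed)
                _, expanded, _, dec = pipeline_to_decomposition(
                    params, sliders=False)
                scores = decomposition.asymmetry_scores(dec, expanded)
                vals.append(scores.table["transversal_score"].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
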