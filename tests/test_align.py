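"""Centroid size, Procrustes fits, GPA, bending energy and sliding."""

import numpy as np
import pytest

import florasym as fs
from florasym import align
from florasym.align import (
    DegenerateConfigurationError,
    bending_energy,
    bending_energy_matrix,
    default_slider_spec,
    slide_semilandmarks,
)
from conftest import tiny_params


def rigid(points, angle=0.0, shift=(0.0, 0.0), scale=1.0):
    c, s = np.cos(angle), np.sin(angle)
    return scale * points @ np.array([[c, s], [-s, c]]) + np.asarray(shift)


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        pts = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert fs.centroid_size(pts) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneity_and_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 2))
        cs = fs.centroid_size(pts)
        assert fs.centroid_size(2.0 * pts) == pytest.approx(2.0 * cs, rel=1e-12)
        assert fs.centroid_size(rigid(pts, 0.7, (3, -4))) == pytest.approx(
            cs, rel=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 2)) * 50 + 10
        centre = pts.mean(axis=0)
        oracle = np.sqrt(sum((p - centre) @ (p - centre) for p in pts))
        assert fs.centroid_size(pts) == pytest.approx(oracle, rel=1e-12)

    def test_coincident_points_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fs.centroid_size(np.ones((5, 2))) == 0.0


class TestPartialProcrustesFit:
    def test_recovers_rigid_plus_scale_copy(self):
        rng = np.random.default_rng(3)
        src = rng.normal(size=(30, 2))
        tgt = rigid(src, angle=1.2, shift=(5, -2), scale=3.7)
        _, d = fs.partial_procrustes_fit(src, tgt)
        assert d < 1e-10

    def test_reflection_is_never_used(self):
        rng = np.random.default_rng(4)
        src = rng.normal(size=(30, 2))
        mirrored = src * np.array([-1.0, 1.0])
        _, d = fs.partial_procrustes_fit(src, mirrored)
        assert d > 0.1

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(5)
        src, tgt = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        _, d = fs.partial_procrustes_fit(src, tgt)
        a = src - src.mean(0); a /= np.linalg.norm(a)
        b = tgt - tgt.mean(0); b /= np.linalg.norm(b)
        best = np.inf
        for theta in np.arange(0.0, 2 * np.pi, 1e-4):
            c, s = np.cos(theta), np.sin(theta)
            best = min(best, np.linalg.norm(a @ np.array([[c, -s], [s, c]]) - b))
        assert d == pytest.approx(best, abs=1e-6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            fs.partial_procrustes_fit(np.ones((5, 2)), np.eye(5, 2))


class TestGpa:
    def test_identical_shapes_align_exactly(self):
        rng = np.random.default_rng(6)
        shape = rng.normal(size=(40, 2))
        stack = np.stack([
            rigid(shape, rng.uniform(0, 2 * np.pi), rng.normal(size=2) * 10,
                  rng.uniform(0.5, 2.0))
            for _ in range(8)
        ])
        res = align.gpa(stack)
        assert np.abs(res.aligned - res.aligned[0]).max() < 1e-8
        _, d = fs.partial_procrustes_fit(res.consensus, shape)
        assert d < 1e-8

    def test_aligned_invariants(self, mixed_aligned):
        _, _, res = mixed_aligned
        centroids = res.aligned.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        sizes = np.sqrt(np.sum(res.aligned ** 2, axis=(1, 2)))
        assert np.abs(sizes - 1.0).max() < 1e-9
        assert np.allclose(res.consensus, res.aligned.mean(axis=0), atol=1e-9)

    def test_objective_non_increasing(self):
        data, _ = fs.generate_population(
            tiny_params(sigma_sym=0.06, sigma_lat=0.03, sigma_petal=0.01,
                        sigma_imaging=0.6, seed=21))
        res = align.gpa(data.coords(), tol=1e-12, max_iter=100)
        ss = np.asarray(res.ss_history)
        assert np.all(np.diff(ss) <= 1e-10)

    def test_consensus_of_expanded_group_is_biradial(self):
        data, _ = fs.generate_population(
            tiny_params(sigma_sym=0.05, sigma_lat=0.03, sigma_petal=0.01, seed=12))
        expanded = fs.expand_symmetry_group(data)
        res = align.gpa(expanded, tol=1e-10)
        cfg = fs.Configuration(points=res.consensus, object_id="c")
        for name in ("reflectV", "reflectH"):
            copy = fs.apply_transform(cfg, name)
            _, d = fs.partial_procrustes_fit(copy, cfg)
            assert d < 1e-8

    def test_invariant_to_input_rigid_motion_and_order(self):
        data, _ = fs.generate_population(
            tiny_params(sigma_sym=0.05, sigma_petal=0.01, seed=13))
        coords = data.coords()
        res1 = align.gpa(coords, tol=1e-10)
        moved = np.stack([rigid(c, 0.9, (120, -55), 1.8) for c in coords])
        res2 = align.gpa(moved, tol=1e-10)
        _, d = fs.partial_procrustes_fit(res1.consensus, res2.consensus)
        assert d < 1e-8
        # pairwise shape distances are order- and frame-independent
        res3 = align.gpa(coords[::-1], tol=1e-10)
        d12 = np.linalg.norm(res1.aligned[0] - res1.aligned[1])
        d12_rev = np.linalg.norm(res3.aligned[-1] - res3.aligned[-2])
        assert d12 == pytest.approx(d12_rev, abs=1e-8)

    def test_matches_plain_gpa_oracle_without_sliders(self):
        """Independent oracle: naive iterative GPA with closed-form 2D fits."""
        rng = np.random.default_rng(14)
        stack = rng.normal(size=(6, 20, 2))
        res = align.gpa(stack, tol=1e-12, max_iter=200)

        def fit(a, b):
            m = a.T @ b
            ang = np.arctan2(m[1, 0] - m[0, 1], m[0, 0] + m[1, 1])
            c, s = np.cos(ang), np.sin(ang)
            return a @ np.array([[c, -s], [s, c]])

        norm = []
        for x in stack:
            x = x - x.mean(0)
            norm.append(x / np.sqrt(np.sum(x ** 2)))
        cons = norm[0]
        for _ in range(200):
            norm = [fit(x, cons) for x in norm]
            new = np.mean(norm, axis=0)
            if np.abs(new - cons).max() < 1e-13:
                break
            cons = new
        for mine, oracle in zip(res.aligned, norm):
            assert np.abs(mine - oracle).max() < 1e-8


@pytest.fixture(scope="module")
def reference():
    return fs.render_petal(fs.PetalTemplate(), 20)


class TestBendingEnergy:
    def test_affine_deformations_have_zero_energy(self, reference):
        be = bending_energy_matrix(reference)
        affine = reference @ np.array([[1.2, 0.3], [-0.1, 0.9]]) + [5.0, -2.0]
        assert bending_energy(be, affine - reference) < 1e-8

    def test_nonaffine_deformation_has_positive_energy(self, reference):
        be = bending_energy_matrix(reference)
        bump = np.zeros_like(reference)
        bump[10, 1] = 1.0
        assert bending_energy(be, bump) > 1e-6


class TestSliding:
    def test_configuration_at_consensus_does_not_move(self):
        consensus = fs.generate_corolla(fs.PetalTemplate()).points
        consensus = consensus - consensus.mean(0)
        consensus /= np.linalg.norm(consensus)
        out = slide_semilandmarks(consensus.copy(), consensus,
                                  default_slider_spec())
        assert np.abs(out - consensus).max() < 1e-10

    def test_bending_energy_never_increases(self, mixed_aligned):
        _, _, res = mixed_aligned
        sliders = default_slider_spec()
        be = bending_energy_matrix(res.consensus)
        before = res.aligned[:40]
        after = slide_semilandmarks(before, res.consensus, sliders, be_matrix=be)
        for x, y in zip(before, after):
            e0 = bending_energy(be, x - res.consensus)
            e1 = bending_energy(be, y - res.consensus)
            assert e1 <= e0 + 1e-12
        fixed = sliders.fixed
        assert np.abs(after[:, fixed] - before[:, fixed]).max() == 0.0

    def test_single_slider_matches_scalar_closed_form(self):
        """One sliding point: the linear solve must equal the 1D quadratic
        minimiser of bending energy along the tangent line."""
        rng = np.random.default_rng(15)
        consensus = np.array([[0.0, 0.0], [1.0, 0.1], [2.0, -0.1],
                              [3.0, 0.2], [4.0, 0.0]])
        config = consensus + rng.normal(0, 0.05, size=consensus.shape)
        spec = align.SliderSpec(fixed=np.array([0, 1, 3, 4]),
                                triplets=np.array([[1, 2, 3]]))
        be = bending_energy_matrix(consensus)
        out = slide_semilandmarks(config.copy(), consensus, spec, be_matrix=be)

        tang = config[3] - config[1]
        tang = tang / np.linalg.norm(tang)
        ts = np.linspace(-0.5, 0.5, 100001)
        energies = []
        for t in ts:
            moved = config.copy()
            moved[2] += t * tang
            energies.append(bending_energy(be, moved - consensus))
        t_star = ts[int(np.argmin(energies))]
        expected = config.copy()
        expected[2] += t_star * tang
        assert np.abs(out - expected).max() < 1e-4  # grid resolution
        # and against the analytic quadratic minimum
        dx, dy = (config - consensus)[:, 0], (config - consensus)[:, 1]
        g = tang[0] * (be[2] @ dx) + tang[1] * (be[2] @ dy)
        h = (tang[0] ** 2 + tang[1] ** 2) * be[2, 2]
        t_exact = -g / h
        expected[2] = config[2] + t_exact * tang
        assert np.abs(out - expected).max() < 1e-8
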