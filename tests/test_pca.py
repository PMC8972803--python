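import numpy as np
import pytest

import globaldyn as gd
from globaldyn.errors import ShapeError
from globaldyn.pca import variance_fractions

from conftest import random_nodeset, random_rotation


class TestDeformationVector:
    def test_identical_structures_zero(self, rng):
        a = random_nodeset(rng, 6)
        assert np.abs(gd.deformation_vector(a, a).values).max() < 1e-10
        assert np.all(gd.deformation_vector(a, a, superpose=False).values == 0)

    def test_uniform_shift_without_superposition(self, rng):
        a = random_nodeset(rng, 6)
        b = a.copy(a.coords + [1.0, 0, 0])
        delta = gd.deformation_vector(a, b, superpose=False).as_matrix()
        np.testing.assert_allclose(delta[:, 0], 1.0)
        np.testing.assert_allclose(delta[:, 1:], 0.0)

    def test_rigid_rotation_removed_by_superposition(self, rng):
        a = random_nodeset(rng, 8)
        b = a.copy(a.coords @ random_rotation(rng).T + [2, 3, 4])
        delta = gd.deformation_vector(a, b, superpose=True)
        assert np.linalg.norm(delta.values) < 1e-8


class TestMorph:
    def test_two_frames_are_endpoints(self, rng):
        a = random_nodeset(rng, 6)
        b = a.copy(a.coords + rng.normal(0, 1, (6, 3)))
        ens = gd.morph(a, b, 2, superpose=False)
        np.testing.assert_allclose(ens.members[0], a.coords)
        np.testing.assert_allclose(ens.members[1], b.coords)

    def test_midpoint_is_average(self, rng):
        a = random_nodeset(rng, 6)
        b = a.copy(a.coords + rng.normal(0, 1, (6, 3)))
        ens = gd.morph(a, b, 3, superpose=False)
        np.testing.assert_allclose(ens.members[1], (a.coords + b.coords) / 2)

    def test_rmsd_monotone_along_path(self, rng):
        a = random_nodeset(rng, 8)
        b = a.copy(a.coords + rng.normal(0, 2, (8, 3)))
        ens = gd.morph(a, b, 7)
        dists = [gd.rmsd(ens.members[t], a.coords) for t in range(7)]
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_single_frame_rejected(self, rng):
        a = random_nodeset(rng, 4)
        with pytest.raises(ValueError):
            gd.morph(a, a, 1)


class TestEnsembleCovariance:
    def test_identical_members_zero_matrix(self, rng):
        base = random_nodeset(rng, 5)
        ens = gd.Ensemble(list(base.labels), np.stack([base.coords] * 4))
        cov = gd.ensemble_covariance(ens)
        assert np.abs(cov.matrix).max() == 0.0

    def test_two_member_rank_one_quarter_outer_product(self, rng):
        base = random_nodeset(rng, 5)
        delta = rng.normal(size=15)
        d3 = delta.reshape(-1, 3)
        ens = gd.Ensemble(
            list(base.labels),
            np.stack([base.coords + d3 / 2, base.coords - d3 / 2]),
        )
        cov = gd.ensemble_covariance(ens)
        np.testing.assert_allclose(cov.matrix, np.outer(delta, delta) / 4,
                                   atol=1e-12)
        assert np.linalg.matrix_rank(cov.matrix, tol=1e-10) == 1

    def test_trace_equals_total_variance(self, rng):
        base = random_nodeset(rng, 6)
        members = base.coords[None] + rng.normal(0, 1, (8, 6, 3))
        ens = gd.Ensemble(list(base.labels), members)
        cov = gd.ensemble_covariance(ens)
        msd = np.mean(np.sum((members - members.mean(0)) ** 2, axis=(1, 2)))
        assert cov.total_variance == pytest.approx(msd)

    def test_masked_columns_excluded(self, rng):
        base = random_nodeset(rng, 6)
        members = base.coords[None] + rng.normal(0, 1, (4, 6, 3))
        mask = np.ones((4, 6), bool)
        mask[2, 5] = False
        ens = gd.Ensemble(list(base.labels), members, mask)
        cov = gd.ensemble_covariance(ens)
        assert cov.matrix.shape == (15, 15)
        np.testing.assert_array_equal(cov.core_columns, np.arange(5))

    def test_single_member_rejected(self, rng):
        base = random_nodeset(rng, 5)
        ens = gd.Ensemble(list(base.labels), base.coords[None])
        with pytest.raises(ShapeError):
            gd.ensemble_covariance(ens)


class TestPcaModes:
    def test_rank_one_covariance_recovers_direction(self, rng):
        base = random_nodeset(rng, 5)
        delta = rng.normal(size=15)
        d3 = delta.reshape(-1, 3)
        ens = gd.Ensemble(
            list(base.labels),
            np.stack([base.coords + d3 / 2, base.coords - d3 / 2]),
        )
        modes = gd.pca_modes(gd.ensemble_covariance(ens))
        assert gd.mode_overlap(modes.mode(0), delta) > 1 - 1e-10
        assert variance_fractions(modes)[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_trace(self, rng):
        base = random_nodeset(rng, 6)
        members = base.coords[None] + rng.normal(0, 1, (10, 6, 3))
        cov = gd.ensemble_covariance(gd.Ensemble(list(base.labels), members))
        modes = gd.pca_modes(cov)
        assert modes.variances.sum() == pytest.approx(cov.total_variance,
                                                      abs=1e-10)

    def test_two_state_fixture_recovery(self):
        base = gd.make_lattice_structure(4)
        gen = gd.make_two_state_ensemble(base, amplitude=4.0, noise_sigma=0.4,
                                         m=50, seed=11)
        modes = gd.pca_modes(gd.ensemble_covariance(gen.ensemble))
        assert gd.mode_overlap(modes.mode(0), gen.direction) > 0.99

    def test_enm_covariance_round_trip_recovers_modes(self, rng):
        # PCA of a covariance synthesized from ANM modes returns those modes
        nodes = random_nodeset(rng, 8)
        anm = gd.compute_modes(gd.build_anm_hessian(nodes))
        cov = gd.CovarianceMatrix(gd.covariance_from_modes(anm), nodes, 1)
        pcs = gd.pca_modes(cov, anm.n_modes)
        overlap = gd.overlap_matrix(pcs, anm)
        # signed permutation within degenerate blocks: every PC matches
        # some ANM mode almost perfectly
        assert np.allclose(np.sort(overlap.max(axis=1)), 1.0, atol=1e-6)


class TestProjection:
    def _noisy_ensemble(self, rng, m=10, n=6):
        base = random_nodeset(rng, n)
        members = base.coords[None] + rng.normal(0, 1, (m, n, 3))
        return gd.Ensemble(list(base.labels), members)

    def test_mean_projects_to_origin(self, rng):
        ens = self._noisy_ensemble(rng)
        cov = gd.ensemble_covariance(ens)
        modes = gd.pca_modes(cov)
        mean_ens = gd.Ensemble(list(ens.labels),
                               np.stack([cov.mean.coords] * 2))
        proj = gd.project(mean_ens, modes, mean=cov.mean)
        np.testing.assert_allclose(proj.coordinates, 0.0, atol=1e-10)

    def test_conformer_along_mode_projects_to_coefficient(self, rng):
        ens = self._noisy_ensemble(rng)
        cov = gd.ensemble_covariance(ens)
        modes = gd.pca_modes(cov)
        c = 2.7
        conf = gd.generate_conformer(cov.mean, modes, [c])
        one = gd.Ensemble(list(ens.labels),
                          np.stack([conf.coords, cov.mean.coords]))
        proj = gd.project(one, modes, mean=cov.mean)
        assert proj.coordinates[0, 0] == pytest.approx(c)
        np.testing.assert_allclose(proj.coordinates[0, 1:], 0.0, atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        ens = self._noisy_ensemble(rng, m=12, n=5)
        cov = gd.ensemble_covariance(ens)
        modes = gd.pca_modes(cov)
        proj = gd.project(ens, modes)
        recon = (cov.mean.coords.ravel()[None]
                 + proj.coordinates @ modes.vectors.T)
        np.testing.assert_allclose(
            recon, ens.members.reshape(12, -1), atol=1e-8
        )


class TestGenerateConformer:
    def test_zero_coefficients_return_reference(self, rng):
        nodes = random_nodeset(rng, 6)
        modes = gd.compute_modes(gd.build_anm_hessian(nodes))
        out = gd.generate_conformer(nodes, modes, np.zeros(3))
        np.testing.assert_array_equal(out.coords, nodes.coords)

    def test_rmsd_is_coefficient_over_sqrt_n(self, rng):
        nodes = random_nodeset(rng, 9)
        modes = gd.compute_modes(gd.build_anm_hessian(nodes))
        c = 3.4
        out = gd.generate_conformer(nodes, modes, [c])
        assert gd.rmsd(out, nodes) == pytest.approx(abs(c) / np.sqrt(9))

    def test_opposite_signs_mirror_about_reference(self, rng):
        nodes = random_nodeset(rng, 6)
        modes = gd.compute_modes(gd.build_anm_hessian(nodes))
        plus = gd.generate_conformer(nodes, modes, [1.5])
        minus = gd.generate_conformer(nodes, modes, [-1.5])
        np.testing.assert_allclose(
            plus.coords - nodes.coords, -(minus.coords - nodes.coords),
            atol=1e-12,
        )

    def test_variance_fraction_scaling(self, rng):
        nodes = random_nodeset(rng, 6)
        modes = gd.compute_modes(gd.build_anm_hessian(nodes))
        frac = gd.generate_conformer(nodes, modes, [0.125],
                                     variance_fraction=True)
        expected_amp = np.sqrt(0.125 * modes.variances[0])
        assert gd.rmsd(frac, nodes) == pytest.approx(expected_amp / np.sqrt(6))

    def test_too_many_coefficients_rejected(self, rng):
        nodes = random_nodeset(rng, 4)
        modes = gd.compute_modes(gd.build_anm_hessian(nodes))
        with pytest.raises(ShapeError):
            gd.generate_conformer(nodes, modes, np.ones(modes.n_modes + 1))


class TestLandscape:
    def _proj(self, coords):
        from conftest import random_modeset
        rng = np.random.default_rng(0)
        return gd.ProjectionSet(coords, random_modeset(rng, 12, 2))

    def test_identical_points_single_bin(self):
        proj = self._proj(np.zeros((20, 2)))
        out = gd.landscape_density(proj, "histogram", bins=5)
        assert np.count_nonzero(out.density) == 1
        assert out.density.max() == pytest.approx(1.0)

    def test_histogram_sums_to_one(self, rng):
        proj = self._proj(rng.normal(size=(100, 2)))
        out = gd.landscape_density(proj, "histogram")
        assert out.density.sum() == pytest.approx(1.0, abs=1e-6)

    def test_kde_integrates_to_one(self, rng):
        proj = self._proj(rng.normal(size=(60, 2)))
        out = gd.landscape_density(proj, "kde", bins=40)
        cell = ((out.x_centers[1] - out.x_centers[0])
                * (out.y_centers[1] - out.y_centers[0]))
        assert out.density.sum() * cell == pytest.approx(1.0, abs=1e-6)

    def test_two_planted_clusters_give_two_maxima(self):
        rng = np.random.default_rng(42)
        c1 = rng.normal([-5.0, -5.0], 0.5, size=(100, 2))
        c2 = rng.normal([5.0, 5.0], 0.5, size=(100, 2))
        proj = self._proj(np.vstack([c1, c2]))
        out = gd.landscape_density(proj, "kde", bins=25)
        dens = out.density
        maxima = []
        padded = np.pad(dens, 1, constant_values=-1.0)
        for i in range(dens.shape[0]):
            for j in range(dens.shape[1]):
                window = padded[i:i + 3, j:j + 3].copy()
                window[1, 1] = -1.0
                if dens[i, j] > window.max():
                    maxima.append((out.x_centers[i], out.y_centers[j]))
        assert len(maxima) == 2
        bin_w = out.x_centers[1] - out.x_centers[0]
        for (mx, my), (cx, cy) in zip(sorted(maxima), [(-5, -5), (5, 5)]):
            assert abs(mx - cx) <= bin_w and abs(my - cy) <= bin_w

    def test_free_energy_zero_at_mode_inf_at_empty(self, rng):
        proj = self._proj(rng.normal(size=(50, 2)))
        out = gd.landscape_density(proj, "histogram", bins=8)
        assert out.free_energy.min() == 0.0
        assert np.isinf(out.free_energy[out.density == 0]).all()

    def test_k_not_two_rejected_without_override(self, rng):
        from conftest import random_modeset
        proj = gd.ProjectionSet(rng.normal(size=(30, 3)),
                                random_modeset(rng, 12, 3))
        with pytest.raises(ShapeError):
            gd.landscape_density(proj)
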