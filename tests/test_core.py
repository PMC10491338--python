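"""Gaussian-mixture rendering, analytic projection and FRC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from gmmrefine import (GaussianMixture, Pose, FourierImage, render_volume,
                       project, frc, frc_loss, frc_loss_and_grad)
from gmmrefine.core import default_band, ring_indices


N, APIX = 64, 1.0


def _fft2c(img):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


class TestGaussianMixture:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GaussianMixture(np.zeros((1, 3)), [1.0], [0.0])      # width > 0
        with pytest.raises(ValueError):
            GaussianMixture(np.zeros((1, 3)), [-1.0], [1.0])     # amp >= 0
        with pytest.raises(ValueError):
            GaussianMixture(np.full((1, 3), np.nan), [1.0], [1.0])
        with pytest.raises(ValueError):
            GaussianMixture(np.zeros((0, 3)), [], [])            # N >= 1

    def test_text_serialization_roundtrip_bitexact(self, small_gmm, tmp_path):
        p = tmp_path / "g.txt"
        small_gmm.to_text(p)
        back = GaussianMixture.from_text(p)
        assert np.array_equal(back.centers, small_gmm.centers)
        assert np.array_equal(back.amplitudes, small_gmm.amplitudes)
        assert np.array_equal(back.widths, small_gmm.widths)


class TestPose:
    def test_rotation_orthonormal_det_one(self):
        R = Pose([33.0, 71.0, -12.0]).rotation_matrix()
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_compose_with_inverse_is_identity(self):
        p = Pose([20.0, 50.0, 110.0], [1.5, -2.0])
        ident = p.compose(p.inverse())
        assert np.allclose(ident.rotation_matrix(), np.eye(3), atol=1e-12)
        assert np.allclose(ident.shift, 0.0, atol=1e-12)

    def test_euler_matrix_roundtrip(self):
        eul = np.array([15.0, 80.0, 200.0])
        p = Pose.from_matrix(Pose(eul).rotation_matrix())
        assert np.allclose(Pose(p.euler).rotation_matrix(),
                           Pose(eul).rotation_matrix(), atol=1e-12)


class TestRenderVolume:
    def test_value_one_at_center_voxel(self):
        # Gaussian centered exactly on a voxel -> exponent zero there
        g = GaussianMixture([[2.0, -3.0, 5.0]], [1.0], [2.0])
        vol = render_volume(g, N, APIX)
        half = N // 2
        assert vol.data[half + 5, half - 3, half + 2] == pytest.approx(1.0)

    def test_integral_matches_analytic(self):
        # sum * apix^3 ~ (2 pi)^{3/2} sigma^3 for one unit Gaussian
        sigma = 2.0
        g = GaussianMixture([[0.0, 0.0, 0.0]], [1.0], [sigma])
        vol = render_volume(g, N, APIX)
        expected = (2 * np.pi) ** 1.5 * sigma ** 3
        assert vol.data.sum() * APIX ** 3 == pytest.approx(expected, rel=0.01)

    def test_linear_in_amplitudes(self):
        g1 = GaussianMixture([[1.0, 2.0, 3.0]], [1.0], [2.0])
        g2 = GaussianMixture([[1.0, 2.0, 3.0]] * 2, [1.0, 1.0], [2.0, 2.0])
        v1 = render_volume(g1, N, APIX).data
        v2 = render_volume(g2, N, APIX).data
        assert np.allclose(v2, 2 * v1, atol=1e-12)

    def test_center_outside_box_names_gaussian(self):
        g = GaussianMixture([[0, 0, 0], [500.0, 0, 0]], [1, 1], [2, 2])
        with pytest.raises(ValueError, match="Gaussian 1"):
            render_volume(g, N, APIX)


class TestProject:
    def test_identity_pose_centered_gaussian_is_real_circular(self):
        g = GaussianMixture([[0.0, 0.0, 0.0]], [1.0], [2.0])
        F = project(g, Pose([0, 0, 0]), N, APIX).data
        assert np.abs(F.imag).max() < 1e-9 * np.abs(F).max()
        assert F.real.min() > 0
        # circular symmetry: compare to transpose
        assert np.allclose(F, F.T, atol=1e-9 * np.abs(F).max())

    def test_projection_slice_theorem(self, small_gmm, rng):
        """Analytic projection equals the z-sum of the rendered volume."""
        for _ in range(5):
            pose = Pose(rng.uniform(0, 360, 3))
            R = pose.rotation_matrix()
            rotated = GaussianMixture(small_gmm.centers @ R.T,
                                      small_gmm.amplitudes, small_gmm.widths)
            dense = render_volume(rotated, N, APIX).data.sum(axis=0)
            analytic = project(small_gmm, pose, N, APIX).to_real()
            rel = np.abs(analytic - dense).max() / np.abs(dense).max()
            assert rel < 1e-3

    def test_shift_is_pure_phase_ramp(self, small_gmm):
        p0 = Pose([10, 20, 30])
        ps = Pose([10, 20, 30], [2.5, -1.25])
        F0 = project(small_gmm, p0, N, APIX).data
        Fs = project(small_gmm, ps, N, APIX).data
        assert np.abs(np.abs(Fs) - np.abs(F0)).max() < 1e-10 * np.abs(F0).max()

    def test_rotating_centers_equals_posing(self, small_gmm, rng):
        for _ in range(3):
            pose = Pose(rng.uniform(0, 360, 3))
            R = pose.rotation_matrix()
            rotated = GaussianMixture(small_gmm.centers @ R.T,
                                      small_gmm.amplitudes, small_gmm.widths)
            Fa = project(rotated, Pose([0, 0, 0]), N, APIX).data
            Fb = project(small_gmm, pose, N, APIX).data
            assert np.abs(Fa - Fb).max() < 1e-8 * np.abs(Fb).max()

    def test_linear_in_amplitudes(self, small_gmm):
        pose = Pose([12, 34, 56], [0.5, 0.5])
        doubled = GaussianMixture(small_gmm.centers, 2 * small_gmm.amplitudes,
                                  small_gmm.widths)
        Fa = project(doubled, pose, N, APIX).data
        Fb = project(small_gmm, pose, N, APIX).data
        assert np.allclose(Fa, 2 * Fb, rtol=1e-12)

    def test_degenerate_grid_errors(self, small_gmm):
        with pytest.raises(ValueError):
            project(small_gmm, Pose([0, 0, 0]), 1, APIX)


class TestFRC:
    def test_self_correlation_is_one(self, small_gmm):
        F = project(small_gmm, Pose([5, 10, 15]), N, APIX)
        rings = frc(F, F)
        assert np.allclose(rings.values[rings.valid], 1.0, atol=1e-12)

    def test_symmetric_and_bounded(self, small_gmm, rng):
        a = project(small_gmm, Pose(rng.uniform(0, 360, 3)), N, APIX)
        b = FourierImage(_fft2c(rng.normal(size=(N, N))), APIX)
        ab = frc(a, b)
        ba = frc(b, a)
        assert np.allclose(ab.values, ba.values)
        assert np.all(np.abs(ab.values) <= 1 + 1e-9)

    def test_insensitive_to_ringwise_gain(self, small_gmm, rng):
        """Multiplying one image by any positive ring-wise gain leaves the
        FRC unchanged — the normalization absorbs filtering."""
        a = project(small_gmm, Pose([5, 10, 15]), N, APIX)
        b = FourierImage(a.data + 0.3 * _fft2c(rng.normal(size=(N, N))), APIX)
        ridx, nrings = ring_indices(N)
        gain = rng.uniform(0.1, 5.0, nrings)
        gmap = np.where(ridx >= 0, gain[np.clip(ridx, 0, None)], 1.0)
        b_f = FourierImage(b.data * gmap, APIX)
        assert np.allclose(frc(a, b).values, frc(a, b_f).values, atol=1e-10)

    def test_white_noise_null_distribution(self):
        """|FRC| of independent noise stays below 3/sqrt(ring count) in at
        least 95% of rings (Monte-Carlo over 200 seeds)."""
        inside, total = 0, 0
        ridx, nrings = ring_indices(N)
        counts = np.bincount(ridx.ravel()[ridx.ravel() >= 0], minlength=nrings)
        for seed in range(200):
            r = np.random.default_rng(seed)
            a = FourierImage(_fft2c(r.normal(size=(N, N))), APIX)
            b = FourierImage(_fft2c(r.normal(size=(N, N))), APIX)
            v = frc(a, b)
            sel = (counts > 3) & v.valid
            inside += np.sum(np.abs(v.values[sel]) < 3.0 / np.sqrt(counts[sel]))
            total += sel.sum()
        assert inside / total >= 0.95

    def test_shape_mismatch_errors(self, small_gmm):
        a = project(small_gmm, Pose([0, 0, 0]), N, APIX)
        b = project(small_gmm, Pose([0, 0, 0]), N // 2, APIX)
        with pytest.raises(ValueError):
            frc(a, b)


class TestFRCLoss:
    def test_perfect_match_is_minus_one_and_local_minimum(self, small_gmm):
        pose = Pose([33, 44, 55], [0.5, -0.3])
        particle = project(small_gmm, pose, N, APIX)
        loss0 = frc_loss(small_gmm, pose, particle)
        assert loss0 == pytest.approx(-1.0, abs=1e-6)
        for d in ([2, 0, 0], [0, -2, 0], [0, 0, 2], [1.2, 1.2, -1.2]):
            perturbed = Pose(pose.euler + d, pose.shift)
            assert frc_loss(small_gmm, perturbed, particle) > loss0

    def test_invariant_to_ringwise_rescaling(self, small_gmm, rng):
        pose = Pose([33, 44, 55])
        particle = project(small_gmm, pose, N, APIX)
        ridx, nrings = ring_indices(N)
        gain = rng.uniform(0.2, 4.0, nrings)
        gmap = np.where(ridx >= 0, gain[np.clip(ridx, 0, None)], 1.0)
        filtered = FourierImage(particle.data * gmap, APIX)
        q = Pose([35, 42, 57], [0.4, 0.1])
        assert frc_loss(small_gmm, q, filtered) == pytest.approx(
            frc_loss(small_gmm, q, particle), abs=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, small_gmm, rng):
        """Pose, amplitude, width and center gradients vs central FD at 10
        random poses: relative error < 1e-4."""
        particle = project(small_gmm, Pose(rng.uniform(0, 360, 3),
                                           rng.normal(0, 1, 2)), N, APIX)
        eps = 1e-5
        for _ in range(10):
            pose = Pose(rng.uniform(0, 360, 3), rng.normal(0, 1, 2))
            _, gr = frc_loss_and_grad(small_gmm, pose, particle,
                                      want_gaussian_grads=True)

            def fd(fun):
                return (fun(eps) - fun(-eps)) / (2 * eps)

            for m in range(3):
                def f(e, m=m):
                    eul = pose.euler.copy()
                    eul[m] += e
                    return frc_loss(small_gmm, Pose(eul, pose.shift), particle)
                v = fd(f)
                assert abs(gr["euler"][m] - v) < 1e-4 * max(abs(v), 1e-6)
            for m in range(2):
                def f(e, m=m):
                    sh = pose.shift.copy()
                    sh[m] += e
                    return frc_loss(small_gmm, Pose(pose.euler, sh), particle)
                v = fd(f)
                assert abs(gr["shift"][m] - v) < 1e-4 * max(abs(v), 1e-6)
            j = 3
            for field, key in (("amplitudes", "amplitudes"), ("widths", "widths")):
                def f(e, field=field):
                    g2 = small_gmm.copy()
                    getattr(g2, field)[j] += e
                    return frc_loss(g2, pose, particle)
                v = fd(f)
                assert abs(gr[key][j] - v) < 1e-4 * max(abs(v), 1e-6)

    def test_empty_band_errors(self, small_gmm):
        particle = project(small_gmm, Pose([0, 0, 0]), N, APIX)
        with pytest.raises(ValueError):
            frc_loss(small_gmm, Pose([0, 0, 0]), particle, band=(5, 4))


@settings(max_examples=25, deadline=None)
@given(st.floats(0.5, 359.5), st.floats(0.5, 179.5), st.floats(0.5, 359.5))
def test_friedel_symmetry_of_projections(a, b, c):
    """Projections of a real structure obey conjugate (Friedel) symmetry."""
    g = GaussianMixture([[3.0, -2.0, 1.0], [-4.0, 5.0, 0.0]], [1.0, 0.7], [2.0, 2.5])
    F = project(g, Pose([a, b, c]), 32, 1.0).data
    flipped = np.conj(F[::-1, ::-1])
    # even-sized DC-centered grids: index 0 row/col has no Friedel partner
    assert np.allclose(F[1:, 1:], np.conj(F[1:, 1:][::-1, ::-1]), atol=1e-8)
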