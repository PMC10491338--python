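"""End-to-end behavior of the refinement loops: patch identities, focused
refinement on a moving domain, and conformation-to-pose conversion.

These tests run the full gold-standard machinery at a reduced scale (a few
hundred particles, small boxes, shortened GMM fits) — enough to expose the
qualitative behavior without long runtimes.
"""

import numpy as np
import pytest

from gmmrefine import (DensityMap, StandinDecoder, fsc, resolution_at,
                       composite, spherical_mask)
from gmmrefine.particles import EVEN, ODD
from gmmrefine.refine import run_global_refinement, RefinementAudit
from gmmrefine.focused import run_focused_refinement, run_patch_refinement
from gmmrefine.conf2pose import hetero_to_pose_pipeline
from gmmrefine.simulate import (SimSpec, simulate_particles, random_phantom,
                                simulate_conformal_particles, perturb_poses,
                                angular_error)
from gmmrefine.io import phase_flip_stack

FAST = dict(fit_epochs=10, n_projections=32)


@pytest.fixture(scope="module")
def rigid_run(phantom48):
    """200 rigid particles plus one global refinement iteration."""
    gmm, labels = phantom48
    spec = SimSpec(phantom=gmm, n_particles=200, n=48, apix=1.0, snr=0.3, seed=5)
    ps, te, ts = simulate_particles(spec)
    ps = phase_flip_stack(ps)
    pe, psh = perturb_poses(te, ts, 3.0, 0.5, np.random.default_rng(2))
    ps = ps.with_poses(pe, psh)
    st = run_global_refinement(ps.half_set(EVEN), ps.half_set(ODD),
                               n_gaussians=120, max_iterations=1, seed=31,
                               stop_on_convergence=False, **FAST)
    return gmm, labels, ps, st


class TestPatchIdentities:
    def test_k1_patch_equals_global_bitwise(self, rigid_run):
        """One patch covers everything, so patch refinement degenerates to
        global refinement: same seed, bit-equal poses."""
        gmm, labels, ps, st_global = rigid_run
        comp_e, comp_o, patches, states = run_patch_refinement(
            ps.half_set(EVEN), ps.half_set(ODD), st_global.gmms[EVEN],
            n_gaussians=120, k=1, iterations=1, seed=31,
            stop_on_convergence=False, **FAST)
        st_patch = states[0]
        for h in (EVEN, ODD):
            assert np.array_equal(st_patch.poses[h][0], st_global.poses[h][0])
            assert np.array_equal(st_patch.poses[h][1], st_global.poses[h][1])
        # composite of a single patch map is that map wherever covered
        covered = patches.masks[0].data > 0
        assert np.allclose(comp_e.data[covered],
                           st_patch.half_maps[EVEN].data[covered])

    def test_all_ones_mask_equals_global_bitwise(self, rigid_run):
        gmm, labels, ps, st_global = rigid_run
        ones = DensityMap(np.ones((48, 48, 48)), 1.0)
        st_ones = run_focused_refinement(ps.half_set(EVEN), ps.half_set(ODD),
                                         n_gaussians=120, iterations=1,
                                         mask=ones, seed=31,
                                         stop_on_convergence=False, **FAST)
        for h in (EVEN, ODD):
            assert np.array_equal(st_ones.poses[h][0], st_global.poses[h][0])
            assert np.array_equal(st_ones.poses[h][1], st_global.poses[h][1])

    def test_rigid_data_focused_within_one_shell_of_global(self, rigid_run):
        """On rigid data a focused mask neither helps nor hurts: the final
        resolutions agree within one Fourier shell."""
        gmm, labels, ps, st_global = rigid_run
        dom = gmm.centers[labels == 1]
        center = dom.mean(axis=0)
        radius = float(np.linalg.norm(dom - center, axis=1).max()) + 1.0
        mask = spherical_mask(48, 1.0, center, radius)
        st_foc = run_focused_refinement(ps.half_set(EVEN), ps.half_set(ODD),
                                        n_gaussians=120, iterations=1,
                                        mask=mask, seed=31,
                                        stop_on_convergence=False, **FAST)
        shell_g = 48.0 / st_global.resolutions[-1]
        shell_f = 48.0 / st_foc.resolutions[-1]
        assert abs(shell_g - shell_f) <= 1.0 + 1e-9


@pytest.fixture(scope="module")
def hinge_dataset():
    """600 particles of a two-domain structure whose second domain rocks
    +-12 deg about a hinge; per-particle latent = hinge fraction.

    The refinement mask (``bmask``) covers the whole moving domain; the
    *metric* masks are tighter spheres that do not overlap the other
    domain, so local FSC is not contaminated by what happens outside the
    region being scored.
    """
    gmm, labels = random_phantom(200, seed=3, n_domains=2, domain_radius=13,
                                 separation=15, width_range=(0.7, 1.0))
    region = labels == 1
    hinge_point = np.array([7.5, 0.0, 0.0])
    dec = StandinDecoder(gmm, region, hinge_point, np.array([0.0, 1.0, 0.0]),
                         max_angle=12.0)
    rng = np.random.default_rng(17)
    P = 600
    zs = rng.uniform(-1.0, 1.0, P)
    spec = SimSpec(phantom=gmm, n_particles=P, n=64, apix=1.0, snr=1.0, seed=23)
    ps, te, ts = simulate_conformal_particles(dec, zs, spec)
    ps = phase_flip_stack(ps)
    dom = gmm.centers[region]
    center = dom.mean(axis=0)
    radius = float(np.linalg.norm(dom - center, axis=1).max()) + 2.0
    bmask = spherical_mask(64, 1.0, center, radius)
    bmetric = spherical_mask(64, 1.0, center, 10.0)
    core_c = gmm.centers[~region].mean(axis=0)
    cmetric = spherical_mask(64, 1.0, core_c, 10.0)
    return dict(gmm=gmm, region=region, dec=dec, zs=zs, ps=ps, te=te, ts=ts,
                bmask=bmask, bmetric=bmetric, cmetric=cmetric)


@pytest.fixture(scope="module")
def hinge_global(hinge_dataset):
    d = hinge_dataset
    ps = d["ps"]
    return run_global_refinement(ps.half_set(EVEN), ps.half_set(ODD),
                                 n_gaussians=200, max_iterations=2, seed=41,
                                 stop_on_convergence=False, **FAST)


def _local_fsc_mean(st, mask, sl=slice(6, 26)):
    curve = fsc(st.half_maps[EVEN], st.half_maps[ODD], mask=mask.data)
    return float(curve.values[sl].mean())


class TestFocusedOnMovingDomain:
    def test_focused_improves_local_fsc_over_global(self, hinge_dataset,
                                                    hinge_global):
        """Width-mask focusing on the rocking domain improves its local FSC
        relative to global refinement at the same seed."""
        d = hinge_dataset
        ps = d["ps"]
        st_foc = run_focused_refinement(ps.half_set(EVEN), ps.half_set(ODD),
                                        n_gaussians=200, iterations=2,
                                        mask=d["bmask"], seed=41,
                                        stop_on_convergence=False, **FAST)
        got = _local_fsc_mean(st_foc, d["bmetric"])
        ref = _local_fsc_mean(hinge_global, d["bmetric"])
        assert got > ref


class TestHeteroToPose:
    def test_zero_motion_conversion_returns_input_poses(self, hinge_dataset):
        d = hinge_dataset
        ps = d["ps"]
        audit = RefinementAudit()
        st = hetero_to_pose_pipeline(
            ps.half_set(EVEN), ps.half_set(ODD),
            sources={h: StandinDecoder(d["gmm"], d["region"],
                                       np.array([7.5, 0.0, 0.0]),
                                       np.array([0.0, 1.0, 0.0]), 12.0, half=h)
                     for h in (EVEN, ODD)},
            latents={h: np.zeros(len(ps.half_set(h))) for h in (EVEN, ODD)},
            mask=d["region"], region_mask_volume=d["bmask"], n_gaussians=200,
            focused_iterations=0, seed=41, audit=audit)
        for h in (EVEN, ODD):
            sub = ps.half_set(h)
            assert np.max(angular_error(st.converted_poses[h][0], sub.eulers)) < 0.1
        assert audit.cross_pairings == []

    def test_pipeline_improves_moving_domain_hurts_core(self, hinge_dataset,
                                                        hinge_global):
        """Converting true conformations to poses immobilizes the rocking
        domain (better local FSC) while the formerly rigid core now moves
        in the new frame (its local FSC does not improve)."""
        d = hinge_dataset
        ps = d["ps"]
        sources = {h: StandinDecoder(d["gmm"], d["region"],
                                     np.array([7.5, 0.0, 0.0]),
                                     np.array([0.0, 1.0, 0.0]), 12.0, half=h)
                   for h in (EVEN, ODD)}
        half = np.asarray(ps.half)
        latents = {h: d["zs"][half == h] for h in (EVEN, ODD)}
        st = hetero_to_pose_pipeline(ps.half_set(EVEN), ps.half_set(ODD),
                                     sources, latents, d["region"], d["bmask"],
                                     n_gaussians=200, focused_iterations=2,
                                     seed=41, stop_on_convergence=False, **FAST)
        got_b = _local_fsc_mean(st, d["bmetric"])
        ref_b = _local_fsc_mean(hinge_global, d["bmetric"])
        assert got_b > ref_b
        got_core = _local_fsc_mean(st, d["cmetric"])
        ref_core = _local_fsc_mean(hinge_global, d["cmetric"])
        assert got_core < ref_core + 0.02  # core does not improve

    def test_wrong_half_decoder_rejected(self, hinge_dataset):
        d = hinge_dataset
        ps = d["ps"]
        bad = {h: StandinDecoder(d["gmm"], d["region"], np.array([7.5, 0, 0]),
                                 np.array([0.0, 1.0, 0.0]), 12.0,
                                 half=1 - h)  # swapped!
               for h in (EVEN, ODD)}
        with pytest.raises(ValueError, match="gold-standard"):
            hetero_to_pose_pipeline(ps.half_set(EVEN), ps.half_set(ODD), bad,
                                    {h: np.zeros(len(ps.half_set(h)))
                                     for h in (EVEN, ODD)},
                                    d["region"], d["bmask"], n_gaussians=50,
                                    focused_iterations=0, seed=1)
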