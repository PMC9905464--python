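import numpy as np
import pytest

from mocospect.acquisition import (
    AcquisitionSpec,
    ProjectionSet,
    acquire_listmode,
    bin_all,
    bin_listmode,
    expected_phase_projections,
)
from mocospect.grid import Grid
from mocospect.phantom import PhantomSpec, TumorSpec, generate_phase_set
from mocospect.projector import Projector, PSFModel
from mocospect.recon import (
    IDENTITY_AFFINE,
    ReconConfig,
    correct_listmode,
    dew_scatter_estimate,
    osem,
    poisson_log_likelihood,
    reconstruct_3d,
    reconstruct_3dcomp,
    reconstruct_gated_4d,
    register_phases_2d_affine,
    register_projection_pair,
)


def _noiseless_projset(projector, activity, mu, acq):
    n = len(projector.angles_deg)
    prim = np.stack(
        [
            projector.forward(activity, a, projector.attenuation_factors(mu, a))
            for a in range(n)
        ]
    )
    return ProjectionSet(prim, np.zeros_like(prim), projector.angles_deg, acq)


class TestDEW:
    def test_zero_scatter_window(self):
        est = dew_scatter_estimate(np.zeros((3, 4, 4)), 28.1, 12.0)
        assert np.all(est == 0)

    def test_default_k_value(self):
        est = dew_scatter_estimate(np.ones((1, 2, 2)), 28.1, 12.0)
        assert est[0, 0, 0] == pytest.approx(28.1 / 12.0 / 2.0)
        assert est[0, 0, 0] == pytest.approx(1.1708, abs=1e-3)

    def test_clip_at_primary(self):
        est = dew_scatter_estimate(
            np.full((1, 2, 2), 10.0), 28.1, 12.0, primary_counts=np.full((1, 2, 2), 3.0)
        )
        assert np.all(est == 3.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            dew_scatter_estimate(np.ones((1, 2, 2)), 0.0, 12.0)

    def test_dew_improves_primary_estimate(self):
        # simulator ground truth: corrected counts closer to geometric truth
        spec = PhantomSpec(grid_shape=(24, 24, 24), spacing_mm=(8.0,) * 3)
        ph = generate_phase_set(spec, 1)
        acq = AcquisitionSpec(n_projections=4)
        prj = acq.projector(ph.grid)
        prim, scat = expected_phase_projections(ph, acq, prj)
        geo = np.stack(
            [
                prj.forward(ph.phases[0].activity, a,
                            prj.attenuation_factors(ph.phases[0].attenuation, a))
                for a in range(4)
            ]
        )
        est = dew_scatter_estimate(scat[0], acq.primary_window.width_kev,
                                   acq.scatter_window.width_kev)
        err_corrected = np.abs((prim[0] - est) - geo).sum()
        err_raw = np.abs(prim[0] - geo).sum()
        assert err_corrected < err_raw


@pytest.fixture(scope="module")
def point_case():
    g = Grid((32, 32, 32), (6.0, 6.0, 6.0))
    acq = AcquisitionSpec(n_projections=12)
    pr = Projector(g, acq.angles_deg, PSFModel())
    act = np.zeros(g.shape)
    act[16, 14, 18] = 100.0
    mu = np.full(g.shape, 0.01)
    return g, pr, act, mu, acq


class TestOSEM:
    def test_all_zero_projections_fixed_point(self, point_case):
        g, pr, act, mu, acq = point_case
        projs = ProjectionSet(
            np.zeros((12,) + pr.detector_shape), np.zeros((12,) + pr.detector_shape),
            pr.angles_deg, acq,
        )
        img = osem(projs, mu, pr, ReconConfig(4, 3))
        assert np.all(img.values == 0)

    def test_noiseless_point_source_recovery(self, point_case):
        g, pr, act, mu, acq = point_case
        projs = _noiseless_projset(pr, act, mu, acq)
        img = osem(projs, mu, pr, ReconConfig(1, 60))
        # centroid within half a voxel, totals within a few percent
        from scipy import ndimage

        c = ndimage.center_of_mass(img.values)
        assert np.allclose(c, (16, 14, 18), atol=0.5)
        assert img.values.sum() == pytest.approx(act.sum(), rel=0.02)

    def test_mlem_likelihood_nondecreasing(self, point_case, rng):
        g, pr, act, mu, acq = point_case
        smooth = np.zeros(g.shape)
        smooth[10:22, 10:22, 10:22] = 5.0
        projs = _noiseless_projset(pr, smooth, mu, acq)
        noisy = ProjectionSet(
            rng.poisson(projs.primary).astype(float),
            np.zeros_like(projs.primary), pr.angles_deg, acq,
        )
        lls = []
        for it in (1, 3, 6, 10, 15, 20):
            img = osem(noisy, mu, pr, ReconConfig(1, it))
            lls.append(poisson_log_likelihood(img.values, noisy, mu, pr))
        assert np.all(np.diff(lls) >= -1e-6 * np.abs(lls[0]))

    def test_nonnegative_finite(self, point_case, rng):
        g, pr, act, mu, acq = point_case
        projs = _noiseless_projset(pr, act, mu, acq)
        noisy = ProjectionSet(
            rng.poisson(projs.primary * 5).astype(float),
            np.zeros_like(projs.primary), pr.angles_deg, acq,
        )
        img = osem(noisy, mu, pr, ReconConfig(4, 4))
        assert np.all(img.values >= 0)
        assert np.all(np.isfinite(img.values))


@pytest.fixture(scope="module")
def static_lm():
    spec = PhantomSpec(grid_shape=(24, 24, 24), spacing_mm=(8.0,) * 3,
                       motion_amplitude_mm=(0, 0, 0))
    ph = generate_phase_set(spec, 8)
    acq = AcquisitionSpec(n_projections=8)
    prj = acq.projector(ph.grid)
    prim, scat = expected_phase_projections(ph, acq, prj)
    dwell = acq.time_per_projection_s / 8
    scale = 2e6 / ((prim.sum() + scat.sum()) * dwell)
    lm = acquire_listmode(ph, acq, seed=5, projector=prj,
                          expected=(prim * scale, scat * scale))
    return ph, acq, prj, lm


class TestGated:
    def test_zero_motion_phase_images_agree(self, static_lm):
        ph, acq, prj, lm = static_lm
        imgs = reconstruct_gated_4d(lm, lm.true_phase.astype(int),
                                    ph.phases[0].attenuation, prj, ReconConfig(4, 3))
        liver = ph.phases[0].labels >= 2
        means = [img.values[liver].mean() for img in imgs]
        assert np.std(means) / np.mean(means) < 0.05

    def test_gated_noise_scales_with_phase_count(self, static_lm):
        ph, acq, prj, lm = static_lm
        cfgr = ReconConfig(4, 6)
        gated = reconstruct_gated_4d(lm, lm.true_phase.astype(int),
                                     ph.phases[0].attenuation, prj, cfgr)
        # zero motion: the 8 gated images are independent replicates; their
        # voxelwise variance estimates the gated noise level.  Two split-half
        # 3D reconstructions estimate the full-count noise at 1/2 counts.
        liver = (ph.phases[0].labels == 2)
        stack = np.stack([g.values for g in gated])
        relvar_gated = stack.var(axis=0, ddof=1)[liver].mean() / stack[:, liver].mean() ** 2
        labels2 = (lm.true_phase.astype(int) % 2)
        halves = reconstruct_gated_4d(lm, labels2, ph.phases[0].attenuation, prj, cfgr)
        var_half = 0.5 * ((halves[0].values - halves[1].values) ** 2)[liver].mean()
        relvar_half = var_half / halves[0].values[liver].mean() ** 2
        # relative variance at 1/8 counts vs 1/2 counts ~ 4 under Poisson
        ratio = relvar_gated / relvar_half
        assert ratio == pytest.approx(4.0, rel=0.35)

    def test_empty_phase_zero_image(self, static_lm):
        ph, acq, prj, lm = static_lm
        labels = np.zeros(len(lm), dtype=int)
        labels[0] = 2  # phase 1 has no events
        with pytest.warns(UserWarning):
            imgs = reconstruct_gated_4d(lm, labels, ph.phases[0].attenuation, prj,
                                        ReconConfig(2, 1))
        assert len(imgs) == 3
        assert np.all(imgs[1].values == 0)


class TestRegistration:
    def test_self_registration_identity(self, rng):
        img = rng.uniform(size=(32, 32)) + 5.0
        p = register_projection_pair(img, img)
        np.testing.assert_allclose(p, IDENTITY_AFFINE, atol=0.05)

    @pytest.mark.parametrize("shift_bins", [1.0, 2.0, 3.0])
    def test_known_shift_recovered(self, shift_bins):
        from scipy import ndimage

        base = np.zeros((48, 48))
        base[18:30, 20:34] = 1.0
        base = ndimage.gaussian_filter(base, 2.0)
        moved = ndimage.shift(base, (0.0, shift_bins), order=1)
        p = register_projection_pair(moved, base)
        # affine_transform offset convention: recovered offset ~ +shift
        assert p[5] == pytest.approx(shift_bins, abs=0.5)

    def test_reference_rows_identity(self, rng):
        acq = AcquisitionSpec(n_projections=3)
        prim = rng.poisson(50, size=(2, 3, 16, 16)).astype(float)
        gated = [
            ProjectionSet(prim[i], np.zeros_like(prim[i]), acq.angles_deg, acq)
            for i in range(2)
        ]
        tr = register_phases_2d_affine(gated, reference=1)
        np.testing.assert_array_equal(tr[1], np.tile(IDENTITY_AFFINE, (3, 1)))


@pytest.fixture(scope="module")
def moving_case():
    spec = PhantomSpec(grid_shape=(32, 32, 32), spacing_mm=(6.0,) * 3,
                       tumors=[TumorSpec((-12, 0, -32), 15.0, 4.0)],
                       motion_amplitude_mm=(0, 0, 12.0))
    ph = generate_phase_set(spec, 4)
    acq = AcquisitionSpec(n_projections=12)
    prj = acq.projector(ph.grid)
    prim, scat = expected_phase_projections(ph, acq, prj)
    dwell = acq.time_per_projection_s / 4
    scale = 1.2e6 / ((prim.sum() + scat.sum()) * dwell)
    lm = acquire_listmode(ph, acq, seed=9, projector=prj,
                          expected=(prim * scale, scat * scale))
    return ph, acq, prj, lm


class TestMotionCompensated:
    def test_event_count_bookkeeping(self, moving_case):
        ph, acq, prj, lm = moving_case
        labels = lm.true_phase.astype(int)
        gated = bin_listmode(lm, labels, 4)
        tr = register_phases_2d_affine(gated, 0)
        projs, dropped = correct_listmode(lm, labels, tr)
        total = projs.primary.sum() + projs.scatter.sum()
        assert total + dropped == pytest.approx(len(lm), rel=1e-6)

    def test_3dcomp_improves_tumor_recovery(self, moving_case):
        ph, acq, prj, lm = moving_case
        labels = lm.true_phase.astype(int)
        cfgr = ReconConfig(6, 5)
        mu = ph.phases[0].attenuation
        img3d = reconstruct_3d(lm, mu, prj, cfgr)
        imgc = reconstruct_3dcomp(lm, labels, 0, mu, prj, cfgr)
        tumor = ph.phases[0].labels == 4
        truth = ph.phases[0].activity

        def recovery(img):
            return (img.values[tumor].mean() / img.values.sum()) / (
                truth[tumor].mean() / truth.sum()
            )

        assert recovery(imgc) > recovery(img3d)

    def test_zero_motion_3dcomp_matches_3d(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), spacing_mm=(8.0,) * 3,
                           motion_amplitude_mm=(0, 0, 0))
        ph = generate_phase_set(spec, 4)
        acq = AcquisitionSpec(n_projections=8)
        prj = acq.projector(ph.grid)
        prim, scat = expected_phase_projections(ph, acq, prj)
        dwell = acq.time_per_projection_s / 4
        scale = 1e6 / ((prim.sum() + scat.sum()) * dwell)
        lm = acquire_listmode(ph, acq, seed=4, projector=prj,
                              expected=(prim * scale, scat * scale))
        cfgr = ReconConfig(4, 4)
        mu = ph.phases[0].attenuation
        img3d = reconstruct_3d(lm, mu, prj, cfgr)
        imgc = reconstruct_3dcomp(lm, lm.true_phase.astype(int), 0, mu, prj, cfgr)
        liver = ph.phases[0].labels == 2
        m3, mc = img3d.values[liver].mean(), imgc.values[liver].mean()
        assert abs(mc - m3) / m3 < 0.02
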