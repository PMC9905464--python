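import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage, stats

from mocospect import metrics as m

finite = st.floats(min_value=0.1, max_value=1e6, allow_nan=False)


class TestFormulas:
    def test_pdd_examples(self):
        assert m.pdd(105.0, 100.0) == pytest.approx(5.0)
        assert m.pdd(50.0, 50.0) == 0.0
        # lung doses halved by compensation: (4 - 8)/8
        assert m.pdd(4.0, 8.0) == pytest.approx(-50.0)
        with pytest.raises(ValueError):
            m.pdd(1.0, 0.0)

    def test_lsf_examples(self):
        assert m.lsf(5.0, 95.0) == pytest.approx(5.0)
        assert m.lsf(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            m.lsf(0.0, 0.0)

    def test_tn_examples(self):
        assert m.tn_ratio(10.0, 5.0, 20.0, 10.0) == pytest.approx(1.0)
        assert m.tn_ratio(80.0, 10.0, 200.0, 100.0) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            m.tn_ratio(1.0, 0.0, 1.0, 1.0)

    def test_pda_worked_example(self):
        # largest printed discrepancy: 1.28 vs 1.57 GBq
        assert abs(m.pda(1.57, 1.28)) == pytest.approx(22.66, abs=0.01)
        assert m.pda(2.0, 2.0) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(a=finite, b=finite)
    def test_pdd_pda_machine_precision(self, a, b):
        assert m.pdd(a, b) == (a - b) / b * 100.0
        assert m.pda(a, b) == (a - b) / b * 100.0

    @settings(max_examples=200, deadline=None)
    @given(cl=finite, cli=finite)
    def test_lsf_bounds(self, cl, cli):
        v = m.lsf(cl, cli)
        assert 0.0 <= v <= 100.0

    @settings(max_examples=100, deadline=None)
    @given(c=finite, v=finite, c2=finite, v2=finite)
    def test_tn_positive_and_uniform_unity(self, c, v, c2, v2):
        assert m.tn_ratio(c, v, c2, v2) > 0
        assert m.tn_ratio(3 * v, v, 3 * v2, v2) == pytest.approx(1.0)

    def test_pve_threshold_volume(self):
        assert m.pve_threshold_volume_ml(7.4, 2.5) == pytest.approx(3.3, abs=0.05)


class TestBlandAltman:
    def test_identical_series(self):
        ba = m.bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert ba.mean_diff == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_constant_offset(self):
        a = np.array([2.0, 3.0, 4.0])
        ba = m.bland_altman(a + 1, a)
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.loa_high - ba.loa_low == pytest.approx(0.0)

    def test_limits_match_brute_force(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        ba = m.bland_altman(a, b)
        d = a - b
        assert ba.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            m.bland_altman([1.0, 2.0], [1.0])


@pytest.fixture(scope="module")
def liver_image():
    shape = (32, 32, 32)
    spacing = (4.418, 4.418, 4.418)
    x, y, z = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                          indexing="ij")
    c = np.array([16, 16, 16]) * 4.418
    img = np.exp(-(((x - c[0]) / 30) ** 2 + ((y - c[1]) / 22) ** 2
                   + ((z - c[2]) / 25) ** 2))
    img += 0.3 * np.exp(-(((x - c[0] - 15) / 10) ** 2 + ((y - c[1]) / 10) ** 2
                          + ((z - c[2] + 12) / 10) ** 2))
    mask = img > 0.3
    return img, mask, spacing


class TestAmplitude:

    def test_identical_images_zero(self, liver_image):
        img, mask, spacing = liver_image
        assert m.estimate_amplitude(img, img, mask, spacing) == pytest.approx(
            0.0, abs=0.5
        )

    def test_known_shift_recovered(self, liver_image):
        img, mask, spacing = liver_image
        shift_mm = np.array([0.0, 0.0, 10.0])
        moved = ndimage.shift(img, shift_mm / np.asarray(spacing), order=1)
        est = m.estimate_amplitude(img, moved, mask, spacing)
        assert est == pytest.approx(10.0, abs=spacing[2] / 2)

    def test_tiny_mask_not_estimable(self, liver_image):
        img, _, spacing = liver_image
        mask = np.zeros(img.shape, bool)
        mask[2, 2, 2] = True
        with pytest.raises(m.AmplitudeNotEstimable):
            m.estimate_amplitude(img, img, mask, spacing)


class TestTumorFeatures:
    def _sphere(self, shape, center, r, spacing=1.0):
        idx = np.indices(shape).astype(float) * spacing
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        return d2 <= r**2

    def test_lesion_equals_liver_degenerate(self):
        liver = self._sphere((40, 40, 40), (20, 20, 20), 15)
        f = m.tumor_features(liver, liver, (1.0, 1.0, 1.0))
        assert f["min_border_dist_mm"] == 0.0
        assert f["mean_border_dist_mm"] > 0.0  # interior voxels are off-border
        assert f["cc_top_gap_mm"] == 0.0

    def test_centered_spheres_com_distance(self):
        # 10 mm lesion centered in a 30 mm liver, 1 mm voxels: the lesion
        # center of mass sits 30 mm from the liver border
        liver = self._sphere((70, 70, 70), (35, 35, 35), 30)
        lesion = self._sphere((70, 70, 70), (35, 35, 35), 10)
        f = m.tumor_features(lesion, liver, (1.0, 1.0, 1.0))
        assert f["com_border_dist_mm"] == pytest.approx(30.0, abs=1.5)
        assert f["com_border_dist_cc_mm"] == pytest.approx(30.0, abs=1.5)
        assert f["min_border_dist_mm"] == pytest.approx(20.0, abs=1.5)

    def test_volume_and_normalization(self):
        liver = self._sphere((40, 40, 40), (20, 20, 20), 18)
        lesion = self._sphere((40, 40, 40), (20, 20, 20), 6)
        f = m.tumor_features(lesion, liver, (1.0, 1.0, 1.0), cc_amplitude_mm=9.0)
        vol = f["volume_ml"]
        assert vol == pytest.approx(4 / 3 * np.pi * 6**3 / 1000, rel=0.1)
        assert f["cc_amplitude_mm"] == 9.0
        assert f["cc_amplitude_mm_per_ml"] == pytest.approx(9.0 / vol)

    def test_outside_liver_warns(self):
        liver = self._sphere((30, 30, 30), (10, 15, 15), 8)
        lesion = self._sphere((30, 30, 30), (22, 15, 15), 4)
        with pytest.warns(UserWarning):
            m.tumor_features(lesion, liver, (1.0, 1.0, 1.0))


class TestStatsSuite:
    def test_self_comparison(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = m.paired_test(a, a.copy())
        assert rep.p_value == pytest.approx(1.0)
        assert rep.mean_diff == 0.0

    def test_normal_pairs_take_t_branch(self):
        # with a clear normal sample, Shapiro should pass both series
        rng = np.random.default_rng(0)
        chosen = []
        for _ in range(20):
            a = rng.normal(0, 1, 30)
            b = a + 1.0 + rng.normal(0, 1, 30)
            chosen.append(m.paired_test(a, b).branch == "paired-t")
        assert np.mean(chosen) >= 0.8

    def test_power_matches_noncentral_t(self):
        # delta=1, sd=1, n=30 paired t: power oracle from the noncentral t
        n, delta, sd = 30, 1.0, 1.0
        rng = np.random.default_rng(42)
        rejections = 0
        trials = 300
        for _ in range(trials):
            d = rng.normal(delta, sd, n)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            if abs(t) > stats.t.ppf(0.975, n - 1):
                rejections += 1
        nc = delta / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        assert rejections / trials == pytest.approx(power, abs=0.05)

    def test_skewed_pairs_take_wilcoxon(self):
        rng = np.random.default_rng(3)
        a = rng.exponential(1.0, 50) ** 3
        b = a + rng.exponential(0.5, 50) ** 3
        rep = m.paired_test(a, b)
        assert rep.branch == "wilcoxon"

    def test_constant_series_forces_wilcoxon(self):
        a = np.array([1.0, 1.0, 1.0, 1.0])
        b = np.array([1.0, 2.0, 0.5, 1.5])
        rep = m.paired_test(a, b)
        assert rep.forced_branch
        assert rep.branch == "wilcoxon"

    def test_spearman_monotone_exact(self):
        x = np.linspace(-2, 2, 20)
        out = m.spearman_screen(x**3, {"x": x})
        assert out["x"][0] == pytest.approx(1.0)

    def test_stats_suite_report_shape(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(size=20)
        rep = m.stats_suite(a, b, features={"f": rng.normal(size=20)})
        assert {"branch", "p_value", "spearman"} <= set(rep)
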