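"""Tests for the synthetic perfusion/LGE phantom generators."""

import dataclasses

import numpy as np
import pytest

import fermiperf as fp
from fermiperf.phantom import (
    generate_lge_image,
    phantom_truth,
    scar_masks,
    slice_contours,
)


class TestAif:
    def test_peak_location_and_value(self):
        spec = fp.AifSpec(amplitude=1, t0=5, alpha=2, beta=3)
        curve = fp.generate_aif(spec, 3000, 0.01)
        # gamma-variate maximum at t0 + alpha*beta with value alpha^alpha e^-alpha
        assert curve.times[np.argmax(curve.values)] == pytest.approx(11.0, abs=0.01)
        assert curve.values.max() == pytest.approx(4 * np.exp(-2), rel=1e-3)

    def test_zero_before_onset(self):
        spec = fp.AifSpec(t0=5.0)
        curve = fp.generate_aif(spec, 60, 1.0)
        assert np.all(curve.values[curve.times <= 5.0] == 0.0)
        assert np.all(curve.values >= 0) and np.all(np.isfinite(curve.values))

    @pytest.mark.parametrize("bad", [dict(alpha=-1), dict(beta=0), dict(amplitude=0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            fp.AifSpec(**bad)

    def test_invalid_sampling(self):
        with pytest.raises(ValueError):
            fp.generate_aif(fp.AifSpec(), 1, 1.0)
        with pytest.raises(ValueError):
            fp.generate_aif(fp.AifSpec(), 60, 0.0)


class TestTissueCurve:
    def test_zero_aif_gives_zero_tissue(self):
        aif = fp.Curve(times=np.arange(30.0), values=np.zeros(30))
        out = fp.generate_tissue_curve(aif, fp.FermiParams(1, 0.3, 5), 1.0)
        assert np.all(out.values == 0)

    def test_sampling_mismatch_rejected(self):
        aif = fp.Curve(times=np.arange(30.0) * 0.5, values=np.ones(30))
        with pytest.raises(ValueError):
            fp.generate_tissue_curve(aif, fp.FermiParams(1, 0.3, 5), 1.0)


class TestPerfusionSeries:
    def test_determinism(self, small_spec):
        a, _, _ = fp.generate_perfusion_series(small_spec, "stress")
        b, _, _ = fp.generate_perfusion_series(small_spec, "stress")
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.frames, sb.frames)

    def test_states_distinct_noise(self):
        spec = fp.PhantomSpec(
            shape=(32, 32), pixel_spacing_mm=2.4, slice_labels=("mid",),
            endo_radii_mm=(14.0,), epi_radii_mm=(22.0,), n_frames=30,
            noise_sigma=0.5, seed=1,
        )
        s, _, _ = fp.generate_perfusion_series(spec, "stress")
        r, _, _ = fp.generate_perfusion_series(spec, "rest")
        assert not np.array_equal(s[0].frames, r[0].frames)

    def test_uniform_mpr_truth(self):
        spec = fp.PhantomSpec(rest_mbf=1.0, stress_mbf=2.0)
        truth = phantom_truth(spec)
        for mpr, c in zip(truth.mpr, truth.contours):
            ann = c.annulus_mask(spec.shape)
            np.testing.assert_allclose(mpr[ann], 2.0)

    def test_noiseless_round_trip_small(self, small_spec):
        series, aif, truth = fp.generate_perfusion_series(small_spec, "rest")
        ann = truth.contours[0].annulus_mask(small_spec.shape)
        m = fp.quantify_pixelwise(
            series[0], ann, aif, dose_ratio=small_spec.aif.dose_ratio
        )
        assert m.tau_d == small_spec.tau_d
        rel = np.abs(m.values[m.valid] - truth.mbf_rest[0][m.valid])
        rel /= truth.mbf_rest[0][m.valid]
        assert m.valid.sum() == ann.sum()
        assert rel.max() <= 1e-3

    def test_blood_pool_carries_full_dose_aif(self, small_spec):
        series, aif, truth = fp.generate_perfusion_series(small_spec, "rest")
        blood = truth.contours[0].endo_mask(small_spec.shape)
        # erode to avoid contour-boundary pixels
        inner = np.nonzero(blood)
        r, c = inner[0][len(inner[0]) // 2], inner[1][len(inner[1]) // 2]
        expected = small_spec.baseline + aif.values * small_spec.aif.dose_ratio
        np.testing.assert_allclose(series[0].frames[:, r, c], expected, atol=1e-9)

    def test_scar_outside_annulus_rejected(self):
        spec = fp.PhantomSpec()
        bad = np.zeros(spec.shape, bool)
        bad[0, 0] = True  # far outside the annulus
        contours = slice_contours(spec)[0]
        annulus = contours.annulus_mask(spec.shape)
        assert not (bad <= annulus).all()  # sanity: mask really is outside
        field = np.full(spec.shape, np.nan)
        field[annulus] = 1.0
        field[0, 0] = -1.0  # invalid value outside annulus is fine though
        # direct invariant check through the truth constructor with override
        with pytest.raises(ValueError):
            spec2 = dataclasses.replace(
                spec, stress_mbf_fields=(np.full(spec.shape, -1.0),) * 3
            )
            phantom_truth(spec2)

    @pytest.mark.parametrize(
        "bad",
        [dict(n_frames=10), dict(dt=0.0), dict(rest_mbf=-1.0),
         dict(endo_radii_mm=(30.0, 16.0, 12.0)), dict(jitter_px=-1)],
    )
    def test_spec_invariants(self, bad):
        with pytest.raises(ValueError):
            fp.PhantomSpec(**bad)


class TestLge:
    def _scar_spec(self, **kw):
        return fp.PhantomSpec(
            scar=fp.ScarSpec(angle_start=0.5, angle_width=1.0, **kw), seed=3
        )

    def test_scar_means_exceed_six_sd(self):
        spec = self._scar_spec(lge_offset_sd=10.0)
        img, _ = generate_lge_image(spec, 0, at_means=True)
        truth = scar_masks(spec)[0]
        thr = spec.lge_remote_mean + 6 * spec.lge_remote_sd
        assert np.all(img.image[truth] > thr)
        # offset 10, sd 10, mean 100 -> scar pixels at exactly 200
        np.testing.assert_allclose(img.image[truth], 200.0)

    def test_no_scar_segments_empty(self):
        spec = fp.PhantomSpec(seed=5)
        img, _ = generate_lge_image(spec, 0, at_means=True)
        assert fp.segment_scar(img).n_pixels == 0

    def test_remote_roi_disjoint_from_scar(self):
        spec = self._scar_spec()
        img, remote = generate_lge_image(spec, 0)
        assert remote.any()
        assert not (remote & scar_masks(spec)[0]).any()

    def test_invalid_offset(self):
        with pytest.raises(ValueError):
            fp.ScarSpec(lge_offset_sd=0.0)

    def test_determinism(self):
        spec = self._scar_spec()
        a, _ = generate_lge_image(spec, 0)
        b, _ = generate_lge_image(spec, 0)
        np.testing.assert_array_equal(a.image, b.image)


class TestCohort:
    def test_prevalence_rounding(self):
        specs = fp.generate_cohort(30, 0.7, seed=1)
        n_scar = sum(s.scar is not None for s in specs)
        assert n_scar == 21

    def test_zero_prevalence(self):
        specs = fp.generate_cohort(10, 0.0, seed=2)
        assert all(s.scar is None for s in specs)

    def test_determinism(self):
        a = fp.generate_cohort(12, 0.5, seed=9)
        b = fp.generate_cohort(12, 0.5, seed=9)
        assert a == b

    def test_scar_subjects_have_depressed_scar_mpr(self):
        specs = fp.generate_cohort(10, 1.0, seed=4)
        for s in specs:
            assert s.scar is not None
            assert s.scar.stress_mbf < s.rest_mbf  # scar MPR < 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fp.generate_cohort(0, 0.5)
        with pytest.raises(ValueError):
            fp.generate_cohort(5, 1.5)
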