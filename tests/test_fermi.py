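"""Unit and property tests for the Fermi impulse response and deconvolution."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

import fermiperf as fp
from fermiperf.fermi import DEFAULT_BOUNDS, FermiDeconvolution, fermi_model_curve

from conftest import conv_double_sum

params_st = st.builds(
    fp.FermiParams,
    R=st.floats(0.1, 50),
    k=st.floats(0.01, 5),
    tau0=st.floats(0.0, 30),
    tau_d=st.floats(0.0, 10),
)


class TestImpulseResponse:
    def test_printed_formula_value(self):
        # R=2, k=1, tau0=3, tau_d=0 at t=0: 2 / (exp(-3) + 1)
        p = fp.FermiParams(R=2, k=1, tau0=3, tau_d=0)
        expected = 2.0 / (np.exp(-3.0) + 1.0)  # = 1.9051482536448664
        assert fp.fermi_impulse_response(p, 0.0) == pytest.approx(
            expected, rel=1e-12
        )

    @given(params_st)
    def test_midpoint_is_half_amplitude(self, p):
        assert fp.fermi_impulse_response(p, p.tau0 + p.tau_d) == pytest.approx(
            p.R / 2, rel=1e-12
        )

    @given(params_st, st.floats(0.01, 10))
    def test_zero_before_delay(self, p, eps):
        if p.tau_d > 0:
            t = max(p.tau_d - eps, 0.0)
            if t < p.tau_d:
                assert fp.fermi_impulse_response(p, t) == 0.0

    @given(params_st)
    def test_non_increasing_and_bounded_after_delay(self, p):
        t = np.linspace(p.tau_d, p.tau_d + 120, 400)
        h = fp.fermi_impulse_response(p, t)
        assert np.all(np.diff(h) <= 1e-12)
        assert np.all(h > 0) and np.all(h <= p.R)

    def test_plateau_limit_mbf_tends_to_R(self):
        # as k*tau0 grows with tau_d = 0, h(0) -> R
        p = fp.FermiParams(R=3.7, k=5.0, tau0=40.0, tau_d=0.0)
        assert p.mbf == pytest.approx(3.7, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs", [dict(R=-1, k=1, tau0=1), dict(R=1, k=0, tau0=1),
                   dict(R=1, k=1, tau0=-2), dict(R=1, k=1, tau0=1, tau_d=-1)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fp.FermiParams(**kwargs)


class TestConvolution:
    def test_matches_double_sum_oracle(self, aif_curve):
        p = fp.FermiParams(R=2, k=0.3, tau0=5, tau_d=2)
        dt = 1.0
        h = fp.fermi_impulse_response(p, np.arange(60) * dt)
        expected = conv_double_sum(aif_curve.values, h, dt)
        got = fermi_model_curve(aif_curve.values, p, dt)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-14)

    def test_unit_impulse_returns_impulse_response(self):
        dt = 0.8
        n = 50
        aif = np.zeros(n)
        aif[0] = 1.0 / dt
        p = fp.FermiParams(R=1.5, k=0.2, tau0=4, tau_d=1.6)
        got = fermi_model_curve(aif, p, dt)
        expected = fp.fermi_impulse_response(p, np.arange(n) * dt)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_zero_aif_gives_zero_tissue(self):
        p = fp.FermiParams(R=1, k=0.3, tau0=5)
        assert np.all(fermi_model_curve(np.zeros(30), p, 1.0) == 0.0)


class TestFit:
    def test_noiseless_recovery(self, aif_curve):
        true = fp.FermiParams(R=2.0, k=0.3, tau0=5.0, tau_d=0.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        res = fp.fit_fermi(aif_curve.values, tissue, 1.0, tau_d=0.0)
        assert res.valid
        assert res.params.R == pytest.approx(true.R, rel=1e-3)
        assert res.params.k == pytest.approx(true.k, rel=1e-3)
        assert res.params.tau0 == pytest.approx(true.tau0, rel=1e-3)
        assert res.mbf == pytest.approx(true.mbf, rel=1e-3)

    def test_scale_equivariance(self, aif_curve):
        true = fp.FermiParams(R=1.3, k=0.25, tau0=6.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        r1 = fp.fit_fermi(aif_curve.values, tissue, 1.0)
        r2 = fp.fit_fermi(aif_curve.values, 3.0 * tissue, 1.0)
        assert r2.params.R == pytest.approx(3.0 * r1.params.R, rel=1e-6)
        assert r2.mbf == pytest.approx(3.0 * r1.mbf, rel=1e-6)
        assert r2.params.k == pytest.approx(r1.params.k, rel=1e-4)
        assert r2.params.tau0 == pytest.approx(r1.params.tau0, rel=1e-4)

    def test_zero_tissue_is_invalid_not_exception(self, aif_curve):
        res = fp.fit_fermi(aif_curve.values, np.zeros(60), 1.0)
        assert not res.valid
        assert np.isnan(res.mbf)

    def test_estimator_sklearn_interface(self, aif_curve):
        est = FermiDeconvolution(dt=1.0, tau_d=2.0)
        assert est.get_params()["tau_d"] == 2.0
        est2 = clone(est).set_params(tau_d=3.0)
        assert est2.tau_d == 3.0
        true = fp.FermiParams(R=2.0, k=0.3, tau0=5.0, tau_d=2.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        est.fit(aif_curve.values, tissue)
        assert est.converged_
        np.testing.assert_allclose(est.predict(), tissue, atol=1e-8)

    def test_bounds_respected(self, aif_curve):
        true = fp.FermiParams(R=2.0, k=0.3, tau0=5.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        res = fp.fit_fermi(aif_curve.values, tissue, 1.0)
        lb, ub = DEFAULT_BOUNDS
        x = (res.params.R, res.params.k, res.params.tau0)
        assert all(lo <= v <= hi for v, lo, hi in zip(x, lb, ub))


class TestDelayEstimation:
    def test_round_trip(self, aif_curve):
        true = fp.FermiParams(R=2.0, k=0.3, tau0=5.0, tau_d=2.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        assert fp.estimate_delay(aif_curve.values, tissue, 1.0) == 2.0

    def test_scaled_aif_copy_gives_zero(self, aif_curve):
        # tissue proportional to the AIF itself: no arrival delay
        tissue = fermi_model_curve(
            aif_curve.values, fp.FermiParams(R=1.0, k=0.2, tau0=3.0), 1.0
        )
        assert fp.estimate_delay(aif_curve.values, tissue, 1.0) == 0.0

    def test_matches_brute_force_scan(self, aif_curve):
        true = fp.FermiParams(R=1.5, k=0.35, tau0=4.0, tau_d=3.0)
        tissue = fermi_model_curve(aif_curve.values, true, 1.0)
        rng = np.random.default_rng(7)
        noisy = tissue + rng.normal(0, tissue.max() / 30, tissue.size)
        # independent scan: refit at every offset, track the smallest RSS
        best, best_tau = np.inf, None
        for f in range(6):
            r = fp.fit_fermi(aif_curve.values, noisy, 1.0, tau_d=float(f))
            if r.rss < best:
                best, best_tau = r.rss, float(f)
        assert fp.estimate_delay(aif_curve.values, noisy, 1.0) == best_tau

    def test_empty_candidates_error(self, aif_curve):
        with pytest.raises(ValueError):
            fp.estimate_delay(aif_curve.values, aif_curve.values, 1.0, [])


class TestMaps:
    def test_compute_mpr_arithmetic_and_masks(self):
        stress = fp.MBFMap(values=np.array([[3.0, 2.0]]),
                           valid=np.array([[True, True]]),
                           state="stress", slice_label="mid")
        rest = fp.MBFMap(values=np.array([[1.5, 1.0]]),
                         valid=np.array([[True, False]]),
                         state="rest", slice_label="mid")
        mpr = fp.compute_mpr(stress, rest)
        assert mpr.values[0, 0] == pytest.approx(2.0)
        assert not mpr.valid[0, 1]

    def test_zero_rest_mbf_pixel_invalidated(self):
        stress = fp.MBFMap(values=np.array([[3.0]]), valid=np.array([[True]]),
                           state="stress", slice_label="mid")
        rest = fp.MBFMap(values=np.array([[0.0]]), valid=np.array([[True]]),
                         state="rest", slice_label="mid")
        assert not fp.compute_mpr(stress, rest).valid[0, 0]

    def test_identical_maps_give_unit_mpr(self):
        v = np.array([[1.2, 2.2], [0.5, 4.0]])
        m = fp.MBFMap(values=v, valid=np.ones_like(v, bool),
                      state="stress", slice_label="mid")
        r = fp.MBFMap(values=v.copy(), valid=np.ones_like(v, bool),
                      state="rest", slice_label="mid")
        np.testing.assert_allclose(fp.compute_mpr(m, r).values, 1.0)

    def test_pixelwise_flags_degenerate_pixel(self, small_spec, aif_curve):
        series, aif, truth = fp.generate_perfusion_series(small_spec, "rest")
        s = series[0]
        ann = truth.contours[0].annulus_mask(small_spec.shape)
        rows, cols = np.nonzero(ann)
        frames = s.frames.copy()
        frames[:, rows[0], cols[0]] = 0.0  # inject one dead pixel
        s2 = fp.PerfusionSeries(frames=frames, times=s.times,
                                slice_label=s.slice_label, state=s.state)
        m = fp.quantify_pixelwise(
            s2, ann, aif, tau_d=small_spec.tau_d,
            dose_ratio=small_spec.aif.dose_ratio,
        )
        assert not m.valid[rows[0], cols[0]]
        assert m.valid.sum() == ann.sum() - 1
        assert not m.valid[~ann].any()
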