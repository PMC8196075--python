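"""ΔF/F, airPLS baseline, standardization, and transient detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strugglescope import photometry as P
from strugglescope.errors import DegenerateInputError, DomainError, FormatError


def _rec(signal, reference=None, rate=20.0):
    n = len(signal)
    return P.PhotometryRecording(
        time=np.arange(n) / rate,
        signal=np.asarray(signal, float),
        reference=None if reference is None else np.asarray(reference, float),
    )


class TestReadPhotometryTable:
    def test_roundtrip_and_duration(self, tmp_path):
        f = tmp_path / "phot.csv"
        t = np.arange(1000) / 20.0
        np.savetxt(
            f, np.c_[t, 100 + t, 80 - t], delimiter=",",
            header="time_s,ch470,ch405", comments="",
        )
        rec = P.read_photometry_table(f)
        assert rec.n_samples == 1000
        assert rec.duration_s == pytest.approx(50.0)
        assert rec.sample_rate == pytest.approx(20.0)

    def test_repeated_timestamp_is_format_error(self, tmp_path):
        f = tmp_path / "phot.csv"
        f.write_text("time_s,ch470\n0.0,1\n0.05,2\n0.05,3\n")
        with pytest.raises(FormatError):
            P.read_photometry_table(f)

    def test_decimation_block_average(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.arange(10000) / 1000.0
        sig = 5.0 + rng.normal(size=t.size)
        f = tmp_path / "phot.csv"
        np.savetxt(f, np.c_[t, sig], delimiter=",", header="time_s,ch470",
                   comments="")
        rec = P.read_photometry_table(f, decimate_to=20.0)
        assert rec.n_samples == 200
        # block-average oracle
        assert rec.signal.mean() == pytest.approx(sig.mean(), rel=1e-3)
        np.testing.assert_allclose(
            rec.signal[:3], sig[:150].reshape(3, 50).mean(axis=1)
        )


class TestIsosbesticFit:
    def test_identity(self):
        x = np.linspace(1, 2, 100)
        fit = P.fit_isosbestic(_rec(x, x))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_exact_affine(self):
        x = np.linspace(1, 2, 100)
        fit = P.fit_isosbestic(_rec(2 * x + 3, x))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(10, 2, 500)
        sig = 1.7 * ref + 4.0 + rng.normal(0, 0.5, 500)
        fit = P.fit_isosbestic(_rec(sig, ref))
        slope = np.cov(ref, sig, ddof=1)[0, 1] / np.var(ref, ddof=1)
        intercept = sig.mean() - slope * ref.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_constant_reference_raises(self):
        with pytest.raises(DegenerateInputError):
            P.fit_isosbestic(_rec(np.arange(10.0), np.ones(10)))


class TestComputeDff:
    def test_null_and_proportional(self):
        ref = np.linspace(10, 12, 50)
        rec = _rec(ref.copy(), ref)
        fit = P.IsosbesticFit(1.0, 0.0, ref)
        np.testing.assert_allclose(P.compute_dff(rec, fit).dff, 0.0, atol=1e-12)
        rec2 = _rec(1.1 * ref, ref)
        np.testing.assert_allclose(P.compute_dff(rec2, fit).dff, 0.1, atol=1e-12)

    def test_elementwise_hand_computation(self):
        sig = np.array([11.0, 9.0, 10.0, 14.0])
        f0 = np.array([10.0, 10.0, 8.0, 7.0])
        rec = _rec(sig, f0, rate=1.0)
        fit = P.IsosbesticFit(1.0, 0.0, f0)
        np.testing.assert_allclose(
            P.compute_dff(rec, fit).dff, [0.1, -0.1, 0.25, 1.0], atol=1e-12
        )

    def test_nonpositive_fitted_reference_names_sample(self):
        f0 = np.array([1.0, -0.5, 1.0, 1.0])
        rec = _rec(np.ones(4), np.ones(4), rate=1.0)
        fit = P.IsosbesticFit(1.0, 0.0, f0)
        with pytest.raises(DomainError, match="sample 1"):
            P.compute_dff(rec, fit)

    def test_common_channel_gain_invariance(self):
        rng = np.random.default_rng(2)
        ref = 80 + rng.normal(0, 1, 400)
        sig = 1.3 * ref + 5 + rng.normal(0, 0.3, 400)
        d1 = P.compute_dff(_rec(sig, ref), P.fit_isosbestic(_rec(sig, ref))).dff
        d2 = P.compute_dff(
            _rec(3 * sig, 3 * ref), P.fit_isosbestic(_rec(3 * sig, 3 * ref))
        ).dff
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestAirplsBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        z = P.airpls_baseline(np.full(200, 3.7))
        np.testing.assert_allclose(z, 3.7, atol=1e-6)

    def test_tracks_bleach_like_drift_within_one_percent(self):
        t = np.arange(20000) / 20.0
        drift = 80 * (0.7 + 0.3 * np.exp(-t / 600))
        z = P.airpls_baseline(drift)
        assert np.max(np.abs(z - drift) / drift) < 0.01

    def test_rides_under_positive_transients(self):
        t = np.arange(20000) / 20.0
        drift = 80 * (0.7 + 0.3 * np.exp(-t / 600))
        bump = np.zeros_like(t)
        for t0 in (200.0, 500.0, 800.0):
            m = t >= t0
            bump[m] += 40 * (np.exp(-(t[m] - t0) / 1.5) - np.exp(-(t[m] - t0) / 0.1))
        z = P.airpls_baseline(drift + bump)
        under = bump > 2.0
        assert np.max(np.abs(z - drift)[under] / drift[under]) < 0.05

    def test_additive_constant_equivariance(self):
        t = np.arange(5000) / 20.0
        drift = 50 * (0.8 + 0.2 * np.exp(-t / 100))
        z = P.airpls_baseline(drift)
        z_shift = P.airpls_baseline(drift + 25.0)
        np.testing.assert_allclose(z_shift, z + 25.0, atol=1e-6)

    def test_baseline_below_signal_where_weighted(self):
        rng = np.random.default_rng(3)
        y = 10 + rng.normal(0, 0.5, 2000)
        y[500:520] += 8.0
        z = P.airpls_baseline(y)
        # under the peak, baseline stays near the surrounding level
        assert z[500:520].max() < y[500:520].max() - 4.0


class TestStandardizeTrace:
    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        np.testing.assert_allclose(
            P.standardize_trace(x), P.standardize_trace(2.5 * x + 7), atol=1e-9
        )

    def test_four_point_hand_calc(self):
        z = P.standardize_trace(np.array([0.0, 0.0, 0.0, 10.0]))
        # mean 2.5, sd 5 (n-1)
        np.testing.assert_allclose(z, [-0.5, -0.5, -0.5, 1.5])

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        z = P.standardize_trace(rng.gamma(2, 3, 1000))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            P.standardize_trace(np.ones(10))


def brute_force_transients(z, thr, min_samples, rate):
    """Independent oracle: per-sample scan for supra-threshold runs."""
    out, run = [], []
    for i, v in enumerate(list(z) + [-np.inf]):
        if v >= thr:
            run.append(i)
        elif run:
            if len(run) >= min_samples:
                seg = np.asarray(z)[run]
                t = np.asarray(run) / rate
                area = np.trapezoid(seg, t) if len(run) > 1 else 0.0
                out.append((run[0] / rate, run[-1] / rate, seg.max(), area))
            run = []
    return out


class TestDetectTransients:
    def test_all_subthreshold_empty(self):
        assert P.detect_transients(np.zeros(100), sample_rate=1.0) == []

    def test_two_runs_with_peaks(self):
        z = np.array([0.0, 3.0, 3.0, 0.0, 5.0, 0.0])
        ts = P.detect_transients(z, sample_rate=1.0)
        assert [t.max_peak for t in ts] == [3.0, 5.0]
        assert ts[0].start_s == 1.0 and ts[0].end_s == 2.0
        assert ts[0].area == pytest.approx(3.0)  # trapezoid of [3,3] over 1 s
        assert ts[1].area == 0.0  # single-sample run

    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_oracle_equivalence_random_traces(self, seed, min_samples):
        rng = np.random.default_rng(seed)
        z = rng.normal(1.5, 1.5, rng.integers(5, 400))
        cfg = P.TransientConfig(z_threshold=2.91, min_samples=min_samples)
        got = P.detect_transients(z, sample_rate=10.0, cfg=cfg)
        want = brute_force_transients(z, 2.91, min_samples, 10.0)
        assert len(got) == len(want)
        for g, (s, e, pk, area) in zip(got, want):
            assert g.start_s == pytest.approx(s)
            assert g.end_s == pytest.approx(e)
            assert g.max_peak == pytest.approx(pk)
            assert g.area == pytest.approx(area, abs=1e-9)

    def test_frequency_arithmetic(self):
        assert P.transient_frequency([], 60.0) == 0.0
        ts = P.detect_transients(
            np.tile([0, 0, 5, 0, 0, 0, 0, 0, 0, 0], 6).astype(float),
            sample_rate=1.0,
        )
        assert P.transient_frequency(ts, 60.0) == pytest.approx(0.1)

    def test_injected_frequency_recovered_exactly(self):
        """30 well-separated large transients over 600 s -> 0.05 Hz."""
        from strugglescope.evaluate import match_transients
        from strugglescope.synthetic import (
            PhotometrySimParams,
            simulate_photometry_session,
        )

        params = PhotometrySimParams(
            session_s=600.0, spont_rate_hz=0.08, spont_amp_z=10.0,
            spont_min_sep_s=12.0, p_trig=0.0, coupling_z_per_s=0.0,
            noise_sd_470=0.02, noise_sd_405=0.002, artifact_frac_sd=0.001,
            seed=123,
        )
        rec, truth = simulate_photometry_session(params)
        n_true = len(truth.transients)
        res = P.process_recording(rec)
        m = match_transients(truth.transients["time_s"].to_numpy(), res.transients)
        assert m["detection_rate"] == 1.0
        assert m["n_spurious"] == 0
        # amplitudes far above threshold, negligible noise: each injected
        # transient is exactly one detected run
        assert len(res.transients) == n_true
        assert res.frequency_hz == pytest.approx(n_true / 600.0)
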