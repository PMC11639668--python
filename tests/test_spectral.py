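import numpy as np
import pytest

from neoflow.containers import IQBlock
from neoflow.morphology import Skeleton
from neoflow.params import AcquisitionParams
from neoflow.simulate import VesselSegment, cardiac_waveform, synthesize_iq
from neoflow.spectral import (
    CardiacLandmarks,
    NoCardiacSignalError,
    Spectrogram,
    average_neighbourhood,
    dealias,
    global_landmarks,
    map_skeleton_ri,
    mean_frequency,
    noise_floor,
    psv_edv,
    spectrogram,
    to_velocity,
)
from tests.conftest import make_tilted_block, tone_block


@pytest.fixture(scope="module")
def params():
    return AcquisitionParams(prf=9600, n_angles=3, n_frames=1280, shape=(6, 6))


class TestSpectrogram:
    def test_tone_ridge_at_tone_frequency(self, params):
        f0 = 400.0
        spec = spectrogram(tone_block(f0, params), (2, 2))
        win_samples = round(0.040 * params.frame_rate)
        ridge = spec.freqs[np.argmax(spec.magnitude, axis=0)]
        assert np.all(np.abs(ridge - f0) <= params.frame_rate / win_samples)

    def test_zero_input_zero_magnitude(self, params):
        block = IQBlock(np.zeros((6, 6, 1280), complex), params)
        spec = spectrogram(block, (0, 0))
        assert np.all(spec.magnitude == 0)

    def test_conjugate_tones_give_symmetric_ridges(self, params):
        t = np.arange(1280) / params.frame_rate
        sig = np.exp(2j * np.pi * 300 * t) + np.exp(-2j * np.pi * 300 * t)
        block = IQBlock(np.broadcast_to(sig, (6, 6, 1280)).copy(), params)
        spec = spectrogram(block, (1, 1))
        pos = spec.magnitude[np.argmin(np.abs(spec.freqs - 300))]
        neg = spec.magnitude[np.argmin(np.abs(spec.freqs + 300))]
        assert np.allclose(pos, neg, rtol=1e-6)

    def test_block_shorter_than_window_rejected(self):
        p = AcquisitionParams(prf=9600, n_angles=3, n_frames=64, shape=(2, 2))
        with pytest.raises(ValueError, match="window"):
            spectrogram(IQBlock(np.zeros((2, 2, 64), complex), p), (0, 0))


class TestAverageNeighbourhood:
    def test_identical_pixels_equal_single_pixel(self, params):
        block = tone_block(500.0, params)
        single = spectrogram(block, (2, 2))
        avg = average_neighbourhood(block, (2, 2))
        assert np.allclose(avg.magnitude, single.magnitude, rtol=1e-9)

    def test_one_signal_pixel_among_zeros_scales_by_population(self, params):
        t = np.arange(1280) / params.frame_rate
        data = np.zeros((6, 6, 1280), complex)
        data[2, 2] = np.exp(2j * np.pi * 500 * t)
        block = IQBlock(data, params)
        single = spectrogram(block, (2, 2))
        avg = average_neighbourhood(block, (2, 2), size=5)
        assert np.allclose(avg.magnitude, single.magnitude / 25.0, rtol=1e-9)

    def test_border_truncation(self, params):
        block = tone_block(500.0, params)
        avg = average_neighbourhood(block, (0, 0), size=5)  # 3x3 corner window
        single = spectrogram(block, (0, 0))
        assert np.allclose(avg.magnitude, single.magnitude, rtol=1e-9)

    def test_averaging_reduces_floor_fluctuations_by_sqrt_population(self, params):
        # magnitude averaging over 25 independent-noise pixels leaves the
        # noise-floor mean unchanged but shrinks its fluctuations ~sqrt(25),
        # so the ridge stands ~5x further above the floor variability
        rng = np.random.default_rng(0)
        gains = []
        t = np.arange(1280) / params.frame_rate
        for _ in range(20):
            noise = rng.normal(size=(6, 6, 1280)) + 1j * rng.normal(size=(6, 6, 1280))
            sig = 0.5 * np.exp(2j * np.pi * 500 * t)
            block = IQBlock(noise + sig, params)

            def ridge_snr(spec):
                i = np.argmin(np.abs(spec.freqs - 500))
                ridge = spec.magnitude[i].mean()
                off = np.delete(spec.magnitude, slice(i - 3, i + 4), axis=0)
                return (ridge - off.mean()) / off.std()

            gains.append(
                ridge_snr(average_neighbourhood(block, (2, 2))) / ridge_snr(spectrogram(block, (2, 2)))
            )
        assert np.mean(gains) == pytest.approx(np.sqrt(25), rel=0.35)


class TestNoiseFloor:
    def test_uniform_spectrogram_unchanged(self):
        spec = Spectrogram(np.ones((8, 4)), np.arange(8.0), np.arange(4.0), 100.0)
        assert np.array_equal(noise_floor(spec).magnitude, spec.magnitude)

    def test_fraction_zero_unchanged(self):
        rng = np.random.default_rng(1)
        spec = Spectrogram(rng.random((8, 4)), np.arange(8.0), np.arange(4.0), 100.0)
        assert np.array_equal(noise_floor(spec, 0.0).magnitude, spec.magnitude)

    def test_matrix_example(self):
        mag = np.array([[1.0, 0.05], [0.2, 0.09]])
        spec = Spectrogram(mag, np.arange(2.0), np.arange(2.0), 100.0)
        out = noise_floor(spec, 0.1)
        assert np.array_equal(out.magnitude, [[1.0, 0.0], [0.2, 0.0]])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        spec = Spectrogram(rng.random((16, 8)), np.arange(16.0), np.arange(8.0), 100.0)
        once = noise_floor(spec)
        twice = noise_floor(once)
        assert np.array_equal(once.magnitude, twice.magnitude)


class TestDealias:
    def test_wrapped_tone_restored_with_in_band_anchor(self, params):
        # tone at 0.7 fr (wrapped to -0.3 fr) plus a stronger in-band tone
        # at 0.35 fr anchoring the flow sign
        fr = params.frame_rate
        t = np.arange(1280) / fr
        sig = np.exp(2j * np.pi * 0.7 * fr * t) + 1.3 * np.exp(2j * np.pi * 0.35 * fr * t)
        block = IQBlock(np.broadcast_to(sig, (6, 6, 1280)).copy(), params)
        spec = dealias(noise_floor(spectrogram(block, (0, 0))))
        assert spec.dealiased and spec.flow_sign == 1
        # mask the anchor ridge; the remaining ridge must sit at 0.7 fr
        mag = spec.magnitude.copy()
        mag[np.abs(spec.freqs - 0.35 * fr) < 200] = 0
        ridge = spec.freqs[np.argmax(mag, axis=0)]
        assert np.all(np.abs(ridge - 0.7 * fr) < 100)

    def test_non_aliased_tone_unchanged_position(self, params):
        fr = params.frame_rate
        spec = dealias(noise_floor(spectrogram(tone_block(0.3 * fr, params), (0, 0))))
        ridge = spec.freqs[np.argmax(spec.magnitude, axis=0)]
        assert np.all(np.abs(ridge - 0.3 * fr) < 50)

    def test_below_nyquist_mean_frequency_is_noop(self, params):
        fr = params.frame_rate
        spec = noise_floor(spectrogram(tone_block(0.45 * fr, params), (0, 0)))
        with_trace, _ = mean_frequency(dealias(spec))
        without_trace, _ = mean_frequency(spec)
        assert np.allclose(with_trace, without_trace, atol=1e-9)

    def test_balanced_bidirectional_flagged_ambiguous(self, params):
        fr = params.frame_rate
        t = np.arange(1280) / fr
        sig = np.exp(2j * np.pi * 0.2 * fr * t) + np.exp(-2j * np.pi * 0.25 * fr * t)
        block = IQBlock(np.broadcast_to(sig, (6, 6, 1280)).copy(), params)
        spec = dealias(noise_floor(spectrogram(block, (0, 0))))
        assert spec.flags.get("ambiguous_flow_sign")
        assert not spec.dealiased


class TestMeanFrequency:
    def test_single_tone_constant_trace(self, params):
        spec = noise_floor(spectrogram(tone_block(640.0, params), (0, 0)))
        trace, empty = mean_frequency(spec)
        win_samples = round(0.040 * params.frame_rate)
        assert not empty.any()
        assert np.all(np.abs(trace - 640.0) <= params.frame_rate / win_samples)

    def test_symmetric_spectrum_zero_centroid(self):
        mag = np.zeros((9, 3))
        mag[2] = mag[6] = 1.0
        freqs = np.linspace(-400, 400, 9)
        spec = Spectrogram(mag, freqs, np.arange(3.0), 800.0)
        trace, _ = mean_frequency(spec)
        assert np.allclose(trace, 0.0)

    def test_chirp_tracked_within_two_bins(self, params):
        fr = params.frame_rate
        t = np.arange(1280) / fr
        f0, f1 = 200.0, 1000.0
        f_inst = f0 + (f1 - f0) * t / t[-1]
        phase = 2 * np.pi * np.cumsum(f_inst) / fr
        block = IQBlock(np.broadcast_to(np.exp(1j * phase), (6, 6, 1280)).copy(), params)
        spec = noise_floor(spectrogram(block, (0, 0)))
        trace, _ = mean_frequency(spec)
        expected = np.interp(spec.times, t, f_inst)
        bin_hz = fr / round(0.040 * fr)
        assert np.all(np.abs(trace - expected) <= 2 * bin_hz)

    def test_all_zero_column_flagged(self):
        mag = np.zeros((5, 2))
        mag[1, 0] = 1.0
        spec = Spectrogram(mag, np.linspace(-2, 2, 5), np.arange(2.0), 10.0)
        trace, empty = mean_frequency(spec)
        assert trace[1] == 0.0 and empty[1] and not empty[0]


class TestToVelocity:
    def test_zero_frequency_zero_velocity(self, params):
        assert to_velocity(0.0, params) == 0.0

    def test_hand_computed_value(self, params):
        # f = 1600 Hz, c0 = 1540 m/s, f_pulse = 6 MHz, theta = 0
        assert float(to_velocity(1600.0, params)) == pytest.approx(20.533, abs=5e-3)

    def test_sixty_degrees_doubles_velocity(self, params):
        v0 = float(to_velocity(800.0, params, theta=0.0))
        v60 = float(to_velocity(800.0, params, theta=np.radians(60)))
        assert v60 == pytest.approx(2 * v0)

    def test_grazing_angle_rejected(self, params):
        with pytest.raises(ValueError, match="grazing"):
            to_velocity(100.0, params, theta=np.radians(89))


class TestGlobalLandmarks:
    def test_two_cycles_detected_at_true_phase(self, pulsatile_block):
        block, truth = pulsatile_block
        from neoflow.clutter import svd_clutter_filter

        filt = svd_clutter_filter(block, rank="adaptive")
        lm = global_landmarks(filt, truth.lumen)
        # waveform (cycle 0.4 s, phase 0.5): PSV at 0.26/0.66 s, EDV at 0.2/0.6 s
        assert lm.t_psv.size == 2 and lm.t_edv.size == 2
        assert np.all(np.abs(lm.t_psv - [0.26, 0.66]) <= 0.020)
        assert np.all(np.abs(lm.t_edv - [0.20, 0.60]) <= 0.020)
        order = np.sort(np.concatenate([lm.t_psv, lm.t_edv]))
        interleaved = np.sort(
            np.concatenate([lm.t_edv, lm.t_psv])
        )  # EDV precedes PSV within each cycle here
        assert np.array_equal(order, interleaved)

    def test_constant_flow_has_no_cardiac_signal(self, small_params):
        seg = VesselSegment(points=((0.2, 0.8), (2.2, 0.8)), diameter_mm=0.8,
                            psv_cms=8.0, edv_cms=8.0, label="vein")
        block, truth = synthesize_iq([seg], small_params, clutter_to_blood_db=None,
                                     noise_db=30.0, seed=5)
        with pytest.raises(NoCardiacSignalError):
            global_landmarks(block, truth.lumen)

    def test_empty_mask_rejected(self, pulsatile_block):
        block, _ = pulsatile_block
        with pytest.raises(ValueError, match="empty"):
            global_landmarks(block, np.zeros(block.data.shape[:2], bool))


class TestPsvEdv:
    def _landmarks(self):
        return CardiacLandmarks(t_psv=[0.26, 0.66], t_edv=[0.20, 0.60])

    def test_exact_waveform_gives_exact_ri(self):
        times = np.arange(0, 0.8, 0.003)
        v = np.interp(times, np.arange(2560) / 3200, cardiac_waveform(10, 4, 3200, 2560))
        res = psv_edv(v, times, self._landmarks())
        assert res.psv == pytest.approx(10.0, abs=0.01)
        assert res.edv == pytest.approx(4.0, abs=0.01)
        assert res.ri == pytest.approx(0.6, abs=0.002)
        assert res.n_cycles == 2

    def test_zero_edv_gives_ri_one(self):
        times = np.arange(0, 0.8, 0.003)
        v = np.interp(times, np.arange(2560) / 3200, cardiac_waveform(10, 0, 3200, 2560))
        res = psv_edv(v, times, self._landmarks())
        assert res.ri == pytest.approx(1.0, abs=0.002)

    def test_noisy_trace_ri_within_tolerance_over_seeds(self):
        # noise on a mean-frequency trace is correlated over the 40 ms STFT
        # window; white per-sample noise would bias the window max/min
        from scipy.ndimage import gaussian_filter1d

        times = np.arange(0, 0.8, 0.003)
        clean = np.interp(times, np.arange(2560) / 3200, cardiac_waveform(10, 4, 3200, 2560))
        rng = np.random.default_rng(8)
        ris = []
        for _ in range(100):
            noise = gaussian_filter1d(rng.normal(0, 1, clean.size), 6.0)
            noise *= 0.5 / noise.std()
            res = psv_edv(clean + noise, times, self._landmarks())
            ris.append(res.ri)
        assert abs(np.mean(ris) - 0.6) <= 0.05

    def test_negative_edv_flagged_not_clamped(self):
        times = np.arange(0, 0.8, 0.003)
        v = np.where((np.abs(times - 0.20) < 0.01) | (np.abs(times - 0.60) < 0.01), -1.0, 5.0)
        res = psv_edv(v, times, self._landmarks())
        assert res.flags.get("negative_edv")
        assert res.ri > 1.0

    def test_all_windows_off_record_flagged_undefined(self):
        times = np.arange(0, 0.1, 0.003)
        res = psv_edv(np.ones_like(times), times, self._landmarks())
        assert res.flags.get("undefined")


class TestMapSkeletonRI:
    def test_pulsatile_vessel_ri_recovered(self, pulsatile_block, small_params):
        from neoflow.clutter import svd_clutter_filter

        block, truth = pulsatile_block
        filt = svd_clutter_filter(block, rank="adaptive")
        skel = Skeleton(truth.centreline, small_params.pixel_spacing)
        skel.diameter_mm = truth.diameter_map
        out = map_skeleton_ri(filt, skel, mask=truth.lumen)
        ri = out.ri[np.isfinite(out.ri)]
        assert ri.size >= 0.8 * truth.centreline.sum()
        assert np.all(np.abs(ri - 0.6) <= 0.05)

    def test_angle_invariance_of_ri(self):
        from neoflow.clutter import svd_clutter_filter

        means = []
        for ang in (0, 30, 60):
            block, truth = make_tilted_block(ang)
            filt = svd_clutter_filter(block, rank="adaptive")
            skel = Skeleton(truth.centreline, 0.1)
            out = map_skeleton_ri(filt, skel, mask=truth.lumen)
            means.append(np.nanmean(out.ri))
        assert max(means) - min(means) <= 0.03

    def test_vein_ri_near_zero(self, small_params):
        from neoflow.clutter import svd_clutter_filter

        artery = VesselSegment(points=((0.2, 0.4), (2.2, 0.4)), diameter_mm=0.5)
        vein = VesselSegment(points=((0.2, 1.2), (2.2, 1.2)), diameter_mm=0.5,
                             psv_cms=6.0, edv_cms=6.0, label="vein")
        block, truth = synthesize_iq([artery, vein], small_params, seed=6)
        filt = svd_clutter_filter(block, rank="adaptive")
        skel = Skeleton(truth.centreline, 0.1)
        out = map_skeleton_ri(filt, skel, mask=truth.lumen)
        vein_ri = out.ri[truth.segment_lumens[1] & truth.centreline]
        vein_ri = vein_ri[np.isfinite(vein_ri)]
        assert vein_ri.size > 0
        assert np.nanmedian(vein_ri) < 0.15

    def test_ambiguous_flow_sign_left_undefined(self, small_params):
        from neoflow.clutter import svd_clutter_filter

        up = VesselSegment(points=((0.2, 0.8), (2.2, 0.8)), diameter_mm=0.8, flow_sign=1)
        down = VesselSegment(points=((0.2, 0.8), (2.2, 0.8)), diameter_mm=0.8, flow_sign=-1)
        block, truth = synthesize_iq([up, down], small_params, seed=7)
        filt = svd_clutter_filter(block, rank="adaptive")
        skel = Skeleton(truth.centreline, 0.1)
        lm = CardiacLandmarks(t_psv=[0.26, 0.66], t_edv=[0.20, 0.60])
        out = map_skeleton_ri(filt, skel, landmarks=lm, mask=truth.lumen)
        assert np.isnan(out.ri[truth.centreline]).all()


class TestAmplitudeInvariance:
    def test_scaling_iq_leaves_velocity_quantities_unchanged(self, pulsatile_block):
        from neoflow.clutter import svd_clutter_filter

        block, truth = pulsatile_block
        filt = svd_clutter_filter(block, rank=5)
        r, c = np.argwhere(truth.centreline)[8]
        results = []
        for alpha in (1.0, 7.3):
            scaled = IQBlock(alpha * filt.data, filt.params)
            spec = dealias(noise_floor(average_neighbourhood(scaled, (r, c))))
            trace, _ = mean_frequency(spec)
            results.append(trace)
        assert np.allclose(results[0], results[1], atol=1e-9)
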