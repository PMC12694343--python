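import numpy as np
import pytest
from scipy.signal import periodogram

from wavescape.audio_io import P0, read_wav
from wavescape.energy import leq, leq_series
from wavescape.modwt import level_energies, modwt
from wavescape.peaks import PeakMode, find_peaks, inter_peak_lags
from wavescape.synth import (
    SceneConfig,
    SourceSpec,
    chirp_train,
    colored_noise,
    dawn_diel_profile,
    poisson_event_times,
    pure_tone,
    render_clip,
    render_session,
    rms_for_level,
    transient_events,
)


class TestPureTone:
    def test_leq_closed_form(self):
        amp = 0.01
        clip = pure_tone(1000, 1.0, amplitude=amp, fs=48000)
        expected = 10 * np.log10(amp**2 / (2 * P0**2))
        assert leq(clip.samples) == pytest.approx(expected, abs=1e-6)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pure_tone(24000, 1.0, fs=48000)

    def test_1khz_maps_to_w5(self):
        clip = pure_tone(1000, 1.0, amplitude=0.1, fs=48000)
        fr = level_energies(modwt(clip.samples, "d4", 10))["fraction"]
        assert max(fr, key=fr.get) == "W5"

    def test_decomposition_linearity_two_tones(self):
        a = pure_tone(500, 0.25, amplitude=0.1, fs=8000)
        b = pure_tone(1500, 0.25, amplitude=0.05, fs=8000)
        dec_sum = modwt(a.samples + b.samples, "d4", 4)
        da, db = modwt(a.samples, "d4", 4), modwt(b.samples, "d4", 4)
        for j in range(4):
            np.testing.assert_allclose(
                dec_sum.details[j], da.details[j] + db.details[j], atol=1e-10
            )


class TestChirpTrain:
    def test_zero_rate_is_silence(self):
        clip = chirp_train(rate_per_min=0.0, duration=10.0, fs=8000, seed=1)
        assert np.all(clip.samples == 0)

    def test_poisson_event_count(self):
        # 6 events/min over a 60 min equivalent: count within 3 sigma of 360
        times = poisson_event_times(6.0, 3600.0, np.random.default_rng(1))
        assert abs(len(times) - 360) <= 3 * np.sqrt(360)
        assert np.all(np.diff(times) >= 0)
        assert len(poisson_event_times(0.0, 60.0, np.random.default_rng(1))) == 0

    def test_waveform_event_count_matches_rate(self):
        # events visible in the rendered waveform at a sparse rate
        clip = chirp_train(rate_per_min=4.0, duration=300.0, fs=16000, seed=2, level_db=70)
        env = np.max(np.abs(clip.samples).reshape(-1, 1600), axis=1)  # 0.1 s grid
        active = env > 0.25 * np.sqrt(2) * rms_for_level(70)
        n_bursts = int(np.sum(np.diff(active.astype(int)) == 1) + active[0])
        assert abs(n_bursts - 20) <= 3 * np.sqrt(20) + 2  # Poisson 3 sigma + merge slack

    def test_deterministic_spacing_recovers_lags(self):
        # a weak low-frequency floor accompanies the chirps: without any
        # floor the inter-event windows sit at the transform's numerical
        # noise level and its jitter produces meaningless extra peaks
        clip = chirp_train(
            band=(3000, 6000), duration=60.0, fs=48000, spacing=10.0, offset=5.5,
            event_duration=4.5, level_db=75, seed=0,
        )
        floor = colored_noise(1.0, (20, 375), 60.0, 48000, seed=1, level_db=60)
        clip.samples = clip.samples + floor.samples
        dec = modwt(clip.samples, "d4", 10)
        w3 = [s for s in leq_series(clip, dec, tau=1.0) if s.band == "W3"][0]
        peaks = find_peaks(w3, PeakMode(2, 2))
        lags = inter_peak_lags(peaks)
        assert len(lags) >= 4
        # the floor contributes an occasional peak of its own, so the
        # spacing shows up in the median, not in every single lag
        assert abs(np.median(lags) - 10.0) <= 1.0
        assert np.mean(np.abs(lags - 10.0) <= 1.0) >= 0.5

    def test_same_seed_identical(self):
        a = chirp_train(seed=7, duration=5.0, fs=8000)
        b = chirp_train(seed=7, duration=5.0, fs=8000)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestColoredNoise:
    @pytest.mark.parametrize("alpha,tol", [(0.0, 0.05), (1.0, 0.1)])
    def test_periodogram_slope(self, alpha, tol):
        clip = colored_noise(alpha, None, duration=2**20 / 48000, fs=48000, seed=3)
        f, P = periodogram(clip.samples, fs=48000)
        sel = (f > 10) & (f < 20000)
        slope = np.polyfit(np.log10(f[sel]), np.log10(P[sel]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=tol)

    def test_band_limiting(self):
        clip = colored_noise(1.0, band=(100, 400), duration=2.0, fs=8000, seed=2)
        f, P = periodogram(clip.samples, fs=8000)
        in_band = P[(f >= 100) & (f <= 400)].sum()
        assert in_band / P.sum() > 0.999

    def test_unit_rms_and_level_scaling(self):
        clip = colored_noise(0.5, None, duration=1.0, fs=8000, seed=4)
        assert np.sqrt(np.mean(clip.samples**2)) == pytest.approx(1.0, abs=1e-9)
        scaled = colored_noise(0.5, None, duration=1.0, fs=8000, seed=4, level_db=60)
        assert leq(scaled.samples) == pytest.approx(60.0, abs=1e-6)

    def test_same_seed_identical(self):
        a = colored_noise(1.0, None, 1.0, 8000, seed=11)
        b = colored_noise(1.0, None, 1.0, 8000, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            colored_noise(2.5, None, 1.0, 8000)


def test_transient_events_level(rng):
    clip = transient_events(rate_per_min=30, duration=10.0, fs=8000, seed=3, level_db=70)
    assert np.max(np.abs(clip.samples)) > 0


class TestRenderSession:
    def _scene(self, seed=5):
        return SceneConfig(
            components=[
                SourceSpec(kind="chirp_train", band=(3000, 6000), level_db=70,
                           rate_per_min=6, diel=True),
                SourceSpec(kind="colored_noise", band=(20, 375), level_db=60,
                           spectral_exponent=1.0),
            ],
            seed=seed,
            sample_rate=16000.0,
            diel_profile=dawn_diel_profile(peak_hour=6, depth_db=12),
        )

    def test_file_count_and_manifest(self, tmp_path):
        manifest = render_session(self._scene(), "S1", tmp_path, hours=[3, 4], clips_per_hour=2)
        assert len(manifest) == 4
        assert (tmp_path / "manifest.csv").exists()
        wavs = sorted(tmp_path.glob("*.wav"))
        assert len(wavs) == 4
        clip = read_wav(wavs[0])
        assert clip.duration == pytest.approx(60.0)

    def test_duty_cycle_timestamps(self, tmp_path):
        manifest = render_session(self._scene(), "S1", tmp_path, hours=[0], clips_per_hour=3)
        times = [np.datetime64(t) for t in manifest["start_time"]]
        deltas = np.diff(times).astype("timedelta64[s]").astype(int)
        assert list(deltas) == [360, 360]  # 1 min record + 5 min pause

    def test_seed_determinism_across_renders(self, tmp_path):
        m1 = render_session(self._scene(9), "A", tmp_path / "r1", hours=[2], clips_per_hour=1)
        m2 = render_session(self._scene(9), "A", tmp_path / "r2", hours=[2], clips_per_hour=1)
        a = read_wav(tmp_path / "r1" / m1["path"][0])
        b = read_wav(tmp_path / "r2" / m2["path"][0])
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_silent_scene_flagged_by_leq(self, tmp_path):
        scene = SceneConfig(
            components=[SourceSpec(kind="chirp_train", rate_per_min=0.0, band=(3000, 6000))],
            seed=1, sample_rate=8000.0,
        )
        manifest = render_session(scene, "Q", tmp_path, hours=[0], clips_per_hour=1)
        clip = read_wav(tmp_path / manifest["path"][0])
        assert leq(clip.samples) == -np.inf

    def test_component_separability(self):
        """Chirp band levels unaffected by the low-frequency floor and vice versa."""
        fs = 48000.0
        chirps = SourceSpec(kind="chirp_train", band=(3000, 6000), level_db=70, rate_per_min=30)
        noise = SourceSpec(kind="colored_noise", band=(20, 375), level_db=65, spectral_exponent=1.0)
        rng = np.random.default_rng(0)

        def band_leq(components):
            scene = SceneConfig(components=components, seed=3, sample_rate=fs, duration=10.0)
            clip = render_clip(scene, 12, np.random.default_rng(3))
            dec = modwt(clip.samples, "d4", 10)
            return {
                s.band: 10 * np.log10(np.mean(10 ** (s.values / 10)))
                for s in leq_series(clip, dec, tau=1.0)[1:]
            }

        both = band_leq([chirps, noise])
        chirps_only = band_leq([chirps])
        noise_only = band_leq([noise])
        for b in ("W2", "W3"):
            assert abs(both[b] - chirps_only[b]) < 1.0
        for b in ("W7", "W8", "W9", "W10"):
            assert abs(both[b] - noise_only[b]) < 1.0


def test_dawn_profile_shape():
    prof = dawn_diel_profile(peak_hour=6, depth_db=12)
    assert len(prof) == 24
    assert prof[6] == pytest.approx(0.0)
    assert np.argmax(prof) == 6
    assert prof.min() >= -12.0
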