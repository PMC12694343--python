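from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy.io import wavfile

from wavescape.audio_io import (
    AudioClip,
    CalibrationConfig,
    assemble_session,
    load_manifest,
    normalize_energy,
    read_wav,
    write_wav,
)
from wavescape.energy import leq


def test_read_constant_zero_file(tmp_path):
    wavfile.write(tmp_path / "z.wav", 48000, np.zeros(4800, dtype=np.int16))
    clip = read_wav(tmp_path / "z.wav", site_id="A")
    assert np.all(clip.samples == 0.0)
    assert clip.duration == pytest.approx(0.1)
    assert clip.site_id == "A"


def test_full_scale_negative_int16_maps_to_minus_one(tmp_path):
    wavfile.write(tmp_path / "fs.wav", 48000, np.full(100, -32768, dtype=np.int16))
    clip = read_wav(tmp_path / "fs.wav")
    assert np.all(clip.samples == -1.0)


def test_roundtrip_within_16bit_quantization(tmp_path, rng):
    x = np.clip(rng.standard_normal(48000) * 0.3, -1, 0.999)
    clip = AudioClip(x, 48000.0)
    write_wav(tmp_path / "r.wav", clip)
    back = read_wav(tmp_path / "r.wav")
    assert back.duration == pytest.approx(1.0)
    assert np.max(np.abs(back.samples - x)) <= 2.0**-15


def test_stereo_keeps_channel_zero(tmp_path):
    data = np.stack([np.full(100, 1000), np.full(100, -1000)], axis=1).astype(np.int16)
    wavfile.write(tmp_path / "st.wav", 48000, data)
    with pytest.warns(UserWarning, match="channel 0"):
        clip = read_wav(tmp_path / "st.wav")
    assert np.all(clip.samples > 0)


def test_empty_and_unreadable_files_rejected(tmp_path):
    wavfile.write(tmp_path / "e.wav", 48000, np.zeros(0, dtype=np.int16))
    with pytest.raises(ValueError, match="no samples"):
        read_wav(tmp_path / "e.wav")
    (tmp_path / "bad.wav").write_bytes(b"not a wav at all")
    with pytest.raises(ValueError):
        read_wav(tmp_path / "bad.wav")


def test_clip_invariants():
    with pytest.raises(ValueError, match="finite"):
        AudioClip(np.array([0.0, np.nan]), 48000)
    with pytest.raises(ValueError, match="positive"):
        AudioClip(np.zeros(10), 0)


class TestNormalizeEnergy:
    def test_none_mode_is_identity(self, rng):
        clip = AudioClip(rng.standard_normal(1000), 48000)
        out = normalize_energy(clip, CalibrationConfig())
        np.testing.assert_array_equal(out.samples, clip.samples)

    def test_gain_is_pure_rescale(self, rng):
        x = rng.standard_normal(1000) * 0.01
        clip = AudioClip(x, 48000)
        cal = CalibrationConfig(full_scale_db=94, normalization_mode="per_file_energy")
        out = normalize_energy(clip, cal)
        ratio = out.samples / x
        np.testing.assert_allclose(ratio, ratio[0])

    def test_full_scale_sine_hits_reference_level(self):
        t = np.arange(48000) / 48000
        clip = AudioClip(np.sin(2 * np.pi * 1000 * t), 48000)
        cal = CalibrationConfig(full_scale_db=94, normalization_mode="per_file_energy")
        out = normalize_energy(clip, cal)
        assert leq(out.samples, cal.p0) == pytest.approx(94.0, abs=0.01)

    def test_idempotent(self, rng):
        clip = AudioClip(rng.standard_normal(500), 48000)
        cal = CalibrationConfig(full_scale_db=80, normalization_mode="per_file_energy")
        once = normalize_energy(clip, cal)
        twice = normalize_energy(once, cal)
        np.testing.assert_allclose(twice.samples, once.samples, rtol=1e-10)

    def test_all_zero_clip_rejected(self):
        clip = AudioClip(np.zeros(100), 48000)
        cal = CalibrationConfig(full_scale_db=94, normalization_mode="per_file_energy")
        with pytest.raises(ValueError, match="all-zero"):
            normalize_energy(clip, cal)


def _clips(starts, site="S", fs=48000.0):
    return [
        AudioClip(np.zeros(10), fs, start_time=s, site_id=site) for s in starts
    ]


class TestAssembleSession:
    def test_ten_clips_one_hour(self):
        base = datetime(2021, 6, 1, 13, 0, 0)
        clips = _clips([base + timedelta(minutes=6 * i) for i in range(10)])
        layout = assemble_session(clips)
        assert len(layout.hour_groups) == 1
        (group,) = layout.hour_groups.values()
        assert len(group) == 10
        assert layout.incomplete_hours == []

    def test_empty_list(self):
        layout = assemble_session([])
        assert layout.clips == [] and layout.hour_groups == {}

    def test_full_day_240_clips(self):
        base = datetime(2021, 6, 1, 0, 0, 0)
        starts = [base + timedelta(hours=h, minutes=6 * i) for h in range(24) for i in range(10)]
        layout = assemble_session(_clips(starts))
        assert len(layout.hour_groups) == 24
        assert all(len(g) == 10 for g in layout.hour_groups.values())
        # every clip appears exactly once
        assert sum(len(g) for g in layout.hour_groups.values()) == 240

    def test_incomplete_hour_flagged_not_dropped(self):
        base = datetime(2021, 6, 1, 5, 0, 0)
        layout = assemble_session(_clips([base, base + timedelta(minutes=6)]))
        assert len(layout.incomplete_hours) == 1
        assert len(layout.clips) == 2

    def test_mixed_sample_rates_rejected(self):
        base = datetime(2021, 6, 1, 5, 0, 0)
        clips = _clips([base]) + _clips([base + timedelta(minutes=6)], fs=44100.0)
        with pytest.raises(ValueError, match="sample rates"):
            assemble_session(clips)


def test_manifest_roundtrip(tmp_path):
    wavfile.write(tmp_path / "a.wav", 48000, np.zeros(10, dtype=np.int16))
    (tmp_path / "m.csv").write_text(
        "path,site_id,start_time\na.wav,S1,2021-06-01T13:00:00\n"
    )
    df = load_manifest(tmp_path / "m.csv")
    assert df["path"].iloc[0].endswith("a.wav")
    assert df["start_time"].iloc[0].hour == 13
    with pytest.raises(ValueError, match="lacks columns"):
        (tmp_path / "bad.csv").write_text("path\nx.wav\n")
        load_manifest(tmp_path / "bad.csv")
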