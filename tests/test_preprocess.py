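"""Band-limiting, normalization, spline interpolation, windowing, splits."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdefusion.edf import read_edf, write_edf
from mdefusion.montage import CHANNELS_16, CHANNELS_19, EXTRA_19, load_montage_table
from mdefusion.preprocess import (bandlimit, harmonize_channels, normalize,
                                  segment_windows, spherical_spline_interpolate,
                                  split_subjects, undersample_subjects)
from mdefusion.types import (ConfigurationError, DegenerateInputError,
                             ParameterError, Recording)


def _rec(signal, fs=128.0, channels=None, group="HC", sid="s1"):
    if channels is None:
        channels = [f"ch{i}" for i in range(signal.shape[0])]
    return Recording(sid, group, fs, channels, signal)


class TestReadRecording:
    def test_fixture_roundtrip_metadata(self, edf_dir):
        p = sorted(edf_dir.glob("*.edf"))[0]
        rec = read_edf(p)
        assert rec.fs == 128.0
        assert rec.n_channels == 16
        assert rec.channels == CHANNELS_16

    def test_legacy_alias_t3_becomes_t7(self, tmp_path, rng):
        sig = rng.normal(size=(4, 128))
        rec = Recording("a", "HC", 128.0, ["T3", "T4", "T5", "T6"], sig)
        write_edf(rec, tmp_path / "a.edf")
        back = read_edf(tmp_path / "a.edf")
        assert back.channels == ["T7", "T8", "P7", "P8"]

    def test_truncated_file_raises(self, tmp_path):
        p = tmp_path / "bad.edf"
        p.write_bytes(b"0       junk")
        from mdefusion.types import FormatError
        with pytest.raises((FormatError, OSError)):
            read_edf(p)


class TestBandlimit:
    def test_out_of_band_tone_attenuated(self, rng):
        fs = 512.0
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * 120.0 * t)[None, :]
        out = bandlimit(_rec(x, fs=fs), 0.0, 100.0)
        rms_in = np.sqrt((x ** 2).mean())
        rms_out = np.sqrt((out.signal ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_dc_passes_through_lowpass(self):
        x = np.full((2, 1024), 5.0)
        out = bandlimit(_rec(x), 0.0, 45.0)
        center = out.signal[:, 100:-100]
        assert np.allclose(center, 5.0, rtol=0.01)

    def test_edge_above_nyquist_rejected(self):
        x = np.zeros((1, 256))
        with pytest.raises(ParameterError):
            bandlimit(_rec(x, fs=256.0), 0.0, 200.0)


class TestNormalize:
    def test_zscore_definition(self, rng):
        rec = _rec(rng.normal(3.0, 7.0, size=(5, 1000)))
        out = normalize(rec)
        assert np.allclose(out.signal.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.signal.std(axis=1), 1.0, atol=1e-9)

    def test_idempotent(self, rng):
        rec = normalize(_rec(rng.normal(size=(3, 500))))
        again = normalize(rec)
        assert np.allclose(again.signal, rec.signal, atol=1e-9)

    def test_constant_channel_named_in_error(self, rng):
        sig = rng.normal(size=(3, 100))
        sig[1] = 0.0
        with pytest.raises(DegenerateInputError, match="ch1"):
            normalize(_rec(sig))


@pytest.fixture(scope="module")
def montage():
    return load_montage_table()


class TestSphericalSpline:
    def test_constant_field_reproduced(self, montage):
        rec = _rec(np.full((16, 20), 4.2), channels=list(CHANNELS_16))
        out = spherical_spline_interpolate(rec, montage, EXTRA_19, reorder=False)
        assert np.allclose(out.signal[16:], 4.2, atol=1e-6)

    def test_existing_electrode_recovered(self, montage, rng):
        # interpolate at a position coincident with a measured electrode:
        # for fields in the spline's smoothness class the ridge-regularized
        # solution smooths only slightly
        pos = montage.coords(CHANNELS_16)
        basis = np.column_stack([np.ones(16), pos, pos[:, 0] * pos[:, 2],
                                 pos[:, 1] * pos[:, 2]])
        pat = basis @ rng.normal(size=(basis.shape[1], 300))
        rec = _rec(pat, channels=list(CHANNELS_16))
        out = spherical_spline_interpolate(rec, montage, ["C3"], reorder=False)
        est = out.signal[16]
        truth = pat[CHANNELS_16.index("C3")]
        rel = np.linalg.norm(est - truth) / np.linalg.norm(truth)
        assert rel < 0.02

    def test_16_to_19_canonical_order(self, montage, rng):
        rec = _rec(rng.normal(size=(16, 50)), channels=list(CHANNELS_16))
        out = spherical_spline_interpolate(rec, montage, EXTRA_19)
        assert out.channels == CHANNELS_19
        # measured channels pass through untouched
        for ch in CHANNELS_16:
            assert np.array_equal(out.signal[CHANNELS_19.index(ch)],
                                  rec.signal[CHANNELS_16.index(ch)])

    def test_unknown_target_rejected(self, montage, rng):
        rec = _rec(rng.normal(size=(16, 10)), channels=list(CHANNELS_16))
        with pytest.raises(ConfigurationError):
            spherical_spline_interpolate(rec, montage, ["XX9"])

    def test_smooth_field_heldout_sites(self, montage, rng):
        """A low-order spherical-harmonic-smooth field sampled on the full
        montage is recovered at held-out sites within 5% RMS."""
        names = CHANNELS_19 + ["Fz", "Cz", "Pz", "Fpz"]
        pos = montage.coords(names)
        # smooth field: linear + quadratic functions of position over time
        basis = np.column_stack([np.ones(len(names)), pos,
                                 pos[:, 0] * pos[:, 2], pos[:, 1] * pos[:, 2]])
        field = basis @ rng.normal(size=(basis.shape[1], 100))
        held = ["C3", "Pz", "F4"]
        keep = [n for n in names if n not in held]
        rec = _rec(field[[names.index(n) for n in keep]], channels=keep)
        out = spherical_spline_interpolate(rec, montage, held, reorder=False)
        est = out.signal[len(keep):]
        truth = field[[names.index(n) for n in held]]
        rel = np.linalg.norm(est - truth) / np.linalg.norm(truth)
        assert rel < 0.05

    def test_agrees_with_independent_perrin_implementation(self, montage, rng):
        from mne.channels.interpolation import _make_interpolation_matrix
        src = montage.coords(CHANNELS_16)
        dst = montage.coords(EXTRA_19)
        ref = _make_interpolation_matrix(src, dst)
        sig = rng.normal(size=(16, 4)) @ rng.normal(size=(4, 120))
        rec = _rec(sig, channels=list(CHANNELS_16))
        out = spherical_spline_interpolate(rec, montage, EXTRA_19, reorder=False)
        mine = out.signal[16:]
        assert np.linalg.norm(mine - ref @ sig) / np.linalg.norm(ref @ sig) < 1e-3


class TestSegmentWindows:
    def test_canonical_counts(self):
        rec = _rec(np.zeros((2, 900 * 8)), fs=8.0)
        assert len(segment_windows(rec, 2.0, 1.0)) == 899
        rec = _rec(np.zeros((2, 60 * 8)), fs=8.0)
        assert len(segment_windows(rec, 2.0, 1.0)) == 59

    def test_duration_equals_window(self):
        rec = _rec(np.zeros((1, 256)), fs=128.0)
        segs = segment_windows(rec, 2.0, 1.0)
        assert len(segs) == 1 and segs[0].t0 == 0.0

    def test_window_longer_than_recording_warns_empty(self):
        rec = _rec(np.zeros((1, 128)), fs=128.0)
        with pytest.warns(UserWarning):
            assert segment_windows(rec, 2.0, 1.0) == []

    def test_metadata_carried(self, small_cohort):
        segs = segment_windows(small_cohort[0], 2.0, 1.0)
        assert all(s.subject_id == small_cohort[0].subject_id for s in segs)
        assert all(s.label == small_cohort[0].group for s in segs)
        assert [s.t0 for s in segs] == sorted(s.t0 for s in segs)

    @settings(max_examples=200, deadline=None)
    @given(dur=st.integers(2, 60), win=st.integers(1, 20), stride=st.integers(1, 10))
    def test_count_formula_matches_enumeration(self, dur, win, stride):
        """floor((T-w)/s)+1 equals brute-force enumeration of start times."""
        if win > dur:
            return
        fs = 4.0
        rec = _rec(np.zeros((1, int(dur * fs))), fs=fs)
        got = len(segment_windows(rec, float(win), float(stride)))
        brute = sum(1 for start in range(0, int(dur * fs))
                    if start % int(stride * fs) == 0
                    and start + int(win * fs) <= int(dur * fs))
        assert got == brute == (dur - win) // stride + 1


def _subjects(n_sz, n_hc, fs=8.0, dur=4.0):
    recs = []
    for i in range(n_sz):
        recs.append(Recording(f"SZ{i:02d}", "SZ", fs, ["a"],
                              np.zeros((1, int(fs * dur)))))
    for i in range(n_hc):
        recs.append(Recording(f"HC{i:02d}", "HC", fs, ["a"],
                              np.zeros((1, int(fs * dur)))))
    return recs


class TestSplits:
    @pytest.mark.parametrize("n,expect", [
        (14, (22, 3, 3)),   # 15-min cohort: 22 x 899 / 3 x 899 / 3 x 899
        (39, (62, 8, 8)),   # 1-min cohort: 62 x 59 / 8 x 59 / 8 x 59
    ])
    def test_canonical_cohort_partition_sizes(self, n, expect):
        plan = split_subjects(_subjects(n, n), seed=0)
        sizes = tuple(len(plan.subjects(p)) for p in ("train", "val", "test"))
        assert sizes == expect

    def test_subject_disjoint_and_deterministic(self):
        recs = _subjects(10, 10)
        p1 = split_subjects(recs, seed=5)
        p2 = split_subjects(recs, seed=5)
        assert p1.assignment == p2.assignment
        parts = [set(p1.subjects(x)) for x in ("train", "val", "test")]
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
        assert set.union(*parts) == {r.subject_id for r in recs}

    def test_both_classes_in_every_partition_when_feasible(self):
        plan = split_subjects(_subjects(14, 14), seed=1)
        for part in ("train", "val", "test"):
            groups = {s[:2] for s in plan.subjects(part)}
            assert groups == {"SZ", "HC"}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            split_subjects(_subjects(2, 2), seed=0)


class TestUndersample:
    def test_majority_class_reduced_to_target(self):
        recs = _subjects(45, 39)
        out = undersample_subjects(recs, 39, seed=0)
        by = {}
        for r in out:
            by[r.group] = by.get(r.group, 0) + 1
        assert by == {"SZ": 39, "HC": 39}

    def test_balanced_input_identity(self):
        recs = _subjects(5, 5)
        out = undersample_subjects(recs, 5, seed=0)
        assert {r.subject_id for r in out} == {r.subject_id for r in recs}

    def test_deterministic(self):
        recs = _subjects(9, 6)
        a = undersample_subjects(recs, 6, seed=3)
        b = undersample_subjects(recs, 6, seed=3)
        assert [r.subject_id for r in a] == [r.subject_id for r in b]

    def test_target_above_class_size_rejected(self):
        with pytest.raises(ParameterError):
            undersample_subjects(_subjects(4, 4), 5, seed=0)


def test_harmonize_16_channel_recording(small_cohort):
    rec19 = harmonize_channels(small_cohort[0])
    assert rec19.channels == CHANNELS_19
    assert rec19.signal.shape[0] == 19
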