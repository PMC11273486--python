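"""Recording I/O, windowing arithmetic and participant-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsbreath import nirs_io
from nirsbreath.nirs_io import (
    CHANNELS,
    FormatError,
    NIRSRecording,
    WindowedSample,
    load_recording,
    split_by_participant,
    window_recording,
    write_recording,
)


def _recording(n, label="slow", pid="p1"):
    rng = np.random.default_rng(0)
    return NIRSRecording(values=rng.normal(size=(4, n)), participant_id=pid,
                         task_label=label)


class TestRecordingIO:
    def test_csv_round_trip_is_bit_exact(self, tmp_path, sine_recording):
        path = tmp_path / "rec.csv"
        write_recording(sine_recording, path)
        back = load_recording(path, participant_id="p0", task_label="normal")
        # text round-trip via repr-precision floats
        np.testing.assert_array_equal(back.values, sine_recording.values)
        assert back.channels == CHANNELS

    def test_duration_from_rows_and_rate(self, tmp_path):
        rec = _recording(480)
        path = write_recording(rec, tmp_path / "r.csv")
        back = load_recording(path)
        assert back.n_samples == 480
        assert back.duration == pytest.approx(4.0)

    def test_missing_channel_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,PD1-O2Hb,PD1-HHb,PD2-O2Hb\n0,1,2,3\n")
        with pytest.raises(FormatError, match="PD2-HHb"):
            load_recording(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            load_recording(path)

    def test_non_finite_cells_rejected(self, tmp_path):
        path = tmp_path / "nan.csv"
        header = ",".join(CHANNELS)
        path.write_text(f"{header}\n1,2,nan,4\n")
        with pytest.raises(FormatError):
            load_recording(path)

    def test_tsv_dialect(self, tmp_path, sine_recording):
        path = write_recording(sine_recording, tmp_path / "rec.tsv")
        assert "\t" in path.read_text().splitlines()[0]
        back = load_recording(path)
        np.testing.assert_array_equal(back.values, sine_recording.values)


class TestWindowing:
    @pytest.mark.parametrize(
        "n, length, stride, expected_starts",
        [
            (768, 384, 384, [0, 384]),
            (768, 384, 128, [0, 128, 256, 384]),
            (383, 384, 384, []),
            (384, 384, 1, [0]),
            (390, 384, 2, [0, 2, 4, 6]),
        ],
    )
    def test_window_starts(self, n, length, stride, expected_starts):
        rec = _recording(n)
        windows = window_recording(rec, length=length, stride=stride)
        assert [w.start_index for w in windows] == expected_starts
        for w in windows:
            assert w.data.shape == (4, length)
            assert w.label == nirs_io.CLASS_IDS["slow"]
            assert w.participant_id == "p1"

    @given(n=st.integers(1, 600), length=st.integers(1, 400),
           stride=st.integers(1, 97))
    @settings(max_examples=60, deadline=None)
    def test_window_count_matches_enumeration(self, n, length, stride):
        rec = _recording(n, label=None)
        windows = window_recording(rec, length=length, stride=stride)
        brute = [s for s in range(0, n + 1) if s % stride == 0 and s + length <= n]
        assert len(windows) == len(brute)
        if n >= length:
            assert len(windows) == (n - length) // stride + 1

    def test_window_values_match_source(self):
        rec = _recording(500)
        w = window_recording(rec, length=384, stride=100)[1]
        np.testing.assert_array_equal(w.data, rec.values[:, 100:484])


def _samples(assignment):
    """One unlabelled window per (participant, index) pair."""
    out = []
    for pid, k in assignment:
        out.append(WindowedSample(data=np.zeros((1, 4)), label=None,
                                  participant_id=pid, start_index=k))
    return out


class TestSplitting:
    def test_heldout_windows_come_only_from_test_participants(self):
        samples = _samples([(f"P{i}", j) for i in range(14) for j in range(5)])
        split = split_by_participant(samples, n_test=3, seed=0)
        assert len(split.test_participants) == 3
        assert {s.participant_id for s in split.test} == split.test_participants
        assert len(split.train) == 11 * 5 and len(split.test) == 3 * 5

    def test_same_seed_same_split(self):
        samples = _samples([(f"P{i}", 0) for i in range(10)])
        a = split_by_participant(samples, test_fraction=0.3, seed=5)
        b = split_by_participant(samples, test_fraction=0.3, seed=5)
        assert a.test_participants == b.test_participants

    def test_single_participant_cannot_split(self):
        with pytest.raises(ValueError, match="2 participants"):
            split_by_participant(_samples([("only", i) for i in range(4)]),
                                 test_fraction=0.5)

    def test_explicit_ids(self):
        samples = _samples([("a", 0), ("b", 0), ("c", 0)])
        split = split_by_participant(samples, test_participants={"b"})
        assert split.test_participants == {"b"}
        assert split.train_participants == {"a", "c"}

    @given(
        assignment=st.lists(
            st.tuples(st.sampled_from("abcdefgh"), st.integers(0, 3)),
            min_size=2, max_size=40,
        ).filter(lambda a: len({p for p, _ in a}) >= 2),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_participant_disjointness_for_all_seeds(self, assignment, seed):
        split = split_by_participant(_samples(assignment), test_fraction=0.4,
                                     seed=seed)
        assert not (split.train_participants & split.test_participants)
        for s in split.train:
            assert s.participant_id in split.train_participants
        for s in split.test:
            assert s.participant_id in split.test_participants


class TestDatasetCache:
    def test_hdf5_round_trip(self, tmp_path, small_split):
        path = nirs_io.save_dataset(small_split, tmp_path / "cache.h5")
        back = nirs_io.load_dataset(path)
        assert len(back.train) == len(small_split.train)
        assert back.test_participants == small_split.test_participants
        np.testing.assert_array_equal(back.train[0].data, small_split.train[0].data)
        assert back.train[0].label == small_split.train[0].label
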