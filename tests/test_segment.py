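import numpy as np
import pytest

from evoeeg.io import EEGRecording, EventMarker
from evoeeg.segment import (
    SegmentationError, Window, WindowDataset,
    make_sliding_set, make_training_set, split_by_events, stride_for,
)

from conftest import recording_with_markers


# ---------------------------------------------------------------- oracles

def brute_sliding(n_samples, size, overlap, markers):
    """Independent enumeration: (start, label) for every sliding window."""
    stride = max(1, int(np.floor(size * (1 - overlap) + 0.5)))
    out = []
    s = 0
    while s + size <= n_samples:
        label = int(any(s <= m < s + size for m in markers))
        out.append((s, label))
        s += stride
    return out


def brute_training(n_samples, size, overlap, markers):
    """Independent enumeration: positive starts + negative starts."""
    stride = max(1, int(np.floor(size * (1 - overlap) + 0.5)))
    half = size // 2
    pos = []
    covered = set()
    for m in markers:
        start = m - half
        if start < 0 or start + size > n_samples:
            continue
        pos.append(start)
        covered.update(range(start, start + size))
    neg = []
    # walk contiguous uncovered runs
    run_start = None
    for i in range(n_samples + 1):
        free = i < n_samples and i not in covered
        if free and run_start is None:
            run_start = i
        elif not free and run_start is not None:
            run_len = i - run_start
            if run_len >= size:
                for s in range(0, run_len - size + 1, stride):
                    neg.append(run_start + s)
            run_start = None
    return pos, neg


# ---------------------------------------------------------------- stride

class TestStride:
    @pytest.mark.parametrize("size,overlap,expected", [
        (250, 0.8, 50),
        (250, 0.5, 125),
        (250, 0.0, 250),
        (250, 0.9, 25),
        (250, 0.87, 33),   # round(32.5) -> floor(32.5 + 0.5) = 33
        (10, 0.99, 1),     # clamped to >= 1
    ])
    def test_examples(self, size, overlap, expected):
        assert stride_for(size, overlap) == expected

    @pytest.mark.parametrize("overlap", [-0.1, 1.0, 1.5])
    def test_invalid_overlap_rejected(self, overlap):
        with pytest.raises(SegmentationError):
            stride_for(250, overlap)


# ---------------------------------------------------------------- sliding

class TestSlidingSet:
    def test_sixteen_windows_at_80_percent(self):
        rec = recording_with_markers(1000, [])
        ds = make_sliding_set(rec, size=250, overlap=0.8)
        assert len(ds) == 16
        assert list(ds.starts) == list(range(0, 751, 50))

    def test_seven_windows_at_50_percent(self):
        rec = recording_with_markers(1000, [])
        ds = make_sliding_set(rec, size=250, overlap=0.5)
        assert len(ds) == 7

    def test_marker_at_300_labels_exactly_its_covering_windows(self):
        rec = recording_with_markers(1000, [300])
        ds = make_sliding_set(rec, size=250, overlap=0.8)
        # start s covers 300 iff s <= 300 < s + 250, s in {0,50,...,750}
        expected = [int(s <= 300 < s + 250) for s in range(0, 751, 50)]
        assert list(ds.labels) == expected
        assert sum(expected) == 5  # one marker spans several windows

    def test_window_values_are_recording_slices(self):
        rec = recording_with_markers(700, [350], n_channels=3)
        ds = make_sliding_set(rec, size=200, overlap=0.25)
        for w in ds.windows:
            np.testing.assert_array_equal(
                w.values, rec.data[:, w.start_index:w.start_index + 200]
            )

    def test_marker_ids_index_the_markers(self):
        rec = recording_with_markers(1000, [100, 120, 800])
        ds = make_sliding_set(rec, size=250, overlap=0.0)
        # window [0,250) holds markers 0 and 1; [750,1000) holds marker 2
        assert ds.marker_ids[0] == (0, 1)
        assert ds.marker_ids[3] == (2,)
        assert ds.marker_ids[1] == () and ds.marker_ids[2] == ()

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(300, 3000))
            size = int(rng.integers(50, 260))
            overlap = float(rng.uniform(0.0, 0.95))
            n_mark = int(rng.integers(0, 8))
            marks = sorted(set(map(int, rng.integers(0, n, n_mark))))
            rec = recording_with_markers(n, marks)
            ds = make_sliding_set(rec, size=size, overlap=overlap)
            oracle = brute_sliding(n, size, overlap, marks)
            assert [(int(s), int(l)) for s, l in zip(ds.starts, ds.labels)] == oracle

    def test_size_larger_than_recording_rejected(self):
        with pytest.raises(SegmentationError):
            make_sliding_set(recording_with_markers(100, []), size=250)


# ---------------------------------------------------------------- training

class TestTrainingSet:
    def test_spec_example_one_marker_two_negatives(self):
        # 1000 samples, marker at 500, size 250: positive [375, 625);
        # runs [0,375) and [625,1000) each yield exactly one window.
        rec = recording_with_markers(1000, [500])
        ds = make_training_set(rec, size=250, overlap=0.0)
        assert list(ds.labels) == [1, 0, 0]
        assert list(ds.starts) == [375, 0, 625]

    def test_positive_windows_are_marker_centered(self):
        rec = recording_with_markers(5000, [400, 1500, 3000])
        ds = make_training_set(rec, size=250, overlap=0.5)
        pos = [w for w in ds.windows if w.label == 1]
        assert [w.start_index for w in pos] == [400 - 125, 1500 - 125, 3000 - 125]
        assert [w.marker_ids for w in pos] == [(0,), (1,), (2,)]

    def test_edge_marker_skipped_with_warning(self):
        rec = recording_with_markers(1000, [30, 500])
        with pytest.warns(UserWarning, match="marker 0"):
            ds = make_training_set(rec, size=250)
        assert int(ds.labels.sum()) == 1

    def test_negatives_exclude_all_positive_samples(self):
        rec = recording_with_markers(4000, [600, 700, 2000])  # overlapping positives
        ds = make_training_set(rec, size=250, overlap=0.6)
        covered = np.zeros(4000, dtype=bool)
        for w in ds.windows:
            if w.label == 1:
                covered[w.start_index:w.start_index + 250] = True
        for w in ds.windows:
            if w.label == 0:
                assert not covered[w.start_index:w.start_index + 250].any()

    def test_higher_overlap_never_yields_fewer_negatives(self):
        rec = recording_with_markers(6000, [1000, 3000, 5000])
        counts = []
        for overlap in (0.0, 0.3, 0.5, 0.8, 0.9):
            ds = make_training_set(rec, size=250, overlap=overlap)
            counts.append(int((ds.labels == 0).sum()))
        assert counts == sorted(counts)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(600, 4000))
            size = int(rng.integers(50, 260))
            overlap = float(rng.uniform(0.0, 0.9))
            n_mark = int(rng.integers(0, 6))
            marks = sorted(set(map(int, rng.integers(0, n, n_mark))))
            rec = recording_with_markers(n, marks)
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    ds = make_training_set(rec, size=size, overlap=overlap)
            pos_oracle, neg_oracle = brute_training(n, size, overlap, marks)
            got_pos = [int(s) for s, l in zip(ds.starts, ds.labels) if l == 1]
            got_neg = [int(s) for s, l in zip(ds.starts, ds.labels) if l == 0]
            assert got_pos == pos_oracle
            assert got_neg == neg_oracle


# ---------------------------------------------------------------- split

class TestSplitByEvents:
    @pytest.mark.parametrize("n_events,expected_train", [
        (183, 128), (218, 153), (66, 46), (27, 19),
    ])
    def test_table_event_counts(self, n_events, expected_train):
        gap = 40
        positions = [gap * (i + 1) for i in range(n_events)]
        rec = recording_with_markers(gap * (n_events + 2), positions)
        a, b = split_by_events(rec, 0.7)
        assert len(a.markers) == expected_train
        assert len(b.markers) == n_events - expected_train

    def test_split_preserves_samples_and_rebases_markers(self):
        rec = recording_with_markers(1000, [100, 300, 600, 900])
        a, b = split_by_events(rec, 0.7)  # k = round(2.8) = 3
        assert a.n_samples + b.n_samples == 1000
        cut = a.n_samples
        assert cut == (600 + 900 + 1) // 2
        assert [m.sample_index for m in a.markers] == [100, 300, 600]
        assert [m.sample_index for m in b.markers] == [900 - cut]
        np.testing.assert_array_equal(np.hstack([a.data, b.data]), rec.data)

    def test_no_markers_rejected(self):
        with pytest.raises(SegmentationError):
            split_by_events(recording_with_markers(100, []))

    def test_degenerate_all_events_in_first_part(self):
        rec = recording_with_markers(1000, [100])
        a, b = split_by_events(rec, 0.9)
        assert len(a.markers) == 1 and len(b.markers) == 0
        assert a.n_samples + b.n_samples == 1000
        assert b.n_samples >= 1


# ---------------------------------------------------------------- dataset

class TestWindowDataset:
    def test_window_label_consistency_enforced(self):
        with pytest.raises(SegmentationError):
            Window(values=np.zeros((1, 4)), label=1, start_index=0, marker_ids=())

    def test_flattened_is_channel_major(self):
        rec = recording_with_markers(500, [], n_channels=2)
        ds = make_sliding_set(rec, size=100, overlap=0.0)
        flat = ds.flattened()
        assert flat.shape == (5, 200)
        np.testing.assert_array_equal(flat[0, :100], rec.data[0, :100])
        np.testing.assert_array_equal(flat[0, 100:], rec.data[1, :100])

    def test_flattened_feature_mask_selects_columns(self):
        rec = recording_with_markers(500, [], n_channels=2)
        ds = make_sliding_set(rec, size=100, overlap=0.0)
        mask = np.zeros(200, dtype=bool)
        mask[[0, 150]] = True
        flat = ds.flattened(mask)
        assert flat.shape == (5, 2)
        np.testing.assert_array_equal(flat[:, 0], ds.values[:, 0, 0])
        np.testing.assert_array_equal(flat[:, 1], ds.values[:, 1, 50])

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(SegmentationError):
            WindowDataset(
                values=np.zeros((2, 1, 10)), labels=np.zeros(3),
                starts=np.zeros(2), marker_ids=[(), ()], size=10, overlap=0.0,
            )
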