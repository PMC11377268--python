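import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitxai import grf_io
from gaitxai.data import GaitDataset, RawRecording
from gaitxai.synthetic import GeneratorConfig, generate_pd_recording, write_gaitpdb


@pytest.fixture()
def recording_file(tmp_path):
    rec = generate_pd_recording(1234, seed=4, source_id="GaSynth_01")
    path = tmp_path / "GaSynth_01.txt"
    write_gaitpdb(rec, str(path))
    return rec, path


class TestReadGaitpdb:
    def test_small_fixture_parses_to_19_columns(self, tmp_path):
        path = tmp_path / "rec.txt"
        rows = np.column_stack([np.arange(3) * 0.01, np.ones((3, 18))])
        np.savetxt(path, rows, fmt="%.5f", delimiter="\t")
        rec = grf_io.read_gaitpdb(str(path))
        assert rec.values.shape == (3, 19)
        assert rec.sample_rate == 100.0
        assert rec.source_id == "rec"

    def test_wrong_column_count_names_the_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("\t".join(["1.0"] * 19) + "\n" + "\t".join(["1.0"] * 18) + "\n")
        with pytest.raises(ValueError, match=":2"):
            grf_io.read_gaitpdb(str(path))

    def test_non_numeric_token_raises(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("\t".join(["1.0"] * 18 + ["abc"]) + "\n")
        with pytest.raises(ValueError, match="non-numeric"):
            grf_io.read_gaitpdb(str(path))

    def test_writer_reader_round_trip_is_bit_exact(self, recording_file):
        rec, path = recording_file
        back = grf_io.read_gaitpdb(str(path))
        np.testing.assert_array_equal(back.values, rec.values)


class TestDropTimestamp:
    def test_removes_first_column_only(self, recording_file):
        rec, _ = recording_file
        out = grf_io.drop_timestamp(rec)
        assert out.values.shape[1] == 18
        np.testing.assert_array_equal(out.values, rec.values[:, 1:])

    def test_idempotent_with_warning(self, recording_file):
        rec, _ = recording_file
        once = grf_io.drop_timestamp(rec)
        with pytest.warns(UserWarning):
            twice = grf_io.drop_timestamp(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestChunk:
    @pytest.mark.parametrize("frames,expected", [(12119, 24), (999, 1), (499, 0), (0, 0)])
    def test_window_counts(self, frames, expected):
        rec = RawRecording("gaitpdb-19col", np.zeros((frames, 18)), 100.0,
                           has_timestamp=False)
        assert len(grf_io.chunk(rec, 500)) == expected

    def test_windows_are_consecutive_from_frame_zero(self):
        values = np.arange(10 * 18, dtype=float).reshape(10, 18)
        rec = RawRecording("gaitpdb-19col", values, 100.0, has_timestamp=False)
        windows = grf_io.chunk(rec, 4)
        assert [w.window_index for w in windows] == [0, 1]
        np.testing.assert_array_equal(windows[1].values, values[4:8])

    @given(st.integers(min_value=0, max_value=3000), st.integers(min_value=1, max_value=700))
    @settings(deadline=None, max_examples=40)
    def test_count_is_floor_of_frames_over_window(self, frames, window):
        rec = RawRecording("gaitpdb-19col", np.zeros((frames, 18)), 100.0,
                           has_timestamp=False)
        assert len(grf_io.chunk(rec, window)) == frames // window

    def test_round_trip_reconstructs_generator_windows(self, tmp_path):
        rec = generate_pd_recording(1500, seed=6, source_id="rt")
        path = tmp_path / "rt.txt"
        write_gaitpdb(rec, str(path))
        windows = grf_io.chunk(grf_io.drop_timestamp(grf_io.read_gaitpdb(str(path))), 500)
        assert len(windows) == 3
        np.testing.assert_array_equal(
            np.stack([w.values for w in windows]).reshape(-1, 18), rec.values[:, 1:]
        )


class TestStandardize:
    def test_hand_example_population_sd(self):
        # channel [1,2,3]: mu=2, population sd sqrt(2/3)
        ds = GaitDataset(np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1))
        out, stats = grf_io.standardize(ds)
        np.testing.assert_allclose(out.values.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert stats.theta[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_to_1e12(self, tiny_pd_dataset):
        again, _ = grf_io.standardize(tiny_pd_dataset)
        np.testing.assert_allclose(again.values, tiny_pd_dataset.values, atol=1e-12)

    def test_recomputed_stats_are_0_and_1(self, tiny_pd_dataset):
        flat = tiny_pd_dataset.values.reshape(-1, tiny_pd_dataset.n_channels)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_raises_with_indices(self):
        values = np.random.default_rng(0).normal(size=(4, 5, 3))
        values[..., 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            grf_io.standardize(GaitDataset(values))


class TestSplit:
    def _dataset(self, n=10, n_subjects=5):
        values = np.random.default_rng(0).normal(size=(n, 6, 2))
        subjects = [f"s{i % n_subjects}" for i in range(n)]
        return GaitDataset(values, labels=[0] * n, subject_ids=subjects)

    def test_60_20_20_sizes(self):
        ds = grf_io.split(self._dataset(10), (0.6, 0.2, 0.2), seed=1)
        sizes = {k: int(np.sum(ds.split == k)) for k in ("train", "val", "test")}
        assert sizes == {"train": 6, "val": 2, "test": 2}

    def test_70_10_20_supported(self):
        ds = grf_io.split(self._dataset(20), (0.7, 0.1, 0.2), seed=1)
        assert int(np.sum(ds.split == "train")) == 14

    def test_same_seed_same_assignment(self):
        a = grf_io.split(self._dataset(), seed=3).split
        b = grf_io.split(self._dataset(), seed=3).split
        np.testing.assert_array_equal(a, b)

    def test_partition_every_sample_exactly_once(self):
        ds = grf_io.split(self._dataset(17, 4), (0.6, 0.2, 0.2), seed=2)
        assert set(ds.split) <= {"train", "val", "test"}
        assert len(ds.split) == 17

    def test_subject_mode_keeps_subjects_together(self):
        ds = grf_io.split(self._dataset(20, 5), seed=2, mode="subject")
        for s in set(map(str, ds.subject_ids)):
            groups = set(ds.split[ds.subject_ids == s])
            assert len(groups) == 1

    def test_leave_one_subject_out(self):
        ds = grf_io.split(self._dataset(20, 5), (0.8, 0.2, 0.0), seed=0,
                          test_subjects=["s3"])
        test_subjects = set(map(str, ds.subject_ids[ds.split == "test"]))
        assert test_subjects == {"s3"}
        assert not np.any((ds.subject_ids == "s3") & (ds.split != "test"))

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            grf_io.split(self._dataset(), (0.5, 0.2, 0.2))

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            grf_io.split(self._dataset(2), (0.6, 0.2, 0.2))


class TestAccessionHelpers:
    def test_count_windows_on_fixture_directory(self, tmp_path):
        lengths = {"Ga01_01": 1234, "Ga02_01": 777, "Ju01_01": 600}
        for stem, n in lengths.items():
            write_gaitpdb(generate_pd_recording(n, seed=hash(stem) % 1000, source_id=stem),
                          str(tmp_path / f"{stem}.txt"))
        total, per = grf_io.count_windows(str(tmp_path), "Ga*.txt", 500)
        assert per == {"Ga01_01": 2, "Ga02_01": 1}
        assert total == 3
        total_all, _ = grf_io.count_windows(str(tmp_path), "*.txt", 500)
        assert total_all == 4

    def test_read_demographics_counts_groups(self, tmp_path):
        path = tmp_path / "demographics.txt"
        path.write_text(
            "ID\tStudy\tGroup\tHoehnYahr\n"
            "GaPt03\tGa\t1\t2.5\nGaPt04\tGa\t1\t3\nGaCo01\tGa\t2\t0\n"
            "JuPt01\tJu\t1\t2\nJuCo01\tJu\t2\t0\n"
        )
        df = grf_io.read_demographics(str(path))
        assert int((df["Group"] == 1).sum()) == 3  # patients
        assert int((df["Group"] == 2).sum()) == 2  # controls

    def test_read_demographics_requires_key_columns(self, tmp_path):
        path = tmp_path / "demographics.txt"
        path.write_text("ID\tStudy\n1\t2\n")
        with pytest.raises(ValueError, match="HoehnYahr"):
            grf_io.read_demographics(str(path))
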