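"""Domain types, readers/writers, and stream segmentation."""

import numpy as np
import pytest

from simnets import (
    EnsembleRecording,
    SpikeTrain,
    Window,
    WindowTable,
    read_json,
    read_long_table,
    read_matrix,
    segment_stream,
    write_json,
    write_long_table,
    write_matrix,
)


class TestSpikeTrain:
    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="sorted"):
            SpikeTrain([0.5, 0.2], 1.0)

    def test_rejects_out_of_window_times(self):
        with pytest.raises(ValueError, match=r"lie in \[0"):
            SpikeTrain([0.2, 1.2], 1.0)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError, match="duration"):
            SpikeTrain([0.1], 0.0)

    def test_duplicate_times_kept(self):
        t = SpikeTrain([0.3, 0.3, 0.3], 1.0)
        assert t.n_spikes == 3


class TestEnsembleRecording:
    def test_rejects_unequal_window_durations(self):
        with pytest.raises(ValueError, match="duration"):
            WindowTable([Window("a", 0, 1.0), Window("b", 1, 2.0)])

    def test_rejects_too_few_neurons_or_windows(self, toy_recording):
        with pytest.raises(ValueError, match="2 neurons"):
            EnsembleRecording(["a"], toy_recording.windows,
                              [toy_recording.trains[0]])
        with pytest.raises(ValueError, match="3 windows"):
            EnsembleRecording(
                ["a", "b"], toy_recording.windows[:2],
                [row[:2] for row in toy_recording.trains])

    def test_incomplete_grid_rejected(self, toy_recording):
        with pytest.raises(ValueError, match="expected 4 trains"):
            EnsembleRecording(["a", "b"], toy_recording.windows,
                              [toy_recording.trains[0],
                               toy_recording.trains[1][:3]])

    def test_reorder_windows_permutes_grid(self, toy_recording):
        rec = toy_recording.reorder_windows([3, 2, 1, 0])
        assert rec.window_ids == ["w3", "w2", "w1", "w0"]
        assert rec.trains[0][0].n_spikes == toy_recording.trains[0][3].n_spikes


class TestLongTable:
    def _write(self, tmp_path, text, name="spikes.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_constructive_case(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "neuron_id,window_id,spike_time_s",
            "n1,w1,0.10", "n1,w1,0.50", "n1,w2,0.20", "n1,w3,0.90",
            "n2,w1,0.30", "n2,w2,0.40", "n2,w3,0.70",
        ]))
        rec = read_long_table(p, duration_s=1.0)
        assert (rec.n_neurons, rec.n_windows) == (2, 3)
        assert rec.neuron_ids == ["n1", "n2"]
        assert rec.trains[0][0].times.tolist() == [0.10, 0.50]

    def test_out_of_bounds_spike_names_row(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "neuron_id,window_id,spike_time_s",
            "n1,w1,0.10", "n1,w2,1.20", "n2,w1,0.30", "n2,w3,0.10",
        ]))
        with pytest.raises(ValueError, match=r"row\(s\) \[3\]"):
            read_long_table(p, duration_s=1.0)

    def test_missing_pair_yields_empty_train(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "neuron_id,window_id,spike_time_s",
            "n1,w1,0.10", "n1,w2,0.20", "n1,w3,0.30",
            "n2,w1,0.40", "n2,w2,0.50",
        ]))
        rec = read_long_table(p, duration_s=1.0)
        assert rec.trains[1][2].n_spikes == 0

    def test_duplicate_rows_warn_but_kept(self, tmp_path):
        p = self._write(tmp_path, "\n".join([
            "neuron_id,window_id,spike_time_s",
            "n1,w1,0.10", "n1,w1,0.10", "n1,w2,0.20", "n1,w3,0.30",
            "n2,w1,0.40", "n2,w2,0.50", "n2,w3,0.60",
        ]))
        with pytest.warns(UserWarning, match="duplicate"):
            rec = read_long_table(p, duration_s=1.0)
        assert rec.trains[0][0].n_spikes == 2

    def test_sidecar_with_unequal_durations_names_windows(self, tmp_path):
        spikes = self._write(tmp_path, "\n".join([
            "neuron_id,window_id,spike_time_s",
            "n1,w1,0.1", "n1,w2,0.2", "n1,w3,0.3",
            "n2,w1,0.1", "n2,w2,0.2", "n2,w3,0.3",
        ]))
        sidecar = self._write(tmp_path, "\n".join([
            "window_id,start_s,duration_s",
            "w1,0,1.0", "w2,1,1.0", "w3,2,2.0",
        ]), name="windows.csv")
        with pytest.raises(ValueError, match="w3"):
            read_long_table(spikes, windows=sidecar)

    def test_round_trip_preserves_times(self, tmp_path, toy_recording):
        write_long_table(toy_recording, tmp_path / "out.csv",
                         windows_path=tmp_path / "win.csv")
        rec = read_long_table(tmp_path / "out.csv",
                              windows=tmp_path / "win.csv")
        assert rec.neuron_ids == toy_recording.neuron_ids
        assert rec.total_spikes() == toy_recording.total_spikes()
        for row_a, row_b in zip(rec.trains, toy_recording.trains):
            for a, b in zip(row_a, row_b):
                assert np.allclose(a.times, b.times, atol=1e-9)


class TestJsonDocument:
    def test_round_trip(self, tmp_path, toy_recording):
        write_json(toy_recording, tmp_path / "rec.json")
        rec = read_json(tmp_path / "rec.json")
        assert rec.window_ids == toy_recording.window_ids
        for row_a, row_b in zip(rec.trains, toy_recording.trains):
            for a, b in zip(row_a, row_b):
                assert np.allclose(a.times, b.times, atol=1e-9)


class TestSegmentStream:
    def test_spikes_re_referenced_to_window_start(self):
        windows = [Window(f"w{j}", start_s=float(j), duration_s=1.0)
                   for j in range(3)]
        rec = segment_stream(
            {"n1": [0.5, 1.5, 2.5], "n2": [0.25, 1.75, 2.25]}, windows)
        assert [tr.times.tolist() for tr in rec.trains[0]] == [[0.5]] * 3

    def test_window_beyond_last_spike_is_empty(self):
        windows = [Window(f"w{j}", start_s=float(j), duration_s=1.0)
                   for j in range(3)]
        rec = segment_stream({"n1": [0.5], "n2": [0.1]}, windows)
        assert rec.trains[0][2].n_spikes == 0

    def test_boundary_spike_goes_to_following_window(self):
        windows = [Window(f"w{j}", start_s=float(j), duration_s=1.0)
                   for j in range(3)]
        rec = segment_stream({"n1": [1.0], "n2": [2.0]}, windows)
        assert rec.trains[0][0].n_spikes == 0
        assert rec.trains[0][1].times.tolist() == [0.0]

    def test_disjoint_cover_conserves_spikes(self):
        rng = np.random.default_rng(11)
        stream = np.sort(rng.uniform(0, 5, size=100))
        stream = stream[stream < 5.0]
        windows = [Window(f"w{j}", start_s=float(j), duration_s=1.0)
                   for j in range(5)]
        rec = segment_stream({"n1": stream, "n2": stream[:10]}, windows)
        assert sum(t.n_spikes for t in rec.trains[0]) == stream.size

    def test_unsorted_stream_rejected(self):
        windows = [Window(f"w{j}", start_s=float(j), duration_s=1.0)
                   for j in range(3)]
        with pytest.raises(ValueError, match="sorted"):
            segment_stream({"n1": [1.0, 0.5], "n2": [0.1]}, windows)


class TestMatrixIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 5, (4, 4))
        m = m + m.T
        write_matrix(m, tmp_path / "m.csv", ids=list("abcd"))
        values, ids = read_matrix(tmp_path / "m.csv")
        assert ids == list("abcd")
        assert np.allclose(values, m, atol=1e-9)

    def test_nonfinite_rejected(self, tmp_path):
        m = np.zeros((3, 3))
        m[0, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            write_matrix(m, tmp_path / "m.csv")

    def test_nonsquare_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="square"):
            write_matrix(np.zeros((2, 3)), tmp_path / "m.csv")
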