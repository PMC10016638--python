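import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afrisk.ingest import (
    BeatSeries,
    CorruptSeriesError,
    Dialect,
    clean_artifacts,
    label_premature_beats,
    read_rr_table,
    segment_hours,
    write_rr_table,
)
from afrisk.synth import SinusParams, inject_artifacts, inject_pacs, simulate_sinus

from conftest import series_from_rr


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_cumulative_time_from_rr(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("rr_ms\n800\n810\n790\n")
        s = read_rr_table(p, Dialect(t_col=None))
        assert np.allclose(s.t, [0.0, 0.81, 1.60])
        assert np.allclose(s.rr, [800, 810, 790])
        assert list(s.labels) == ["U", "U", "U"]

    def test_units_seconds_identical(self, tmp_path):
        p1 = tmp_path / "ms.csv"
        p1.write_text("rr_ms\n800\n810\n790\n")
        p2 = tmp_path / "s.csv"
        p2.write_text("rr\n0.8\n0.81\n0.79\n")
        a = read_rr_table(p1, Dialect(t_col=None))
        b = read_rr_table(p2, Dialect(t_col=None, rr_col="rr", rr_units="s"))
        assert np.allclose(a.rr, b.rr)
        assert np.allclose(a.t, b.t)

    def test_roundtrip_two_hour_series(self, tmp_path):
        s = simulate_sinus(SinusParams(), 7200, seed=5, patient_id="rt")
        p = tmp_path / "rt.csv"
        write_rr_table(s, p)
        back = read_rr_table(p)
        assert back.equals(s)
        assert back.start_day == s.start_day
        assert back.start_hour == s.start_hour

    def test_write_read_write_byte_identical(self, tmp_path):
        s = simulate_sinus(SinusParams(), 300, seed=2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_rr_table(s, p1)
        write_rr_table(read_rr_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unlabeled_series_writes_U(self, tmp_path):
        s = series_from_rr([800.0] * 10, labels=["U"] * 10)
        p = tmp_path / "u.csv"
        write_rr_table(s, p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 11  # header + 10 rows
        assert all(line.endswith(",U") for line in lines[1:])

    def test_nonpositive_rr_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "bad.csv"
        p.write_text("rr_ms\n" + "\n".join(["800"] * 40 + ["-5"]))
        with caplog.at_level("WARNING"):
            s = read_rr_table(p, Dialect(t_col=None))
        assert s.n_beats == 40
        assert any("rejected" in r.message for r in caplog.records)

    def test_too_many_bad_rows_is_corrupt(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("rr_ms\n" + "\n".join(["800", "-1"] * 10))
        with pytest.raises(CorruptSeriesError, match="corrupt series"):
            read_rr_table(p, Dialect(t_col=None))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_rr_table(tmp_path / "nope.csv")

    @settings(max_examples=30, deadline=None)
    @given(
        rr=st.lists(
            st.floats(min_value=300.0, max_value=2000.0, allow_nan=False),
            min_size=2,
            max_size=60,
        ),
        labels=st.lists(st.sampled_from("NAVXU"), min_size=60, max_size=60),
    )
    def test_roundtrip_lossless_property(self, tmp_path_factory, rr, labels):
        s = series_from_rr(rr, labels=labels[: len(rr)])
        p = tmp_path_factory.mktemp("rt") / "s.csv"
        write_rr_table(s, p)
        assert read_rr_table(p).equals(s)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

class TestCleanArtifacts:
    def test_short_rr_removed(self):
        rr = [800.0] * 50
        rr[20] = 150.0
        s = series_from_rr(rr)
        cleaned, report = clean_artifacts(s)
        assert report.n_removed == 1
        assert cleaned.n_beats == 49
        assert np.all(cleaned.rr >= 300)

    def test_clean_series_identity(self):
        s = simulate_sinus(SinusParams(), 600, seed=3)
        cleaned, report = clean_artifacts(s)
        assert report.n_removed == 0
        assert cleaned.equals(s)

    def test_injected_artifacts_exactly_removed(self):
        s = simulate_sinus(SinusParams(), 3600, seed=4)
        corrupted, idx = inject_artifacts(s, 10, seed=9)
        cleaned, report = clean_artifacts(corrupted)
        assert report.n_removed == 10
        kept_t = set(np.delete(corrupted.t, idx))
        assert set(cleaned.t) == kept_t

    def test_idempotent(self):
        s = simulate_sinus(SinusParams(), 1800, seed=6)
        corrupted, _ = inject_artifacts(s, 8, seed=2)
        once, _ = clean_artifacts(corrupted)
        twice, report2 = clean_artifacts(once)
        assert report2.n_removed == 0
        assert twice.equals(once)

    def test_x_labels_removed(self):
        labels = ["N"] * 30
        labels[5] = "X"
        s = series_from_rr([800.0] * 30, labels=labels)
        cleaned, report = clean_artifacts(s)
        assert report.n_removed == 1
        assert "X" not in cleaned.labels

    def test_heavy_loss_hour_flagged(self):
        rr = [800.0] * 200
        for i in range(3, 180, 3):
            rr[i] = 150.0  # ~33% of the hour is artifact
        s = series_from_rr(rr)
        cleaned, report = clean_artifacts(s)
        assert 0 in report.flagged_hours
        segs = segment_hours(cleaned, min_beats=10)
        assert not segs[0].analyzable


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentHours:
    def test_two_hours(self):
        s = simulate_sinus(SinusParams(), 7200, seed=1)
        segs = segment_hours(s)
        assert sum(g.analyzable for g in segs) == 2

    def test_half_open_convention(self):
        t = np.array([3599.2, 3600.0, 3600.8])
        rr = np.array([800.0, 800.0, 800.0])
        s = BeatSeries("T", t, rr, np.array(["N"] * 3))
        segs = segment_hours(s, min_beats=1)
        by_index = {g.segment_index: g for g in segs}
        assert by_index[0].n_beats == 1
        assert by_index[1].n_beats == 2  # beat at exactly 3600.0 goes to segment 1

    def test_partition_of_24h_recording(self):
        s = simulate_sinus(SinusParams(), 24 * 3600, seed=8)
        segs = segment_hours(s)
        assert len(segs) == 24 or len(segs) == 25  # possible sliver at the end
        assert sum(g.n_beats for g in segs) == s.n_beats
        rebuilt = np.concatenate([g.t for g in segs])
        assert np.array_equal(rebuilt, s.t)

    def test_day_index(self):
        s = simulate_sinus(SinusParams(), 3 * 3600, seed=1, start_day=1, start_hour=23.0)
        segs = segment_hours(s)
        assert [g.day for g in segs[:3]] == [1, 2, 2]


# ---------------------------------------------------------------------------
# premature-beat labeling
# ---------------------------------------------------------------------------

class TestLabelPrematureBeats:
    def test_textbook_pac(self):
        rr = [800.0] * 20
        rr[10], rr[11] = 520.0, 1050.0
        s = series_from_rr(rr, labels=["U"] * 20)
        out = label_premature_beats(s)
        assert out.labels[10] == "A"
        assert np.sum(out.labels == "A") == 1

    def test_constant_series_untouched(self):
        s = series_from_rr([800.0] * 100, labels=["U"] * 100)
        out = label_premature_beats(s)
        assert np.sum(out.labels == "A") == 0

    def test_already_labeled_untouched(self):
        rr = [800.0] * 20
        rr[10], rr[11] = 520.0, 1050.0
        s = series_from_rr(rr, labels=["V"] * 20)
        out = label_premature_beats(s)
        assert np.sum(out.labels == "A") == 0

    def test_generator_recovery(self):
        sinus = simulate_sinus(SinusParams(), 3600, seed=11)
        injected, pac_t = inject_pacs(sinus, 30.0, seed=12)
        n_true = int(np.sum(injected.labels == "A"))
        assert n_true >= 10
        relabeled = label_premature_beats(injected.strip_labels())
        truth = injected.labels == "A"
        found = relabeled.labels == "A"
        recovered = int(np.sum(truth & found))
        false_marks = int(np.sum(found & ~truth))
        assert recovered >= 0.9 * n_true
        assert false_marks <= 2
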