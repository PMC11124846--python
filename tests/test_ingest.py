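"""Ingestion and cleaning rules: readers, clip filter, joins, summaries."""

import numpy as np
import pandas as pd
import pytest

import ethoacc as ea
from ethoacc.behaviors import VocabularyError
from ethoacc.core import BehaviorBout, DataError, write_bouts_csv
from ethoacc.ingest import (
    MismatchRules,
    SchemaError,
    filter_video_clips,
    flag_signal_mismatch,
    join_labels,
    nearest_gps_join,
    read_observations,
    read_signal_csv,
    seconds_to_hours,
    summarize_ethogram,
)


class TestReadSignalCsv:
    def test_roundtrip_of_a_wellformed_file(self, resting_frame, tmp_path):
        path = tmp_path / "sig.csv"
        resting_frame.to_csv(path)
        frames = read_signal_csv(path)
        assert len(frames) == 1
        f = frames[0]
        assert f.n_samples == resting_frame.n_samples
        assert f.sample_rate == pytest.approx(40.0, rel=1e-3)
        assert np.allclose(f.az, resting_frame.az)

    def test_gap_splits_into_two_frames(self, tmp_path):
        t = np.concatenate([np.arange(0, 10, 0.025), np.arange(15, 25, 0.025)])
        df = pd.DataFrame(
            {
                "animal_id": "s1",
                "timestamp_utc": t,
                "ax_g": 0.0,
                "ay_g": 0.0,
                "az_g": 1.0,
            }
        )
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        frames = read_signal_csv(path)
        assert len(frames) == 2
        assert frames[0].n_samples == 400 and frames[1].n_samples == 400

    def test_duplicate_timestamp_names_the_row(self, tmp_path):
        t = np.arange(0, 2, 0.025)
        t[10] = t[9]
        df = pd.DataFrame(
            {"animal_id": "s1", "timestamp_utc": t, "ax_g": 0.0, "ay_g": 0.0, "az_g": 1.0}
        )
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match="row 10"):
            read_signal_csv(path)

    def test_missing_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"animal_id": ["s1"], "timestamp_utc": [0.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="ax_g"):
            read_signal_csv(path)


class TestReadObservations:
    def test_labels_are_normalized(self, tmp_path):
        path = tmp_path / "obs.csv"
        pd.DataFrame(
            {
                "animal_id": ["s1"],
                "start_utc": [0.0],
                "end_utc": [30.0],
                "behavior": ["  Grazing "],
                "source": ["In_Pasture"],
            }
        ).to_csv(path, index=False)
        bouts = read_observations(path)
        assert bouts[0].behavior == "grazing"
        assert bouts[0].source == "in_pasture"

    def test_unknown_label_rejected_by_name(self, tmp_path):
        path = tmp_path / "obs.csv"
        pd.DataFrame(
            {
                "animal_id": ["s1"],
                "start_utc": [0.0],
                "end_utc": [30.0],
                "behavior": ["flying"],
                "source": ["in_pasture"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(VocabularyError, match="flying"):
            read_observations(path)

    def test_overlapping_bouts_rejected(self, tmp_path):
        path = tmp_path / "obs.csv"
        pd.DataFrame(
            {
                "animal_id": ["s1", "s1"],
                "start_utc": [0.0, 20.0],
                "end_utc": [30.0, 50.0],
                "behavior": ["grazing", "walking"],
                "source": ["in_pasture", "in_pasture"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(DataError, match="overlap"):
            read_observations(path)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text("animal_id,start_utc,end_utc,behavior,source\n")
        assert read_observations(path) == []

    def test_bout_csv_roundtrip(self, tmp_path):
        bouts = [
            BehaviorBout("s1", 0.0, 30.0, "grazing", "in_pasture"),
            BehaviorBout("s1", 30.0, 45.0, "resting", "collar_video", clip_id="c1"),
        ]
        path = tmp_path / "obs.csv"
        write_bouts_csv(bouts, path)
        back = read_observations(path)
        assert back == bouts


def clip(animal, start, behaviors_and_ends, clip_id=None):
    """Build a 15-s collar-video clip from (behavior, end_offset) pieces."""
    out, t = [], start
    for behavior, end in behaviors_and_ends:
        out.append(
            BehaviorBout(animal, t, start + end, behavior, "collar_video", clip_id=clip_id)
        )
        t = start + end
    return out


class TestFilterVideoClips:
    def test_mixed_clip_removed_entirely(self):
        bouts = clip("s1", 0.0, [("grazing", 8.0), ("walking", 15.0)])
        kept, removed = filter_video_clips(bouts)
        assert kept == [] and len(removed) == 2

    def test_pure_clip_kept(self):
        bouts = clip("s1", 0.0, [("resting", 15.0)])
        kept, removed = filter_video_clips(bouts)
        assert len(kept) == 1 and removed == []

    def test_counts_partition_the_input(self):
        bouts = []
        for i in range(10):
            start = i * 3600.0
            if i < 3:  # mixed clips
                bouts.extend(clip("s1", start, [("grazing", 7.0), ("resting", 15.0)]))
            else:
                bouts.extend(clip("s1", start, [("ruminating", 15.0)]))
        kept, removed = filter_video_clips(bouts)
        kept_clips = len(kept)
        removed_clips = len({b.start_utc // 3600 for b in removed})
        assert kept_clips == 7 and removed_clips == 3
        assert sorted(kept + removed, key=lambda b: b.start_utc) == sorted(
            bouts, key=lambda b: b.start_utc
        )

    def test_in_pasture_bouts_pass_through(self):
        bouts = [BehaviorBout("s1", 0.0, 8.0, "grazing", "in_pasture"),
                 BehaviorBout("s1", 8.0, 20.0, "walking", "in_pasture")]
        kept, removed = filter_video_clips(bouts)
        assert kept == bouts and removed == []

    def test_explicit_clip_ids_group_non_contiguous_bouts(self):
        bouts = clip("s1", 0.0, [("grazing", 8.0), ("walking", 15.0)], clip_id="c9")
        kept, removed = filter_video_clips(bouts)
        assert kept == [] and len(removed) == 2


class TestJoinLabels:
    def test_frame_fully_inside_bout(self, resting_frame):
        bouts = [BehaviorBout("s1", -10.0, 100.0, "grazing")]
        epochs = join_labels(resting_frame, bouts)
        assert len(epochs) == 60
        assert (epochs["behavior"] == "grazing").all()

    def test_partial_overlap_counts_whole_seconds(self, resting_frame):
        bouts = [BehaviorBout("s1", 50.0, 100.0, "walking")]
        epochs = join_labels(resting_frame, bouts)
        assert len(epochs) == 10
        assert epochs["epoch_utc"].min() == 50

    def test_disjoint_bout_warns_and_returns_empty(self, resting_frame):
        bouts = [BehaviorBout("s1", 500.0, 600.0, "walking")]
        with pytest.warns(UserWarning):
            epochs = join_labels(resting_frame, bouts)
        assert len(epochs) == 0

    def test_epoch_count_bounded_by_signal_and_bout_seconds(self, small_herd):
        frames, schedule, epochs = small_herd
        signal_s = sum(int(f.duration) for f in frames)
        bout_s = sum(b.duration for b in schedule)
        assert len(epochs) <= min(signal_s, bout_s)
        assert not epochs.duplicated(["animal_id", "epoch_utc"]).any()


class TestFlagSignalMismatch:
    def make_labeled(self, behavior, frame):
        return join_labels(
            frame, [BehaviorBout(frame.animal_id, frame.t[0], frame.t[0] + frame.duration, behavior)]
        )

    def test_true_grazing_not_flagged(self):
        sched = [BehaviorBout("s1", 0.0, 60.0, "grazing")]
        frame = ea.synthesize_signal(sched, seed=0)
        flagged = flag_signal_mismatch(frame, self.make_labeled("grazing", frame))
        assert not flagged["flagged"].any()

    def test_grazing_label_on_resting_trace_flagged(self):
        sched = [BehaviorBout("s1", 0.0, 60.0, "resting")]
        frame = ea.synthesize_signal(sched, seed=0)  # upright, quiescent
        flagged = flag_signal_mismatch(frame, self.make_labeled("grazing", frame))
        assert flagged["flagged"].all()
        assert (flagged["flag_reason"] == "grazing_static_x_low").all()

    def test_disabled_rules_flag_nothing(self):
        sched = [BehaviorBout("s1", 0.0, 60.0, "resting")]
        frame = ea.synthesize_signal(sched, seed=0)
        flagged = flag_signal_mismatch(
            frame, self.make_labeled("grazing", frame), MismatchRules.disabled()
        )
        assert not flagged["flagged"].any()


class TestNearestGpsJoin:
    def fixes(self, animal="s1", times=(0.0,)):
        return pd.DataFrame(
            {
                "animal_id": animal,
                "timestamp_utc": list(times),
                "lon": np.linspace(-97.3, -97.29, len(times)),
                "lat": np.linspace(34.17, 34.18, len(times)),
            }
        )

    def test_nearest_fix_with_signed_offset(self):
        bout = BehaviorBout("s1", 90.0, 110.0, "grazing")  # midpoint 100
        out = nearest_gps_join([bout], self.fixes(times=(40.0, 220.0)))
        assert out["fix_dt"].iloc[0] == -60.0

    def test_exact_tie_goes_to_earlier_fix(self):
        bout = BehaviorBout("s1", 90.0, 110.0, "grazing")
        out = nearest_gps_join([bout], self.fixes(times=(40.0, 160.0)))
        assert out["fix_dt"].iloc[0] == -60.0

    def test_single_fix_always_chosen(self):
        bout = BehaviorBout("s1", 5000.0, 5100.0, "grazing")
        out = nearest_gps_join([bout], self.fixes(times=(0.0,)))
        assert out["fix_dt"].iloc[0] == pytest.approx(-5050.0)

    def test_missing_animal_is_an_error(self):
        bout = BehaviorBout("s2", 0.0, 10.0, "grazing")
        with pytest.raises(DataError, match="s2"):
            nearest_gps_join([bout], self.fixes())

    def test_offset_is_minimal_by_brute_force(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 10_000, 40))
        fixes = self.fixes(times=times)
        bouts = [
            BehaviorBout("s1", s, s + 30.0, "grazing")
            for s in rng.uniform(0, 10_000, 25)
        ]
        out = nearest_gps_join(bouts, fixes)
        for b, dt in zip(bouts, out["fix_dt"]):
            assert abs(dt) == pytest.approx(np.min(np.abs(times - b.midpoint)))


class TestSummarizeEthogram:
    def test_single_behavior_is_hundred_percent(self):
        epochs = pd.DataFrame(
            {
                "animal_id": "s1",
                "epoch_utc": range(50),
                "behavior": "resting",
                "source": "in_pasture",
            }
        )
        summary = summarize_ethogram(epochs)
        assert summary.percent("resting") == 100.0

    def test_percentages_sum_to_about_hundred(self, small_herd):
        _, _, epochs = small_herd
        summary = summarize_ethogram(epochs)
        assert summary.overall["percent"].sum() == pytest.approx(100.0, abs=0.2)
        assert summary.overall["seconds"].sum() == len(epochs)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_ethogram(pd.DataFrame(columns=["behavior", "epoch_utc"]))

    def test_hours_conversion_rounds_at_one_decimal(self):
        assert seconds_to_hours(5400) == 1.5
        assert seconds_to_hours(5310) == 1.5  # 1.475 h rounds half-up
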