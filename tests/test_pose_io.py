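import json

import numpy as np
import pytest

from skelquant.pose_io import (
    read_openpose_sequence,
    read_sequence_csv,
    repair_missing_joints,
    select_primary_person,
    write_openpose_json,
    write_sequence_csv,
)
from skelquant.skeleton import ADHD, NON_ADHD, N_JOINTS

from tests.conftest import random_sequence


def _write_frame(directory, index, people):
    path = directory / f"video_{index:06d}_keypoints.json"
    path.write_text(json.dumps({"version": 1.3, "people": people}))
    return path


def _person(rng, conf=0.9):
    kp = np.zeros((N_JOINTS, 3))
    kp[:, :2] = rng.uniform(10, 500, (N_JOINTS, 2))
    kp[:, 2] = conf
    return kp


class TestReadOpenpose:
    def test_single_person_field_mapping(self, tmp_path):
        numbers = [float(i) for i in range(75)]
        numbers[2::3] = [0.9] * 25  # confidences
        _write_frame(tmp_path, 0, [{"pose_keypoints_2d": numbers}])
        seq = read_openpose_sequence(tmp_path, "s", NON_ADHD)
        # joint 1 carries the 4th-6th numbers of the flat list
        assert seq.xy[0, 1, 0] == numbers[3]
        assert seq.xy[0, 1, 1] == numbers[4]
        assert seq.confidence[0, 1] == numbers[5]

    def test_empty_people_yields_all_missing(self, tmp_path, rng):
        _write_frame(tmp_path, 0, [{"pose_keypoints_2d": _person(rng).ravel().tolist()}])
        _write_frame(tmp_path, 1, [])
        seq = read_openpose_sequence(tmp_path, "s", NON_ADHD)
        assert seq.n_frames == 2
        assert seq.missing[1].all()
        assert not seq.missing[0].any()

    def test_files_sort_by_numeric_suffix(self, tmp_path, rng):
        # deliberately out of lexicographic order
        for idx in (2, 10, 1):
            person = _person(rng)
            person[:, 0] = idx  # x encodes the frame number
            _write_frame(tmp_path, idx, [{"pose_keypoints_2d": person.ravel().tolist()}])
        seq = read_openpose_sequence(tmp_path, "s", NON_ADHD)
        assert list(seq.frame_indices) == [1, 2, 10]
        assert list(seq.xy[:, 0, 0]) == [1, 2, 10]

    def test_malformed_json_names_file(self, tmp_path):
        bad = tmp_path / "frame_000001.json"
        bad.write_text("{not json")
        with pytest.raises(ValueError, match="frame_000001"):
            read_openpose_sequence(tmp_path, "s", NON_ADHD)

    def test_bad_keypoint_length_names_file(self, tmp_path):
        _write_frame(tmp_path, 0, [{"pose_keypoints_2d": [1.0] * 74}])
        with pytest.raises(ValueError, match="multiple of 75"):
            read_openpose_sequence(tmp_path, "s", NON_ADHD)

    def test_unsortable_filename_is_an_error(self, tmp_path):
        (tmp_path / "nonumber.json").write_text("{}")
        with pytest.raises(ValueError, match="frame number"):
            read_openpose_sequence(tmp_path, "s", NON_ADHD)

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no JSON files"):
            read_openpose_sequence(tmp_path, "s", NON_ADHD)

    def test_round_trip_json(self, tmp_path, rng):
        seq = random_sequence(rng, n_frames=6, missing_prob=0.15, label=ADHD)
        write_openpose_json(seq, tmp_path)
        back = read_openpose_sequence(
            tmp_path, seq.subject_id, seq.label, seq.frame_rate, seq.frame_size
        )
        assert seq.equals(back)


class TestSelectPrimaryPerson:
    def test_single_candidate_returned(self, rng):
        cand = _person(rng)
        assert np.array_equal(select_primary_person([cand]), cand)

    def test_nearest_to_previous_wins(self, rng):
        previous = _person(rng)
        near = previous.copy()
        near[:, :2] += 3.0  # mean distance sqrt(18) ~ 4.24
        far = previous.copy()
        far[:, :2] += 60.0
        chosen = select_primary_person([far, near], previous)
        assert np.array_equal(chosen, near)

    def test_without_previous_highest_total_confidence_wins(self, rng):
        strong = _person(rng, conf=20.1 / 25)
        weak = _person(rng, conf=3.2 / 25)
        assert np.array_equal(select_primary_person([strong, weak]), strong)
        assert np.array_equal(select_primary_person([weak, strong]), strong)

    def test_permutation_invariant_up_to_ties(self, rng):
        previous = _person(rng)
        cands = [_person(rng) for _ in range(4)]
        baseline = select_primary_person(cands, previous)
        for _ in range(5):
            perm = [cands[i] for i in rng.permutation(4)]
            assert np.array_equal(select_primary_person(perm, previous), baseline)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_primary_person([])


class TestRepairMissingJoints:
    def _seq_with_gap(self, rng, joint, start, length, n_frames=30):
        seq = random_sequence(rng, n_frames=n_frames, missing_prob=0.0)
        seq.confidence[start : start + length, joint] = 0.0
        seq.xy[start : start + length, joint] = 0.0
        return seq

    def test_midpoint_interpolation(self, rng):
        seq = self._seq_with_gap(rng, joint=4, start=11, length=1)
        seq.xy[10, 4] = (100.0, 50.0)
        seq.xy[12, 4] = (104.0, 58.0)
        seq.confidence[10, 4] = 0.8
        seq.confidence[12, 4] = 0.6
        repaired, report = repair_missing_joints(seq, max_gap=5)
        assert repaired.xy[11, 4, 0] == pytest.approx(102.0)
        assert repaired.xy[11, 4, 1] == pytest.approx(54.0)
        assert repaired.confidence[11, 4] == pytest.approx(0.6)
        assert report.loc[report.joint == 4, "n_filled"].item() == 1

    def test_long_run_left_untouched_but_reported(self, rng):
        seq = self._seq_with_gap(rng, joint=7, start=10, length=7)
        repaired, report = repair_missing_joints(seq, max_gap=5)
        assert repaired.missing[10:17, 7].all()
        row = report.loc[report.joint == 7]
        assert row["n_unfilled"].item() == 7
        assert row["n_filled"].item() == 0

    def test_runs_touching_sequence_ends_stay_missing(self, rng):
        seq = self._seq_with_gap(rng, joint=3, start=0, length=2)
        repaired, _ = repair_missing_joints(seq, max_gap=5)
        assert repaired.missing[0:2, 3].all()

    def test_fully_present_sequence_is_identity(self, rng):
        seq = random_sequence(rng, missing_prob=0.0)
        repaired, report = repair_missing_joints(seq)
        assert seq.equals(repaired)
        assert report["n_filled"].sum() == 0

    def test_never_alters_detected_joints_nor_adds_missing(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, n_frames=40, missing_prob=0.3)
            repaired, _ = repair_missing_joints(seq, max_gap=int(rng.integers(0, 8)))
            present = ~seq.missing
            assert np.array_equal(seq.xy[present], repaired.xy[present])
            assert np.array_equal(seq.confidence[present], repaired.confidence[present])
            assert repaired.missing.sum() <= seq.missing.sum()


class TestSequenceCsv:
    def test_round_trip(self, tmp_path, rng):
        seq = random_sequence(rng, n_frames=3, missing_prob=0.2, label=ADHD)
        path = tmp_path / "seq.csv"
        write_sequence_csv(seq, path)
        assert seq.equals(read_sequence_csv(path))

    def test_three_frames_give_75_rows(self, tmp_path, rng):
        seq = random_sequence(rng, n_frames=3, missing_prob=0.0)
        path = tmp_path / "seq.csv"
        write_sequence_csv(seq, path)
        rows = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == 1 + 3 * 25  # header + data

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_sequence_csv(path)

    def test_missing_column_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,frame,joint,x,y\ns,0,0,1,2\n")
        with pytest.raises(ValueError, match="confidence"):
            read_sequence_csv(path, label=NON_ADHD)
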