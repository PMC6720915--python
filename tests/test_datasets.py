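import itertools
import json

import numpy as np
import pytest

from pollenstack.cht import ScoredProposal
from pollenstack.datasets import (
    AnnotationError,
    AnnotationSet,
    SampleRecord,
    read_annotations,
    read_proposals,
    scale_sample,
    split_train_test,
    write_annotations,
    write_proposals,
)
from pollenstack.evaluation import GroundTruthGrain
from pollenstack.fusion import Sample
from pollenstack.geometry import Box, iou


def make_annotations():
    rec = SampleRecord(
        sample_id="s0", slide_id="sl0", pollen_type="spA",
        width=640, height=512, n_frames=5,
        frame_files=[f"frames/s0/frame_{i:03d}.png" for i in range(5)],
        frames_of_interest=[2, 3],
    )
    grains = [
        GroundTruthGrain("g0", "s0", Box(10, 10, 60, 60), "spA", 2),
        GroundTruthGrain("g1", "s0", Box(0, 100, 30, 160), "spA", 3, fully_visible=False),
    ]
    return AnnotationSet(samples=[rec], grains=grains)


class TestAnnotationsRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        ann = make_annotations()
        path = tmp_path / "annotations.json"
        write_annotations(ann, path)
        back = read_annotations(path)
        assert back.samples == ann.samples
        assert back.grains == ann.grains

    def test_empty_set_is_valid(self, tmp_path):
        path = tmp_path / "empty.json"
        write_annotations(AnnotationSet(), path)
        back = read_annotations(path)
        assert back.samples == [] and back.grains == []

    def test_dangling_sample_reference_named_in_error(self):
        ann = make_annotations()
        ann.grains.append(GroundTruthGrain("g9", "missing", Box(0, 0, 5, 5), "x", 0))
        with pytest.raises(AnnotationError, match="g9"):
            ann.validate()

    def test_out_of_range_frame_index_rejected(self):
        ann = make_annotations()
        ann.grains.append(GroundTruthGrain("g9", "s0", Box(0, 0, 5, 5), "x", 99))
        with pytest.raises(AnnotationError, match="frame_index"):
            ann.validate()

    def test_duplicate_grain_id_rejected(self):
        ann = make_annotations()
        ann.grains.append(ann.grains[0])
        with pytest.raises(AnnotationError, match="duplicate"):
            ann.validate()

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema": "other/9", "samples": [], "grains": []}))
        with pytest.raises(AnnotationError, match="schema"):
            read_annotations(path)


class TestProposalsIO:
    def test_round_trip(self, tmp_path):
        props = {
            "s0": [ScoredProposal(Box(1, 2, 3, 4), 0.5, 7)],
            "s1": [ScoredProposal(Box(0, 0, 10, 10), 0.9, 0),
                   ScoredProposal(Box(5, 5, 9, 9), 0.25, 3)],
        }
        path = tmp_path / "props.jsonl"
        write_proposals(props, path)
        back = read_proposals(path)
        assert back == props

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"sample_id": "s0", "frame_index": 0}\n')
        with pytest.raises(AnnotationError, match=":1:"):
            read_proposals(path)


class TestScaleSample:
    def make_sample(self, w=1280, h=1024, n=2):
        frames = [np.full((h, w, 3), 200, np.uint8) for _ in range(n)]
        return Sample("s0", "sl", "spA", frames, w, h)

    def test_canonical_half_scaling_of_boxes(self):
        sample = self.make_sample()
        grains = [GroundTruthGrain("g0", "s0", Box(100, 100, 300, 300), "spA", 0)]
        scaled, sg = scale_sample(sample, grains, target=(640, 512))
        assert scaled.width == 640 and scaled.height == 512
        assert scaled.frames[0].shape == (512, 640, 3)
        assert sg[0].box.as_tuple() == pytest.approx((50, 50, 150, 150))

    def test_identity_target_unchanged(self):
        sample = self.make_sample(100, 80)
        grains = [GroundTruthGrain("g0", "s0", Box(5, 5, 20, 20), "spA", 0)]
        scaled, sg = scale_sample(sample, grains, target=(100, 80))
        assert (scaled.frames[0] == sample.frames[0]).all()
        assert sg[0].box == grains[0].box

    def test_iou_invariant_under_uniform_scaling(self, rng):
        sample = self.make_sample(100, 100, n=1)
        for _ in range(50):
            x = np.sort(rng.uniform(0, 99, 2)); y = np.sort(rng.uniform(0, 99, 2))
            a = Box(x[0], y[0], x[1] + 1, y[1] + 1)
            x = np.sort(rng.uniform(0, 99, 2)); y = np.sort(rng.uniform(0, 99, 2))
            b = Box(x[0], y[0], x[1] + 1, y[1] + 1)
            ga = GroundTruthGrain("a", "s0", a, "sp", 0)
            gb = GroundTruthGrain("b", "s0", b, "sp", 0)
            _, scaled = scale_sample(sample, [ga, gb], target=(50, 50))
            assert iou(scaled[0].box, scaled[1].box) == pytest.approx(iou(a, b))


class TestSplitTrainTest:
    def test_single_sample_goes_to_train(self):
        r = split_train_test([("s0", "spA", 5)])
        assert r.train_sample_ids == ["s0"] and r.test_sample_ids == []

    def test_empty_input(self):
        r = split_train_test([])
        assert r.train_grains == 0 and r.test_grains == 0

    def test_greedy_trace_hits_exact_ratio(self):
        # Counts [5,3,1,1]: greedy assigns 5→train, 3→test, 1→test, 1→train,
        # reaching exactly 6/10 = 0.60.
        samples = [("a", "t", 5), ("b", "t", 3), ("c", "t", 1), ("d", "t", 1)]
        r = split_train_test(samples)
        assert r.train_grains == 6 and r.test_grains == 4
        assert set(r.train_sample_ids) == {"a", "d"}
        # No other assignment that respects the sorted order does better.
        best = min(
            abs((5 * m[0] + 3 * m[1] + m[2] + m[3]) / 10 - 0.6)
            for m in itertools.product([0, 1], repeat=4)
        )
        assert abs(r.train_share - 0.6) <= best + 1e-12

    def test_balance_bound_per_type_on_random_profiles(self, rng):
        # Achieved train share deviates from 0.60 by at most
        # (max per-sample count) / (total grains), within every pollen type.
        for trial in range(100):
            n_types = int(rng.integers(1, 4))
            samples = []
            for t in range(n_types):
                for i in range(int(rng.integers(2, 12))):
                    samples.append((f"t{t}-s{i}", f"type{t}", int(rng.integers(1, 30))))
            r = split_train_test(samples)
            for t in range(n_types):
                type_samples = [(s, c) for s, ty, c in samples if ty == f"type{t}"]
                total = sum(c for _s, c in type_samples)
                train = sum(c for s, c in type_samples if s in set(r.train_sample_ids))
                bound = max(c for _s, c in type_samples) / total
                assert abs(train / total - 0.6) <= bound + 1e-12

    def test_deterministic_under_ties(self):
        samples = [("b", "t", 4), ("a", "t", 4), ("c", "t", 4)]
        r1 = split_train_test(samples)
        r2 = split_train_test(list(reversed(samples)))
        assert r1 == r2

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            split_train_test([("s0", "t", -1)])
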