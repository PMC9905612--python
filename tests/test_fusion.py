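import numpy as np
import pytest
from leukofuse.core import Box, ClassLabel, Detection, ImageRecord
from leukofuse.fusion import (
    Cluster,
    FusionConfig,
    cluster_detections,
    ensemble,
    filter_clusters,
    fuse_cluster,
    vote_type,
)

from conftest import make_det, random_instance
from reference import connected_components_by_iou, reference_ensemble

NG, BG, EG, L, M = ClassLabel


def fig_scenario():
    """Six models; four mutually overlapping detections (3 NG + 1 M) from four
    models plus one isolated detection from a fifth; the sixth abstains."""
    overlapping = [
        make_det((100, 100, 200, 200), 0.90, NG, "m0"),
        make_det((103, 102, 203, 199), 0.85, NG, "m1"),
        make_det((98, 101, 199, 204), 0.80, NG, "m2"),
        make_det((101, 97, 202, 201), 0.70, M, "m3"),
    ]
    isolated = [make_det((400, 400, 460, 460), 0.60, NG, "m4")]
    per_model = {
        "m0": [overlapping[0]],
        "m1": [overlapping[1]],
        "m2": [overlapping[2]],
        "m3": [overlapping[3]],
        "m4": isolated,
        "m5": [],
    }
    return per_model


class TestClustering:
    def test_four_plus_singleton_scenario(self):
        clusters = cluster_detections(fig_scenario())
        sizes = sorted(c.n for c in clusters)
        assert sizes == [1, 4]

    def test_empty_input_gives_empty_list(self):
        assert cluster_detections({"m0": [], "m1": []}) == []

    def test_two_separated_groups_match_component_oracle(self, rng):
        boxes = []
        for cx in (50.0, 500.0):  # two well-separated anchors
            for _ in range(5):
                j = rng.normal(0, 1.5, size=4)
                boxes.append(Box(cx + j[0], cx + j[1], cx + 40 + j[2], cx + 40 + j[3]))
        per_model = {f"m{i}": [
            Detection(box=b, confidence=float(rng.uniform(0.3, 1.0)), label=NG, model_id=f"m{i}")
        ] for i, b in enumerate(boxes)}
        clusters = cluster_detections(per_model)
        assert len(clusters) == connected_components_by_iou(boxes, 0.55) == 2

    def test_one_member_per_model(self, rng):
        for _ in range(25):
            per_model = random_instance(rng)
            for cl in cluster_detections(per_model):
                models = [d.model_id for d in cl.members]
                assert len(models) == len(set(models))

    def test_every_detection_assigned_once(self, rng):
        per_model = random_instance(rng)
        clusters = cluster_detections(per_model)
        assigned = [id(d) for c in clusters for d in c.members]
        original = [id(d) for lst in per_model.values() for d in lst]
        assert sorted(assigned) == sorted(original)


class TestFilter:
    def test_singleton_discarded_with_six_models(self):
        clusters = cluster_detections(fig_scenario())
        kept, discarded = filter_clusters(clusters, model_count=6)
        assert [c.n for c in kept] == [4]
        assert [c.n for c in discarded] == [1]

    def test_boundary_exactly_half_is_kept(self):
        cl = Cluster(members=[make_det((0, 0, 10, 10), 0.9, NG, f"m{i}") for i in range(3)])
        kept, discarded = filter_clusters([cl], model_count=6)
        assert kept == [cl] and discarded == []

    def test_single_model_singleton_kept(self):
        cl = Cluster(members=[make_det((0, 0, 10, 10), 0.9, NG, "m0")])
        kept, discarded = filter_clusters([cl], model_count=1)
        assert kept == [cl] and discarded == []


class TestVote:
    def test_clear_majority(self):
        cl = Cluster(members=[
            make_det((0, 0, 10, 10), 0.9, NG, "m0"),
            make_det((0, 0, 10, 10), 0.8, NG, "m1"),
            make_det((0, 0, 10, 10), 0.7, NG, "m2"),
            make_det((0, 0, 10, 10), 0.6, M, "m3"),
        ])
        assert vote_type(cl) == (NG, 3, False)

    def test_singleton(self):
        cl = Cluster(members=[make_det((0, 0, 10, 10), 0.9, NG, "m0")])
        assert vote_type(cl) == (NG, 1, False)

    def test_tie_resolved_by_summed_confidence(self):
        cl = Cluster(members=[
            make_det((0, 0, 10, 10), 0.9, NG, "m0"),
            make_det((0, 0, 10, 10), 0.8, NG, "m1"),
            make_det((0, 0, 10, 10), 0.6, L, "m2"),
            make_det((0, 0, 10, 10), 0.5, L, "m3"),
        ])
        assert vote_type(cl) == (NG, 2, True)  # 1.7 > 1.1

    def test_residual_tie_falls_back_to_class_index(self):
        cl = Cluster(members=[
            make_det((0, 0, 10, 10), 0.7, M, "m0"),
            make_det((0, 0, 10, 10), 0.7, EG, "m1"),
        ])
        label, t, tie = vote_type(cl)
        assert (label, t, tie) == (EG, 1, True)  # EG=2 precedes M=4


class TestFuse:
    def test_identical_boxes_identity(self):
        cl = Cluster(members=[make_det((10, 10, 20, 20), 1.0, NG, f"m{i}") for i in range(3)])
        for mode in ("models", "majority"):
            f = fuse_cluster(cl, 3, FusionConfig(confidence_divisor_mode=mode))
            assert f.box.corners() == (10, 10, 20, 20)
            assert f.confidence == 1.0
            assert (f.label, f.support, f.majority) == (NG, 3, 3)

    def test_worked_three_box_cluster(self):
        cl = Cluster(members=[
            make_det((10, 10, 20, 20), 0.9, NG, "m0"),
            make_det((12, 12, 22, 22), 0.6, NG, "m1"),
            make_det((8, 8, 18, 18), 0.5, NG, "m2"),
        ])
        f_models = fuse_cluster(cl, 6, FusionConfig(confidence_divisor_mode="models"))
        assert f_models.box.corners() == pytest.approx((10.1, 10.1, 20.1, 20.1), abs=1e-12)
        assert f_models.confidence == pytest.approx(2.0 / 6.0, abs=1e-12)
        f_major = fuse_cluster(cl, 6, FusionConfig(confidence_divisor_mode="majority"))
        assert f_major.confidence == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_equal_confidences_give_arithmetic_mean(self):
        for c in (0.2, 0.5, 0.9):
            cl = Cluster(members=[
                make_det((0, 0, 10, 10), c, NG, "m0"),
                make_det((4, 4, 14, 14), c, NG, "m1"),
            ])
            f = fuse_cluster(cl, 2)
            assert f.box.corners() == pytest.approx((2, 2, 12, 12), abs=1e-12)

    def test_all_zero_confidences_rejected(self):
        cl = Cluster(members=[
            make_det((0, 0, 10, 10), 0.0, NG, "m0"),
            make_det((1, 1, 11, 11), 0.0, NG, "m1"),
        ])
        with pytest.raises(ValueError, match="zero"):
            fuse_cluster(cl, 2)

    def test_majority_only_scope_ignores_minority_boxes(self):
        cl = Cluster(members=[
            make_det((10, 10, 20, 20), 0.8, NG, "m0"),
            make_det((10, 10, 20, 20), 0.8, NG, "m1"),
            make_det((50, 50, 60, 60), 0.8, M, "m2"),
        ])
        f = fuse_cluster(cl, 3, FusionConfig(box_average_scope="majority_only"))
        assert f.box.corners() == pytest.approx((10, 10, 20, 20), abs=1e-12)

    def test_majority_mode_confidence_can_exceed_one_and_is_surfaced(self):
        cl = Cluster(members=[
            make_det((0, 0, 10, 10), 0.9, NG, "m0"),
            make_det((0, 0, 10, 10), 0.9, NG, "m1"),
            make_det((0, 0, 10, 10), 0.9, M, "m2"),
        ])
        f = fuse_cluster(cl, 3, FusionConfig(confidence_divisor_mode="majority"))
        assert f.confidence == pytest.approx(2.7 / 2, abs=1e-12)
        assert f.confidence > 1.0  # reported as-is, never clipped


class TestEnsemble:
    def test_fig_scenario_end_to_end(self):
        image = ImageRecord(image_id=0, width=600, height=600, detections=fig_scenario())
        res = ensemble(image)
        assert len(res.fused) == 1
        assert res.fused[0].label is NG
        assert res.fused[0].support == 4 and res.fused[0].majority == 3
        assert len(res.discarded) == 1 and res.discarded[0].n == 1
        assert res.discarded[0].members[0].model_id == "m4"

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(50):
            per_model = random_instance(rng)
            image = ImageRecord(image_id=0, width=200, height=200, detections=per_model)
            res = ensemble(image)
            ref_fused, ref_disc = reference_ensemble(per_model)
            assert len(res.fused) == len(ref_fused)
            for got, exp in zip(res.fused, ref_fused):
                assert got.box.corners() == pytest.approx(exp["box"], abs=1e-9)
                assert got.confidence == pytest.approx(exp["confidence"], abs=1e-9)
                assert got.label is exp["label"]
                assert (got.support, got.majority) == (exp["support"], exp["majority"])
            assert len(res.discarded) == len(ref_disc)

    def test_permutation_invariance(self, rng):
        for _ in range(20):
            per_model = random_instance(rng)
            image = ImageRecord(image_id=0, width=200, height=200, detections=per_model)
            base = ensemble(image)
            keys = list(per_model)
            rng.shuffle(keys)
            shuffled = {}
            for k in keys:
                lst = list(per_model[k])
                rng.shuffle(lst)
                shuffled[k] = lst
            other = ensemble(ImageRecord(image_id=0, width=200, height=200, detections=shuffled))
            assert [f.box.corners() for f in base.fused] == [f.box.corners() for f in other.fused]
            assert [f.confidence for f in base.fused] == [f.confidence for f in other.fused]
            assert [f.label for f in base.fused] == [f.label for f in other.fused]

    def test_idempotence_with_identical_model_copies(self, rng):
        dets = [
            make_det((20, 20, 80, 90), float(rng.uniform(0.1, 1.0)), NG),
            make_det((120, 40, 170, 95), float(rng.uniform(0.1, 1.0)), L),
            make_det((30, 120, 95, 180), float(rng.uniform(0.1, 1.0)), M),
        ]
        per_model = {
            f"m{i}": [Detection(d.box, d.confidence, d.label, f"m{i}") for d in dets]
            for i in range(6)
        }
        image = ImageRecord(image_id=0, width=200, height=200, detections=per_model)
        res = ensemble(image, FusionConfig(confidence_divisor_mode="models"))
        got = sorted((f.box.corners(), f.confidence, f.label) for f in res.fused)
        want = sorted((d.box.corners(), d.confidence, d.label) for d in dets)
        assert got == want  # bit-identical reproduction
        assert res.discarded == ()

    def test_hull_containment_and_equivariance(self, rng):
        for _ in range(25):
            per_model = random_instance(rng)
            if not any(per_model.values()):
                continue
            image = ImageRecord(image_id=0, width=200, height=200, detections=per_model)
            res = ensemble(image)
            clusters = cluster_detections(per_model)
            kept, _ = filter_clusters(clusters, len(per_model))
            for f, cl in zip(
                sorted(res.fused, key=lambda x: x.box.corners()),
                sorted(
                    [fuse_cluster(c, len(per_model)) for c in kept],
                    key=lambda x: x.box.corners(),
                ),
            ):
                assert f.box.corners() == cl.box.corners()
            for c in kept:
                f = fuse_cluster(c, len(per_model))
                for k in range(4):
                    vals = [d.box.corners()[k] for d in c.members]
                    assert min(vals) - 1e-9 <= f.box.corners()[k] <= max(vals) + 1e-9
            # joint translation + uniform scaling equivariance
            dx, dy, s = 37.5, -12.25, 2.5
            moved = {
                k: [
                    Detection(
                        Box(
                            s * (d.box.x1 + dx), s * (d.box.y1 + dy),
                            s * (d.box.x2 + dx), s * (d.box.y2 + dy),
                        ),
                        d.confidence, d.label, d.model_id,
                    )
                    for d in lst
                ]
                for k, lst in per_model.items()
            }
            res2 = ensemble(ImageRecord(image_id=0, width=2000, height=2000, detections=moved))
            assert len(res2.fused) == len(res.fused)
            for a, b in zip(res.fused, res2.fused):
                assert b.confidence == a.confidence
                exp = tuple(s * (v + (dx if k % 2 == 0 else dy)) for k, v in enumerate(a.box.corners()))
                assert b.box.corners() == pytest.approx(exp, rel=1e-9, abs=1e-7)

    def test_confidence_bounded_in_models_mode(self, rng):
        for _ in range(25):
            per_model = random_instance(rng)
            image = ImageRecord(image_id=0, width=200, height=200, detections=per_model)
            for f in ensemble(image).fused:
                assert f.confidence <= 1.0 + 1e-12


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cluster_iou_threshold": 0.0},
            {"cluster_iou_threshold": 1.0},
            {"min_support_fraction": 0.0},
            {"min_support_fraction": 1.5},
            {"confidence_divisor_mode": "mean"},
            {"box_average_scope": "everything"},
            {"tie_break_rule": "random"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FusionConfig(**kwargs)
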