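"""ANN training/prediction, post-filters, pipeline and evaluation."""

import numpy as np
import pytest

import weedvision as wv
from weedvision import classifier as clf
from weedvision.regions import PlantRegion


def _region(area=100, touches_edge=False, label=1):
    k = max(int(np.sqrt(area)), 1)
    px = np.array([(r, c) for r in range(k) for c in range(k)])[:area]
    return PlantRegion(
        label=label, pixels=px + 10, area=area, perimeter=4 * k - 4 or 1,
        width=k, height=k, bbox=(10, 10, 10 + k - 1, 10 + k - 1),
        centroid=(10.0, 10.0), touches_edge=touches_edge,
    )


def _detection(area=100, touches_edge=False, ann_class=clf.WEED):
    return clf.Detection(
        region=_region(area, touches_edge),
        features=np.ones(5), ann_score=0.3 if ann_class == clf.WEED else 0.9,
        ann_class=ann_class, final_class=ann_class,
    )


def test_training_is_deterministic(training_data):
    X, y = training_data
    a = wv.train_ann(X, y, seed=11)
    b = wv.train_ann(X, y, seed=11)
    assert all(np.array_equal(u, v) for u, v in zip(a.weights, b.weights))
    assert all(np.array_equal(u, v) for u, v in zip(a.biases, b.biases))
    c = wv.train_ann(X, y, seed=12)
    assert not all(np.array_equal(u, v) for u, v in zip(a.weights, c.weights))


def test_training_input_validation():
    X = np.random.default_rng(0).random((10, 5))
    with pytest.raises(ValueError):
        wv.train_ann(X, ["crop"] * 10, seed=0)
    with pytest.raises(ValueError):
        wv.train_ann(X, ["crop"] * 9 + ["weed"], seed=0)  # <2 in a class
    Xbad = X.copy()
    Xbad[0, 0] = np.nan
    with pytest.raises(ValueError):
        wv.train_ann(Xbad, ["crop"] * 5 + ["weed"] * 5, seed=0)


def test_architecture_is_5_5_1_1(trained_model):
    assert trained_model.architecture == [5, 5, 1, 1]


def test_holdout_accuracy_on_separable_features(trained_model):
    Xv, yv = wv.generate_feature_dataset(55, 66, overlap=0.0, seed=99)
    preds = [c for _, c in wv.predict(trained_model, Xv)]
    acc = np.mean([p == t for p, t in zip(preds, yv)])
    assert acc >= 0.95


def test_chance_accuracy_when_classes_coincide():
    X, y = wv.generate_feature_dataset(54, 65, overlap=1.0, seed=7)
    model = wv.train_ann(X, y, seed=3)
    Xv, yv = wv.generate_feature_dataset(55, 66, overlap=1.0, seed=99)
    preds = [c for _, c in wv.predict(model, Xv)]
    acc = np.mean([p == t for p, t in zip(preds, yv)])
    assert 0.35 <= acc <= 0.65


def test_accuracy_degrades_monotonically_with_overlap(trained_model):
    accs = []
    for ov in (0.0, 0.5, 1.0):
        X, y = wv.generate_feature_dataset(54, 65, overlap=ov, seed=7)
        m = wv.train_ann(X, y, seed=3)
        Xv, yv = wv.generate_feature_dataset(55, 66, overlap=ov, seed=99)
        preds = [c for _, c in wv.predict(m, Xv)]
        accs.append(np.mean([p == t for p, t in zip(preds, yv)]))
    assert accs[0] >= accs[1] - 0.05 >= accs[2] - 0.10


def test_predict_contract(trained_model, training_data):
    X, _ = training_data
    for score, cls in wv.predict(trained_model, X):
        assert 0.0 <= score <= 1.0
        assert cls == (clf.CROP if score >= 0.5 else clf.WEED)
    with pytest.raises(ValueError):
        wv.predict(trained_model, np.array([1.0, np.inf, 1, 1, 1]))


def test_predict_cluster_centroids(trained_model, training_data):
    X, y = training_data
    crop_mean = X[[lab == clf.CROP for lab in y]].mean(axis=0)
    weed_mean = X[[lab == clf.WEED for lab in y]].mean(axis=0)
    assert wv.predict(trained_model, crop_mean)[1] == clf.CROP
    assert wv.predict(trained_model, weed_mean)[1] == clf.WEED


def test_model_json_roundtrip(trained_model, training_data):
    X, _ = training_data
    restored = clf.ANNModel.from_dict(trained_model.to_dict())
    s0 = [s for s, _ in wv.predict(trained_model, X)]
    s1 = [s for s, _ in wv.predict(restored, X)]
    assert s0 == pytest.approx(s1, abs=1e-12)


def test_post_filter_rules():
    edge = _detection(area=100, touches_edge=True, ann_class=clf.CROP)
    big_weed = _detection(area=500, ann_class=clf.WEED)
    small_weed = _detection(area=200, ann_class=clf.WEED)
    big_crop = _detection(area=500, ann_class=clf.CROP)
    dets = clf.post_filter([edge, big_weed, small_weed, big_crop])
    assert dets[0].final_class == clf.EXCLUDED
    assert dets[0].filter_applied == "edge_excluded"
    assert dets[1].final_class == clf.CROP
    assert dets[1].filter_applied == "size_override"
    assert dets[2].final_class == clf.WEED
    assert dets[3].final_class == clf.CROP
    assert dets[3].filter_applied == "none"


def test_post_filter_never_demotes_crop(rng):
    dets = [
        _detection(area=int(a), touches_edge=bool(e), ann_class=c)
        for a, e, c in zip(
            rng.integers(1, 600, 50), rng.random(50) < 0.3,
            rng.choice([clf.CROP, clf.WEED], 50),
        )
    ]
    for d in clf.post_filter(list(dets)):
        if d.ann_class == clf.CROP:
            assert d.final_class in (clf.CROP, clf.EXCLUDED)
        assert (d.final_class == clf.EXCLUDED) == (d.filter_applied == "edge_excluded")


def test_force_crop_size_rule():
    big_crop_call = _detection(area=500, ann_class=clf.CROP)
    dets = clf.post_filter([big_crop_call], size_rule="force_crop")
    assert dets[0].filter_applied == "size_override"
    assert dets[0].final_class == clf.CROP


def test_process_image_counts_and_classes(trained_model):
    scene = wv.generate_scene(wv.SceneParams(seed=21, n_corn=3, n_weed=2,
                                             n_saturated_patches=0))
    dets, seg = wv.process_image(scene.image, trained_model)
    assert len(dets) == 5
    assert not seg.capped
    metrics = wv.evaluate(dets, scene.truth_labels, scene.truth_classes,
                          scene.truth_mask.shape)
    assert metrics.plant_error_pct == 0.0
    assert metrics.crop_identification_pct == 100.0


def test_process_image_all_soil(trained_model):
    scene = wv.generate_scene(wv.SceneParams(seed=22, n_corn=0, n_weed=0,
                                             n_saturated_patches=0))
    dets, _ = wv.process_image(scene.image, trained_model)
    assert dets == []


def test_border_plant_is_excluded(trained_model):
    scene = wv.generate_scene(wv.SceneParams(seed=23, n_corn=1, n_weed=0,
                                             edge_allowed=True,
                                             n_saturated_patches=0))
    # regenerate until the single plant actually touches the frame border
    s = 23
    while not _touches_border(scene.truth_mask):
        s += 1
        scene = wv.generate_scene(wv.SceneParams(seed=s, n_corn=1, n_weed=0,
                                                 edge_allowed=True,
                                                 n_saturated_patches=0))
    dets, _ = wv.process_image(scene.image, trained_model)
    assert any(d.final_class == clf.EXCLUDED for d in dets)


def _touches_border(mask):
    return mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()


@pytest.mark.parametrize(
    "correct, total, rate",
    [(345, 475, 72.6), (444, 480, 92.5), (388, 408, 95.1)],
)
def test_identification_rate_arithmetic(correct, total, rate):
    m = clf.EvalMetrics(n_crop_truth=total, n_crop_correct=correct)
    assert round(m.crop_identification_pct, 1) == rate


def test_evaluate_counts_misses_and_spurious():
    truth = np.zeros((20, 20), dtype=np.int32)
    truth[2:5, 2:5] = 1   # will be missed
    spurious = _detection(area=4)
    spurious.region.pixels = np.array([(15, 15), (15, 16), (16, 15), (16, 16)])
    m = wv.evaluate([spurious], truth, {1: clf.CROP}, truth.shape)
    assert m.n_missed == 1 and m.n_spurious == 1
    assert m.plant_error_pct == 200.0
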