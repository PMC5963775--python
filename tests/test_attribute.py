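"""Attribution model, reference sampling, and accuracy reporting."""

import numpy as np
import pytest

from firescape.attribute import (FEATURES, assess_accuracy, classify_objects,
                                 predict_from_scores, sample_reference,
                                 train_attribution)
from firescape.config import CLASS_ORDER
from firescape.objects import ChangeObject


def make_object(oid, delta_nbr, **overrides):
    o = ChangeObject(object_id=oid, change_year=2000, duration_yr=1,
                     pixels=np.array([[0, 0]]))
    o.area_ha, o.perimeter_m = 0.09, 120.0
    o.compactness, o.fractal_dimension = 0.785, 1.0
    spec = {}
    for ix in ("nbr", "tcb", "tcg", "tcw"):
        d = delta_nbr if ix == "nbr" else 0.1 * delta_nbr
        spec[f"delta_{ix}"] = d
        spec[f"pre_{ix}"] = 0.5
        spec[f"post_{ix}"] = 0.5 - d
    spec.update(overrides)
    o.spectral = spec
    return o


def toy_training_set(rng, n_per_class=30):
    objects, labels = [], []
    means = {"fire": 0.4, "condition": 0.05}
    oid = 0
    for cls, mu in means.items():
        for _ in range(n_per_class):
            objects.append(make_object(oid, rng.normal(mu, 0.01)))
            labels.append(cls)
            oid += 1
    return objects, labels


def test_separable_two_class_problem_trains_to_perfection(rng):
    objects, labels = toy_training_set(rng)
    model = train_attribution(objects, labels, seed=0, n_trees=50)
    result = classify_objects(model, objects)
    assert (result.predicted == np.asarray(labels, dtype=object)).all()
    assert np.allclose(result.scores.sum(axis=1), 1.0)


def test_single_class_training_set_is_an_error(rng):
    objects, _ = toy_training_set(rng)
    with pytest.raises(ValueError):
        train_attribution(objects, ["fire"] * len(objects))


def test_missing_feature_error_names_object_and_feature(rng):
    objects, labels = toy_training_set(rng)
    model = train_attribution(objects, labels, seed=0, n_trees=10)
    broken = make_object(999, 0.4)
    del broken.spectral["delta_tcw"]
    with pytest.raises(ValueError, match="999.*delta_tcw"):
        classify_objects(model, [broken])


def test_tie_scores_resolve_in_fixed_class_order():
    scores = np.array([[0.25, 0.25, 0.25, 0.25],
                       [0.1, 0.4, 0.4, 0.1]])
    pred = predict_from_scores(scores, CLASS_ORDER)
    assert pred[0] == "fire"      # 4-way tie -> first in order
    assert pred[1] == "harvest"   # harvest before road


def test_batch_equals_per_object_classification(rng):
    objects, labels = toy_training_set(rng)
    model = train_attribution(objects, labels, seed=0, n_trees=50)
    batch = classify_objects(model, objects)
    singles = [classify_objects(model, [o]).predicted[0] for o in objects]
    assert list(batch.predicted) == singles


def test_classifier_deterministic_under_fixed_seed(rng):
    objects, labels = toy_training_set(rng)
    m1 = train_attribution(objects, labels, seed=7, n_trees=50)
    m2 = train_attribution(objects, labels, seed=7, n_trees=50)
    r1, r2 = classify_objects(m1, objects), classify_objects(m2, objects)
    assert np.array_equal(r1.scores, r2.scores)


def grid_labels_and_centroids(rng, n_per_class=40, extent=(100, 100)):
    labels, cents = [], []
    for cls in CLASS_ORDER:
        for _ in range(n_per_class):
            labels.append(cls)
            cents.append(rng.uniform(0, extent[0], 2))
    return labels, np.array(cents)


def test_sample_reference_exact_stratified_counts(rng):
    labels, cents = grid_labels_and_centroids(rng)
    idx = sample_reference(labels, cents, (100, 100), n_per_class=25,
                           spatial_bins=9, seed=0)
    assert len(idx) == 100
    drawn = np.asarray(labels, dtype=object)[idx]
    for cls in CLASS_ORDER:
        assert (drawn == cls).sum() == 25


def test_sample_reference_respects_per_bin_caps(rng):
    labels, cents = grid_labels_and_centroids(rng, n_per_class=40)
    idx = sample_reference(labels, cents, (100, 100), n_per_class=8,
                           spatial_bins=4, seed=0)
    # 4 bins, 8 per class -> cap ceil(8/4) = 2 per bin per class
    labels_arr = np.asarray(labels, dtype=object)
    bin_of = (np.minimum(cents[:, 0] * 2 // 100, 1) * 2
              + np.minimum(cents[:, 1] * 2 // 100, 1))
    for cls in CLASS_ORDER:
        sel = idx[labels_arr[idx] == cls]
        for b in range(4):
            assert (bin_of[sel] == b).sum() <= 2


def test_sample_reference_missing_class_raises_named_error(rng):
    labels = ["fire"] * 10 + ["harvest"] * 10 + ["road"] * 10
    cents = rng.uniform(0, 50, (30, 2))
    with pytest.raises(ValueError, match="condition"):
        sample_reference(labels, cents, (50, 50), 5, 4, seed=0)


def test_accuracy_report_hand_counted_matrix():
    reference = (["fire"] * 100 + ["harvest"] * 60)
    predicted = (["fire"] * 93 + ["harvest"] * 7
                 + ["fire"] * 2 + ["harvest"] * 58)
    rep = assess_accuracy(predicted, reference)
    assert rep.matrix.loc["fire", "fire"] == 93
    assert rep.omission["fire"] == pytest.approx(0.07)
    assert rep.commission["fire"] == pytest.approx(2 / 95)
    assert rep.overall_accuracy == pytest.approx((93 + 58) / 160)
    # marginals equal class counts
    assert rep.matrix.sum(axis=1)["fire"] == 100
    assert rep.matrix.sum(axis=1)["harvest"] == 60


def test_perfect_agreement_reports_zero_errors():
    labels = ["fire", "harvest", "road", "condition"] * 5
    rep = assess_accuracy(labels, labels)
    assert rep.overall_accuracy == 1.0
    assert (rep.omission.fillna(0) == 0).all()
    assert (rep.commission.fillna(0) == 0).all()


def test_absent_class_rates_are_not_applicable():
    rep = assess_accuracy(["fire"] * 5, ["fire"] * 5)
    assert rep.omission["fire"] == 0.0
    assert np.isnan(rep.omission["road"])
    assert np.isnan(rep.commission["harvest"])


def test_length_mismatch_is_an_error():
    with pytest.raises(ValueError):
        assess_accuracy(["fire"], ["fire", "fire"])


def test_overall_accuracy_invariant_to_class_permutation():
    rng = np.random.default_rng(0)
    ref = rng.choice(CLASS_ORDER, 200)
    pred = rng.choice(CLASS_ORDER, 200)
    rep1 = assess_accuracy(pred, ref)
    rep2 = assess_accuracy(pred, ref, classes=tuple(reversed(CLASS_ORDER)))
    assert rep1.overall_accuracy == rep2.overall_accuracy


def test_permuted_labels_score_near_chance(rng):
    """Destroying the feature-label link drops held-out accuracy to ~1/k."""
    objects, labels = [], []
    means = {"fire": 0.45, "harvest": 0.3, "road": 0.2, "condition": 0.07}
    oid = 0
    for cls, mu in means.items():
        for _ in range(60):
            objects.append(make_object(oid, rng.normal(mu, 0.01)))
            labels.append(cls)
            oid += 1
    perm = rng.permutation(len(labels))
    shuffled = [labels[i] for i in perm]
    train, test = np.arange(0, 240, 2), np.arange(1, 240, 2)
    model = train_attribution([objects[i] for i in train],
                              [shuffled[i] for i in train],
                              seed=0, n_trees=100)
    pred = classify_objects(model, [objects[i] for i in test]).predicted
    acc = np.mean(pred == np.asarray([shuffled[i] for i in test],
                                     dtype=object))
    assert abs(acc - 0.25) < 0.15
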