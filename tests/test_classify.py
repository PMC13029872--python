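"""Dual-input model contracts, training behavior and hierarchical routing."""

import numpy as np
import pytest

from shadowpipe.classify import (BASE_CLASSES, ClassTree, DualInputClassifier,
                                 GELATINOUS_SUBCLASSES, Prediction,
                                 TrainConfig, _dataset_arrays,
                                 build_dual_input_model,
                                 classify_hierarchical, predict,
                                 sort_to_directories, train)


def _fit_tiny(dataset, with_size=True, seed=0, **cfg):
    defaults = dict(max_epochs=40, batch_size=32, seed=seed, learning_rate=1e-2)
    defaults.update(cfg)
    model = DualInputClassifier(with_size_input=with_size,
                                config=TrainConfig(**defaults))
    train(model, dataset.subset("train"), dataset.subset("val"))
    return model


def test_output_dimension_and_softmax_contract(dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset)
    X, _, sizes = _dataset_arrays(dimorphic_dataset.subset("test"))
    proba = predict(model, X, sizes)
    assert proba.shape == (len(X), 2)
    assert np.all(proba >= 0)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)


def test_build_model_rejects_single_class():
    with pytest.raises(ValueError, match="n_classes"):
        build_dual_input_model(n_classes=1)


def test_size_pathway_parameter_count(dimorphic_dataset):
    with_size = _fit_tiny(dimorphic_dataset, with_size=True)
    without = _fit_tiny(dimorphic_dataset, with_size=False)
    # the two heads differ by exactly the size pathway: 2 extra inputs
    # feeding the hidden layer
    assert with_size.n_params_ - without.n_params_ == 2 * with_size.hidden_units


def test_training_reaches_full_accuracy_on_separable_data(dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset, with_size=True, max_epochs=100)
    X, y, sizes = _dataset_arrays(dimorphic_dataset.subset("train"))
    assert model.score(X, y, sizes) == 1.0


def test_patience_stops_after_first_flat_evaluation(dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset, patience=1, max_epochs=50,
                      learning_rate=0.0)  # frozen weights: metric constant
    # first evaluation sets the best; second is non-improving -> stop
    assert len(model.history_["epoch"]) == 2


def test_training_deterministic_given_seed(dimorphic_dataset):
    m1 = _fit_tiny(dimorphic_dataset, seed=3)
    m2 = _fit_tiny(dimorphic_dataset, seed=3)
    assert m1.history_ == m2.history_
    assert np.array_equal(m1.W2_, m2.W2_)


def test_val_class_absent_from_train_rejected(dimorphic_dataset):
    X, y, sizes = _dataset_arrays(dimorphic_dataset.subset("train"))
    model = DualInputClassifier(config=TrainConfig(max_epochs=1))
    y_val = np.array(["unseen_class"] * 3)
    with pytest.raises(ValueError, match="absent"):
        model.fit(X, y, sizes, X_val=X[:3], y_val=y_val, sizes_val=sizes[:3])


def test_prediction_purity_and_batch_invariance(dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset)
    X, _, sizes = _dataset_arrays(dimorphic_dataset.subset("test"))
    dup = np.concatenate([X[:1], X[:1], X])
    dup_sizes = np.concatenate([sizes[:1], sizes[:1], sizes])
    proba = model.predict_proba(dup, dup_sizes)
    assert np.array_equal(proba[0], proba[1])  # duplicates agree
    assert np.allclose(proba[2:], model.predict_proba(X, sizes))


def test_missing_sizes_raise_when_model_has_size_input(dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset)
    X, _, _ = _dataset_arrays(dimorphic_dataset.subset("test"))
    with pytest.raises(ValueError, match="size"):
        model.predict_proba(X, None)


def test_model_roundtrip_serialization(tmp_path, dimorphic_dataset):
    model = _fit_tiny(dimorphic_dataset)
    path = tmp_path / "model.pkl"
    model.save(path)
    loaded = DualInputClassifier.load(path)
    X, _, sizes = _dataset_arrays(dimorphic_dataset.subset("test"))
    assert np.allclose(loaded.predict_proba(X, sizes),
                       model.predict_proba(X, sizes))
    sidecar = path.with_suffix(".pkl.json")
    assert sidecar.exists()
    import json

    meta = json.loads(sidecar.read_text())
    assert meta["classes"] == list(model.classes_)
    assert meta["input_px"] == model.input_px_


def test_size_input_beats_ablation_on_dimorphic_pair(dimorphic_dataset):
    """The size-aware head must outperform the image-only head on classes
    whose silhouettes are identical and only sizes differ (sign test over
    5 seeds, p < 0.05)."""
    from scipy.stats import binomtest

    X, y, sizes = _dataset_arrays(dimorphic_dataset.subset("test"))
    wins = 0
    for seed in range(5):
        acc = {}
        for with_size in (True, False):
            model = _fit_tiny(dimorphic_dataset, with_size=with_size,
                              seed=seed, max_epochs=100)
            acc[with_size] = model.score(X, y, sizes)
        wins += acc[True] > acc[False]
    assert binomtest(wins, 5, 0.5, alternative="greater").pvalue < 0.05


# --- hierarchy ------------------------------------------------------------


class _StubModel:
    """Deterministic fake classifier for routing tests."""

    def __init__(self, classes, proba_fn, input_px=32):
        self.classes_ = np.asarray(classes)
        self.input_px_ = input_px
        self._fn = proba_fn

    def predict_proba(self, X, sizes=None):
        return np.stack([self._fn(x) for x in np.asarray(X)])


def _tree(base_proba, niche_proba=None):
    base = _StubModel(list(BASE_CLASSES), base_proba)
    niche = {}
    if niche_proba is not None:
        niche["Gelatinous"] = _StubModel(list(GELATINOUS_SUBCLASSES),
                                         niche_proba)
    return ClassTree(base_model=base, niche_models=niche,
                     subclasses={"Gelatinous": list(GELATINOUS_SUBCLASSES)}
                     if niche else {})


def _const(classes, label, conf):
    v = np.full(len(classes), (1 - conf) / (len(classes) - 1))
    v[list(classes).index(label)] = conf
    return lambda x: v


def test_confident_undivided_class_not_routed():
    tree = _tree(_const(BASE_CLASSES, "Crustacean", 0.95),
                 _const(GELATINOUS_SUBCLASSES, "Medusozoa", 0.9))
    preds = classify_hierarchical(tree, [np.full((20, 20), 0.5)])
    assert preds[0].base_class == "Crustacean"
    assert preds[0].subclass is None
    assert preds[0].accepted


def test_confident_gelatinous_routed_to_niche():
    tree = _tree(_const(BASE_CLASSES, "Gelatinous", 0.90),
                 _const(GELATINOUS_SUBCLASSES, "Ctenophora", 0.8))
    preds = classify_hierarchical(tree, [np.full((20, 20), 0.5)])
    assert preds[0].base_class == "Gelatinous"
    assert preds[0].subclass == "Ctenophora"
    assert preds[0].subclass in GELATINOUS_SUBCLASSES


def test_below_threshold_unaccepted_and_unrouted():
    tree = _tree(_const(BASE_CLASSES, "Gelatinous", 0.65),
                 _const(GELATINOUS_SUBCLASSES, "Doliolid", 0.9))
    preds = classify_hierarchical(tree, [np.full((20, 20), 0.5)], 0.70)
    assert not preds[0].accepted
    assert preds[0].subclass is None


def test_subdivided_class_without_niche_model_rejected():
    tree = ClassTree(base_model=_StubModel(list(BASE_CLASSES),
                                           _const(BASE_CLASSES, "Gelatinous", 0.9)),
                     subclasses={"Gelatinous": list(GELATINOUS_SUBCLASSES)},
                     niche_models={})
    with pytest.raises(ValueError, match="niche"):
        classify_hierarchical(tree, [np.full((20, 20), 0.5)])


def test_threshold_monotonicity_of_accept_count():
    rng = np.random.default_rng(0)

    def fn(x):
        v = rng.dirichlet(np.ones(len(BASE_CLASSES)))
        return v

    imgs = [np.full((16, 16), 0.4)] * 30
    accepted = []
    for thr in (0.2, 0.5, 0.8):
        rng = np.random.default_rng(0)
        tree = _tree(fn)
        preds = classify_hierarchical(tree, imgs, thr)
        accepted.append(sum(p.accepted for p in preds))
    assert accepted == sorted(accepted, reverse=True)


def test_sort_to_directories_bookkeeping(tmp_path):
    src = tmp_path / "crops"
    src.mkdir()
    import imageio.v3 as iio

    for name in ("a.png", "b.png", "c.png", "d.png"):
        iio.imwrite(src / name, np.zeros((4, 4), dtype=np.uint8))
    preds = [
        Prediction("Crustacean", 0.9, source="a.png"),
        Prediction("Crustacean", 0.95, source="b.png"),
        Prediction("Crustacean", 0.99, source="c.png"),
        Prediction("Chaetognath", 0.4, accepted=False, source="d.png"),
    ]
    out = tmp_path / "sorted"
    manifest = sort_to_directories(preds, out, image_root=src)
    assert len(list((out / "Crustacean").glob("*.png"))) == 3
    assert len(list((out / "_unsorted").glob("*.png"))) == 1
    assert len(manifest) == 4
    # rerun is idempotent
    manifest2 = sort_to_directories(preds, out, image_root=src)
    assert len(list((out / "Crustacean").glob("*.png"))) == 3
    assert manifest2["dest"].tolist() == manifest["dest"].tolist()


def test_sort_empty_predictions(tmp_path):
    manifest = sort_to_directories([], tmp_path / "sorted")
    assert manifest.empty
    assert (tmp_path / "sorted" / "manifest.csv").exists()


def test_class_tree_validation():
    with pytest.raises(ValueError, match="duplicate"):
        ClassTree(base_classes=("A", "A")).validate()
    with pytest.raises(ValueError, match="unknown base"):
        ClassTree(base_classes=("A",), subclasses={"B": ["x"]}).validate()
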