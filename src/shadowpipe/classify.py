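"""Dual-input classification with hierarchical (niched) routing.

The classifier pairs an image feature backbone with the organism's
*original* pixel dimensions.  Resizing every ROI crop to the common network
input destroys the scale difference between look-alike taxa (the classic
chaetognath-vs-larvacean confusion), so the head concatenates the backbone
feature vector with the pre-resize (height, width), normalizes, applies an
activation, and finishes with fully-connected + softmax over the classes.

The backbone is pluggable.  The default is a bank of fixed, seeded random
convolution filters with ReLU and coarse average pooling — cheap to run on
CPU and adequate for silhouette shape; the trainable part is the head,
optimized with minibatch Adam on cross-entropy with early stopping on
validation accuracy.

Hierarchical routing: a class tree attaches niche models to base classes
(default: the Gelatinous class subdivides into six orders).  ROIs whose
base prediction is confident enough and whose class has a niche model are
re-classified by it; predictions below the confidence threshold are
flagged unaccepted.
"""

from __future__ import annotations

import json
import logging
import pickle
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin

from .datasetprep import LabeledImageSet, standardize_image

logger = logging.getLogger(__name__)

BASE_CLASSES = ("Chaetognath", "Crustacean", "DetritusA", "DetritusB",
                "Gelatinous", "Larvacean")
GELATINOUS_SUBCLASSES = ("Annelid", "Ctenophora", "Doliolid", "Medusozoa",
                         "Radiolaria", "Siphonophora")
DEFAULT_CONF_THRESHOLD = 0.70


@dataclass
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 15
    patience: int = 50  # validation evaluations without improvement
    learning_rate: float = 1e-3
    eval_every: int = 1  # epochs between validation evaluations
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")


class RandomConvBackbone:
    """Fixed random convolutional features: conv -> ReLU -> coarse pooling.

    Filters are He-initialized once from the seed and never trained; the
    feature dimension is n_filters * pool_grid**2.
    """

    def __init__(self, n_filters: int = 8, kernel_size: int = 5,
                 pool_grid: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.filters = rng.normal(0.0, scale,
                                  size=(n_filters, kernel_size, kernel_size))
        self.pool_grid = pool_grid
        self.n_features = n_filters * pool_grid**2

    def transform(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        n = images.shape[0]
        out = np.empty((n, self.n_features))
        g = self.pool_grid
        for i in range(n):
            feats = []
            for f in self.filters:
                resp = np.maximum(ndimage.correlate(images[i], f,
                                                    mode="nearest"), 0.0)
                h, w = resp.shape
                rb = np.linspace(0, h, g + 1).astype(int)
                cb = np.linspace(0, w, g + 1).astype(int)
                for a in range(g):
                    for b in range(g):
                        feats.append(resp[rb[a]:rb[a + 1], cb[b]:cb[b + 1]].mean())
            out[i] = feats
        return out


class FlattenBackbone:
    """Downsample to a small square and flatten; the minimal baseline."""

    def __init__(self, side: int = 16):
        self.side = side
        self.n_features = side * side

    def transform(self, images: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        images = np.asarray(images, dtype=np.float64)
        return np.stack([
            resize(img, (self.side, self.side), order=1, anti_aliasing=True,
                   preserve_range=True).ravel()
            for img in images
        ])


def _make_backbone(spec, seed: int):
    if hasattr(spec, "transform"):
        return spec
    if spec in (None, "random_conv"):
        return RandomConvBackbone(seed=seed)
    if spec == "flatten":
        return FlattenBackbone()
    raise ValueError(f"unknown backbone {spec!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DualInputClassifier(BaseEstimator, ClassifierMixin):
    """Image + original-size classifier with a trainable dense head.

    Parameters
    ----------
    backbone : "random_conv", "flatten" or an object with
        transform(images) -> (n, d) features.
    with_size_input : bool
        Concatenate the z-scored original (height, width) to the backbone
        features.  Setting this False is the ablation arm.
    hidden_units : int
        Width of the hidden fully-connected layer; 0 for a single
        softmax layer.
    config : TrainConfig or None
        Batch size, epochs, patience, learning rate, seed.

    Fitted attributes end in an underscore: classes_, history_,
    n_params_, input_px_, feature_mean_/feature_std_ and the weight
    matrices.
    """

    def __init__(self, backbone="random_conv", with_size_input: bool = True,
                 hidden_units: int = 32, config: TrainConfig | None = None):
        self.backbone = backbone
        self.with_size_input = with_size_input
        self.hidden_units = hidden_units
        self.config = config

    # -- internals ---------------------------------------------------------

    def _features(self, images, sizes) -> np.ndarray:
        feats = self.backbone_.transform(np.asarray(images, dtype=np.float64))
        if self.with_size_input:
            if sizes is None:
                raise ValueError("model has a size input; sizes are required")
            sizes = np.asarray(sizes, dtype=np.float64).reshape(len(feats), 2)
            feats = np.hstack([feats, sizes])
        return feats

    def _head_forward(self, z):
        # normalization -> activation -> (hidden FC ->) final FC -> softmax
        zn = np.maximum((z - self.feature_mean_) / self.feature_std_, 0.0)
        if self.hidden_units > 0:
            h = np.maximum(zn @ self.W1_ + self.b1_, 0.0)
        else:
            h = zn
        logits = h @ self.W2_ + self.b2_
        return _softmax(logits), zn, h

    def head_param_count(self, n_features: int) -> int:
        """Trainable head parameters for a given input feature dimension."""
        d = n_features + (2 if self.with_size_input else 0)
        if self.hidden_units > 0:
            return (d * self.hidden_units + self.hidden_units
                    + self.hidden_units * len(self.classes_) + len(self.classes_))
        return d * len(self.classes_) + len(self.classes_)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, sizes=None, X_val=None, y_val=None, sizes_val=None):
        """Train the head on standardized images (n, s, s) and labels.

        If a validation set is given, early stopping monitors its accuracy
        and the best-validation weights are restored; otherwise the
        training set doubles as the stopping metric (documented, desk-scale
        behavior).
        """
        cfg = self.config or TrainConfig()
        cfg.validate()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if y_val is not None:
            missing = set(np.unique(y_val)) - set(self.classes_)
            if missing:
                raise ValueError(
                    f"class(es) {sorted(missing)} present in validation but "
                    "absent from training")
        self.input_px_ = X.shape[1]
        rng = np.random.default_rng(cfg.seed)
        self.backbone_ = _make_backbone(self.backbone, seed=cfg.seed)

        Z = self._features(X, sizes)
        self.feature_mean_ = Z.mean(axis=0)
        std = Z.std(axis=0)
        self.feature_std_ = np.where(std > 1e-12, std, 1.0)
        if X_val is not None:
            Z_val = self._features(np.asarray(X_val, dtype=np.float64), sizes_val)
            yv = np.asarray(y_val)
        else:
            Z_val, yv = Z, y

        n_classes = len(self.classes_)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        t = np.array([class_index[c] for c in y])
        tv = np.array([class_index[c] for c in yv])

        d = Z.shape[1]
        h_units = self.hidden_units
        if h_units > 0:
            self.W1_ = rng.normal(0, np.sqrt(2.0 / d), size=(d, h_units))
            self.b1_ = np.zeros(h_units)
            self.W2_ = rng.normal(0, np.sqrt(2.0 / h_units),
                                  size=(h_units, n_classes))
        else:
            self.W1_ = self.b1_ = None
            self.W2_ = rng.normal(0, np.sqrt(2.0 / d), size=(d, n_classes))
        self.b2_ = np.zeros(n_classes)

        params = [p for p in (self.W1_, self.b1_, self.W2_, self.b2_)
                  if p is not None]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        history = {"epoch": [], "train_loss": [], "val_accuracy": []}
        best_acc, best_weights, stall = -np.inf, None, 0
        n = len(Z)
        stop = False
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            losses = []
            for s0 in range(0, n, cfg.batch_size):
                idx = order[s0:s0 + cfg.batch_size]
                grads, loss = self._batch_grads(Z[idx], t[idx])
                losses.append(loss)
                step += 1
                for k, (p, g) in enumerate(zip(params, grads)):
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
                    mhat = m_t[k] / (1 - beta1**step)
                    vhat = v_t[k] / (1 - beta2**step)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if epoch % cfg.eval_every == 0 or epoch == cfg.max_epochs:
                proba, _, _ = self._head_forward(Z_val)
                acc = float((proba.argmax(axis=1) == tv).mean())
                history["epoch"].append(epoch)
                history["train_loss"].append(float(np.mean(losses)))
                history["val_accuracy"].append(acc)
                if acc > best_acc:
                    best_acc = acc
                    best_weights = [None if p is None else p.copy()
                                    for p in (self.W1_, self.b1_, self.W2_, self.b2_)]
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        stop = True
            if stop:
                break
        if best_weights is not None:
            self.W1_, self.b1_, self.W2_, self.b2_ = best_weights
        self.history_ = history
        self.best_val_accuracy_ = best_acc
        self.n_params_ = self.head_param_count(self.backbone_.n_features)
        return self

    def _batch_grads(self, Zb, tb):
        proba, zn, h = self._head_forward(Zb)
        nb = len(Zb)
        onehot = np.zeros_like(proba)
        onehot[np.arange(nb), tb] = 1.0
        loss = float(-np.log(np.clip(proba[np.arange(nb), tb], 1e-12, None)).mean())
        dlogits = (proba - onehot) / nb
        gW2 = h.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        if self.hidden_units > 0:
            dh = dlogits @ self.W2_.T
            dh[h <= 0] = 0.0
            gW1 = zn.T @ dh
            gb1 = dh.sum(axis=0)
            return [gW1, gb1, gW2, gb2], loss
        return [gW2, gb2], loss

    def predict_proba(self, X, sizes=None) -> np.ndarray:
        """Softmax probability vectors, one per image; batch-order invariant."""
        Z = self._features(np.asarray(X, dtype=np.float64), sizes)
        proba, _, _ = self._head_forward(Z)
        return proba

    def predict(self, X, sizes=None) -> np.ndarray:
        proba = self.predict_proba(X, sizes)
        # argmax breaks ties toward the lowest class index
        return self.classes_[proba.argmax(axis=1)]

    def score(self, X, y, sizes=None) -> float:
        return float((self.predict(X, sizes) == np.asarray(y)).mean())

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Opaque model file plus a JSON sidecar of the public metadata."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        cfg = self.config or TrainConfig()
        sidecar = {
            "classes": [str(c) for c in self.classes_],
            "input_px": int(self.input_px_),
            "with_size_input": bool(self.with_size_input),
            "hidden_units": int(self.hidden_units),
            "n_params": int(self.n_params_),
            "train_config": cfg.__dict__,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "DualInputClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_dual_input_model(backbone_spec="random_conv", n_classes: int = 6,
                           with_size_input: bool = True,
                           config: TrainConfig | None = None) -> DualInputClassifier:
    """Construct the (untrained) dual-input model; n_classes checked at fit."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    model = DualInputClassifier(backbone=backbone_spec,
                                with_size_input=with_size_input, config=config)
    model._declared_n_classes = n_classes
    return model


def _dataset_arrays(ds: LabeledImageSet):
    X = np.stack([r.image for r in ds.records])
    y = np.array([r.label for r in ds.records])
    sizes = np.array([r.original_size for r in ds.records], dtype=np.float64)
    return X, y, sizes


def train(model: DualInputClassifier, train_set: LabeledImageSet,
          val_set: LabeledImageSet, config: TrainConfig | None = None):
    """Fit on LabeledImageSets; returns (model, history)."""
    if config is not None:
        model.config = config
    Xt, yt, st = _dataset_arrays(train_set)
    Xv, yv, sv = _dataset_arrays(val_set)
    declared = getattr(model, "_declared_n_classes", None)
    model.fit(Xt, yt, sizes=st, X_val=Xv, y_val=yv, sizes_val=sv)
    if declared is not None and len(model.classes_) != declared:
        raise ValueError(
            f"model declared {declared} classes but data has {len(model.classes_)}")
    return model, model.history_


def predict(model: DualInputClassifier, images, sizes=None) -> np.ndarray:
    """Probability vectors for a batch of standardized images."""
    return model.predict_proba(images, sizes)


# -- hierarchy -------------------------------------------------------------


@dataclass
class ClassTree:
    """Base classes plus optional per-class subclass lists with niche models."""

    base_classes: tuple = BASE_CLASSES
    subclasses: dict = field(
        default_factory=lambda: {"Gelatinous": list(GELATINOUS_SUBCLASSES)})
    base_model: DualInputClassifier | None = None
    niche_models: dict = field(default_factory=dict)  # base class -> model

    def validate(self) -> None:
        if len(set(self.base_classes)) != len(self.base_classes):
            raise ValueError("duplicate base class names")
        for base, subs in self.subclasses.items():
            if base not in self.base_classes:
                raise ValueError(f"subclasses attached to unknown base {base!r}")
            if len(set(subs)) != len(subs):
                raise ValueError(f"duplicate subclass names under {base!r}")


@dataclass
class Prediction:
    """Routing outcome for one ROI."""

    base_class: str
    base_confidence: float
    subclass: str | None = None
    subclass_confidence: float | None = None
    accepted: bool = True
    source: str | None = None  # file reference for sorting


def _roi_inputs(rois, input_px: int):
    images, sizes, sources = [], [], []
    for roi in rois:
        if hasattr(roi, "crop"):
            img, orig = standardize_image(roi.crop, input_px)
            sizes.append(getattr(roi, "original_size", orig))
            sources.append(f"{roi.video_id}_{roi.frame_index:05d}_{roi.roi_id:03d}.png"
                           if hasattr(roi, "video_id") else None)
        else:  # bare image
            img, orig = standardize_image(np.asarray(roi), input_px)
            sizes.append(orig)
            sources.append(None)
        images.append(img)
    return np.stack(images), np.asarray(sizes, dtype=np.float64), sources


def classify_hierarchical(tree: ClassTree, rois,
                          conf_threshold: float = DEFAULT_CONF_THRESHOLD
                          ) -> list[Prediction]:
    """Base prediction for every ROI, niche refinement where routed.

    An ROI is routed into a niche model only when its base class has one
    attached AND its base confidence is at or above the threshold; ROIs
    below the threshold are flagged unaccepted and never routed.
    """
    tree.validate()
    if tree.base_model is None:
        raise ValueError("class tree has no base model attached")
    for base in tree.subclasses:
        if base not in tree.niche_models:
            raise ValueError(f"subdivided class {base!r} has no niche model")
    if not rois:
        return []
    model = tree.base_model
    images, sizes, sources = _roi_inputs(rois, model.input_px_)
    proba = model.predict_proba(images, sizes)
    preds: list[Prediction] = []
    for i in range(len(images)):
        k = int(proba[i].argmax())
        base = str(model.classes_[k])
        conf = float(proba[i, k])
        pred = Prediction(base_class=base, base_confidence=conf,
                          accepted=conf >= conf_threshold, source=sources[i])
        if pred.accepted and base in tree.niche_models:
            niche = tree.niche_models[base]
            nimg, _ = standardize_image(images[i], niche.input_px_)
            nproba = niche.predict_proba(nimg[None], sizes[i:i + 1])[0]
            j = int(nproba.argmax())
            pred.subclass = str(niche.classes_[j])
            pred.subclass_confidence = float(nproba[j])
        preds.append(pred)
    return preds


def sort_to_directories(predictions: list[Prediction], out_dir: str | Path,
                        image_root: str | Path | None = None) -> pd.DataFrame:
    """Copy accepted images under out_dir/<base>[/<subclass>]/, the rest
    under out_dir/_unsorted/; returns (and writes) the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    claimed: set = set()  # names taken within THIS run; re-runs overwrite
    for pred in predictions:
        if pred.accepted:
            dest_dir = out_dir / pred.base_class
            if pred.subclass:
                dest_dir = dest_dir / pred.subclass
        else:
            dest_dir = out_dir / "_unsorted"
        dest_dir.mkdir(parents=True, exist_ok=True)
        dest = None
        if pred.source is not None:
            src = Path(image_root) / pred.source if image_root else Path(pred.source)
            dest = dest_dir / src.name
            k = 1
            while dest in claimed:
                dest = dest_dir / f"{src.stem}_{k}{src.suffix}"
                k += 1
                logger.warning("name collision; writing %s", dest)
            claimed.add(dest)
            if src.exists():
                shutil.copyfile(src, dest)
            else:
                logger.warning("source image %s not found; manifest only", src)
        rows.append(
            {
                "source": pred.source,
                "dest": str(dest) if dest else None,
                "base_class": pred.base_class,
                "base_confidence": pred.base_confidence,
                "subclass": pred.subclass,
                "subclass_confidence": pred.subclass_confidence,
                "accepted": pred.accepted,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["source", "dest", "base_class", "base_confidence",
                       "subclass", "subclass_confidence", "accepted"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
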