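"""The three 4-level chaos classifiers.

* **RF-3f** — a random forest over the volume-only features (mean RMSE,
  std RMSE, peak amplitude).  Its role is adversarial: it measures how
  far loudness alone gets you, and it should lose badly whenever volume
  and chaos level are decoupled.
* **RF-53f** — the same forest over the 53 classical acoustic features.
* **CNN** — a compact convolutional network over 2-s, 96-band log-mel
  patches: three 5x5 convolutions with pre-activation batch
  normalization (BN -> ReLU -> conv), two interleaved max-pools and
  two dense layers, ~0.5M trainable weights.  Trained with categorical
  cross-entropy, batch size 64, Adam at lr 0.001, early stopping on
  validation accuracy with patience 15.  Segment-level predictions
  aggregate the per-patch class probabilities by element-wise geometric
  mean (renormalized), with argmax ties resolved to the lowest chaos
  level.

Both forests use 1000 estimators and are fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import _nn

N_CLASSES = 4
PROB_FLOOR = 1e-12  # geometric-mean floor so a single zero cannot annihilate


class ModelConfigError(ValueError):
    """Raised when a model configuration violates its invariants."""


# -- random forests --------------------------------------------------------

_FEATURE_DIMS = {"f3": 3, "f53": 53}


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 1000
    feature_set: str = "f53"  # {"f3", "f53"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ModelConfigError("n_estimators must be >= 1")
        if self.feature_set not in _FEATURE_DIMS:
            raise ModelConfigError(f"feature_set must be one of {sorted(_FEATURE_DIMS)}")

    @property
    def n_features(self) -> int:
        return _FEATURE_DIMS[self.feature_set]


def train_rf(features: np.ndarray, labels: np.ndarray, config: RFConfig) -> RandomForestClassifier:
    """Fit a seeded 4-class forest on a (n, 3) or (n, 53) feature table."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] != config.n_features:
        raise ModelConfigError(
            f"feature table must be (n, {config.n_features}) for {config.feature_set}, "
            f"got {X.shape}"
        )
    if np.unique(y).size < 2:
        raise ModelConfigError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
    )
    rf.fit(X, y)
    return rf


# -- CNN -------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters for the chaos CNN.

    The architecture is fixed to 3 conv layers / 2 pools / 2 dense
    layers; channel widths and the dense width are the free knobs and
    default to values landing near 0.5M parameters for 96x101 patches.
    ``max_epochs`` bounds the training loop on top of early stopping.
    """

    conv_channels: tuple[int, int, int] = (4, 8, 16)
    kernel: int = 5
    pool_sizes: tuple[int, int] = (4, 2)
    dense_units: int = 200
    n_classes: int = N_CLASSES
    batch_size: int = 64
    learning_rate: float = 0.001
    early_stopping_patience: int = 15
    max_epochs: int = 60
    param_count_bounds: tuple[int, int] = (300_000, 700_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ModelConfigError("the architecture has exactly 3 conv layers")


class ChaosCNN:
    """Log-mel patch classifier wrapping the numpy engine.

    Input patches are (96, 101) log-mel matrices; ``predict_proba``
    returns per-patch 4-class probabilities.
    """

    def __init__(self, config: CNNConfig, input_shape: tuple[int, int] = (96, 101)):
        self.config = config
        self.input_shape = input_shape
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.conv_channels
        k = config.kernel
        s1, s2 = config.pool_sizes
        h, w = input_shape
        h2, w2 = h // s1, w // s1  # after pool 1
        h3, w3 = h2 // s2, w2 // s2  # after pool 2
        self.net = _nn.Sequential(
            [
                _nn.BatchNorm2D(1),
                _nn.ReLU(),
                _nn.Conv2D(1, c1, k, rng),
                _nn.MaxPool(s1),
                _nn.BatchNorm2D(c1),
                _nn.ReLU(),
                _nn.Conv2D(c1, c2, k, rng),
                _nn.MaxPool(s2),
                _nn.BatchNorm2D(c2),
                _nn.ReLU(),
                _nn.Conv2D(c2, c3, k, rng),
                _nn.Flatten(),
                _nn.Dense(c3 * h3 * w3, config.dense_units, rng),
                _nn.ReLU1D(),
                _nn.Dense(config.dense_units, config.n_classes, rng),
            ]
        )
        self.history: list[dict] = []

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def _as_batch(self, patches: np.ndarray) -> np.ndarray:
        X = np.asarray(patches, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None, :, :]
        return X

    def fit(
        self,
        patches: np.ndarray,
        labels: np.ndarray,
        val_patches: np.ndarray,
        val_labels: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> "ChaosCNN":
        cfg = self.config
        rng = rng or np.random.default_rng(cfg.seed + 1)
        self.history = _nn.fit(
            self.net,
            self._as_batch(patches),
            np.asarray(labels, dtype=np.int64),
            self._as_batch(val_patches),
            np.asarray(val_labels, dtype=np.int64),
            rng,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            patience=cfg.early_stopping_patience,
            max_epochs=cfg.max_epochs,
        )
        return self

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return _nn.predict_proba(self.net, self._as_batch(patches))


def build_cnn(config: CNNConfig, input_shape: tuple[int, int] = (96, 101)) -> ChaosCNN:
    """Construct an untrained chaos CNN, enforcing the parameter budget.

    Raises :class:`ModelConfigError` (with the offending count) if the
    trainable parameter count falls outside ``config.param_count_bounds``
    — an engineering tolerance of +-0.2M around the ~0.5M target.
    """
    model = ChaosCNN(config, input_shape)
    lo, hi = config.param_count_bounds
    n = model.n_parameters
    if not lo <= n <= hi:
        raise ModelConfigError(
            f"parameter count {n} outside [{lo}, {hi}]; adjust conv_channels/dense_units"
        )
    return model


def validation_split(
    labels: np.ndarray,
    groups: np.ndarray | None,
    rng: np.random.Generator,
    fraction: float = 0.1,
) -> np.ndarray:
    """Boolean mask of held-out validation items for early stopping.

    Participant-grouped when at least 5 distinct groups are available
    (whole participants held out until ~``fraction`` of items is
    reached); otherwise a class-stratified random split.
    """
    labels = np.asarray(labels)
    n = labels.size
    mask = np.zeros(n, dtype=bool)
    if groups is not None:
        uniq = np.unique(np.asarray(groups))
        if uniq.size >= 5:
            for g in rng.permutation(uniq):
                mask |= np.asarray(groups) == g
                if mask.mean() >= fraction:
                    return mask
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        k = max(1, int(round(fraction * idx.size)))
        mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def train_cnn(
    patches: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig,
    groups: np.ndarray | None = None,
) -> ChaosCNN:
    """Train the CNN on labeled 2-s patches.

    Every patch carries its source segment's chaos label.  A ~10%
    validation split (participant-grouped when possible) drives early
    stopping; the best-epoch weights are kept.
    """
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels)
    if patches.shape[0] == 0:
        raise ModelConfigError("empty training set")
    rng = np.random.default_rng(config.seed + 17)
    val = validation_split(labels, groups, rng)
    model = build_cnn(config, input_shape=patches.shape[-2:])
    model.fit(patches[~val], labels[~val], patches[val], labels[val], rng)
    return model


# -- segment-level aggregation --------------------------------------------


@dataclass
class ChaosPrediction:
    segment_id: str
    probabilities: np.ndarray
    predicted_level: int = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        self.probabilities = p / p.sum()
        # np.argmax takes the first maximum -> ties break to the lowest level
        self.predicted_level = int(np.argmax(self.probabilities))


def aggregate_patch_probabilities(patch_probs: np.ndarray) -> np.ndarray:
    """Element-wise geometric mean over patches, renormalized to sum 1.

    Probabilities are floored at 1e-12 first so a single zero cannot
    annihilate a class.  With one patch this is the identity; the result
    is invariant to patch order.
    """
    p = np.maximum(np.asarray(patch_probs, dtype=float), PROB_FLOOR)
    g = np.exp(np.mean(np.log(p), axis=0))
    return g / g.sum()


def predict_segment(model: ChaosCNN, patches: np.ndarray, segment_id: str = "") -> ChaosPrediction:
    """Segment-level prediction: per-patch probabilities -> geometric mean."""
    probs = model.predict_proba(patches)
    return ChaosPrediction(segment_id, aggregate_patch_probabilities(probs))


# -- segment-classifier adapters (shared interface for the evaluation harness)


class RFSegmentClassifier:
    """Forest over a precomputed per-segment feature store.

    ``feature_store`` maps segment_id -> feature vector (3 or 53 dims).
    """

    def __init__(self, feature_store: dict[str, np.ndarray], config: RFConfig):
        self.store = feature_store
        self.config = config
        self.model: RandomForestClassifier | None = None

    def fit(self, segment_ids: list[str], labels: np.ndarray) -> "RFSegmentClassifier":
        X = np.stack([self.store[s] for s in segment_ids])
        self.model = train_rf(X, labels, self.config)
        return self

    def predict(self, segment_ids: list[str]) -> np.ndarray:
        X = np.stack([self.store[s] for s in segment_ids])
        return self.model.predict(X)


class CNNSegmentClassifier:
    """CNN over a precomputed per-segment log-mel patch store.

    ``patch_store`` maps segment_id -> (n_patches, 96, 101) array;
    ``participant_of`` (optional) supplies grouping for the validation
    split.  Prediction aggregates patch probabilities per segment.
    """

    def __init__(
        self,
        patch_store: dict[str, np.ndarray],
        config: CNNConfig,
        participant_of: dict[str, str] | None = None,
    ):
        self.store = patch_store
        self.config = config
        self.participant_of = participant_of or {}
        self.model: ChaosCNN | None = None

    def fit(self, segment_ids: list[str], labels: np.ndarray) -> "CNNSegmentClassifier":
        X, y, groups = [], [], []
        for sid, lab in zip(segment_ids, labels):
            p = self.store[sid]
            X.append(p)
            y.extend([lab] * p.shape[0])
            groups.extend([self.participant_of.get(sid, "")] * p.shape[0])
        X = np.concatenate(X, axis=0).astype(np.float32)
        self.model = train_cnn(X, np.asarray(y), self.config, groups=np.asarray(groups))
        return self

    def predict(self, segment_ids: list[str]) -> np.ndarray:
        counts = [self.store[s].shape[0] for s in segment_ids]
        X = np.concatenate([self.store[s] for s in segment_ids], axis=0).astype(np.float32)
        probs = self.model.predict_proba(X)
        out, lo = [], 0
        for c in counts:
            out.append(
                int(np.argmax(aggregate_patch_probabilities(probs[lo : lo + c])))
            )
            lo += c
        return np.asarray(out)
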