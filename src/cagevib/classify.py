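"""Dataset assembly, ensemble training with cross-validated hyperparameter
search, and evaluation (confusion matrix, per-class TPR/PPV, accuracy).

A data point is one 15-s window: the 11 vibration features paired with the
velocity-based ground-truth label. Training performs a seeded random search
over tree-ensemble hyperparameters — both bagged (random forest) and boosted
(gradient-boosted trees) candidates — scored by 5-fold cross-validated
accuracy, then refits the winner on the full training set. Trees are
scale-free, so no feature scaling or class rebalancing is applied.

The per-axis ablation harness retrains the same pipeline on feature subsets
(all axes, X+Z, X only, Y only, Z only) over an identical train/test split to
quantify how much activity information each vibration axis carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .errors import ConfigError, ContractError, FormatError
from .features import AXIS_FEATURES, FEATURE_NAMES
from .labeling import LabeledWindow
from .sim import CLASS_ORDER, ActivityClass

__all__ = [
    "Dataset", "SplitSpec", "TrainConfig", "ModelBundle", "EvalReport",
    "build_dataset", "split", "train", "evaluate", "ablation",
    "class_shares", "AXIS_MASKS", "save_bundle", "load_bundle",
]

log = logging.getLogger(__name__)

#: Feature-subset masks for the per-axis ablation, by feature index.
AXIS_MASKS: dict[str, tuple[int, ...]] = {
    "all": tuple(range(len(FEATURE_NAMES))),
    "xz": AXIS_FEATURES["x"] + AXIS_FEATURES["z"],
    "x": AXIS_FEATURES["x"],
    "y": AXIS_FEATURES["y"],
    "z": AXIS_FEATURES["z"],
}


@dataclass
class Dataset:
    """Rows of (window id, 11-feature vector, activity label)."""

    ids: np.ndarray            # window indices, unique
    X: np.ndarray              # (n, n_features)
    y: np.ndarray              # ActivityClass values as strings
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if not (len(self.ids) == len(self.X) == len(self.y)):
            raise ContractError("ids, X and y must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ContractError("window ids must be unique")
        if self.X.shape[1] != len(self.feature_names):
            raise ContractError("feature count does not match feature names")

    def __len__(self) -> int:
        return len(self.y)

    def select_features(self, mask: tuple[int, ...]) -> "Dataset":
        if len(mask) == 0:
            raise ContractError("feature mask must select at least one feature")
        return Dataset(self.ids, self.X[:, list(mask)], self.y,
                       tuple(self.feature_names[i] for i in mask))

    def take(self, rows: np.ndarray) -> "Dataset":
        return Dataset(self.ids[rows], self.X[rows], self.y[rows], self.feature_names)


@dataclass(frozen=True)
class SplitSpec:
    """Plain uniform random test withholding (1000 of 3880 in the study design)."""

    n_test: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_test <= 0:
            raise ContractError("n_test must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameter-search settings for the ensemble."""

    cv_folds: int = 5
    n_candidates: int = 6
    seed: int = 0


@dataclass
class ModelBundle:
    """A fitted ensemble plus everything needed to apply it consistently."""

    estimator: object
    feature_names: tuple[str, ...]
    mask_name: str
    cv_accuracy: float
    best_params: dict
    classes: tuple[str, ...] = tuple(c.value for c in CLASS_ORDER)
    config: TrainConfig = field(default_factory=TrainConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = prediction, class order
    resting/stationary/locomotion) and the derived metrics."""

    confusion: np.ndarray
    classes: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.n)

    @property
    def tpr(self) -> np.ndarray:
        """Per-class true positive rate (recall): diagonal over row sums."""
        rows = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(rows > 0, np.diag(self.confusion) / rows, np.nan)

    @property
    def ppv(self) -> np.ndarray:
        """Per-class positive predictive value (precision): diagonal over column sums."""
        cols = self.confusion.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(cols > 0, np.diag(self.confusion) / cols, np.nan)

    @property
    def binary_accuracy(self) -> float:
        """Resting-vs-active accuracy: stationary and locomotion collapsed."""
        c = self.confusion
        correct = c[0, 0] + c[1:, 1:].sum()
        return float(correct / self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tpr": self.tpr, "ppv": self.ppv},
            index=list(self.classes),
        )

    def __str__(self) -> str:
        lines = [
            "confusion matrix (rows: truth, cols: prediction)",
            pd.DataFrame(self.confusion, index=list(self.classes),
                         columns=list(self.classes)).to_string(),
            "",
            self.to_frame().to_string(float_format=lambda v: f"{100 * v:.1f}%"),
            "",
            f"accuracy: {100 * self.accuracy:.1f}%",
            f"resting-vs-active accuracy: {100 * self.binary_accuracy:.1f}%",
        ]
        return "\n".join(lines)


def build_dataset(features: pd.DataFrame, labels: list[LabeledWindow]) -> Dataset:
    """Inner-join features and labels on window index.

    Windows missing from either source, or flagged invalid by the labeler,
    are dropped (the count is logged).
    """
    label_frame = pd.DataFrame(
        {"window_index": [l.index for l in labels],
         "label": [l.label.value for l in labels],
         "valid": [l.valid for l in labels]}
    )
    n_before = max(len(features), len(label_frame))
    merged = features.merge(label_frame, on="window_index", how="inner")
    merged = merged[merged["valid"]]
    dropped = n_before - len(merged)
    if len(merged) == 0:
        raise FormatError("no overlapping valid windows between features and labels")
    if dropped:
        log.info("build_dataset: dropped %d unmatched or invalid windows", dropped)
    return Dataset(
        merged["window_index"].to_numpy(),
        merged[list(FEATURE_NAMES)].to_numpy(dtype=float),
        merged["label"].to_numpy(dtype=object),
    )


def split(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Withhold ``n_test`` rows uniformly at random (without replacement)."""
    if spec.n_test >= len(dataset):
        raise ContractError("n_test must be smaller than the dataset")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(dataset))
    return dataset.take(perm[spec.n_test:]), dataset.take(perm[:spec.n_test])


def class_shares(labels: np.ndarray) -> dict[str, float]:
    """Per-class share of a label vector, in percent."""
    labels = np.asarray(labels)
    return {c.value: 100.0 * float((labels == c.value).sum()) / len(labels)
            for c in CLASS_ORDER}


def _candidates(config: TrainConfig) -> list[tuple[str, dict]]:
    """Seeded random draw from the bagged/boosted ensemble search space."""
    rng = np.random.default_rng(config.seed)
    space: list[tuple[str, dict]] = []
    for _ in range(config.n_candidates):
        if rng.random() < 0.5:
            space.append(("bag", {
                "n_estimators": int(rng.choice([100, 200, 300])),
                "max_depth": [None, 8, 16][int(rng.integers(3))],
                "max_features": ["sqrt", 0.5, 1.0][int(rng.integers(3))],
            }))
        else:
            space.append(("boost", {
                "max_iter": int(rng.choice([100, 200, 300])),
                "learning_rate": float(rng.choice([0.03, 0.1, 0.3])),
                "max_depth": [None, 3, 6][int(rng.integers(3))],
            }))
    return space


def _make_estimator(family: str, params: dict, seed: int):
    if family == "bag":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    return HistGradientBoostingClassifier(random_state=seed, **params)


def train(dataset: Dataset, config: TrainConfig = TrainConfig(),
          mask_name: str = "all") -> ModelBundle:
    """Fit the ensemble after a seeded hyperparameter search.

    Every candidate is scored by ``cv_folds``-fold cross-validated accuracy
    on the training set; the best candidate is refit on all training rows.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ConfigError("training requires at least two classes")
    if len(dataset) < 5 * config.cv_folds:
        raise ConfigError("training set too small for cross-validation")
    cv = StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed)
    best = None
    for family, params in _candidates(config):
        est = _make_estimator(family, params, config.seed)
        score = cross_val_score(est, dataset.X, dataset.y, cv=cv,
                                scoring="accuracy", n_jobs=1).mean()
        log.debug("candidate %s %s: CV accuracy %.4f", family, params, score)
        if best is None or score > best[0]:
            best = (score, family, params)
    score, family, params = best
    estimator = _make_estimator(family, params, config.seed)
    estimator.fit(dataset.X, dataset.y)
    return ModelBundle(estimator, dataset.feature_names, mask_name,
                       cv_accuracy=float(score),
                       best_params={"family": family, **params},
                       config=config)


def evaluate(bundle: ModelBundle, test: Dataset) -> EvalReport:
    """Confusion matrix and derived metrics of the bundle on held-out rows."""
    if test.feature_names != bundle.feature_names:
        raise ContractError(
            "test features do not match the bundle "
            f"({test.feature_names} vs {bundle.feature_names})")
    pred = bundle.predict(test.X)
    classes = bundle.classes
    lut = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for truth, p in zip(test.y, pred):
        confusion[lut[truth], lut[p]] += 1
    return EvalReport(confusion, classes)


def ablation(dataset: Dataset, spec: SplitSpec,
             masks: dict[str, tuple[int, ...]] | None = None,
             config: TrainConfig = TrainConfig()) -> pd.DataFrame:
    """Train and evaluate one model per feature mask on the identical split.

    Returns one row per mask with accuracy and per-class TPR/PPV (the shape
    of the per-axis comparison table).
    """
    masks = dict(masks) if masks is not None else dict(AXIS_MASKS)
    train_all, test_all = split(dataset, spec)
    rows = []
    for name, mask in masks.items():
        bundle = train(train_all.select_features(mask), config, mask_name=name)
        report = evaluate(bundle, test_all.select_features(mask))
        row = {"mask": name, "accuracy": report.accuracy,
               "binary_accuracy": report.binary_accuracy}
        for i, c in enumerate(report.classes):
            row[f"tpr_{c}"] = report.tpr[i]
            row[f"ppv_{c}"] = report.ppv[i]
        rows.append(row)
    return pd.DataFrame(rows).set_index("mask")


# ---------------------------------------------------------------------------
# Model persistence: a versioned joblib archive; loading refuses on
# feature-name mismatch so a model is never applied to the wrong columns.
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump({
        "version": _BUNDLE_VERSION,
        "feature_names": list(bundle.feature_names),
        "mask_name": bundle.mask_name,
        "cv_accuracy": bundle.cv_accuracy,
        "best_params": bundle.best_params,
        "classes": list(bundle.classes),
        "estimator": bundle.estimator,
    }, path)


def load_bundle(path, expect_features: tuple[str, ...] | None = None) -> ModelBundle:
    doc = joblib.load(path)
    if doc.get("version") != _BUNDLE_VERSION:
        raise FormatError(f"unsupported model bundle version {doc.get('version')!r}")
    names = tuple(doc["feature_names"])
    if expect_features is not None and names != tuple(expect_features):
        raise FormatError("model bundle feature names do not match the expected features")
    if any(n not in FEATURE_NAMES for n in names):
        raise FormatError("model bundle names unknown features")
    return ModelBundle(doc["estimator"], names, doc["mask_name"],
                       doc["cv_accuracy"], doc["best_params"],
                       tuple(doc["classes"]))
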