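"""The microbiome-derived IBS index.

A gradient-boosted-tree binary classifier (XGBoost, DART booster, binary
logistic objective) is trained to separate IBS from healthy genus-level
profiles; its logistic output in [0, 1] is the *IBS index* — higher means a
more IBS-like community. Hyperparameters come from a seeded random search
over a fixed space; performance is reported by stratified k-fold
cross-validation repeated over seeds.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .io import SCHEMA_VERSION, AbundanceTable

POSITIVE_CLASS = "ibs"
#: Decision threshold applied to the index when reporting accuracy.
ACCURACY_THRESHOLD = 0.5


@dataclass
class TrainingConfig:
    """Boosted-tree hyperparameters. ``booster='dart'`` adds tree dropout
    during training (``rate_drop``); prediction always uses the full ensemble."""

    max_depth: int = 4
    learning_rate: float = 0.1
    n_estimators: int = 150
    subsample: float = 0.8
    rate_drop: float = 0.1
    booster: str = "dart"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)


#: Random-search space for hyperparameter tuning (log-uniform where noted).
SEARCH_SPACE = {
    "max_depth": (2, 6),            # uniform integer
    "learning_rate": (0.01, 0.3),   # log-uniform
    "n_estimators": (50, 300),      # uniform integer
    "subsample": (0.5, 1.0),        # uniform
    "rate_drop": (0.0, 0.3),        # uniform
}


def _make_classifier(config: TrainingConfig, seed: int) -> xgboost.XGBClassifier:
    return xgboost.XGBClassifier(
        booster=config.booster,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        subsample=config.subsample,
        rate_drop=config.rate_drop if config.booster == "dart" else 0.0,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed) % (2**31),
    )


def _encode_labels(labels, sample_ids) -> np.ndarray:
    labels = pd.Series(labels)
    if not labels.index.equals(pd.Index(range(len(labels)))):
        labels = labels.reindex(sample_ids)
    classes = set(labels.unique())
    if classes != {"healthy", "ibs"}:
        raise ValueError(f"labels must contain exactly {{'healthy', 'ibs'}}, got {sorted(classes)}")
    return (labels == POSITIVE_CLASS).to_numpy().astype(int)


def _sample_config(rng: np.random.Generator) -> TrainingConfig:
    lo, hi = SEARCH_SPACE["learning_rate"]
    return TrainingConfig(
        max_depth=int(rng.integers(SEARCH_SPACE["max_depth"][0], SEARCH_SPACE["max_depth"][1] + 1)),
        learning_rate=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        n_estimators=int(rng.integers(SEARCH_SPACE["n_estimators"][0],
                                      SEARCH_SPACE["n_estimators"][1] + 1)),
        subsample=float(rng.uniform(*SEARCH_SPACE["subsample"])),
        rate_drop=float(rng.uniform(*SEARCH_SPACE["rate_drop"])),
    )


def tune_hyperparameters(
    table: AbundanceTable, labels, n_trials: int, seed: int = 0, inner_folds: int = 3
) -> TrainingConfig:
    """Seeded random search; the best trial by mean inner-CV ROC-AUC wins.

    Ties break toward the earlier trial, so the result is deterministic.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    y = _encode_labels(labels, table.sample_ids)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("tuning requires at least 10 samples per class")
    rng = np.random.default_rng(seed)
    X = table.values
    best_auc, best_config = -np.inf, None
    for trial in range(n_trials):
        config = _sample_config(rng)
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        aucs = []
        for train_idx, test_idx in skf.split(X, y):
            clf = _make_classifier(config, seed)
            clf.fit(X[train_idx], y[train_idx])
            aucs.append(roc_auc_score(y[test_idx], clf.predict_proba(X[test_idx])[:, 1]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_config = mean_auc, config
    return best_config


@dataclass
class CVReport:
    """Held-out performance over (seed, fold) cells of repeated stratified CV."""

    records: pd.DataFrame  # columns: seed, fold, roc_auc, accuracy, n_test
    config: TrainingConfig

    @property
    def mean_auc(self) -> float:
        return float(self.records["roc_auc"].mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def sd_auc(self) -> float:
        return float(self.records["roc_auc"].std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_auc": self.sd_auc,
            "config": self.config.to_dict(),
            "records": self.records.to_dict(orient="records"),
        }


def cross_validate(
    table: AbundanceTable,
    labels,
    k: int = 5,
    n_seeds: int = 10,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV repeated over ``n_seeds`` shuffles.

    Reports held-out ROC-AUC and accuracy (index thresholded at 0.5) per
    (seed, fold); folds partition the samples within each repetition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or TrainingConfig()
    y = _encode_labels(labels, table.sample_ids)
    X = table.values
    rows = []
    for rep in range(n_seeds):
        rep_seed = int(seed) + rep
        if k == len(y):  # leave-one-out: stratification is moot
            splits = list(KFold(n_splits=k).split(X))
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            try:
                splits = list(skf.split(X, y))
            except ValueError as exc:
                raise ValueError(f"stratification failed — use a smaller k ({exc})") from exc
        for fold, (train_idx, test_idx) in enumerate(splits):
            if len(set(y[train_idx])) < 2:
                raise ValueError("a class is absent from a training fold — use a smaller k")
            clf = _make_classifier(config, rep_seed)
            clf.fit(X[train_idx], y[train_idx])
            prob = clf.predict_proba(X[test_idx])[:, 1]
            auc = roc_auc_score(y[test_idx], prob) if len(set(y[test_idx])) == 2 else np.nan
            acc = accuracy_score(y[test_idx], (prob >= ACCURACY_THRESHOLD).astype(int))
            rows.append((rep_seed, fold, float(auc), float(acc), len(test_idx)))
    records = pd.DataFrame(rows, columns=["seed", "fold", "roc_auc", "accuracy", "n_test"])
    return CVReport(records=records, config=config)


class IBSIndexModel:
    """A trained boosted-tree scorer mapping a genus composition to [0, 1].

    Feature order is part of the model: scoring realigns input columns by
    taxon name and refuses vectors whose taxa do not match.
    """

    def __init__(self, clf: xgboost.XGBClassifier, feature_names: list[str],
                 config: TrainingConfig):
        self._clf = clf
        self.feature_names = list(feature_names)
        self.config = config
        self.schema_version = SCHEMA_VERSION

    def _align(self, composition) -> np.ndarray:
        if isinstance(composition, AbundanceTable):
            composition = composition.data
        if isinstance(composition, pd.DataFrame):
            missing = [t for t in self.feature_names if t not in composition.columns]
            if missing:
                raise ValueError(f"composition lacks model taxon {missing[0]!r}")
            extra = [t for t in composition.columns if t not in self.feature_names]
            if extra:
                raise ValueError(f"composition has unknown taxon {extra[0]!r}")
            return composition[self.feature_names].to_numpy(dtype=float)
        if isinstance(composition, pd.Series):
            return self._align(composition.to_frame().T)
        arr = np.atleast_2d(np.asarray(composition, dtype=float))
        if arr.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} taxa, got {arr.shape[1]}"
            )
        return arr

    def score(self, composition):
        """IBS index in [0, 1] for one composition or a batch (rows)."""
        if isinstance(composition, pd.Series):
            one_dim = True
        elif isinstance(composition, (pd.DataFrame, AbundanceTable)):
            one_dim = False
        else:
            one_dim = np.asarray(composition, dtype=float).ndim == 1
        arr = self._align(composition)
        scores = np.clip(self._clf.get_booster().inplace_predict(arr), 0.0, 1.0)
        return float(scores[0]) if one_dim else scores

    def save(self, path) -> None:
        """JSON artifact: config + feature names + serialized ensemble."""
        with tempfile.NamedTemporaryFile(suffix=".json", mode="r+") as tmp:
            self._clf.get_booster().save_model(tmp.name)
            booster_json = json.loads(Path(tmp.name).read_text())
        payload = {
            "schema_version": self.schema_version,
            "feature_names": self.feature_names,
            "config": self.config.to_dict(),
            "booster": booster_json,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path) -> "IBSIndexModel":
        payload = json.loads(Path(path).read_text())
        config = TrainingConfig.from_dict(payload["config"])
        clf = _make_classifier(config, 0)
        with tempfile.NamedTemporaryFile(suffix=".json", mode="w") as tmp:
            tmp.write(json.dumps(payload["booster"]))
            tmp.flush()
            booster = xgboost.Booster()
            booster.load_model(tmp.name)
        clf._Booster = booster
        return cls(clf, payload["feature_names"], config)


def train_index_model(
    table: AbundanceTable, labels, config: TrainingConfig | None = None, seed: int = 0
) -> IBSIndexModel:
    """Fit the final index model on every supplied sample."""
    config = config or TrainingConfig()
    y = _encode_labels(labels, table.sample_ids)
    if len(set(y)) < 2:
        raise ValueError("training requires both classes")
    clf = _make_classifier(config, seed)
    clf.fit(table.values, y)
    return IBSIndexModel(clf, table.taxon_names, config)


def score_index(model: IBSIndexModel, composition):
    """Functional alias for :meth:`IBSIndexModel.score`."""
    return model.score(composition)
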