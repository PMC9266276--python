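"""Bag-of-words gradient-boosted classification of oversweet-phrase reviews.

Separates reviews whose oversweet phrase refers to the purchased product
from reviews that merely contain such a phrase (e.g. comparisons to other
brands).  The feature space is word counts over a frequency-mass vocabulary
prefix; hyperparameters are grid-searched with k-fold cross-validation
scored by F1.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .corpus_io import Review
from .sweetmatch import tokenize

__all__ = [
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LabeledReview",
    "TrainedClassifier",
    "DEFAULT_GRID",
    "split_labeled",
    "build_vocabulary",
    "featurize",
    "train_classifier",
    "predict",
    "predict_texts",
    "evaluate",
    "save_classifier",
    "load_classifier",
]

LABEL_POSITIVE = "oversweet-product"
LABEL_NEGATIVE = "not-oversweet-product"
LABELS = (LABEL_POSITIVE, LABEL_NEGATIVE)

# Artifact defaults; the source method does not print its grid.
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 6],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [100, 300],
}


@dataclass(frozen=True)
class LabeledReview:
    review_id: str
    label: str  # LABEL_POSITIVE | LABEL_NEGATIVE
    source: str = "manual"  # manual | model

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        if self.source not in ("manual", "model"):
            raise ValueError(f"invalid source {self.source!r}")


@dataclass
class TrainedClassifier:
    vocabulary: list[str]
    model: GradientBoostingClassifier
    params: dict
    metrics: dict = field(default_factory=dict)


def split_labeled(
    labeled: Sequence, train_fraction: float, seed: int
) -> tuple[list, list]:
    """Random, reproducible, exact train/test partition.

    ``n_train = floor(n * train_fraction)`` (5590 items at 0.75 -> 4192/1398);
    the remainder is the test set.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    items = list(labeled)
    if len(items) < 2:
        raise ValueError("need at least 2 labeled reviews to split")
    n_train = int(len(items) * train_fraction)
    n_train = min(max(n_train, 1), len(items) - 1)
    order = np.random.default_rng(seed).permutation(len(items))
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


def build_vocabulary(texts: Iterable[str], mass_fraction: float = 0.995,
                     type_quantile: bool = False) -> list[str]:
    """Most-frequent-word vocabulary.

    Words are sorted by descending corpus frequency (ties lexicographic).
    By default the smallest prefix whose cumulative token frequency reaches
    ``mass_fraction`` is kept; with ``type_quantile`` the most frequent
    ``mass_fraction`` share of word *types* is kept instead.
    """
    if not 0 < mass_fraction <= 1:
        raise ValueError("mass_fraction must be in (0, 1]")
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(tokenize(text))
    if not counts:
        raise ValueError("empty corpus: no tokens to build a vocabulary from")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if type_quantile:
        n_keep = max(1, int(np.ceil(mass_fraction * len(ranked))))
        return [w for w, _ in ranked[:n_keep]]
    total = sum(counts.values())
    vocab = []
    cum = 0
    for word, c in ranked:
        vocab.append(word)
        cum += c
        if cum / total >= mass_fraction:
            break
    return vocab


def featurize(texts: Sequence[str], vocabulary: Sequence[str]) -> sparse.csr_matrix:
    """Document-term count matrix; out-of-vocabulary words are ignored."""
    if not vocabulary:
        raise ValueError("vocabulary is empty")
    index = {w: j for j, w in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, text in enumerate(texts):
        doc = Counter(tokenize(text))
        for word, c in doc.items():
            j = index.get(word)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(texts), len(vocabulary)), dtype=np.int64
    )


def _encode(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if l == LABEL_POSITIVE else 0 for l in labels])


def train_classifier(
    texts: Sequence[str],
    labels: Sequence[str],
    grid: Optional[Mapping[str, list]] = None,
    k_folds: int = 10,
    seed: int = 0,
    mass_fraction: float = 0.995,
    vocabulary: Optional[Sequence[str]] = None,
) -> TrainedClassifier:
    """Grid-search a gradient-boosted bag-of-words model by cross-validated F1.

    The winning combination is refit on the full training set; CV accuracy
    and F1 (mean +/- sd) are recorded in ``metrics``.
    """
    y = _encode(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both labels")
    if vocabulary is None:
        vocabulary = build_vocabulary(texts, mass_fraction)
    X = featurize(texts, vocabulary)
    grid = dict(grid) if grid is not None else DEFAULT_GRID
    n_folds = min(k_folds, int(np.bincount(y).min()))
    search = GridSearchCV(
        GradientBoostingClassifier(random_state=seed),
        param_grid=grid,
        scoring={"f1": "f1", "accuracy": "accuracy"},
        refit="f1",
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
    )
    search.fit(X, y)
    best = search.best_index_
    metrics = {
        "cv_f1_mean": float(search.cv_results_["mean_test_f1"][best]),
        "cv_f1_sd": float(search.cv_results_["std_test_f1"][best]),
        "cv_accuracy_mean": float(search.cv_results_["mean_test_accuracy"][best]),
        "cv_accuracy_sd": float(search.cv_results_["std_test_accuracy"][best]),
        "n_train": int(len(texts)),
        "k_folds": int(n_folds),
        "seed": int(seed),
    }
    return TrainedClassifier(
        vocabulary=list(vocabulary),
        model=search.best_estimator_,
        params={k: v for k, v in search.best_params_.items()},
        metrics=metrics,
    )


def predict_texts(classifier: TrainedClassifier, texts: Sequence[str]) -> list[str]:
    if not texts:
        return []
    X = featurize(texts, classifier.vocabulary)
    y = classifier.model.predict(X)
    return [LABEL_POSITIVE if v == 1 else LABEL_NEGATIVE for v in y]


def predict(classifier: TrainedClassifier, reviews: Sequence[Review]) -> list[LabeledReview]:
    """Label each review with the model; ``source`` is always ``"model"``."""
    texts = [f"{r.title} {r.text}" for r in reviews]
    return [
        LabeledReview(review_id=r.review_id, label=label, source="model")
        for r, label in zip(reviews, predict_texts(classifier, texts))
    ]


def evaluate(classifier: TrainedClassifier, texts: Sequence[str],
             labels: Sequence[str]) -> dict[str, float]:
    """Accuracy and F1 of the model against reference labels."""
    if not texts:
        raise ValueError("cannot evaluate on an empty set")
    y_true = _encode(labels)
    y_pred = _encode(predict_texts(classifier, texts))
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0.0)),
    }


def save_classifier(classifier: TrainedClassifier, directory: str | Path) -> None:
    """Versioned archive: joblib model + JSON manifest with vocabulary/metrics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(classifier.model, directory / "model.joblib")
    manifest = {
        "format_version": 1,
        "vocabulary": classifier.vocabulary,
        "params": classifier.params,
        "metrics": classifier.metrics,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_classifier(directory: str | Path) -> TrainedClassifier:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text("utf-8"))
    model = joblib.load(directory / "model.joblib")
    return TrainedClassifier(
        vocabulary=manifest["vocabulary"],
        model=model,
        params=manifest["params"],
        metrics=manifest["metrics"],
    )
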