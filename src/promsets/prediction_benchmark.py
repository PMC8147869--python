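"""MT-vs-ST classification benchmark.

Fingerprint features, three classifier families (RBF-kernel SVM, k-NN with
Tanimoto distance, random forest), repeated balanced trials scored by
balanced accuracy, and a variant comparison of the original dataset against
its randomly reduced and NN-reduced halves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from promsets.activity_data import PromiscuityDataset
from promsets.chem import Fingerprint
from promsets.errors import ContractError
from promsets.set_reduction import nn_removal, random_removal

CLASSIFIERS = ("support_vector_machine", "k_nearest_neighbor", "random_forest")
VARIANTS = ("original", "random_removal", "nn_removal")


@dataclass
class BenchmarkResult:
    """Balanced-accuracy distributions per (classifier, variant)."""

    scores: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    n_trials: int = 0
    seed: int = 0
    split_fraction: float = 0.5

    def median(self, classifier: str, variant: str = "original") -> float:
        return float(np.median(self.scores[classifier][variant]))

    def as_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "split_fraction": self.split_fraction,
            "scores": self.scores,
        }


def featurize(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
) -> tuple[np.ndarray, np.ndarray]:
    """Bit-vector feature rows and binary MT labels.

    Row order is deterministic: groups by ascending id, MT row first, then
    ST rows in target-position order.
    """
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for g in sorted(dataset.groups, key=lambda g: g.group_id):
        for i, cid in enumerate(g.members()):
            fp = fingerprints[cid]
            v = np.zeros(fp.n_bits, dtype=bool)
            v[sorted(fp.bits)] = True
            rows.append(v)
            labels.append(1 if i == 0 else 0)
    if not rows:
        return np.zeros((0, 0), dtype=bool), np.zeros(0, dtype=int)
    return np.vstack(rows), np.asarray(labels, dtype=int)


def balanced_accuracy(labels: Sequence[int], predictions: Sequence[int]) -> float:
    """(sensitivity + specificity) / 2."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ContractError("labels and predictions differ in length")
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise ContractError("both classes must be present in labels")
    sensitivity = float((p[pos] == 1).mean())
    specificity = float((p[neg] == 0).mean())
    return (sensitivity + specificity) / 2.0


def _make_classifiers(trial_seed: int, knn_metric: str) -> dict:
    return {
        "support_vector_machine": SVC(kernel="rbf", C=1.0, random_state=trial_seed),
        "k_nearest_neighbor": KNeighborsClassifier(n_neighbors=1, metric=knn_metric),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=trial_seed, n_jobs=1),
    }


def run_trials(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
    n_trials: int = 10,
    seed: int = 0,
    split_fraction: float = 0.5,
    knn_metric: str = "jaccard",
) -> dict[str, list[float]]:
    """Repeated balanced MT-vs-ST trials on one dataset.

    Per trial: ST compounds are down-sampled uniformly to the MT count, the
    balanced set is split stratified into training/test halves, and each
    classifier family is fit and scored by balanced accuracy. All randomness
    derives from (seed, trial index); results are reproducible.
    """
    X, y = featurize(dataset, fingerprints)
    n_mt = int((y == 1).sum())
    n_st = int((y == 0).sum())
    if n_mt < 2 or n_st < 2:
        raise ContractError("need >= 2 compounds in each class")
    scores: dict[str, list[float]] = {name: [] for name in CLASSIFIERS}
    for trial in range(n_trials):
        rng = np.random.default_rng([seed, trial])
        st_idx = np.flatnonzero(y == 0)
        keep_st = rng.choice(st_idx, size=min(n_mt, n_st), replace=False)
        idx = np.sort(np.concatenate([np.flatnonzero(y == 1), keep_st]))
        Xb, yb = X[idx], y[idx]
        trial_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xb, yb, test_size=split_fraction, stratify=yb, random_state=trial_seed
        )
        for name, clf in _make_classifiers(trial_seed, knn_metric).items():
            clf.fit(X_tr, y_tr)
            scores[name].append(balanced_accuracy(y_te, clf.predict(X_te)))
    return scores


def run_benchmark(
    dataset: PromiscuityDataset,
    fingerprints: Mapping[str, Fingerprint],
    n_trials: int = 10,
    seed: int = 0,
    split_fraction: float = 0.5,
) -> BenchmarkResult:
    """Original vs random-removal vs NN-removal comparison."""
    random_ds, _ = random_removal(dataset, 0.5, seed)
    nn_ds, _ = nn_removal(dataset, fingerprints)
    variants = {"original": dataset, "random_removal": random_ds, "nn_removal": nn_ds}
    result = BenchmarkResult(
        scores={name: {} for name in CLASSIFIERS},
        n_trials=n_trials,
        seed=seed,
        split_fraction=split_fraction,
    )
    for variant, ds in variants.items():
        per_clf = run_trials(
            ds, fingerprints, n_trials=n_trials, seed=seed, split_fraction=split_fraction
        )
        for name in CLASSIFIERS:
            result.scores[name][variant] = per_clf[name]
    return result
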