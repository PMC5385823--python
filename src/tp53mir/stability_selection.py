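"""Resampled SVM-RFE stability selection with an abundance score.

Each repeat draws a stratified random 1/3 train / 2/3 test split, runs
recursive feature elimination with a linear soft-margin SVM (features ranked
by squared weight, the weakest half dropped per iteration, never below the
requested feature count), refits on the surviving features and records the
test accuracy. Per-gene abundance is the fraction of repeats in which the
gene was selected; the abundance of a gene set is the mean over repeats of
|selected ∩ set| / |set| (average fractional presence).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import MergedMatrix
from .errors import DegenerateInputError, ParameterError


@dataclass
class RepeatResult:
    seed: int
    train_samples: list[str]
    selected: list[str]
    accuracy: float
    balanced_accuracy: float
    failed: bool = False
    reason: str = ""


@dataclass
class SelectionRun:
    n_repeats: int
    n_features: int
    repeats: list[RepeatResult]
    abundance: pd.Series  # per gene
    set_abundance: float
    novel_set: list[str] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.repeats if not r.failed])

    @property
    def n_successful(self) -> int:
        return sum(not r.failed for r in self.repeats)


def split_samples(
    sample_ids: list[str],
    class_labels,
    train_frac: float = 1 / 3,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified random split; each class keeps >= 1 training sample."""
    labels = pd.Series(list(class_labels), index=list(sample_ids))
    rng = np.random.default_rng(seed)
    train: list[str] = []
    for cls in sorted(labels.unique()):
        members = list(labels.index[labels == cls])
        if len(members) < 2:
            raise ParameterError(f"split_samples: class {cls!r} has < 2 samples")
        n_train = min(max(1, round(train_frac * len(members))), len(members) - 1)
        picked = rng.choice(len(members), size=n_train, replace=False)
        train.extend(members[i] for i in sorted(picked))
    train_set = set(train)
    test = [s for s in sample_ids if s not in train_set]
    train = [s for s in sample_ids if s in train_set]
    return train, test


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    n_features: int = 20,
    drop_frac: float = 0.5,
    C: float = 1.0,
) -> list[str]:
    """Recursive feature elimination by squared linear-SVM weight.

    Per iteration the lowest ceil(drop_frac * current) features are dropped,
    never going below ``n_features``. Ties are broken by feature id. The
    survivors come back ranked by final |weight| (descending).
    """
    X = np.asarray(X, dtype=float)
    if n_features > X.shape[1]:
        raise ParameterError("svm_rfe: n_features exceeds available features")
    if not 0 < drop_frac <= 1:
        raise ParameterError("svm_rfe: drop_frac must be in (0, 1]")
    if np.all(X.std(axis=0) == 0):
        raise DegenerateInputError("svm_rfe: all features constant")
    remaining = list(range(X.shape[1]))

    def fit_weights(cols: list[int]) -> np.ndarray:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, cols], y)
        return np.asarray(clf.coef_).ravel() ** 2

    while len(remaining) > n_features:
        w2 = fit_weights(remaining)
        n_drop = min(
            math.ceil(drop_frac * len(remaining)), len(remaining) - n_features
        )
        order = sorted(range(len(remaining)), key=lambda i: (w2[i], feature_names[remaining[i]]))
        drop = set(order[:n_drop])
        remaining = [c for i, c in enumerate(remaining) if i not in drop]
    w2 = fit_weights(remaining)
    final_order = sorted(
        range(len(remaining)), key=lambda i: (-w2[i], feature_names[remaining[i]])
    )
    return [feature_names[remaining[i]] for i in final_order]


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def run_selection(
    matrix: pd.DataFrame | MergedMatrix,
    labels=None,
    novel_set: list[str] | None = None,
    n_repeats: int = 100,
    n_features: int = 20,
    train_frac: float = 1 / 3,
    drop_frac: float = 0.5,
    C: float = 1.0,
    base_seed: int = 0,
) -> SelectionRun:
    """The full resampling procedure over a genes x samples matrix.

    Repeat i uses seed base_seed + i for its split. Failed repeats are
    recorded and skipped; more than 10% failures aborts the run.
    """
    if isinstance(matrix, MergedMatrix):
        labels = pd.Series(matrix.classes, index=matrix.samples)
        matrix = matrix.to_frame()
    if labels is None:
        raise ParameterError("run_selection: labels required with a DataFrame matrix")
    labels = pd.Series(list(labels), index=list(matrix.columns)) if not isinstance(
        labels, pd.Series
    ) else labels.loc[list(matrix.columns)]
    novel_set = list(novel_set or [])
    unknown = set(novel_set) - set(matrix.index)
    if unknown:
        raise ParameterError(f"run_selection: novel genes outside universe: {sorted(unknown)}")
    if not novel_set:
        warnings.warn("run_selection: empty novel set; set abundance defined as 0")
    genes = list(matrix.index)
    X_all = matrix.to_numpy(float).T  # samples x genes
    sample_index = {s: i for i, s in enumerate(matrix.columns)}

    repeats: list[RepeatResult] = []
    counts = pd.Series(0, index=genes, dtype=float)
    set_fracs = []
    for i in range(n_repeats):
        seed = base_seed + i
        try:
            train_ids, test_ids = split_samples(
                list(matrix.columns), labels, train_frac=train_frac, seed=seed
            )
            tr = [sample_index[s] for s in train_ids]
            te = [sample_index[s] for s in test_ids]
            X_tr, X_te = _standardize(X_all[tr], X_all[te])
            y_tr = labels.loc[train_ids].to_numpy()
            y_te = labels.loc[test_ids].to_numpy()
            selected = svm_rfe(
                X_tr, y_tr, genes, n_features=n_features, drop_frac=drop_frac, C=C
            )
            cols = [genes.index(g) for g in selected]
            clf = SVC(kernel="linear", C=C).fit(X_tr[:, cols], y_tr)
            pred = clf.predict(X_te[:, cols])
            acc = float((pred == y_te).mean())
            per_class = [
                float((pred[y_te == c] == c).mean()) for c in np.unique(y_te)
            ]
            repeats.append(
                RepeatResult(
                    seed=seed,
                    train_samples=train_ids,
                    selected=selected,
                    accuracy=acc,
                    balanced_accuracy=float(np.mean(per_class)),
                )
            )
            counts[selected] += 1
            if novel_set:
                set_fracs.append(len(set(selected) & set(novel_set)) / len(novel_set))
        except (ParameterError, DegenerateInputError, ValueError) as exc:
            repeats.append(
                RepeatResult(
                    seed=seed, train_samples=[], selected=[], accuracy=float("nan"),
                    balanced_accuracy=float("nan"), failed=True, reason=str(exc),
                )
            )
            n_failed = sum(r.failed for r in repeats)
            if n_failed > 0.1 * n_repeats:
                raise RuntimeError(
                    f"run_selection: {n_failed} repeats failed (> 10% of {n_repeats}); "
                    f"last reason: {exc}"
                ) from exc
    n_ok = sum(not r.failed for r in repeats)
    abundance = counts / n_repeats
    set_abundance = float(np.mean(set_fracs)) if set_fracs else 0.0
    return SelectionRun(
        n_repeats=n_repeats,
        n_features=n_features,
        repeats=repeats,
        abundance=abundance,
        set_abundance=set_abundance,
        novel_set=novel_set,
    )
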