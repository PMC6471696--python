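"""Biomarker panel construction and evaluation.

Pairwise Pearson correlation between candidate methylation markers, greedy
redundancy pruning (a highly correlated pair keeps the member with the
larger univariate effect), repeated stratified random-split evaluation of
a linear soft-margin SVM classifier, and backward panel minimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_formats import SampleMatrix

logger = logging.getLogger(__name__)


@dataclass
class MarkerPanel:
    probes: list[str]
    correlations: pd.DataFrame
    mean_accuracy: float = float("nan")
    sd_accuracy: float = float("nan")
    n_splits: int = 0
    seed: int | None = None


def marker_correlation(beta: SampleMatrix) -> pd.DataFrame:
    """Pearson correlation between every pair of probes over all samples."""
    if beta.values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    constant = beta.values.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "constant probes with undefined correlations: %s",
            beta.values.index[constant].tolist(),
        )
    return beta.values.T.corr(method="pearson")


def decorrelate(
    candidates: list[str],
    corr: pd.DataFrame,
    effects: dict[str, float],
    threshold: float = 0.8,
) -> list[str]:
    """Greedy redundancy pruning: no retained pair exceeds |corr| > threshold.

    Pairs are visited by descending |correlation|; when both members of an
    offending pair are still present, the one with the smaller |effect| is
    dropped (ties: the lexicographically larger id). Deterministic; output
    preserves input order.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    kept = set(candidates)
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append((abs(r), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, a, b in pairs:
        if a in kept and b in kept:
            ea, eb = abs(effects.get(a, 0.0)), abs(effects.get(b, 0.0))
            if ea < eb:
                kept.discard(a)
            elif eb < ea:
                kept.discard(b)
            else:
                kept.discard(max(a, b))
    return [c for c in candidates if c in kept]


def _default_classifier():
    return SVC(kernel="linear", C=1.0)


def evaluate_panel(
    features: SampleMatrix,
    labels: pd.Series,
    n_splits: int = 100,
    train_fraction: float = 0.5,
    classifier_factory=None,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Mean held-out accuracy over repeated stratified random splits.

    Each iteration draws ``train_fraction`` of every class for training,
    fits the classifier (default: linear soft-margin SVM, C = 1) and scores
    accuracy on the held-out rest. Seeded and reproducible.
    """
    if classifier_factory is None:
        classifier_factory = _default_classifier
    labels = labels.loc[features.samples]
    y = labels.to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 samples per class")
    X = features.values.to_numpy(dtype=float).T  # samples x probes
    rng = np.random.default_rng(seed)
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    accuracies = []
    for _ in range(n_splits):
        while True:
            train_idx = []
            for c in classes:
                idx = class_idx[c]
                n_train = int(round(train_fraction * idx.size))
                n_train = min(max(n_train, 1), idx.size - 1)
                perm = rng.permutation(idx)
                train_idx.extend(perm[:n_train])
            train_mask = np.zeros(y.size, dtype=bool)
            train_mask[train_idx] = True
            if len(set(y[train_mask])) == 2 and len(set(y[~train_mask])) == 2:
                break
            logger.warning("degenerate split resampled")
        clf = classifier_factory()
        clf.fit(X[train_mask], y[train_mask])
        pred = clf.predict(X[~train_mask])
        accuracies.append(float(np.mean(pred == y[~train_mask])))
    acc = np.asarray(accuracies)
    return float(acc.mean()), float(acc.std(ddof=0)), accuracies


def greedy_panel_minimize(
    features: SampleMatrix,
    labels: pd.Series,
    start_probes: list[str],
    min_size: int,
    n_splits: int = 100,
    seed: int = 0,
    classifier_factory=None,
) -> tuple[list[str], list[tuple[list[str], float]]]:
    """Backward elimination: drop the probe whose removal hurts accuracy least.

    Accuracy ties are broken by dropping the probe with the smallest
    univariate class separation (|mean difference| / pooled sd), then by id.
    Runs from the start panel down to ``min_size`` probes; returns the final
    probe subset and the full trace [(panel, mean accuracy)] including the
    starting panel.
    """
    if len(start_probes) <= min_size:
        raise ValueError("start panel must be larger than min_size")
    labels_aligned = labels.loc[features.samples]
    classes = sorted(set(labels_aligned))
    vals = features.values

    def separation(probe: str) -> float:
        a = vals.loc[probe, labels_aligned == classes[0]].to_numpy(dtype=float)
        b = vals.loc[probe, labels_aligned == classes[1]].to_numpy(dtype=float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        return abs(a.mean() - b.mean()) / pooled if pooled > 0 else 0.0

    current = list(start_probes)
    mean, _, _ = evaluate_panel(
        features.subset(current), labels, n_splits, seed=seed,
        classifier_factory=classifier_factory,
    )
    trace = [(list(current), mean)]
    while len(current) > min_size:
        best = None  # (mean, -separation, probe)
        for probe in current:
            reduced = [p for p in current if p != probe]
            mean, _, _ = evaluate_panel(
                features.subset(reduced), labels, n_splits, seed=seed,
                classifier_factory=classifier_factory,
            )
            key = (mean, -separation(probe), probe)
            if best is None or key > best:
                best = key
        current = [p for p in current if p != best[2]]
        trace.append((list(current), best[0]))
    return current, trace
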