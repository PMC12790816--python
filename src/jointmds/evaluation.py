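"""Alignment quality metrics: FOSCTTM and k-NN label transfer accuracy.

FOSCTTM ("fraction of samples closer than the true match") assumes row i of
both embeddings is the same sample: for each sample it counts the fraction of
the other domain's points lying *strictly* closer than the true counterpart,
averaged over all samples and both directions.  0 means perfect alignment;
a random alignment scores about 0.5.

Label transfer accuracy is unsupervised heterogeneous domain adaptation: a
k-NN classifier (k = 5 by default) fit on one domain's aligned embedding
predicts the other domain's labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "foscttm",
    "label_transfer_accuracy",
    "MetricReport",
    "evaluate_pair",
    "evaluate_tri",
    "repeated_runs",
]


def foscttm(Z: np.ndarray, Z_prime: np.ndarray) -> float:
    """Fraction of samples closer than the true match, averaged both ways.

    Strict inequality: points tied with the true match do not count against
    it, so identical embeddings score exactly 0.
    """
    Z = np.asarray(Z, float)
    Z_prime = np.asarray(Z_prime, float)
    n = Z.shape[0]
    if Z_prime.shape[0] != n:
        raise ValueError(
            f"embeddings must pair the same samples: {n} vs {Z_prime.shape[0]} rows"
        )
    if n < 2:
        raise ValueError("FOSCTTM needs at least 2 samples")
    D = cdist(Z, Z_prime)
    true = np.diag(D)
    frac_12 = (D < true[:, None]).sum(axis=1) / (n - 1)  # per sample of Z
    frac_21 = (D < true[None, :]).sum(axis=0) / (n - 1)  # per sample of Z'
    return float((frac_12.mean() + frac_21.mean()) / 2.0)


def label_transfer_accuracy(
    Z_train: np.ndarray,
    labels_train,
    Z_test: np.ndarray,
    labels_test,
    k: int = 5,
) -> float:
    """Accuracy of a k-NN classifier trained on one domain, tested on the other.

    Distance ties are resolved by training-sample index and vote ties by the
    lexicographically first label (the behaviour of the underlying
    scikit-learn majority vote with sorted classes).
    """
    Z_train = np.asarray(Z_train, float)
    Z_test = np.asarray(Z_test, float)
    y_train = np.asarray(labels_train)
    y_test = np.asarray(labels_test)
    if k > Z_train.shape[0]:
        raise ValueError(f"k={k} exceeds the {Z_train.shape[0]} training samples")
    if y_train.shape[0] != Z_train.shape[0] or y_test.shape[0] != Z_test.shape[0]:
        raise ValueError("label lengths do not match embedding rows")
    clf = KNeighborsClassifier(n_neighbors=k, algorithm="brute")
    clf.fit(Z_train, y_train)
    return float(np.mean(clf.predict(Z_test) == y_test))


@dataclass
class MetricReport:
    """Aggregated alignment metrics, mean ± population standard deviation."""

    foscttm: float
    transfer_accuracy: float
    foscttm_std: float = 0.0
    transfer_accuracy_std: float = 0.0
    per_seed: pd.DataFrame | None = None
    n_runs: int = 1


def evaluate_pair(
    Z: np.ndarray, Z_prime: np.ndarray, labels, k: int = 5, direction: str = "1to2"
) -> MetricReport:
    """FOSCTTM plus label transfer for one aligned pair.

    ``direction`` controls the transfer: ``"1to2"`` trains on the first
    embedding, ``"2to1"`` on the second, ``"both"`` averages the two.
    """
    labels = np.asarray(labels)
    f = foscttm(Z, Z_prime)
    if direction == "1to2":
        acc = label_transfer_accuracy(Z, labels, Z_prime, labels, k=k)
    elif direction == "2to1":
        acc = label_transfer_accuracy(Z_prime, labels, Z, labels, k=k)
    elif direction == "both":
        acc = (
            label_transfer_accuracy(Z, labels, Z_prime, labels, k=k)
            + label_transfer_accuracy(Z_prime, labels, Z, labels, k=k)
        ) / 2.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return MetricReport(foscttm=f, transfer_accuracy=acc)


def evaluate_tri(result, labels, k: int = 5, direction: str = "1to2") -> MetricReport:
    """Average FOSCTTM and transfer accuracy over the three final embedding pairs.

    The pairs are (Z1, Z2), (Z1, Z3), (Z2, Z3); the per-pair table is kept in
    ``per_seed`` for inspection.  All three domains share the same samples,
    so one label vector covers every embedding.
    """
    labels = _labels_for(result.Z1, labels)
    pairs = [("1-2", result.Z1, result.Z2), ("1-3", result.Z1, result.Z3),
             ("2-3", result.Z2, result.Z3)]
    rows = []
    for name, Za, Zb in pairs:
        rep = evaluate_pair(Za, Zb, labels, k=k, direction=direction)
        rows.append({"pair": name, "foscttm": rep.foscttm,
                     "transfer_accuracy": rep.transfer_accuracy})
    table = pd.DataFrame(rows)
    return MetricReport(
        foscttm=float(table["foscttm"].mean()),
        transfer_accuracy=float(table["transfer_accuracy"].mean()),
        per_seed=table,
        n_runs=1,
    )


def _labels_for(Z: np.ndarray, labels) -> np.ndarray:
    if isinstance(labels, Mapping):
        labels = pd.Series(labels)
    arr = np.asarray(labels)
    if arr.shape[0] != Z.shape[0]:
        raise ValueError(
            f"labels cover {arr.shape[0]} samples but embeddings have {Z.shape[0]} rows"
        )
    return arr


def repeated_runs(
    align_spec: Callable[[int], Mapping[str, float]],
    n_runs: int = 50,
    base_seed: int = 0,
) -> MetricReport:
    """Run an alignment under seeds base_seed..base_seed+n_runs−1 and aggregate.

    ``align_spec`` maps a seed to a mapping with keys ``foscttm`` and
    ``transfer_accuracy``.  Means and *population* standard deviations over
    the seeds are reported (a single run has std 0 by definition).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for s in range(base_seed, base_seed + n_runs):
        m = align_spec(s)
        records.append({"seed": s, "foscttm": m["foscttm"],
                        "transfer_accuracy": m["transfer_accuracy"]})
    table = pd.DataFrame(records)
    return MetricReport(
        foscttm=float(table["foscttm"].mean()),
        transfer_accuracy=float(table["transfer_accuracy"].mean()),
        foscttm_std=float(table["foscttm"].std(ddof=0)),
        transfer_accuracy_std=float(table["transfer_accuracy"].std(ddof=0)),
        per_seed=table,
        n_runs=n_runs,
    )
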