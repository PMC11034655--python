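"""Confusion matrices, sensitivity and inter-observer agreement statistics.

Cohen's kappa corrects observed agreement for chance:
``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the fraction of the
cross-table on the diagonal and ``p_e`` the agreement expected from the
marginal distributions.  For more than two observers the arithmetic mean
of all unordered pairwise kappas is reported.  The nominal (unweighted)
statistic is used throughout.

The package ships, as packaged CSVs, the category and subcategory tables
of a three-pathologist re-annotation study of a 200-sample cervical biopsy
subset (50 slides per category); they serve as worked-example fixtures for
the agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .categories import CATEGORIES, Category

__all__ = [
    "ConfusionMatrix",
    "AgreementStats",
    "confusion",
    "malignant_sensitivity",
    "cohens_kappa",
    "cohens_kappa_from_labels",
    "mean_pairwise_kappa",
    "load_interobserver_category_table",
]

DEFAULT_LABELS = tuple(c.value for c in CATEGORIES)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are truth, columns are prediction."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def row_percent(self) -> np.ndarray:
        """Row-normalized matrix in percent (rows sum to 100)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums * 100.0, 0.0)

    def sensitivity(self, label: str) -> float:
        i = self.labels.index(label)
        row = self.counts[i].sum()
        if row == 0:
            raise ValueError(f"no samples with true label {label!r}")
        return float(self.counts[i, i] / row)

    def per_class_sensitivity(self) -> dict[str, float]:
        return {
            l: self.sensitivity(l)
            for i, l in enumerate(self.labels)
            if self.counts[i].sum() > 0
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def _as_label(x) -> str:
    if isinstance(x, Category):
        return x.value
    return str(x)


def confusion(true_labels, predicted_labels, labels=None) -> ConfusionMatrix:
    """Build a confusion matrix from paired label lists."""
    t = [_as_label(x) for x in true_labels]
    p = [_as_label(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError("label lists must have equal length")
    if not t:
        raise ValueError("empty label lists")
    if labels is None:
        labels = DEFAULT_LABELS if set(t) | set(p) <= set(DEFAULT_LABELS) else tuple(
            sorted(set(t) | set(p))
        )
    labels = tuple(labels)
    unknown = (set(t) | set(p)) - set(labels)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(t, p):
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, labels=labels)


def malignant_sensitivity(cm: ConfusionMatrix) -> float:
    """Fraction of truly malignant slides predicted malignant."""
    return cm.sensitivity(Category.MALIGNANT.value)


@dataclass
class AgreementStats:
    """Agreement between two labelings of the same items."""

    table: np.ndarray
    p_o: float
    p_e: float
    kappa: float


def cohens_kappa(table: np.ndarray) -> AgreementStats:
    """Cohen's kappa from a square cross-count table.

    ``p_o = trace / total``; ``p_e = sum_j row_j * col_j / total**2``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("table must be square")
    total = table.sum()
    if total <= 0:
        raise ValueError("empty agreement table")
    p_o = float(np.trace(table) / total)
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum() / total**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(table=table, p_o=p_o, p_e=p_e, kappa=float(kappa))


def cohens_kappa_from_labels(a, b, labels=None) -> AgreementStats:
    cm = confusion(a, b, labels=labels)
    return cohens_kappa(cm.counts)


def mean_pairwise_kappa(labelings, labels=None) -> float:
    """Arithmetic mean of Cohen's kappa over all unordered observer pairs."""
    labelings = list(labelings)
    if len(labelings) < 2:
        raise ValueError("need at least two labelings")
    n = len(labelings[0])
    if any(len(l) != n for l in labelings):
        raise ValueError("labelings must have equal length")
    kappas = [
        cohens_kappa_from_labels(labelings[i], labelings[j], labels=labels).kappa
        for i in range(len(labelings))
        for j in range(i + 1, len(labelings))
    ]
    return float(np.mean(kappas))


def _data_path(name: str):
    return resources.files("wsitriage.data").joinpath(name)


def load_interobserver_category_table(observer: str) -> np.ndarray:
    """4x4 original-vs-observer category count table for observer A, B or C.

    Rows are original categories, columns observer-assigned categories,
    both in the order malignant, high grade, low grade, normal.
    """
    df = pd.read_csv(_data_path("interobserver_categories.csv"))
    sub = df[df["observer"] == observer.upper()]
    if sub.empty:
        raise ValueError(f"unknown observer {observer!r}")
    order = ["malignant", "high_grade", "low_grade", "normal"]
    table = np.zeros((4, 4), dtype=int)
    for rec in sub.itertuples():
        table[order.index(rec.original_category), order.index(rec.observed_category)] = (
            rec.count
        )
    return table
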