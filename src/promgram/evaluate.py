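"""Classifier evaluation: confusion-matrix metrics, LOOCV and background
robustness.

The histone class is "positive" throughout.  Ratios with a zero
denominator are reported as NA (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bayesnet import (CLASS_STATES, BNModel, BNStructure, fit,
                       predict_proba)
from .features import FeatureTable, FeatureVector
from .pwm import ParameterError


@dataclass(frozen=True)
class Metrics:
    """Binary-classification summary; fractions in [0, 1] or None (NA)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, float | None]:
        """Metrics as percentages rounded to one decimal (reporting form)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(100.0 * v, 1)
        return out


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Sensitivity, specificity, ppv and accuracy from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        accuracy=_ratio(tp + tn, total),
    )


def metrics_from_calls(labels: Sequence[str], calls: Sequence[str]) -> Metrics:
    pos = CLASS_STATES[0]
    tp = sum(1 for l, c in zip(labels, calls) if l == pos and c == pos)
    fn = sum(1 for l, c in zip(labels, calls) if l == pos and c != pos)
    fp = sum(1 for l, c in zip(labels, calls) if l != pos and c == pos)
    tn = sum(1 for l, c in zip(labels, calls) if l != pos and c != pos)
    return compute_metrics(tp, fp, tn, fn)


def loocv(
    table: FeatureTable,
    structure: BNStructure,
    alpha: float = 1.0,
    cut: float = 0.5,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
) -> tuple[Metrics, np.ndarray]:
    """Leave-one-out cross-validation of the grammar network.

    For each row the model is refitted on the remaining rows and the
    held-out row is classified at posterior cutoff ``cut``.  Returns the
    pooled metrics and the per-row held-out posteriors.  Deterministic
    given the table.
    """
    rows = table.rows
    counts = {}
    for r in rows:
        counts[r.class_label] = counts.get(r.class_label, 0) + 1
    if any(counts.get(c, 0) < 2 for c in CLASS_STATES):
        raise ParameterError("LOOCV needs >= 2 rows per class")
    posteriors = np.empty(len(rows))
    calls = []
    for i in range(len(rows)):
        rest = FeatureTable(rows[:i] + rows[i + 1:], table.motif_alphabet,
                            table.n_positions, table.spacer_bins)
        model = fit(structure, rest, alpha=alpha, em_max_iter=em_max_iter,
                    em_tol=em_tol)
        p = float(predict_proba(model, [rows[i]])[0])
        posteriors[i] = p
        calls.append(CLASS_STATES[0] if p > cut else CLASS_STATES[1])
    metrics = metrics_from_calls([r.class_label for r in rows], calls)
    return metrics, posteriors


def background_robustness(
    positives: Sequence[FeatureVector],
    background_sets: Sequence[Sequence[FeatureVector]],
    structure: BNStructure,
    alpha: float = 1.0,
    motif_alphabet: Sequence[str] | None = None,
    spacer_bins: Sequence[float] | None = None,
    cut: float = 0.5,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
) -> dict:
    """LOOCV once per background set against fixed positives.

    Reports per-set metrics and the mean and sample standard deviation of
    each metric across sets (the spread quantifies sensitivity to the
    random background draw).
    """
    if len(background_sets) < 2:
        raise ParameterError("need at least 2 background sets")
    from .features import DEFAULT_BINS, DEFAULT_MAX_POSITIONS, MISSING

    if motif_alphabet is None:
        motif_alphabet = sorted({m for r in positives for m in r.M
                                 if m != MISSING}
                                | {m for bs in background_sets for r in bs
                                   for m in r.M if m != MISSING})
    bins = tuple(spacer_bins) if spacer_bins is not None else DEFAULT_BINS
    p = len(positives[0].M)
    per_set: list[Metrics] = []
    for bg in background_sets:
        table = FeatureTable(list(positives) + list(bg),
                             list(motif_alphabet), p, bins)
        m, _ = loocv(table, structure, alpha=alpha, cut=cut,
                     em_max_iter=em_max_iter, em_tol=em_tol)
        per_set.append(m)
    summary = {}
    for name in ("sensitivity", "specificity", "ppv", "accuracy"):
        vals = [getattr(m, name) for m in per_set]
        if any(v is None for v in vals):
            summary[name] = {"mean": None, "sd": None}
        else:
            arr = 100.0 * np.asarray(vals)
            summary[name] = {
                "mean": round(float(arr.mean()), 1),
                "sd": round(float(arr.std(ddof=1)), 1),
            }
    return {"per_set": per_set, "summary": summary}
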