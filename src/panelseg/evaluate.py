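"""Overlap-based panel matching and precision/recall/F1 scoring.

A predicted panel counts as correct when its intersection with a matched
ground-truth panel strictly exceeds two-thirds of the ground-truth panel's
area.  With Nc correct panels among Ne predictions and Nt ground-truth
panels: precision = Nc/Ne, recall = Nc/Nt, F1 = 2PR/(P+R).
"""

from __future__ import annotations

from dataclasses import dataclass

from .regions import PanelRegion

#: overlap must strictly exceed this fraction of the ground-truth area
DEFAULT_MIN_OVERLAP = 2.0 / 3.0


@dataclass(frozen=True)
class EvalReport:
    """Matching counts and derived scores for one figure or a pooled corpus."""

    n_correct: int
    n_extracted: int
    n_truth: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, n_correct: int, n_extracted: int, n_truth: int) -> "EvalReport":
        precision = n_correct / n_extracted if n_extracted else 0.0
        recall = n_correct / n_truth if n_truth else 0.0
        denom = precision + recall
        f1 = 2.0 * precision * recall / denom if denom else 0.0
        return cls(n_correct, n_extracted, n_truth, precision, recall, f1)


def overlap_fraction(pred: PanelRegion, truth: PanelRegion) -> float:
    """area(pred ∩ truth) / area(truth); the denominator is the truth area."""
    return pred.intersection_area(truth) / truth.area


def match_and_score(
    preds: list[PanelRegion],
    truths: list[PanelRegion],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> EvalReport:
    """Greedy one-to-one matching followed by precision/recall/F1.

    Truths are visited in order; each takes the unmatched prediction with the
    largest positive overlap fraction (earlier prediction index wins ties).
    A match contributes to ``n_correct`` only when its overlap fraction
    strictly exceeds ``min_overlap``.
    """
    matched: set[int] = set()
    n_correct = 0
    for truth in truths:
        best_j = -1
        best_frac = 0.0
        for j, pred in enumerate(preds):
            if j in matched:
                continue
            frac = overlap_fraction(pred, truth)
            if frac > best_frac:
                best_j, best_frac = j, frac
        if best_j >= 0:
            matched.add(best_j)
            if best_frac > min_overlap:
                n_correct += 1
    return EvalReport.from_counts(n_correct, len(preds), len(truths))
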