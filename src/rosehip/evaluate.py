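"""Recovery metrics against simulation ground truth."""
from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score



def reciprocal_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> float:
    """min(overlap/len_a, overlap/len_b); 0 on different chromosomes."""
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1])
    if inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1]), inter / (b[2] - b[1]))


def interval_precision_recall(
    called: list[tuple[str, int, int]],
    truth: list[tuple[str, int, int]],
    min_reciprocal: float = 0.5,
) -> tuple[float, float]:
    """Precision/recall with a reciprocal-overlap match criterion."""
    if not called:
        return (float("nan"), 0.0 if truth else float("nan"))
    matched_called = sum(
        1
        for c in called
        if any(reciprocal_overlap(c, t) >= min_reciprocal for t in truth)
    )
    matched_truth = sum(
        1
        for t in truth
        if any(reciprocal_overlap(c, t) >= min_reciprocal for c in called)
    )
    precision = matched_called / len(called)
    recall = matched_truth / len(truth) if truth else float("nan")
    return precision, recall


def score_auc(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """AUC for separating two score populations."""
    y = np.concatenate(
        [np.ones(len(positive_scores)), np.zeros(len(negative_scores))]
    )
    s = np.concatenate([positive_scores, negative_scores])
    return float(roc_auc_score(y, s))
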