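"""Held-out evaluation: per-profile AUROC/AUPRC and correlation structure."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["EvaluationResult", "evaluate", "prediction_correlation_structure"]


def _rank_correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman matrix via rank transform + Pearson; constant columns give
    NaN rows/columns rather than poisoning the whole matrix."""
    from scipy.stats import rankdata

    ranks = rankdata(x, axis=0)
    constant = ranks.std(axis=0) == 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return corr


@dataclass
class EvaluationResult:
    per_profile: pd.DataFrame  # columns: n_positives, n_negatives, auroc, auprc, included
    mean_auroc: float
    mean_auprc: float

    @property
    def included(self) -> pd.DataFrame:
        return self.per_profile[self.per_profile["included"]]


def evaluate(
    predictions: np.ndarray,
    labels: np.ndarray,
    profile_ids: Optional[list[str]] = None,
    min_positives: int = 25,
) -> EvaluationResult:
    """Per-profile AUROC (midrank tie convention) and AUPRC
    (precision-recall step integration).

    Profiles with fewer than ``min_positives`` positive labels — or with
    no negatives — are excluded from the averages, mirroring held-out-set
    evaluation practice.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("prediction/label shape mismatch")
    n, t = labels.shape
    if profile_ids is None:
        profile_ids = [f"profile_{i}" for i in range(t)]
    rows = []
    for j in range(t):
        y = labels[:, j]
        s = predictions[:, j]
        n_pos = int(y.sum())
        n_neg = int(n - n_pos)
        included = n_pos >= min_positives and n_neg > 0
        auroc = auprc = np.nan
        if n_pos > 0 and n_neg > 0:
            auroc = float(roc_auc_score(y, s))
            auprc = float(average_precision_score(y, s))
        rows.append(
            {
                "profile_id": profile_ids[j],
                "n_positives": n_pos,
                "n_negatives": n_neg,
                "auroc": auroc,
                "auprc": auprc,
                "included": included,
            }
        )
    frame = pd.DataFrame(rows).set_index("profile_id")
    inc = frame[frame["included"]]
    return EvaluationResult(
        per_profile=frame,
        mean_auroc=float(inc["auroc"].mean()) if len(inc) else np.nan,
        mean_auprc=float(inc["auprc"].mean()) if len(inc) else np.nan,
    )


def prediction_correlation_structure(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pairwise Spearman correlation matrices over profiles for the
    predictions and the true labels, plus their agreement (the Spearman
    correlation between the two upper triangles).

    Constant columns yield undefined correlations, reported as NaN and
    dropped from the agreement statistic.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape[0] < 3:
        raise ValueError("need at least 3 evaluation points")
    corr_pred = _rank_correlation_matrix(predictions)
    corr_label = _rank_correlation_matrix(labels)
    iu = np.triu_indices(predictions.shape[1], k=1)
    a, b = corr_pred[iu], corr_label[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    agreement = np.nan
    if ok.sum() >= 2:
        agreement = float(spearmanr(a[ok], b[ok]).statistic)
    return corr_pred, corr_label, agreement
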