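"""k-nearest-neighbour locomotor-mode prediction along a shape-space axis.

The classifier works on one principal-component axis of the Procrustes shape
space (the locomotor axis, PC2 in the femoral analysis): the distance between
two specimens is the absolute difference of their axis scores, which is
exactly the full-shape Procrustes distance restricted to that axis under the
orthonormal PCA basis. Indeterminate specimens receive the majority vote of
their k=5 nearest known-mode neighbours; known specimens are evaluated by
leave-one-out. A ``full-shape`` distance mode using Procrustes distances on
the complete configurations is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class KnnPrediction:
    specimen_id: str
    predicted_mode: str
    neighbor_ids: list[str]
    neighbor_distances: list[float]
    k: int
    axis: str


class AxisKNNClassifier(BaseEstimator, ClassifierMixin):
    """k-NN on 1D axis scores with deterministic tie-breaking.

    Parameters
    ----------
    k : int, default 5
        Number of neighbours; must be odd so two-class votes cannot tie.

    Distance ties are broken lexicographically on specimen id (logged in the
    prediction record through the neighbour list). Fitted attributes:
    ``classes_``, ``scores_``, ``ids_``, ``modes_``.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y, ids: list[str] | None = None):
        scores = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, dtype=object)
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        if len(scores) < self.k:
            raise ValueError(f"need at least k={self.k} known specimens")
        if len(scores) != len(y):
            raise ValueError("scores and labels must be matched")
        ids = list(ids) if ids is not None else [f"s{i}" for i in range(len(scores))]
        # sort by (id) once so that argsort on (distance, id-rank) is stable
        order = np.argsort(np.array(ids, dtype=object))
        self.ids_ = [ids[i] for i in order]
        self.scores_ = scores[order]
        self.modes_ = y[order]
        self.classes_ = np.unique(y)
        return self

    def _neighbors(self, score: float, exclude: str | None = None):
        mask = np.ones(len(self.scores_), dtype=bool)
        if exclude is not None:
            mask &= np.array([i != exclude for i in self.ids_])
        d = np.abs(self.scores_[mask] - score)
        ids = [i for i, m in zip(self.ids_, mask) if m]
        modes = self.modes_[mask]
        order = np.argsort(d, kind="stable")[: self.k]
        return ([ids[j] for j in order], d[order].tolist(),
                [modes[j] for j in order])

    def predict_one(self, score: float, specimen_id: str = "?",
                    exclude: str | None = None, axis: str = "PC2") -> KnnPrediction:
        nid, nd, nm = self._neighbors(score, exclude=exclude)
        votes = pd.Series(nm).value_counts()
        top = votes.max()
        winners = sorted(votes[votes == top].index)
        return KnnPrediction(specimen_id=specimen_id, predicted_mode=winners[0],
                             neighbor_ids=nid, neighbor_distances=nd,
                             k=self.k, axis=axis)

    def predict(self, X):
        check_is_fitted(self, "scores_")
        scores = np.asarray(X, float).reshape(-1)
        return np.array([self.predict_one(s).predicted_mode for s in scores],
                        dtype=object)


def knn_predict(scores_axis: dict[str, float], known: dict[str, str],
                unknown_ids: list[str], k: int = 5,
                axis: str = "PC2") -> list[KnnPrediction]:
    """Predict modes of unknown specimens from known neighbours on one axis.

    ``scores_axis`` maps specimen id -> axis score for both known and unknown
    specimens; ``known`` maps id -> mode (B/Q).
    """
    missing = [u for u in unknown_ids if u not in scores_axis]
    if missing:
        raise ValueError(f"unknown specimens missing scores: {missing}")
    est = AxisKNNClassifier(k=k).fit(
        [scores_axis[i] for i in known], list(known.values()), ids=list(known))
    return [est.predict_one(scores_axis[u], specimen_id=u, axis=axis)
            for u in unknown_ids]


def loo_evaluate(scores_axis: dict[str, float], known: dict[str, str],
                 k: int = 5, axis: str = "PC2") -> dict:
    """Leave-one-out evaluation over the known-mode specimens.

    Each known specimen is predicted from all the others. Returns per-specimen
    predictions plus the success rate over knowns, and (for samples that also
    contain unscored specimens in ``scores_axis``) the rate over the whole
    sample under the convention that only contradictions count as errors.
    """
    if len(known) < k + 1:
        raise ValueError(f"leave-one-out needs at least k+1={k+1} known specimens")
    est = AxisKNNClassifier(k=k).fit(
        [scores_axis[i] for i in known], list(known.values()), ids=list(known))
    preds = []
    correct = 0
    for sid, mode in known.items():
        p = est.predict_one(scores_axis[sid], specimen_id=sid, exclude=sid, axis=axis)
        preds.append(p)
        if p.predicted_mode == mode:
            correct += 1
    n_known = len(known)
    n_total = len(scores_axis)
    errors = n_known - correct
    return {
        "predictions": preds,
        "n_known": n_known,
        "n_errors": errors,
        "success_rate_known": correct / n_known,
        "success_rate_all": (n_total - errors) / n_total,
    }


def evaluate_against_inputs(table: pd.DataFrame) -> dict:
    """Agreement report for an input-vs-predicted locomotor-mode table.

    Expects columns ``input_mode`` (B/Q/I) and ``predicted_mode`` (B/Q).
    Counts agreements, contradictions (known input != prediction), and
    indeterminate-resolved rows; percentages are reported both over known
    rows and over all rows (the convention in which only contradictions
    count against the sample).
    """
    inp = table["input_mode"].astype(str)
    pred = table["predicted_mode"].astype(str)
    bad = set(pred) - {"B", "Q"}
    if bad:
        raise ValueError(f"predictions must be B/Q, got {sorted(bad)}")
    n = len(table)
    known_mask = inp.isin(["B", "Q"])
    n_known = int(known_mask.sum())
    n_indet = n - n_known
    contradictions = int((known_mask & (inp != pred)).sum())
    agreements = n_known - contradictions
    report = {
        "n_total": n,
        "n_known": n_known,
        "n_indeterminate": n_indet,
        "n_agreements": agreements,
        "n_contradictions": contradictions,
        "contradiction_ids": table.loc[known_mask & (inp != pred)].iloc[:, 0].tolist(),
        "pct_indeterminate": 100.0 * n_indet / n if n else float("nan"),
        "pct_correct_all": 100.0 * (n - contradictions) / n if n else float("nan"),
        "pct_contradictions_all": 100.0 * contradictions / n if n else float("nan"),
    }
    if n_known:
        report["pct_correct_known"] = 100.0 * agreements / n_known
    else:
        report["pct_correct_known"] = None
        report["flag"] = "no known-mode rows; known-denominator rate undefined"
    return report
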