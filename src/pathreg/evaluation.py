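"""ROC/AUROC scoring of regulator rankings against known positives.

The positive class is the set of literature-documented regulators of the
pathway; the negative set is every other candidate TF in the universe.  A
ranking is swept cutoff by cutoff: at cutoff k the top-k TFs are called
positive, giving (TP, FP, TN, FN) with sensitivity = TP/(TP+FN)*100 and
specificity = TN/(TN+FP)*100.  Candidate TFs the method never reported are
treated as one exchangeable tail block — a single straight ROC segment to
(1, 1) — because the order among never-reported TFs is undefined.  AUROC is
trapezoidal; :func:`auroc_mann_whitney` recomputes it independently as the
normalized count of correctly ordered (positive, negative) pairs (ties = 1/2)
and serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROCCurve",
    "ComparisonSummary",
    "roc_curve",
    "auroc_mann_whitney",
    "auroc_oracle_check",
    "summarize_comparison",
]


@dataclass
class ROCCurve:
    """(FPR, TPR) step points from (0,0) to (1,1) with per-cutoff counts."""

    fpr: np.ndarray
    tpr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    auroc: float

    @property
    def points(self):
        return list(zip(self.fpr, self.tpr))

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn) * 100.0

    @property
    def specificity(self) -> np.ndarray:
        return self.tn / (self.tn + self.fp) * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fpr": self.fpr,
                "tpr": self.tpr,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
            }
        )


def _ranked_ids(ranking) -> list:
    if isinstance(ranking, pd.DataFrame):
        frame = ranking.sort_values("rank") if "rank" in ranking.columns else ranking
        return [str(t) for t in frame["tf_id"]]
    return [str(t) for t in ranking]


def _check_sets(ranked, positives, universe):
    positives = {str(p) for p in positives}
    universe = {str(u) for u in universe}
    if not positives:
        raise ValueError("positive set is empty")
    if not positives <= universe:
        raise ValueError("positives must be a subset of the candidate universe")
    extra = set(ranked) - universe
    if extra:
        raise ValueError(f"ranking contains IDs outside the universe: {sorted(extra)[:5]}")
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranking contains duplicate IDs")
    negatives = universe - positives
    if not negatives:
        raise ValueError("negative set is empty")
    return positives, universe, negatives


def roc_curve(ranking, positives, universe) -> ROCCurve:
    """ROC curve of a ranking against known positives over a TF universe."""
    ranked = _ranked_ids(ranking)
    positives, universe, negatives = _check_sets(ranked, positives, universe)
    n_pos, n_neg = len(positives), len(negatives)

    tp = [0]
    fp = [0]
    for tf in ranked:
        tp.append(tp[-1] + (tf in positives))
        fp.append(fp[-1] + (tf not in positives))
    # exchangeable tail: all unranked candidates as one straight segment
    if tp[-1] < n_pos or fp[-1] < n_neg:
        tp.append(n_pos)
        fp.append(n_neg)
    tp = np.array(tp, dtype=float)
    fp = np.array(fp, dtype=float)
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, tp=tp, fp=fp, tn=tn, fn=fn, auroc=auroc)


def auroc_mann_whitney(ranking, positives, universe) -> float:
    """AUROC as the normalized Mann-Whitney count of correctly ordered
    (positive, negative) pairs, with ties scoring 1/2.

    Ranked TFs score by rank position; all unranked candidates share one tied
    score below every ranked one.  Computed by explicit pair comparison,
    independently of the trapezoidal path.
    """
    ranked = _ranked_ids(ranking)
    positives, universe, negatives = _check_sets(ranked, positives, universe)
    score = {tf: 0.0 for tf in universe}
    m = len(ranked)
    for i, tf in enumerate(ranked):
        score[tf] = float(m - i)
    pos_scores = np.array([score[t] for t in sorted(positives)])
    neg_scores = np.array([score[t] for t in sorted(negatives)])
    diff = pos_scores[:, None] - neg_scores[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(pos_scores) * len(neg_scores)))


# spec'd oracle name
auroc_oracle_check = auroc_mann_whitney


@dataclass
class ComparisonSummary:
    """Side-by-side top-k comparison of two methods against the positives."""

    method_a: str
    method_b: str
    top_k: int
    n_positive_in_top_k_a: int
    n_positive_in_top_k_b: int
    overlap: int
    overlap_positive: int
    auroc_a: float | None = None
    auroc_b: float | None = None

    def to_dict(self) -> dict:
        return {
            "top_k": self.top_k,
            "methods": [
                {
                    "method": self.method_a,
                    "n_positive_in_top_k": self.n_positive_in_top_k_a,
                    "auroc": self.auroc_a,
                },
                {
                    "method": self.method_b,
                    "n_positive_in_top_k": self.n_positive_in_top_k_b,
                    "auroc": self.auroc_b,
                },
            ],
            "overlap": self.overlap,
            "overlap_positive": self.overlap_positive,
        }

    def to_table(self) -> str:
        rows = [
            f"{'Method':<10} {'Positives in top-' + str(self.top_k):<22} {'In common':<10}",
            f"{self.method_a:<10} {self.n_positive_in_top_k_a:<22} "
            f"{self.overlap_positive:<10}",
            f"{self.method_b:<10} {self.n_positive_in_top_k_b:<22} "
            f"{self.overlap_positive:<10}",
        ]
        return "\n".join(rows)


def summarize_comparison(
    ranking_a,
    ranking_b,
    positives,
    top_k: int,
    universe=None,
    method_a: str = "tgmi",
    method_b: str = "spls",
) -> ComparisonSummary:
    """Compare the top-k prefixes of two rankings.

    ``overlap_positive`` counts positives shared between the two top-k lists
    ("in common"); ``overlap`` is the raw shared-TF count regardless of status.
    When ``universe`` is given, each method's AUROC is included.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    positives = {str(p) for p in positives}
    top_a = set(_ranked_ids(ranking_a)[:top_k])
    top_b = set(_ranked_ids(ranking_b)[:top_k])
    auroc_a = auroc_b = None
    if universe is not None:
        auroc_a = roc_curve(ranking_a, positives, universe).auroc
        auroc_b = roc_curve(ranking_b, positives, universe).auroc
    return ComparisonSummary(
        method_a=method_a,
        method_b=method_b,
        top_k=top_k,
        n_positive_in_top_k_a=len(top_a & positives),
        n_positive_in_top_k_b=len(top_b & positives),
        overlap=len(top_a & top_b),
        overlap_positive=len(top_a & top_b & positives),
        auroc_a=auroc_a,
        auroc_b=auroc_b,
    )
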