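"""Binary-classification scoring of hub calls against ground truth.

A hub call is a positive; the confusion counts feed six metrics: FDR, FPR,
precision, TPR (sensitivity), the Matthews correlation coefficient and
bookmaker informedness (TPR − FPR).  With p nodes and a handful of true
hubs the problem is heavily imbalanced, which is why MCC and BM are
reported alongside the rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "evaluate_replicates",
    "ReplicateStudy",
]

METRIC_NAMES = ("fdr", "fpr", "precision", "tpr", "mcc", "bm")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def p(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(true_hubs, called_hubs, p) -> ConfusionCounts:
    """Count TP/FP/TN/FN of called hubs against the true hub set.

    Node ids are 1-based and must lie in {1..p}.  A true positive is a
    correctly identified hub node; a true negative a correctly identified
    non-hub.
    """
    true_hubs = set(int(i) for i in true_hubs)
    called_hubs = set(int(i) for i in called_hubs)
    for ids, name in ((true_hubs, "true_hubs"), (called_hubs, "called_hubs")):
        bad = [i for i in ids if not 1 <= i <= p]
        if bad:
            raise ValueError(f"{name} contains out-of-range ids {bad} "
                             f"for p={p}")
    tp = len(true_hubs & called_hubs)
    fp = len(called_hubs - true_hubs)
    fn = len(true_hubs - called_hubs)
    return ConfusionCounts(tp=tp, fp=fp, tn=p - tp - fp - fn, fn=fn)


def metrics(counts: ConfusionCounts) -> dict:
    """The six hub-detection quality metrics.

    FDR = FP/(FP+TP), FPR = FP/(FP+TN), Pre = TP/(TP+FP), TPR = TP/(TP+FN),
    MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), BM = TPR − FPR.

    Degenerate cases: FDR and precision are NaN when no calls were made
    (tp+fp = 0); TPR is NaN when there are no true hubs; MCC is 0 by
    convention when any denominator factor vanishes.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    fdr = fp / (fp + tp) if (fp + tp) > 0 else float("nan")
    pre = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    tpr = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    bm = tpr - fpr if not (math.isnan(tpr) or math.isnan(fpr)) else float("nan")
    return {"fdr": fdr, "fpr": fpr, "precision": pre, "tpr": tpr,
            "mcc": mcc, "bm": bm}


@dataclass
class ReplicateStudy:
    """Per-replicate and aggregated metrics of a simulation scenario."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    n_failed: int
    n_no_calls: int
    scenario: dict


def evaluate_replicates(model, p, n, n_replicates, *, model_kwargs=None,
                        estimator="glasso", estimator_kwargs=None,
                        gamma=3.0, s_min=None, seed=0) -> ReplicateStudy:
    """Run generate → fit path → MDSD → call → score over R replicates.

    Each replicate draws a fresh ground-truth network (where the generator
    is random) and a fresh Gaussian sample with a sub-seed derived from
    ``seed``, screens hubs with :class:`~mdsd.screening.MDSDHubDetector`,
    and scores the calls.  The summary reports the mean and sd of each
    metric over replicates; replicates where the estimator failed are
    skipped and counted, and NaN metrics (e.g. FDR with zero calls) are
    excluded from averages, with the number of zero-call replicates
    reported.
    """
    from .networks import make_network, sample_gaussian
    from .screening import MDSDHubDetector

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    model_kwargs = dict(model_kwargs or {})
    estimator_kwargs = dict(estimator_kwargs or {})
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 2))
    rows = []
    n_failed = 0
    for r in range(n_replicates):
        net_seed, data_seed = (int(s) for s in sub_seeds[r])
        truth = make_network(model, p, seed=net_seed, **model_kwargs)
        data = sample_gaussian(truth, n, seed=data_seed)
        detector = MDSDHubDetector(
            estimator=_build_estimator(estimator, estimator_kwargs),
            gamma=gamma, s_min=s_min)
        try:
            detector.fit(data.to_numpy())
        except ValueError:
            n_failed += 1
            continue
        counts = confusion(truth.hub_ids, detector.hub_ids_, p)
        row = {"replicate": r, "seed": data_seed,
               "n_true_hubs": len(truth.hub_ids),
               "n_called": len(detector.hub_ids_),
               "tp": counts.tp, "fp": counts.fp, "tn": counts.tn,
               "fn": counts.fn}
        row.update(metrics(counts))
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    if len(per_rep):
        stats = per_rep[list(METRIC_NAMES)].agg(["mean", "std", "count"]).T
        stats.columns = ["mean", "sd", "n_defined"]
        n_no_calls = int((per_rep["n_called"] == 0).sum())
    else:
        stats = pd.DataFrame(columns=["mean", "sd", "n_defined"])
        n_no_calls = 0
    scenario = {"model": model, "p": p, "n": n, "R": n_replicates,
                "estimator": str(estimator), "gamma": gamma, "s_min": s_min,
                "seed": seed, "model_kwargs": model_kwargs,
                "estimator_kwargs": estimator_kwargs}
    return ReplicateStudy(per_replicate=per_rep, summary=stats,
                          n_failed=n_failed, n_no_calls=n_no_calls,
                          scenario=scenario)


def _build_estimator(estimator, estimator_kwargs):
    if isinstance(estimator, str) and estimator_kwargs:
        from .screening import _NAMED_ESTIMATORS
        return _NAMED_ESTIMATORS[estimator](**estimator_kwargs)
    return estimator
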