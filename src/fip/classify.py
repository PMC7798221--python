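"""ES/HS classification from per-compound scores.

Any real-valued score column (ZRFT, or external synthetic-accessibility
scores supplied as plain numbers) is turned into easy-to-synthesize (ES)
versus hard-to-synthesize (HS) calls. Orientation throughout: higher
score ⇒ ES, and ES is the positive class for sensitivity.

The operating point is the Youden-index maximizer J = SN + SP − 1 over
candidate thresholds (midpoints of consecutive distinct scores plus the
two infinities), ties broken toward the lowest threshold; the decision
rule is score ≥ threshold ⇒ ES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

LABELS = ("ES", "HS")


class ClassifyError(ValueError):
    pass


@dataclass
class ScoredSet:
    """Rows of (compound_id, score, label) with label in {ES, HS}."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_id", "score", "label"}
        if not required.issubset(self.frame.columns):
            raise ClassifyError(f"scored set needs columns {sorted(required)}")
        bad = set(self.frame["label"]) - set(LABELS)
        if bad:
            raise ClassifyError(f"unknown labels {sorted(bad)}; expected ES/HS")
        if not np.all(np.isfinite(self.frame["score"].to_numpy(dtype=float))):
            raise ClassifyError("scores must be finite")

    @classmethod
    def from_arrays(
        cls, ids: Sequence, scores: Sequence[float], labels: Sequence[str]
    ) -> "ScoredSet":
        return cls(
            pd.DataFrame({"compound_id": ids, "score": scores, "label": labels})
        )

    @classmethod
    def read_tsv(cls, path: str) -> "ScoredSet":
        return cls(pd.read_csv(path, sep="\t"))

    def scores_and_truth(self) -> tuple[np.ndarray, np.ndarray]:
        y = (self.frame["label"] == "ES").to_numpy()
        s = self.frame["score"].to_numpy(dtype=float)
        if y.all() or not y.any():
            raise ClassifyError("both ES and HS labels must be present")
        return s, y


@dataclass
class ClassificationReport:
    auc: float
    threshold: float
    acc: float
    sn: float
    sp: float
    n_instances: int = 1
    per_instance: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "n_instances": self.n_instances,
        }


def roc_auc(s: ScoredSet) -> float:
    """Trapezoidal area under the ROC curve, higher score ⇒ ES."""
    scores, truth = s.scores_and_truth()
    return float(roc_auc_score(truth, scores))


def _metrics_at(scores: np.ndarray, truth: np.ndarray, thr: float) -> tuple:
    pred = scores >= thr
    sn = float((pred & truth).sum() / truth.sum())
    sp = float((~pred & ~truth).sum() / (~truth).sum())
    acc = float((pred == truth).mean())
    return acc, sn, sp


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_threshold(s: ScoredSet) -> tuple[float, ClassificationReport]:
    """Exhaustive scan for the threshold maximizing J = SN + SP − 1.

    Candidates are midpoints of consecutive distinct scores plus ±inf;
    among equal maximizers the lowest threshold wins.
    """
    scores, truth = s.scores_and_truth()
    best_thr, best_j, best = None, -np.inf, None
    for thr in _candidate_thresholds(scores):
        acc, sn, sp = _metrics_at(scores, truth, thr)
        j = sn + sp - 1
        if j > best_j + 1e-12:
            best_thr, best_j, best = float(thr), j, (acc, sn, sp)
    report = ClassificationReport(
        auc=roc_auc(s), threshold=best_thr, acc=best[0], sn=best[1], sp=best[2]
    )
    return best_thr, report


def evaluate_instances(
    instances: Sequence[ScoredSet],
    threshold_policy: Union[str, float] = "youden_per_instance",
) -> ClassificationReport:
    """Per-instance AUC/Acc/SN/SP, arithmetically averaged across instances.

    threshold_policy: "youden_per_instance" re-optimizes the Youden
    threshold inside each instance; a float applies that fixed threshold
    to every instance.
    """
    if not instances:
        raise ClassifyError("need at least one scored instance")
    rows = []
    for k, inst in enumerate(instances):
        if threshold_policy == "youden_per_instance":
            thr, rep = youden_threshold(inst)
            auc, acc, sn, sp = rep.auc, rep.acc, rep.sn, rep.sp
        else:
            thr = float(threshold_policy)
            scores, truth = inst.scores_and_truth()
            acc, sn, sp = _metrics_at(scores, truth, thr)
            auc = roc_auc(inst)
        rows.append(
            {"instance": k, "auc": auc, "threshold": thr, "acc": acc, "sn": sn, "sp": sp}
        )
    per = pd.DataFrame(rows)
    return ClassificationReport(
        auc=float(per["auc"].mean()),
        threshold=float(per["threshold"].mean()),
        acc=float(per["acc"].mean()),
        sn=float(per["sn"].mean()),
        sp=float(per["sp"].mean()),
        n_instances=len(instances),
        per_instance=per,
    )
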