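"""Symmetric direct/reverse evaluation and bias categorization.

An unbiased stability predictor scores a mutation X→Y and its reverse
Y→X consistently (the underlying ΔΔG is antisymmetric).  Test sets are
therefore split by direction and accuracy is reported separately for the
direct and reverse halves, together with their average and a categorical
bias mark derived from the accuracy gap:

    no mark   |Δacc| ≤ 0.05
    ●         0.05 < |Δacc| ≤ 0.1
    ●●        0.1  < |Δacc| ≤ 0.2
    ●●●       |Δacc| > 0.2

The signed difference (reverse minus direct) is reported alongside; the
marks themselves flag the magnitude of the bias regardless of direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn import metrics as skmetrics

from .data_model import DIRECT, Dataset, REVERSE, ValidationError


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    auc: float | None
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SymmetricReport:
    direct: EvalReport
    reverse: EvalReport
    bias_difference: float          # signed: reverse − direct
    bias_marks: str                 # "", "●", "●●", "●●●"

    @property
    def accuracy_avg(self) -> float:
        return (self.direct.accuracy + self.reverse.accuracy) / 2.0

    def as_dict(self) -> dict:
        return {
            "direct": self.direct.as_dict(),
            "reverse": self.reverse.as_dict(),
            "accuracy_avg": self.accuracy_avg,
            "bias_difference": self.bias_difference,
            "bias_marks": self.bias_marks,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def table(self) -> str:
        rows = [
            ("direct", self.direct), ("reverse", self.reverse),
        ]
        lines = [f"{'set':<8s} {'n':>5s} {'acc':>6s} {'prec':>6s} "
                 f"{'rec':>6s} {'auc':>6s}"]
        for name, rep in rows:
            auc = "n/a" if rep.auc is None else f"{rep.auc:.3f}"
            lines.append(
                f"{name:<8s} {rep.n:>5d} {rep.accuracy:>6.3f} "
                f"{rep.precision:>6.3f} {rep.recall:>6.3f} {auc:>6s}"
            )
        lines.append(
            f"average accuracy {self.accuracy_avg:.3f}; "
            f"bias {self.bias_difference:+.3f} {self.bias_marks or '(none)'}"
        )
        return "\n".join(lines)


def split_direct_reverse(dataset: Dataset) -> tuple[Dataset, Dataset]:
    """Exhaustive disjoint partition of a dataset by mutation direction."""
    direct, reverse = [], []
    for rec in dataset:
        if rec.direction == DIRECT:
            direct.append(rec)
        elif rec.direction == REVERSE:
            reverse.append(rec)
        else:  # pragma: no cover - MutationRecord already validates this
            raise ValidationError(f"record {rec.record_id}: missing direction")
    return (Dataset(records=direct, name=f"{dataset.name}-direct"),
            Dataset(records=reverse, name=f"{dataset.name}-reverse"))


def bias_category(accuracy_direct: float, accuracy_reverse: float) -> str:
    """Categorical bias mark from the absolute direct/reverse accuracy gap."""
    for name, value in (("accuracy_direct", accuracy_direct),
                        ("accuracy_reverse", accuracy_reverse)):
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    # round away float artifacts so e.g. |0.90 - 0.85| sits exactly on the
    # 0.05 boundary rather than 1e-17 above it
    diff = round(abs(accuracy_direct - accuracy_reverse), 9)
    if diff > 0.2:
        return "●●●"
    if diff > 0.1:
        return "●●"
    if diff > 0.05:
        return "●"
    return ""


def compute_metrics(labels, probabilities,
                    threshold: float = 0.5) -> EvalReport:
    """Accuracy/precision/recall at the threshold plus rank-statistic AUC.

    AUC uses the midrank tie convention; for single-class inputs it is
    reported as undefined (None), never defaulted to 0.5.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValidationError("compute_metrics needs a nonempty input")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    auc = None
    if len(np.unique(y)) == 2:
        auc = float(skmetrics.roc_auc_score(y, p))
    return EvalReport(
        accuracy=float(skmetrics.accuracy_score(y, pred)),
        precision=float(skmetrics.precision_score(y, pred, zero_division=0)),
        recall=float(skmetrics.recall_score(y, pred, zero_division=0)),
        auc=auc,
        n=int(y.size),
    )


def symmetric_report(labels, probabilities, directions) -> SymmetricReport:
    """Evaluate direct and reverse subsets and categorize the bias."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    d = np.asarray(directions)
    direct = compute_metrics(y[d == DIRECT], p[d == DIRECT])
    reverse = compute_metrics(y[d == REVERSE], p[d == REVERSE])
    return SymmetricReport(
        direct=direct,
        reverse=reverse,
        bias_difference=reverse.accuracy - direct.accuracy,
        bias_marks=bias_category(direct.accuracy, reverse.accuracy),
    )
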