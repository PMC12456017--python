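"""Classifier evaluation: confusion matrices, rate formulas, threshold sweeps.

The positive class is CHROMID. Rates follow the standard definitions

    Acc = (TP + TN) / (P + N),   precision = TP / (TP + FP),
    TPR = TP / (TP + FN),        FPR = FP / (FP + TN),

reported as percentages rounded half-up to two decimals. The threshold
sweep exploits that the tetranucleotide distance only acts at the final
pipeline step: clustering is computed once and the distance filter is
re-applied per grid value, yielding ROC / precision-recall tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .classify import (
    CHROMID,
    PipelineState,
    Thresholds,
    finalize_calls,
    prepare_pipeline,
)
from .errors import ValidationError
from .markers import MarkerDatabase
from .seq_io import Replicon
from .synthetic import SyntheticTruth

POSITIVE_ROLE = CHROMID


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _pct(numerator: int, denominator: int, what: str) -> float:
    """Percentage rounded half-up to 2 decimals; NaN with a warning if undefined."""
    if denominator == 0:
        warnings.warn(f"{what} undefined: zero denominator")
        return math.nan
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (P + N) as a percentage."""
    return _pct(cm.tp + cm.tn, cm.total, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP) as a percentage."""
    return _pct(cm.tp, cm.tp + cm.fp, "precision")


def tpr(cm: ConfusionMatrix) -> float:
    """True positive rate (sensitivity, recall): TP / (TP + FN) as a percentage."""
    return _pct(cm.tp, cm.tp + cm.fn, "TPR")


def fpr(cm: ConfusionMatrix) -> float:
    """False positive rate: FP / (FP + TN) as a percentage."""
    return _pct(cm.fp, cm.fp + cm.tn, "FPR")


def _truth_roles(truth) -> dict[str, str]:
    if isinstance(truth, SyntheticTruth):
        return truth.roles
    if isinstance(truth, (str, Path)):
        from .synthetic import read_truth

        return read_truth(truth)
    return dict(truth)


def confusion(calls, truth) -> ConfusionMatrix:
    """Tally a confusion matrix over all truth replicons.

    ``calls`` is a ClassificationResult or a plain id→role mapping;
    ``truth`` is a SyntheticTruth, an id→role mapping, or a truth TSV path.
    A prediction is positive iff the call is CHROMID (UNASSIGNED and OTHER
    count as negative); a truth label is positive iff it is CHROMID.
    """
    call_map = calls.calls if hasattr(calls, "calls") else dict(calls)
    roles = _truth_roles(truth)
    orphans = sorted(set(roles) - set(call_map))
    if orphans:
        raise ValidationError(f"truth ids missing from calls: {orphans}")
    tp = fp = fn = tn = 0
    for rid, true_role in roles.items():
        truth_pos = true_role == POSITIVE_ROLE
        pred_pos = call_map[rid] == POSITIVE_ROLE
        if truth_pos and pred_pos:
            tp += 1
        elif truth_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class SweepPoint:
    """Metrics of the pipeline at one tetranucleotide threshold (percent units)."""

    threshold: float
    tpr: float
    fpr: float
    precision: float
    recall: float

    def __post_init__(self) -> None:
        # recall and TPR are the same quantity by definition
        if not (math.isnan(self.tpr) and math.isnan(self.recall)):
            assert self.tpr == self.recall


def threshold_sweep(
    pool: list[Replicon],
    truth,
    db: MarkerDatabase,
    th_base: Thresholds | None = None,
    grid: list[float] | None = None,
    state: PipelineState | None = None,
    **pipeline_kwargs,
) -> list[SweepPoint]:
    """Evaluate the MAG pipeline along an ascending tetranucleotide-threshold grid.

    Steps 1–3 (profiles and clustering) are computed once; only the step-4
    distance filter is re-applied per grid value. ``math.inf`` is accepted
    as a sentinel at which every cluster member passes. A precomputed
    ``state`` may be supplied to share work with other evaluations.
    """
    if not grid:
        raise ValidationError("threshold grid must be non-empty")
    if sorted(grid) != list(grid):
        raise ValidationError("threshold grid must be sorted ascending")
    th_base = th_base or Thresholds()
    if state is None:
        state = prepare_pipeline(pool, db, th=th_base, **pipeline_kwargs)
    points = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined rates on degenerate grids
        for value in grid:
            result = finalize_calls(
                state,
                Thresholds(
                    gc_delta_max=th_base.gc_delta_max,
                    tetra_dist_max=value,
                    dinuc_dist_max=th_base.dinuc_dist_max,
                    marker_rule=th_base.marker_rule,
                    signature_scale=th_base.signature_scale,
                ),
            )
            cm = confusion(result, truth)
            rate_tpr = tpr(cm)
            points.append(
                SweepPoint(
                    threshold=value,
                    tpr=rate_tpr,
                    fpr=fpr(cm),
                    precision=precision(cm),
                    recall=rate_tpr,
                )
            )
    return points


def sweep_to_frame(points: list[SweepPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "tpr_pct": p.tpr,
                "fpr_pct": p.fpr,
                "precision_pct": p.precision,
                "recall_pct": p.recall,
            }
            for p in points
        ]
    )


def roc_auc(points: list[SweepPoint]) -> float:
    """Trapezoidal area under the ROC curve traced by the sweep (0..1 scale).

    The curve is anchored at (0,0) and (100,100) in percent units.
    """
    pts = sorted({(p.fpr, p.tpr) for p in points if not math.isnan(p.fpr)})
    xs = [0.0] + [x for x, _ in pts] + [100.0]
    ys = [0.0] + [y for _, y in pts] + [100.0]
    area = 0.0
    for i in range(1, len(xs)):
        area += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2
    return area / 10_000


def plot_sweep(points: list[SweepPoint], path: str | Path) -> None:
    """Write a two-panel ROC / precision-recall figure for a sweep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = sweep_to_frame(points)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(frame["fpr_pct"], frame["tpr_pct"], marker="o")
    ax1.set_xlabel("FPR (%)")
    ax1.set_ylabel("TPR (%)")
    ax1.set_title("ROC")
    ax2.plot(frame["recall_pct"], frame["precision_pct"], marker="o")
    ax2.set_xlabel("recall (%)")
    ax2.set_ylabel("precision (%)")
    ax2.set_title("precision-recall")
    for ax in (ax1, ax2):
        ax.set_xlim(-2, 102)
        ax.set_ylim(-2, 102)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
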