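"""Evaluation of predicted neighbor graphs against ground truth.

A predicted edge set is compared with a ground-truth edge set over the
universe of all C(n, 2) unordered cell pairs.  Predicted edges present in
the truth are true positives (TP); predicted edges absent from the truth are
false positives (FP); truth edges the prediction missed are false negatives
(FN); pairs connected in neither graph are true negatives (TN).

The headline metrics deliberately avoid TN — in a spatial contact graph
non-neighboring pairs vastly outnumber neighbors, so TN-dependent scores are
inflated:

    TPR = TP / (TP + FN)            (sensitivity / recall)
    PPV = TP / (TP + FP)            (precision)
    JI  = TP / (TP + FN + FP)       (Jaccard index of the edge sets)

F1 (harmonic mean of TPR and PPV) and the Matthews correlation coefficient
(which does use TN) are reported alongside for completeness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "implied_jaccard",
    "PUBLISHED_BENCHMARKS",
]

# Reported detection metrics of this method on five public dual-labelled
# (nuclear + membrane) microscopy datasets, evaluated against manually
# annotated membrane-contact ground truth.  Used only for internal
# consistency checks of the metric identities, never as test oracles for
# this implementation's output.
PUBLISHED_BENCHMARKS = {
    "drosophila_midgut_2d": {"n": 27, "tpr": 0.902, "ppv": 0.948, "ji": 0.859, "dim": 2},
    "drosophila_embryo_2d": {"n": 93, "tpr": 0.988, "ppv": 1.0, "ji": 0.988, "dim": 2},
    "tribolium_blastoderm_2d": {"n": 36, "tpr": 0.952, "ppv": 0.976, "ji": 0.930, "dim": 2},
    "arabidopsis_stem_2d": {"n": 105, "tpr": 0.927, "ppv": 0.86, "ji": 0.806, "dim": 2},
    "celegans_embryo_3d": {"n": 24, "tpr": 0.976, "ppv": 0.92, "ji": 0.900, "dim": 3},
}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    n_nodes: int

    def __post_init__(self):
        total = self.TP + self.FP + self.FN + self.TN
        universe = self.n_nodes * (self.n_nodes - 1) // 2
        if total != universe:
            raise ValueError(
                f"counts ({total}) do not partition the C(n,2)={universe} pair universe"
            )


@dataclass(frozen=True)
class MetricsReport:
    TPR: float
    PPV: float
    JI: float
    F1: float
    MCC: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "TPR": self.TPR,
            "PPV": self.PPV,
            "JI": self.JI,
            "F1": self.F1,
            "MCC": self.MCC,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "TN": self.counts.TN,
            "n_nodes": self.counts.n_nodes,
        }


def _canonical(edges) -> set:
    out = set()
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-loop edge ({a}, {b})")
        out.add((a, b) if a < b else (b, a))
    return out


def confusion_counts(predicted, truth, node_ids) -> ConfusionCounts:
    """Partition all unordered node pairs into TP/FP/FN/TN."""
    nodes = {int(n) for n in node_ids}
    pred = _canonical(predicted)
    true = _canonical(truth)
    for name, edges in (("predicted", pred), ("truth", true)):
        bad = [e for e in edges if e[0] not in nodes or e[1] not in nodes]
        if bad:
            raise ValueError(f"{name} edges reference unknown node ids: {bad[:5]}")
    n = len(nodes)
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, n_nodes=n)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """TPR, PPV, JI, F1 and MCC from a confusion table.

    Metrics with a zero denominator are reported as NaN with a warning
    rather than silently coerced to 0.
    """
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    tpr = _ratio(tp, tp + fn, "TPR")
    ppv = _ratio(tp, tp + fp, "PPV")
    ji = _ratio(tp, tp + fn + fp, "JI")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return MetricsReport(TPR=tpr, PPV=ppv, JI=ji, F1=f1, MCC=mcc, counts=counts)


def implied_jaccard(tpr: float, ppv: float) -> float:
    """Jaccard index implied by sensitivity and precision.

    From the count definitions, 1/JI = 1/TPR + 1/PPV - 1 whenever TP > 0.
    Useful as an internal-consistency check on reported metric triples.
    """
    if tpr <= 0 or ppv <= 0:
        return math.nan
    return 1.0 / (1.0 / tpr + 1.0 / ppv - 1.0)
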