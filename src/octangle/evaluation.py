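"""Quantitative evaluation: measurement error, narrow-angle classification
and ROC analysis.

The measurement error of a method q is the signed relative error
δ_q = (w_M − w_P)/w_P · 100% of a measured value w_M against a reference
w_P.  Narrow-angle screening uses the clinical risk thresholds TIA < 15°,
AOD < 190 μm, TISA < 0.11 mm² (strictly below = at risk); distance-minimum
methods (AOM/AOM2) take their threshold from the ROC operating point.  The
ROC sweep moves the cut-off from 0 to 180 in steps of 1 — covering both the
angular range (TIA, degrees) and the distance range (AOD/AOM, pixels) —
predicting "narrow" whenever the score falls below the cut-off; AUC is the
trapezoid under the swept curve and the operating point maximizes Youden's
J = TPR + SPC − 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EvaluationError

__all__ = [
    "MeasurementError",
    "NarrowCriteria",
    "ConfusionMatrix",
    "RocResult",
    "delta_q",
    "classify_narrow",
    "confusion",
    "roc_sweep",
    "plot_roc",
]


@dataclass(frozen=True)
class MeasurementError:
    """Signed percent error of one measurement against its reference."""

    w_M: float
    w_P: float
    q: str
    delta_q_pct: float


def delta_q(w_M: float, w_P: float, q: str = "") -> MeasurementError:
    """δ_q = (w_M − w_P)/w_P · 100%."""
    if w_P == 0:
        raise EvaluationError("reference value w_P is zero: δ_q undefined")
    return MeasurementError(float(w_M), float(w_P), q, (w_M - w_P) / w_P * 100.0)


@dataclass(frozen=True)
class NarrowCriteria:
    """Per-method narrow-angle thresholds ("narrow" strictly below)."""

    tia_deg: float = 15.0
    aod_um: float = 190.0
    tisa_mm2: float = 0.11
    aom_um: float | None = None  # set from the ROC operating point
    aom2_um: float | None = None


def classify_narrow(measurement, criteria: NarrowCriteria | None = None) -> str:
    """Label one AngleMeasurement narrow/open by its method's threshold."""
    criteria = criteria or NarrowCriteria()
    m, v = measurement.method, measurement.value
    if not math.isfinite(v):
        raise EvaluationError(f"non-finite {m} value")
    thresholds = {
        "TIA": criteria.tia_deg,
        "AOD": criteria.aod_um,
        "TISA": criteria.tisa_mm2,
        "AOM": criteria.aom_um,
        "AOM2": criteria.aom2_um,
    }
    if m not in thresholds:
        raise ConfigurationError(f"no narrow-angle criterion for method {m!r}")
    t = thresholds[m]
    if t is None:
        raise ConfigurationError(
            f"{m} threshold unset; choose one (e.g. the ROC Youden optimum)"
        )
    return "narrow" if v < t else "open"


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def ACC(self) -> float:
        return (self.TP + self.TN) / (self.TP + self.TN + self.FP + self.FN)

    @property
    def SPC(self) -> float:
        return self.TN / (self.FP + self.TN)

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN)


def _as_narrow(labels) -> np.ndarray:
    out = []
    for x in labels:
        if isinstance(x, str):
            if x not in ("narrow", "open"):
                raise EvaluationError(f"unknown label {x!r}")
            out.append(x == "narrow")
        else:
            out.append(bool(x))
    return np.asarray(out, dtype=bool)


def confusion(labels_pred, labels_true) -> ConfusionMatrix:
    """Confusion counts with "narrow" (at-risk) as the positive class."""
    pred, true = _as_narrow(labels_pred), _as_narrow(labels_true)
    if pred.size != true.size or pred.size == 0:
        raise EvaluationError("label lists must be non-empty and equally long")
    return ConfusionMatrix(
        TP=int(np.sum(pred & true)),
        TN=int(np.sum(~pred & ~true)),
        FP=int(np.sum(pred & ~true)),
        FN=int(np.sum(~pred & true)),
    )


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr_curve: np.ndarray
    fpr_curve: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_tpr: float
    optimal_spc: float


def roc_sweep(
    scores, labels_true, lo: float = 0.0, hi: float = 180.0, step: float = 1.0
) -> RocResult:
    """Threshold sweep ROC.

    Predict "narrow" iff score < t for each t in [lo, hi] (step `step`);
    smaller angles/distances are more pathological.  AUC by the trapezoidal
    rule over the swept (FPR, TPR) points plus the (0,0) and (1,1)
    endpoints; the operating threshold maximizes Youden's J, ties going to
    the smallest t.
    """
    s = np.asarray(list(scores), dtype=float)
    y = _as_narrow(labels_true)
    if s.size != y.size or s.size == 0:
        raise EvaluationError("scores and labels must be non-empty and equally long")
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    P, N = int(y.sum()), int((~y).sum())
    if P == 0 or N == 0:
        raise EvaluationError("both classes must be present for a ROC sweep")

    ts = np.arange(lo, hi + step / 2.0, step)
    pred = s[None, :] < ts[:, None]
    tpr = (pred & y[None, :]).sum(axis=1) / P
    fpr = (pred & ~y[None, :]).sum(axis=1) / N

    fx = np.concatenate([[0.0], fpr, [1.0]])
    ty = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((ty, fx))
    auc = float(np.trapezoid(ty[order], fx[order]))

    j = tpr + (1.0 - fpr) - 1.0
    k = int(np.argmax(j))  # argmax takes the first (smallest t) maximizer
    return RocResult(
        thresholds=ts,
        tpr_curve=tpr,
        fpr_curve=fpr,
        auc=auc,
        optimal_threshold=float(ts[k]),
        optimal_tpr=float(tpr[k]),
        optimal_spc=float(1.0 - fpr[k]),
    )


def plot_roc(roc: RocResult, path, title: str = "ROC") -> None:
    """Write the swept ROC curve as a PNG (deterministic output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr_curve, roc.tpr_curve, "b-", lw=1.5, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.plot(
        1.0 - roc.optimal_spc, roc.optimal_tpr, "ro",
        label=f"Youden optimum @ t = {roc.optimal_threshold:g}",
    )
    ax.set_xlabel("1 − specificity (FPR)")
    ax.set_ylabel("sensitivity (TPR)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
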