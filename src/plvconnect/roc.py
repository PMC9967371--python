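"""ROC discrimination analysis with stratified-bootstrap confidence
intervals.

Scores are one connectivity feature per subject (e.g. delta-band
motor-task global PLV); the positive class defaults to healthy controls
because the feature is elevated in that group. Classification is
``score >= threshold`` -> positive. The empirical ROC is built from all
distinct score thresholds; the trapezoidal AUC equals the Mann-Whitney
probability (ties counted 1/2) exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass
class LabeledScores:
    """Scores with binary class labels; direction: higher -> positive."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive class
    positive_label: str = "HC"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and the same shape")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if self.labels.all() or not self.labels.any():
            raise ValueError(
                "need at least one positive and one negative observation"
            )

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        band: str,
        condition: str,
        positive: str = "HC",
        response: str = "global_plv",
    ) -> "LabeledScores":
        """Extract one band x condition feature from a connectivity table."""
        sliced = table[(table["band"] == band) & (table["condition"] == condition)]
        if len(sliced) == 0:
            raise ValueError(f"no rows for band={band!r}, condition={condition!r}")
        return cls(
            scores=sliced[response].to_numpy(dtype=float),
            labels=(sliced["group"] == positive).to_numpy(),
            positive_label=positive,
        )


@dataclass
class ConfusionMetrics:
    """Counts and derived metrics at one threshold. Ratios with a zero
    denominator are NaN and listed in ``undefined`` (never silently 0)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_metrics(data: LabeledScores, threshold: float) -> ConfusionMetrics:
    """Classify ``score >= threshold`` as positive and tabulate."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = data.scores >= threshold
    tp = int(np.sum(pred & data.labels))
    fp = int(np.sum(pred & ~data.labels))
    tn = int(np.sum(~pred & ~data.labels))
    fn = int(np.sum(~pred & data.labels))

    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        accuracy=(tp + tn) / len(data.scores),
        undefined=tuple(undefined),
    )


@dataclass
class ROCResult:
    """Empirical ROC curve plus, once evaluated, the chosen operating
    point, its confusion metrics, and bootstrap confidence intervals."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    data: LabeledScores
    cutoff: float | None = None
    confusion: ConfusionMetrics | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_dropped: dict[str, int] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None


def roc_curve(data: LabeledScores) -> ROCResult:
    """Empirical ROC from all distinct score thresholds.

    The curve starts at (0, 0) (threshold +inf: nothing positive) and
    ends at (1, 1) (threshold = min score: everything positive). AUC is
    the trapezoidal integral, identical to the Mann-Whitney U
    probability with ties counted one half.
    """
    order = np.argsort(-data.scores, kind="stable")
    scores = data.scores[order]
    labels = data.labels[order]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    # last index of each run of equal scores
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.concatenate([distinct, [labels.size - 1]])
    tps = np.cumsum(labels)[idx]
    fps = (idx + 1) - tps
    thresholds = np.concatenate([[np.inf], scores[idx]])
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, data=data)


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold maximising PPV + NPV.

    Candidates are every curve threshold (finite ones classify at least
    one observation positive). Thresholds where PPV or NPV is undefined
    are skipped. Ties go to higher sensitivity, then to the lower
    threshold. If no threshold defines both predictive values (e.g. all
    scores identical), falls back to maximising sensitivity +
    specificity over finite thresholds.
    """
    best: tuple[float, float, float] | None = None  # (ppv+npv, sens, -thr)
    best_thr: float | None = None
    for thr in roc.thresholds:
        if not math.isfinite(thr):
            continue
        cm = confusion_metrics(roc.data, thr)
        if "ppv" in cm.undefined or "npv" in cm.undefined:
            continue
        key = (cm.ppv + cm.npv, cm.sensitivity, -thr)
        if best is None or key > best:
            best, best_thr = key, float(thr)
    if best_thr is not None:
        return best_thr
    fallback: tuple[float, float] | None = None
    for thr in roc.thresholds:
        if not math.isfinite(thr):
            continue
        cm = confusion_metrics(roc.data, thr)
        youden = (0.0 if math.isnan(cm.sensitivity) else cm.sensitivity) + (
            0.0 if math.isnan(cm.specificity) else cm.specificity
        )
        key = (youden, -thr)
        if fallback is None or key > fallback:
            fallback, best_thr = key, float(thr)
    assert best_thr is not None
    return best_thr


def bootstrap_ci(
    data: LabeledScores,
    n_boot: int = 10_000,
    seed: int = 0,
    freeze_cutoff: float | None = None,
) -> tuple[dict[str, tuple[float, float]], dict[str, int]]:
    """Stratified-bootstrap 95% percentile intervals for AUC and the
    operating-point metrics.

    Positives and negatives are resampled separately with replacement so
    every replicate keeps the class proportions. By default the cutoff
    is re-selected inside each replicate; pass ``freeze_cutoff`` to hold
    it fixed. Replicates where a metric is undefined are dropped for
    that metric and counted in the second return value.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    n_pos, n_neg = len(pos), len(neg)
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    names = ("auc",) + METRIC_NAMES
    draws = {name: np.empty(n_boot) for name in names}
    for b in range(n_boot):
        scores = np.concatenate(
            [rng.choice(pos, n_pos, replace=True), rng.choice(neg, n_neg, replace=True)]
        )
        rep = LabeledScores(scores, labels, data.positive_label)
        curve = roc_curve(rep)
        thr = freeze_cutoff if freeze_cutoff is not None else optimal_cutoff(curve)
        cm = confusion_metrics(rep, thr)
        draws["auc"][b] = curve.auc
        for name in METRIC_NAMES:
            draws[name][b] = getattr(cm, name)
    ci: dict[str, tuple[float, float]] = {}
    dropped: dict[str, int] = {}
    for name in names:
        vals = draws[name]
        ok = vals[~np.isnan(vals)]
        dropped[name] = int(np.isnan(vals).sum())
        if len(ok) == 0:
            ci[name] = (float("nan"), float("nan"))
        else:
            ci[name] = (
                float(np.percentile(ok, 2.5)),
                float(np.percentile(ok, 97.5)),
            )
    return ci, dropped


def evaluate(
    data: LabeledScores,
    n_boot: int = 10_000,
    seed: int = 0,
    freeze_cutoff: bool = False,
) -> ROCResult:
    """Full discrimination analysis: curve, AUC, operating point,
    confusion metrics, and stratified-bootstrap intervals."""
    result = roc_curve(data)
    result.cutoff = optimal_cutoff(result)
    result.confusion = confusion_metrics(data, result.cutoff)
    result.ci, result.ci_dropped = bootstrap_ci(
        data,
        n_boot=n_boot,
        seed=seed,
        freeze_cutoff=result.cutoff if freeze_cutoff else None,
    )
    result.n_boot = n_boot
    result.seed = seed
    return result
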