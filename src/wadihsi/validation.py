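"""Presence/background model validation battery.

Confusion-matrix metrics (sensitivity, specificity, TSS, accuracy,
balanced accuracy, precision, F1, prevalences), rank-based AUC, threshold
selection (MaxSS / MinROCdist), the normalised calibration ratio, the
continuous Boyce index, and leave-one-out cross-validation of the
habitat-suitability pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ValidationReport",
    "ThresholdChoice",
    "LoocvReport",
    "confusion_metrics",
    "auc",
    "select_threshold",
    "calibration_ratio",
    "boyce_index",
    "loocv",
]

#: sentinel reason strings accompany NaN metrics with zero denominators
PREVALENCE_MISMATCH_TOLERANCE = 0.10


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty confusion matrix (N = 0)")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ValidationReport:
    """All derived confusion-matrix metrics; NaN where a denominator is zero,
    with the reason recorded in ``undefined``."""

    sensitivity: float
    specificity: float
    tss: float
    accuracy: float
    balanced_accuracy: float
    precision: float
    f1: float
    predicted_prevalence: float
    observed_prevalence: float
    prevalence_mismatch: bool
    undefined: dict[str, str] = field(default_factory=dict)


def _ratio(num: int, den: int, name: str, undefined: dict[str, str]) -> float:
    if den == 0:
        undefined[name] = f"denominator zero ({name})"
        return float("nan")
    return num / den


def confusion_metrics(c: ConfusionCounts) -> ValidationReport:
    """Derive the full metric battery from TP/FP/TN/FN.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    TSS = sensitivity + specificity - 1, accuracy = (TP+TN)/N,
    balanced accuracy = (sens+spec)/2, precision = TP/(TP+FP),
    F1 = 2 * precision * sensitivity / (precision + sensitivity),
    predicted prevalence = (TP+FP)/N, observed prevalence = (TP+FN)/N.
    A deviation of more than 10 percentage points between predicted and
    observed prevalence raises the mismatch flag.
    """
    und: dict[str, str] = {}
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", und)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", und)
    acc = (c.tp + c.tn) / c.n
    prec = _ratio(c.tp, c.tp + c.fp, "precision", und)
    if math.isnan(sens) or math.isnan(spec):
        tss = bal = float("nan")
        und.setdefault("tss", "needs both sensitivity and specificity")
        und.setdefault("balanced_accuracy", "needs both sensitivity and specificity")
    else:
        tss = sens + spec - 1.0
        bal = (sens + spec) / 2.0
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
        und.setdefault("f1", "precision + sensitivity is zero or undefined")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    pred_prev = (c.tp + c.fp) / c.n
    obs_prev = (c.tp + c.fn) / c.n
    return ValidationReport(
        sensitivity=sens,
        specificity=spec,
        tss=tss,
        accuracy=acc,
        balanced_accuracy=bal,
        precision=prec,
        f1=f1,
        predicted_prevalence=pred_prev,
        observed_prevalence=obs_prev,
        prevalence_mismatch=abs(pred_prev - obs_prev) > PREVALENCE_MISMATCH_TOLERANCE,
        undefined=und,
    )


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann–Whitney) AUC with ties counted half.

    Probability that a random presence score outranks a random background
    score; 0.5 is no discrimination, 1.0 perfect.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    u = stats.mannwhitneyu(p, b, alternative="two-sided").statistic
    return float(u / (p.size * b.size))


@dataclass(frozen=True)
class ThresholdChoice:
    method: str
    threshold: float
    objective: float


def _sens_spec_at(p: np.ndarray, b: np.ndarray, t: float) -> tuple[float, float]:
    # predicted positive iff score >= threshold
    return float(np.mean(p >= t)), float(np.mean(b < t))


def select_threshold(
    presence_scores, background_scores, method: str = "MaxSS"
) -> ThresholdChoice:
    """Pick a binarisation threshold for continuous suitability scores.

    ``default``: 0.5 regardless of the data. ``MaxSS``: maximise
    sensitivity + specificity. ``MinROCdist``: minimise the Euclidean
    distance to the perfect-classification corner (sens=1, spec=1) of ROC
    space. Candidate cuts are the midpoints of consecutive sorted unique
    scores plus the endpoints 0 and 1; ties break toward the lower
    threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if method == "default":
        sens, spec = _sens_spec_at(p, b, 0.5)
        return ThresholdChoice("default", 0.5, sens + spec)
    uniq = np.unique(np.concatenate([p, b]))
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]])
    best_t, best_obj = None, None
    for t in candidates:
        sens, spec = _sens_spec_at(p, b, t)
        if method == "MaxSS":
            obj = sens + spec
            better = best_obj is None or obj > best_obj
        elif method == "MinROCdist":
            obj = math.hypot(1.0 - sens, 1.0 - spec)
            better = best_obj is None or obj < best_obj
        else:
            raise ValueError(f"unknown method {method!r}")
        if better:  # strict: first (lowest) threshold wins ties
            best_t, best_obj = float(t), obj
    return ThresholdChoice(method, best_t, best_obj)


def calibration_ratio(presence_scores, background_scores) -> float:
    """Normalised calibration statistic (q - 1)/(q + 1) in (-1, 1),
    q = mean presence suitability / mean background suitability.

    Positive values mean the model assigns higher suitability where the
    species actually occurs; 0 means no calibration signal.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    mb = b.mean()
    if mb <= 0:
        raise ValueError("mean background suitability must be positive")
    q = p.mean() / mb
    return (q - 1.0) / (q + 1.0)


def boyce_index(
    presence_scores,
    background_scores,
    n_windows: int = 10,
    window_width: float | None = None,
) -> float:
    """Continuous Boyce index: Spearman correlation between suitability and
    the predicted-to-expected occurrence ratio.

    Overlapping windows slide across the score range; in each, P = fraction
    of presence points and E = fraction of background points. Windows with
    E = 0 are dropped; ranks use the average-rank tie rule. +1 means
    occurrence frequency rises monotonically with predicted suitability.

    ``window_width`` defaults to 20% of the observed score range.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    allv = np.concatenate([p, b])
    lo, hi = allv.min(), allv.max()
    if hi <= lo:
        raise ValueError("degenerate score range")
    width = window_width if window_width is not None else 0.2 * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    pe, kept_mids = [], []
    for m in mids:
        wlo, whi = m - width / 2.0, m + width / 2.0
        pr = np.mean((p >= wlo) & (p <= whi))
        ex = np.mean((b >= wlo) & (b <= whi))
        if ex > 0:
            pe.append(pr / ex)
            kept_mids.append(m)
    if len(pe) < 2:
        raise ValueError("fewer than two windows with background support")
    rho = stats.spearmanr(kept_mids, pe).statistic
    return float(rho)


@dataclass
class LoocvReport:
    """Leave-one-out transferability of the suitability pipeline."""

    site_ids: list
    observed: np.ndarray
    predicted: np.ndarray
    residuals: np.ndarray  # observed - predicted
    r2: float
    rmse: float
    mae: float
    mean_residual: float
    flagged_folds: list = field(default_factory=list)


def loocv(
    site_ids,
    observed,
    predictor: Callable[[int], float],
) -> LoocvReport:
    """Generic LOOCV driver.

    ``predictor(i)`` must return the prediction for site i from a model
    trained without site i. ``observed`` are the full-data reference values
    (for an unsupervised index, its full-data scores). A fold whose
    predictor raises is flagged — never silently skipped — and excluded
    from the summary statistics. R^2 = 1 - SS_res/SS_tot can be negative
    when transfer is worse than predicting the mean.
    """
    ids = list(site_ids)
    obs = np.asarray(observed, dtype=float)
    if len(ids) != obs.size:
        raise ValueError("site_ids and observed must align")
    if obs.size < 3:
        raise ValueError("LOOCV needs at least three sites")
    pred = np.full(obs.size, np.nan)
    flagged = []
    for i in range(obs.size):
        try:
            pred[i] = predictor(i)
        except Exception as exc:  # degenerate re-fit etc.
            flagged.append((ids[i], str(exc)))
    ok = ~np.isnan(pred)
    if ok.sum() < 3:
        raise ValueError("fewer than three successful folds")
    resid = obs[ok] - pred[ok]
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs[ok] - obs[ok].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    full_resid = obs - pred  # NaN at flagged folds
    return LoocvReport(
        site_ids=ids,
        observed=obs,
        predicted=pred,
        residuals=full_resid,
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        mean_residual=float(np.mean(resid)),
        flagged_folds=flagged,
    )
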