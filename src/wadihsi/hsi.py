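"""Composite Habitat Suitability Index: geometric-mean combination,
quantile classification, and substrate-impact comparison.

The geometric mean is deliberately conservative: a single near-zero
parameter score drags the composite toward zero, penalising habitats with
any one critical limitation — an arithmetic mean would average it away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "PRESET_THRESHOLDS",
    "HsiResult",
    "geometric_mean_hsi",
    "quantile_thresholds",
    "classify",
    "classify_quantile",
    "substrate_impact",
]

#: five suitability classes, worst to best
CLASS_LABELS = (
    "Unsuitable",
    "Less Suitable",
    "Moderately Suitable",
    "Suitable",
    "Highly Suitable",
)

#: named threshold presets; "hajar" is the published twelve-wadi field-survey
#: classification of the Hajar Mountain study
PRESET_THRESHOLDS: dict[str, tuple[float, float, float, float]] = {
    "hajar": (0.47, 0.51, 0.59, 0.75),
}


@dataclass
class HsiResult:
    """Per-site composite suitability with its classification context."""

    site_id: str
    scores: dict[str, float]
    hsi: float
    label: str
    thresholds: tuple[float, float, float, float] = field(repr=False)


def geometric_mean_hsi(scores) -> float:
    """Geometric mean (prod s_i)^(1/n) of per-parameter suitabilities.

    Computed in log space for numerical stability. Scores must be strictly
    positive: a zero would annihilate the composite, and zeros are expected
    to be floored upstream (e.g. the substrate-score floor), never passed
    here silently.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if np.any(s <= 0):
        raise ValueError(
            "scores must be strictly positive: the geometric mean reduces the "
            "composite to zero whenever one parameter proves unsuitable; "
            "floor near-zero scores upstream instead"
        )
    return float(np.exp(np.mean(np.log(s))))


def quantile_thresholds(
    values, n_classes: int = 5, interpolation: str = "linear"
) -> tuple[float, ...]:
    """Empirical percentile cut points (20/40/60/80 for five classes)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty HSI vector")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    qs = np.linspace(0, 100, n_classes + 1)[1:-1]
    return tuple(float(t) for t in np.percentile(v, qs, method=interpolation))


def classify(values, thresholds) -> list[str]:
    """Label each value by its threshold interval.

    Intervals are closed on the left and open on the right; the top class is
    closed on both sides, so with all thresholds equal every site lands in
    the top class.
    """
    thr = tuple(float(t) for t in thresholds)
    if len(thr) != len(CLASS_LABELS) - 1:
        raise ValueError(f"expected {len(CLASS_LABELS) - 1} thresholds, got {len(thr)}")
    if any(b < a for a, b in zip(thr, thr[1:])):
        raise ValueError("thresholds must be ascending")
    v = np.asarray(values, dtype=float)
    idx = np.searchsorted(thr, v, side="right")
    return [CLASS_LABELS[i] for i in idx]


def classify_quantile(
    hsi_values,
    n_classes: int = 5,
    interpolation: str = "linear",
    thresholds=None,
) -> tuple[tuple[float, ...], list[str]]:
    """Classify sites into suitability zones by the HSI distribution.

    By default the cut points are the 20/40/60/80th percentiles of the data
    itself (data-driven zoning); explicit ``thresholds`` (a 4-tuple or a
    preset name such as ``"hajar"``) override the percentile computation.
    Returns ``(thresholds, labels)``.
    """
    if thresholds is None:
        thr = quantile_thresholds(hsi_values, n_classes, interpolation)
    elif isinstance(thresholds, str):
        try:
            thr = PRESET_THRESHOLDS[thresholds]
        except KeyError:
            raise ValueError(
                f"unknown threshold preset {thresholds!r}; "
                f"available: {sorted(PRESET_THRESHOLDS)}"
            ) from None
    else:
        thr = tuple(float(t) for t in thresholds)
    return thr, classify(hsi_values, thr)


def substrate_impact(hsi_with, hsi_without, site_ids=None) -> pd.DataFrame:
    """Percent change in HSI from including the substrate-texture score.

    Returns a frame with columns ``hsi_with``, ``hsi_without``,
    ``pct_change`` (100 * (with - without) / without) and a summary in
    ``df.attrs`` counting improved / degraded / unchanged sites.
    """
    w = np.asarray(hsi_with, dtype=float)
    wo = np.asarray(hsi_without, dtype=float)
    if w.shape != wo.shape:
        raise ValueError("site sets differ in length")
    if np.any(wo == 0):
        raise ValueError("zero baseline HSI; percent change undefined")
    pct = 100.0 * (w - wo) / wo
    idx = list(site_ids) if site_ids is not None else list(range(len(w)))
    df = pd.DataFrame(
        {"hsi_with": w, "hsi_without": wo, "pct_change": pct}, index=idx
    )
    df.attrs["improved"] = int(np.sum(pct > 0))
    df.attrs["degraded"] = int(np.sum(pct < 0))
    df.attrs["unchanged"] = int(np.sum(pct == 0))
    return df
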