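"""Conservation gap accounting.

High-suitability habitat is the top decile of the suitability surface;
protection rate is the share of it inside the protected-area network.
Progress and required fold-increase are reported against tiered policy
targets (e.g. a national 7.5% wetland-habitat target and the CBD 30x30
global target), and wadi stream networks are scored against density-tiered
protection targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TARGETS",
    "DENSITY_TARGETS",
    "DENSITY_BOUNDS",
    "ProtectionSummary",
    "high_suitability_mask",
    "protection_rate",
    "target_progress",
    "wadi_density_classify",
    "density_protection_summary",
]

#: policy protection targets, percent of habitat
DEFAULT_TARGETS = {"national_2040": 7.5, "cbd_30x30": 30.0}

#: per-density-class protection targets, percent of streams in the class
DENSITY_TARGETS = {"high": 50.0, "medium": 30.0, "low": 10.0}

#: stream density class bounds in km/km^2: low < 0.0004, medium is the
#: closed interval [0.0004, 0.0008], high > 0.0008
DENSITY_BOUNDS = (0.0004, 0.0008)


@dataclass
class ProtectionSummary:
    percentile: float
    threshold: float
    habitat_area: float
    protected_area: float
    rate_pct: float
    targets: dict[str, dict[str, float]] = field(default_factory=dict)


def high_suitability_mask(
    grid, percentile: float = 90.0
) -> tuple[np.ndarray, float]:
    """Top-percentile habitat mask.

    The threshold is the given percentile of all valid (finite) cells;
    cells >= threshold are habitat. NaN cells never enter the threshold
    computation nor the mask. Returns ``(mask, threshold)``.
    """
    g = np.asarray(grid, dtype=float)
    valid = np.isfinite(g)
    if not valid.any():
        raise ValueError("grid has no valid cells")
    thr = float(np.percentile(g[valid], percentile))
    mask = valid & (g >= thr)
    return mask, thr


def protection_rate(
    habitat_mask, protected_mask, cell_area: float = 1.0
) -> tuple[float, float, float]:
    """(rate %, habitat area, protected habitat area).

    rate = 100 * |habitat AND protected| / |habitat|; areas are cell counts
    times a constant per-cell area (equal-area grid assumed).
    """
    h = np.asarray(habitat_mask, dtype=bool)
    p = np.asarray(protected_mask, dtype=bool)
    if h.shape != p.shape:
        raise ValueError("mask shapes differ")
    n_h = int(h.sum())
    if n_h == 0:
        raise ValueError("empty habitat mask")
    n_hp = int((h & p).sum())
    return 100.0 * n_hp / n_h, n_h * cell_area, n_hp * cell_area


def target_progress(
    rate_pct: float, targets: dict[str, float] | None = None
) -> dict[str, dict[str, float]]:
    """Progress toward each protection target and the fold increase needed.

    progress = 100 * rate / target; fold = target / rate (inf when nothing
    is protected yet), also rounded to the nearest integer as commonly
    reported.
    """
    if rate_pct < 0:
        raise ValueError("protection rate cannot be negative")
    targets = DEFAULT_TARGETS if targets is None else targets
    out: dict[str, dict[str, float]] = {}
    for name, tgt in targets.items():
        if tgt <= 0:
            raise ValueError(f"target {name!r} must be positive")
        if rate_pct == 0:
            fold, fold_int = math.inf, math.inf
        else:
            fold = tgt / rate_pct
            fold_int = round(fold)
        out[name] = {
            "target_pct": tgt,
            "progress_pct": 100.0 * rate_pct / tgt,
            "fold_increase": fold,
            "fold_increase_rounded": fold_int,
        }
    return out


def wadi_density_classify(density) -> list[str]:
    """Classify stream densities (km/km^2) into low / medium / high.

    Medium is closed on both ends: exactly 0.0004 or 0.0008 is medium.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative stream density")
    lo, hi = DENSITY_BOUNDS
    return ["low" if x < lo else ("medium" if x <= hi else "high") for x in d]


def density_protection_summary(
    classes,
    protected,
    targets: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-density-class protection accounting for a stream network.

    Two distinct readings are computed and labelled explicitly:

    - ``protected_pct_of_class``: protected streams / all streams *in that
      class* — the within-class protection rate compared against the
      class target (``gap_pct`` = target - rate).
    - ``share_of_protected_pct``: that class's share of *all protected*
      streams — the composition of the protected network.
    """
    cls = list(classes)
    prot = np.asarray(protected, dtype=bool)
    if len(cls) != prot.size:
        raise ValueError("classes and protected flags must align")
    targets = DENSITY_TARGETS if targets is None else targets
    order = ["high", "medium", "low"]
    n_prot_total = int(prot.sum())
    rows = []
    for c in order:
        in_c = np.array([x == c for x in cls])
        total = int(in_c.sum())
        n_prot = int((in_c & prot).sum())
        rate = 100.0 * n_prot / total if total else float("nan")
        share = 100.0 * n_prot / n_prot_total if n_prot_total else float("nan")
        tgt = targets.get(c, float("nan"))
        rows.append(
            {
                "class": c,
                "total_streams": total,
                "protected_streams": n_prot,
                "protected_pct_of_class": rate,
                "share_of_protected_pct": share,
                "target_pct": tgt,
                "gap_pct": tgt - rate if total else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("class")
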