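"""MESS extrapolation analysis, replicate-uncertainty summaries, and the
equal-interval suitability classifier.

MESS (multivariate environmental similarity surface) scores each projection
point by how far it sits inside — or outside — the environmental envelope of
the training reference set. Negative values flag novel (extrapolated)
conditions where model projections are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnvReference",
    "MessResult",
    "mess",
    "mess_similarity",
    "classify_mess",
    "replicate_cv",
    "equal_interval_classes",
    "MESS_STRONG_THRESHOLD",
    "EQUAL_INTERVAL_BOUNDS",
    "EQUAL_INTERVAL_LABELS",
]

#: class boundary between strong and moderate extrapolation
MESS_STRONG_THRESHOLD = -10.0

#: sentinel for a point off a zero-width reference range
DEGENERATE_RANGE_SENTINEL = -1000.0

EQUAL_INTERVAL_BOUNDS = (0.25, 0.50, 0.75)
EQUAL_INTERVAL_LABELS = ("absent", "low", "medium", "high")


@dataclass(frozen=True)
class EnvReference:
    """Training-domain environmental envelope: points x variables."""

    data: np.ndarray
    variables: tuple[str, ...]

    @classmethod
    def from_matrix(cls, matrix, variables=None) -> "EnvReference":
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError("reference needs >= 2 points in a 2-D matrix")
        if np.any(~np.isfinite(m)):
            raise ValueError("reference contains missing values")
        names = (
            tuple(variables)
            if variables is not None
            else tuple(f"v{i}" for i in range(m.shape[1]))
        )
        if len(names) != m.shape[1]:
            raise ValueError("variable names do not match matrix width")
        return cls(data=m, variables=names)


@dataclass(frozen=True)
class MessResult:
    value: float
    most_dissimilar: str
    label: str


def mess_similarity(ref_values: np.ndarray, point: float) -> float:
    """Single-variable similarity of one point to a reference sample.

    With f = percentage of reference values strictly below the point:
    f = 0   -> 100 * (p - min) / (max - min)          (below the envelope)
    0<f<=50 -> 2f
    50<f<100-> 2(100 - f)
    f = 100 -> 100 * (max - p) / (max - min)          (above the envelope)
    Negative iff the point lies outside the reference range.
    """
    r = np.asarray(ref_values, dtype=float)
    rmin, rmax = r.min(), r.max()
    f = 100.0 * np.mean(r < point)
    if rmax == rmin:
        # zero-width envelope: perfect analog on it, a large-negative
        # sentinel off it
        return 100.0 if point == rmin else DEGENERATE_RANGE_SENTINEL
    if f == 0.0:
        return 100.0 * (point - rmin) / (rmax - rmin)
    if f <= 50.0:
        return 2.0 * f
    if f < 100.0:
        return 2.0 * (100.0 - f)
    return 100.0 * (rmax - point) / (rmax - rmin)


def _mess_label(v: float) -> str:
    if v < MESS_STRONG_THRESHOLD:
        return "strong"
    if v < 0.0:
        return "moderate"
    return "analog"


def mess(ref: EnvReference, points) -> list[MessResult]:
    """MESS of each projection point: the minimum similarity over variables,
    tagged with the most dissimilar variable and its extrapolation class.

    NaN rows (masked / NODATA points) propagate as NaN results.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != ref.data.shape[1]:
        raise ValueError(
            f"point dimension {pts.shape[1]} != reference dimension "
            f"{ref.data.shape[1]}; variable sets must match in order"
        )
    out = []
    for row in pts:
        if np.any(~np.isfinite(row)):
            out.append(MessResult(float("nan"), "", "nodata"))
            continue
        sims = np.array(
            [
                mess_similarity(ref.data[:, j], row[j])
                for j in range(ref.data.shape[1])
            ]
        )
        j_min = int(np.argmin(sims))
        v = float(sims[j_min])
        out.append(MessResult(v, ref.variables[j_min], _mess_label(v)))
    return out


def classify_mess(values) -> tuple[list[str], dict[str, float]]:
    """Three-way extrapolation classes and their percentage shares.

    strong: MESS < -10; moderate: -10 <= MESS < 0; analog: MESS >= 0.
    NaN values are excluded from the shares' denominator.
    """
    v = np.asarray(values, dtype=float)
    labels = ["nodata" if not np.isfinite(x) else _mess_label(x) for x in v]
    valid = [lab for lab in labels if lab != "nodata"]
    n = len(valid)
    fractions = {
        name: (100.0 * valid.count(name) / n if n else float("nan"))
        for name in ("strong", "moderate", "analog")
    }
    return labels, fractions


def replicate_cv(stack, threshold: float = 0.5) -> tuple[np.ndarray, float]:
    """Per-cell coefficient of variation across bootstrap replicate grids.

    CV = sample SD / mean per cell; cells with mean 0 (or any NaN replicate)
    are NaN and excluded from the denominator of the reported fraction of
    cells with CV > ``threshold``.
    """
    s = np.asarray(stack, dtype=float)
    if s.ndim < 2 or s.shape[0] < 2:
        raise ValueError("need a stack of >= 2 replicate grids")
    if np.nanmin(s) < 0:
        raise ValueError("replicate values must be nonnegative")
    mean = s.mean(axis=0)
    sd = s.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    cv = np.where(np.any(~np.isfinite(s), axis=0), np.nan, cv)
    valid = np.isfinite(cv)
    frac = float(np.mean(cv[valid] > threshold)) if valid.any() else float("nan")
    return cv, frac


def equal_interval_classes(
    grid, cell_area: float = 1.0
) -> tuple[np.ndarray, dict[str, float]]:
    """Fixed-breakpoint suitability classes and per-class area.

    absent [0, 0.25), low [0.25, 0.5), medium [0.5, 0.75), high [0.75, 1].
    Returns an object array of labels (NaN cells -> None) and a dict of
    class areas (= cell counts x ``cell_area``).
    """
    g = np.asarray(grid, dtype=float)
    labels = np.empty(g.shape, dtype=object)
    areas = dict.fromkeys(EQUAL_INTERVAL_LABELS, 0.0)
    idx = np.searchsorted(EQUAL_INTERVAL_BOUNDS, g, side="right")
    for pos, lab in np.ndenumerate(np.asarray(EQUAL_INTERVAL_LABELS, dtype=object)[idx]):
        if np.isfinite(g[pos]):
            labels[pos] = lab
            areas[lab] += cell_area
        else:
            labels[pos] = None
    return labels, areas
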