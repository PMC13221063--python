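"""Alpha/beta diversity and bootstrap-validated correlations.

Shannon entropy uses the natural logarithm, Simpson is the Gini–Simpson
form (1 - sum p^2), and evenness is Pielou's J = H / ln(S_observed) — the
conventions under which published site tables for small desert-stream
communities back-solve to integer species richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "shannon",
    "simpson",
    "evenness",
    "bray_curtis_matrix",
    "CorrelationResult",
    "correlate_with_bootstrap",
]


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    return c[c > 0] / total


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    p = _proportions(counts)
    return float(-np.sum(p * np.log(p)))


def simpson(counts) -> float:
    """Gini–Simpson index 1 - sum p_i^2 in [0, 1)."""
    p = _proportions(counts)
    return float(1.0 - np.sum(p**2))


def evenness(counts) -> float:
    """Pielou evenness J = H / ln(S_observed).

    Undefined (NaN, not 0) for a single-species community: a monoculture
    has no meaningful evenness, and coding it 0 would conflate it with a
    maximally uneven multi-species community.
    """
    p = _proportions(counts)
    s_obs = p.size
    if s_obs < 2:
        return float("nan")
    return float(-np.sum(p * np.log(p)) / np.log(s_obs))


def bray_curtis_matrix(counts_matrix) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, sites x sites.

    d(x, y) = 1 - 2 sum min(x_i, y_i) / (sum x + sum y); 0 for identical
    communities, 1 for fully disjoint ones.
    """
    m = np.asarray(counts_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D sites x species matrix")
    if np.any(m < 0):
        raise ValueError("negative counts")
    if np.any(m.sum(axis=1) <= 0):
        raise ValueError("every site must have a positive total count")
    return squareform(pdist(m, metric="braycurtis"))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a bootstrap confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"r = {self.r:.3f} (95% CI {self.ci_low:.3f} to {self.ci_high:.3f}), "
            f"p = {self.p_value:.3f}"
        )


def correlate_with_bootstrap(
    x,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
    method: str = "percentile",
) -> CorrelationResult:
    """Pearson r with a bootstrap CI over resampled (x, y) site pairs.

    The resampling unit is the whole site (paired observation); the CI is
    the 2.5/97.5 percentile of the bootstrap distribution of r (``method=
    "bca"`` switches to bias-corrected-accelerated). The p-value is the
    usual two-sided t-transform of r.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = xa.size
    if n < 4:
        raise ValueError("need at least four paired observations")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")

    r, p = stats.pearsonr(xa, ya)
    alpha = (100.0 - ci) / 2.0
    rng = np.random.default_rng(seed)

    if method == "bca":
        res = stats.bootstrap(
            (xa, ya),
            lambda a, b, axis=-1: _safe_pearson(a, b, axis),
            paired=True,
            vectorized=True,
            n_resamples=n_boot,
            confidence_level=ci / 100.0,
            method="BCa",
            rng=rng,
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
        # degenerate (zero-variance) resamples yield NaN and are excluded
        boot = _safe_pearson(xa[idx], ya[idx], axis=1)
        lo, hi = np.nanpercentile(boot, [alpha, 100.0 - alpha])

    return CorrelationResult(
        r=float(r),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def _safe_pearson(a, b, axis):
    a = a - np.mean(a, axis=axis, keepdims=True)
    b = b - np.mean(b, axis=axis, keepdims=True)
    denom = np.sqrt(np.sum(a**2, axis=axis) * np.sum(b**2, axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sum(a * b, axis=axis) / denom
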