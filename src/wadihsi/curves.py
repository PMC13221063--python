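"""Abundance-weighted Gaussian habitat-suitability curves.

Each environmental parameter (depth, width, velocity, temperature, pH, EC,
TDS, salinity, DO, BOD, turbidity, substrate texture) gets a bell-shaped
response curve

    S(x) = exp(-(x - mu)^2 / (2 sigma^2)),

where ``mu`` and ``sigma`` are the abundance-weighted mean and standard
deviation of the field measurements: a site holding many fish pulls the
niche optimum toward its conditions the way a replicated observation would.
Suitability is 1 at the optimum and decays symmetrically; evaluation is
clamped to the observed parameter range by default so the curve is never
extrapolated beyond conditions that were actually sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SuitabilityCurve",
    "TextureComposition",
    "DegenerateNicheError",
    "weighted_gaussian_fit",
    "gaussian_suitability",
    "optimal_range",
    "cosby_conductivity",
    "texture_scores",
]


class DegenerateNicheError(ValueError):
    """All weighted observations coincide: the fitted niche has zero width."""


@dataclass(frozen=True)
class SuitabilityCurve:
    """Fitted Gaussian response for one environmental parameter.

    Attributes
    ----------
    parameter : str
        Name of the environmental variable (units implied by the input data).
    mu, sigma : float
        Abundance-weighted mean and standard deviation; ``sigma > 0``.
    low, high : float
        Observed minimum/maximum of the fitting data; evaluation clamps
        to this interval unless asked not to.
    """

    parameter: str
    mu: float
    sigma: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise DegenerateNicheError(
                f"{self.parameter}: sigma must be positive, got {self.sigma}"
            )
        if not (self.low <= self.mu <= self.high):
            raise ValueError(
                f"{self.parameter}: mu={self.mu} outside observed bounds "
                f"[{self.low}, {self.high}]"
            )

    def __call__(self, x, clamp: bool = True):
        return gaussian_suitability(x, self, clamp=clamp)


def weighted_gaussian_fit(
    values,
    weights,
    parameter: str = "",
    unbiased: bool = False,
) -> SuitabilityCurve:
    """Fit (mu, sigma) by abundance-weighted moments.

    Weights act as replicate (frequency) counts: ``mu = sum(w x)/sum(w)``
    and ``sigma^2 = sum(w (x-mu)^2)/sum(w)`` (biased form). With
    ``unbiased=True`` the reliability-weight correction
    ``sum(w) - sum(w^2)/sum(w)`` is used as the denominator instead.

    Raises
    ------
    DegenerateNicheError
        If every positively-weighted value is identical (sigma would be 0).
    ValueError
        On length mismatch, fewer than two observations, negative weights,
        or all-zero weights.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if x.size < 2:
        raise ValueError("need at least two observations to fit a curve")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all weights are zero; cannot fit a curve")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite parameter values")

    mu = float(np.sum(w * x) / wsum)
    ss = float(np.sum(w * (x - mu) ** 2))
    if unbiased:
        denom = wsum - float(np.sum(w**2)) / wsum
        if denom <= 0:
            raise DegenerateNicheError(
                f"{parameter or 'parameter'}: effective sample size too small "
                "for the unbiased estimator"
            )
    else:
        denom = wsum
    var = ss / denom
    if var <= 0:
        raise DegenerateNicheError(
            f"{parameter or 'parameter'}: all weighted values identical; "
            "niche width is zero"
        )
    return SuitabilityCurve(
        parameter=parameter,
        mu=mu,
        sigma=math.sqrt(var),
        low=float(x.min()),
        high=float(x.max()),
    )


def gaussian_suitability(x, curve: SuitabilityCurve, clamp: bool = True):
    """Evaluate S(x) = exp(-(x-mu)^2 / (2 sigma^2)) in (0, 1].

    With ``clamp`` (the default), x is first clipped to the observed
    [low, high] range so the curve is never read outside sampled conditions.
    Accepts scalars or arrays.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite value passed to {curve.parameter or 'curve'}")
    if clamp:
        arr = np.clip(arr, curve.low, curve.high)
    z = (arr - curve.mu) / curve.sigma
    out = np.exp(-0.5 * z**2)
    return float(out) if np.isscalar(x) else out


def optimal_range(curve: SuitabilityCurve) -> tuple[float, float]:
    """Preferred interval [mu - sigma, mu + sigma], clipped to observed bounds.

    One niche width either side of the optimum (suitability >= exp(-1/2)
    ~ 0.61) is reported as the species' preferred range for the parameter.
    """
    return (
        max(curve.low, curve.mu - curve.sigma),
        min(curve.high, curve.mu + curve.sigma),
    )


@dataclass(frozen=True)
class TextureComposition:
    """Fine-sediment composition of one site's substrate.

    sand/silt/clay are fractions of the fines (gravel excluded and the
    remainder renormalised); they must sum to 1 within 2%.
    """

    sand: float
    silt: float
    clay: float

    def __post_init__(self) -> None:
        for name, v in (("sand", self.sand), ("silt", self.silt), ("clay", self.clay)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} fraction {v} outside [0, 1]")
        if abs(self.sand + self.silt + self.clay - 1.0) > 0.02:
            raise ValueError(
                "sand + silt + clay must sum to 1 within 0.02 "
                f"(got {self.sand + self.silt + self.clay:.4f})"
            )


# Cosby et al. (1984) univariate regression of log10 saturated hydraulic
# conductivity (inches/hour) on sand and clay percentages. Pinned here so the
# pedotransfer choice is auditable and swappable.
COSBY_INTERCEPT = -0.6
COSBY_SAND_COEF = 0.0126
COSBY_CLAY_COEF = -0.0064


def cosby_conductivity(comp: TextureComposition) -> float:
    """Saturated hydraulic conductivity (inches/hour) from the Cosby regression.

    log10 Ks = -0.6 + 0.0126 * sand% - 0.0064 * clay%.
    """
    log10_ks = (
        COSBY_INTERCEPT
        + COSBY_SAND_COEF * comp.sand * 100.0
        + COSBY_CLAY_COEF * comp.clay * 100.0
    )
    return 10.0**log10_ks


#: lower bound for the normalised texture score; keeps the geometric-mean HSI
#: from collapsing to zero at the minimum-conductivity site
TEXTURE_SCORE_FLOOR = 1e-3


def texture_scores(
    compositions, floor: float = TEXTURE_SCORE_FLOOR
) -> np.ndarray:
    """Log-normalised substrate score in [floor, 1] for a set of sites.

    The Cosby conductivity of each site is normalised across the site set:
    score = (log v - log v_min) / (log v_max - log v_min), floored at a small
    positive constant. Needs >= 2 sites to define the normalisation span.
    When every site has the same conductivity the span is degenerate and all
    sites score 1.
    """
    comps = list(compositions)
    if len(comps) < 2:
        raise ValueError("texture normalisation needs at least two sites")
    v = np.array([cosby_conductivity(c) for c in comps])
    logv = np.log(v)
    span = logv.max() - logv.min()
    if span == 0.0:
        return np.ones(len(comps))
    scores = (logv - logv.min()) / span
    return np.maximum(scores, floor)
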