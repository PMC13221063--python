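"""Seeded synthetic wadi datasets.

Emulates the structure of a 12-site arid-mountain stream survey: eleven
environmental parameters drawn within realistic field ranges, fish
abundance following a product-of-Gaussians response around a true niche
optimum with multiplicative lognormal noise, a specialist-dominated
community whose diversity falls as habitat suitability rises, plus
raster fixtures (suitability surface, protected-area mask, stream
density) and presence/background score sets for validation metrics.

All randomness flows from one explicit seed through a named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DEFAULT_PARAMETERS",
    "TrueModel",
    "SyntheticDataset",
    "generate_sites",
    "generate_community",
    "expected_shares",
    "generate_grids",
    "generate_prediction_sets",
]

#: parameter -> (low bound, high bound, true optimum, true niche width).
#: Bounds follow observed field ranges for Hajar Mountain wadis (depth cm,
#: width m, velocity m/s, temperature degC, pH, EC uS/cm, TDS mg/L,
#: salinity ppt, DO mg/L, BOD mg/L, turbidity NTU); optima/widths sit at
#: the centre of published preferred ranges for Aphaniops killifish.
DEFAULT_PARAMETERS: dict[str, tuple[float, float, float, float]] = {
    "depth": (25.0, 84.0, 47.525, 18.815),
    "width": (2.5, 11.5, 6.125, 2.495),
    "velocity": (0.01, 0.40, 0.14, 0.10),
    "temperature": (28.0, 31.6, 30.035, 0.745),
    "ph": (7.9, 8.6, 8.285, 0.215),
    "ec": (696.2, 2609.5, 1753.25, 588.79),
    "tds": (351.7, 1331.2, 887.235, 300.335),
    "salinity": (0.33, 1.33, 0.875, 0.305),
    "do": (5.8, 10.4, 7.54, 1.12),
    "bod": (2.84, 4.36, 3.38, 0.55),
    "turbidity": (1.1, 22.0, 8.28, 6.62),
}

#: highest observed single-wadi killifish count in the emulated survey;
#: the expected abundance of a site sitting exactly on every optimum
DEFAULT_ABUNDANCE_SCALE = 17708.0


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth generating model for synthetic datasets.

    parameters maps each variable to (low, high, optimum, width);
    ``gamma`` is the specialist-dominance exponent (higher -> the
    specialist monopolises good habitat faster), ``n_species`` the
    community pool size, ``noise_dispersion`` the lognormal sigma of the
    abundance noise, ``specialist_cap`` the ceiling on the specialist's
    expected share (kept below 1 so diversity stays defined at h = 1).
    """

    parameters: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAMETERS)
    )
    gamma: float = 3.0
    n_species: int = 4
    abundance_scale: float = DEFAULT_ABUNDANCE_SCALE
    noise_dispersion: float = 0.3
    specialist_cap: float = 0.995
    community_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("model needs at least one parameter")
        for name, (lo, hi, mu, sigma) in self.parameters.items():
            if not lo < hi:
                raise ValueError(f"degenerate bounds for parameter {name!r}: "
                                 f"low={lo} must be < high={hi}")
            if sigma <= 0:
                raise ValueError(f"true niche width for {name!r} must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_species < 2:
            raise ValueError("need a species pool of at least 2")
        if self.abundance_scale <= 0:
            raise ValueError("abundance scale must be positive")
        if self.noise_dispersion < 0:
            raise ValueError("noise dispersion cannot be negative")
        if not 1.0 / self.n_species < self.specialist_cap < 1.0:
            raise ValueError("specialist cap must lie in (1/S, 1)")

    def with_seed(self, seed: int) -> "TrueModel":
        return replace(self, seed=seed)


@dataclass
class SyntheticDataset:
    sites: pd.DataFrame
    community: pd.DataFrame
    model: TrueModel

    @property
    def true_suitability(self) -> np.ndarray:
        return self.sites["true_suitability"].to_numpy()


def _true_response(model: TrueModel, values: pd.DataFrame) -> np.ndarray:
    """Product over parameters of the true Gaussian response, in (0, 1]."""
    resp = np.ones(len(values))
    for name, (_, _, mu, sigma) in model.parameters.items():
        z = (values[name].to_numpy() - mu) / sigma
        resp *= np.exp(-0.5 * z**2)
    return resp


def generate_sites(model: TrueModel, n_sites: int = 12) -> SyntheticDataset:
    """Draw a full synthetic survey of ``n_sites`` wadi sites.

    Parameter values are uniform within their bounds; expected abundance is
    ``abundance_scale`` times the product of true Gaussian responses;
    realised abundance multiplies in lognormal noise and is rounded with a
    floor of 1 fish. Substrate composition (sand/silt/clay/gravel) is a
    Dirichlet draw. The community matrix couples species counts to the
    per-site true suitability (see :func:`generate_community`).
    """
    if n_sites < 2:
        raise ValueError("n_sites must be at least 2")
    rng = np.random.default_rng(model.seed)
    data: dict[str, np.ndarray] = {}
    for name, (lo, hi, _, _) in model.parameters.items():
        data[name] = rng.uniform(lo, hi, size=n_sites)
    df = pd.DataFrame(data)
    df.insert(0, "site_id", [f"S{i + 1:02d}" for i in range(n_sites)])

    # sandy-gravel dominated substrates typical of mountain wadis
    frac = rng.dirichlet([4.0, 1.0, 0.5, 3.5], size=n_sites)
    for j, col in enumerate(["sand", "silt", "clay", "gravel"]):
        df[col] = frac[:, j]

    response = _true_response(model, df)
    expected = model.abundance_scale * response
    if model.noise_dispersion > 0:
        expected = expected * rng.lognormal(0.0, model.noise_dispersion, n_sites)
    df["abundance"] = np.maximum(1, np.rint(expected)).astype(int)
    # geometric-mean per-parameter response: the "true HSI" of the site
    df["true_suitability"] = response ** (1.0 / len(model.parameters))

    community = generate_community(
        df["true_suitability"].to_numpy(), model, rng=rng
    )
    community.index = df["site_id"]
    return SyntheticDataset(sites=df, community=community, model=model)


def expected_shares(h: float, model: TrueModel) -> np.ndarray:
    """Closed-form expected community composition at suitability ``h``.

    The habitat specialist's share rises from 1/S at h = 0 to the cap as
    h -> 1 (scaled by h^gamma); the remainder is split evenly among the
    S - 1 generalists. Shannon entropy of this composition is
    non-increasing in h.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("suitability must lie in [0, 1]")
    s = model.n_species
    p1 = 1.0 / s + (model.specialist_cap - 1.0 / s) * h**model.gamma
    rest = (1.0 - p1) / (s - 1)
    return np.concatenate([[p1], np.full(s - 1, rest)])


def generate_community(
    hsi_scores, model: TrueModel, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Species count matrix (sites x species) for given suitability scores.

    Expected shares come from :func:`expected_shares`; with positive noise
    dispersion the generalist shares are jittered symmetrically via a
    Dirichlet draw before multinomial sampling of ``community_size``
    individuals per site.
    """
    h = np.asarray(hsi_scores, dtype=float)
    if h.size == 0:
        raise ValueError("empty suitability score vector")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("suitability scores must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    s = model.n_species
    counts = np.empty((h.size, s), dtype=int)
    for i, hi in enumerate(h):
        shares = expected_shares(hi, model)
        if model.noise_dispersion > 0:
            alpha = 1.0 / model.noise_dispersion
            jitter = rng.dirichlet(np.full(s - 1, alpha))
            shares = np.concatenate([[shares[0]], (1.0 - shares[0]) * jitter])
        counts[i] = rng.multinomial(model.community_size, shares)
    cols = ["specialist"] + [f"generalist_{j}" for j in range(1, s)]
    return pd.DataFrame(counts, columns=cols)


def _smooth_field(rng: np.random.Generator, shape, scale: float = 3.0) -> np.ndarray:
    """Standardised spatially-correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_grids(
    n_rows: int, n_cols: int, pa_fraction: float = 0.056, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(suitability, protected mask, stream density) raster fixtures.

    Suitability is a smooth field pushed through the normal CDF, so values
    cover [0, 1] and straddle the 0.25/0.5/0.75 class bounds. The protected
    mask thresholds an independent smooth field at its (1 - pa_fraction)
    quantile, giving contiguous reserves covering ~pa_fraction of cells.
    Density is a nonnegative field on the km/km^2 magnitude of wadi
    networks (~1e-4 .. 1.2e-3).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not 0.0 < pa_fraction < 1.0:
        raise ValueError(f"pa_fraction must be in (0, 1), got {pa_fraction}")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    suitability = stats.norm.cdf(_smooth_field(rng, shape))
    pa_field = _smooth_field(rng, shape)
    cut = np.quantile(pa_field, 1.0 - pa_fraction)
    protected = pa_field >= cut
    density = 1.2e-3 * stats.norm.cdf(_smooth_field(rng, shape))
    return suitability, protected, density


def generate_prediction_sets(
    n_presence: int, n_background: int, separation: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Presence and background suitability scores in [0, 1].

    Background scores are uniform on [0, 1/(1+separation)] and presence
    scores uniform on [1 - 1/(1+separation), 1]: at separation 0 the two
    sets are exchangeable (AUC 0.5 in expectation); for separation > 1 the
    supports are disjoint and AUC = 1.
    """
    if n_presence < 1 or n_background < 1:
        raise ValueError("need at least one presence and one background point")
    if separation < 0:
        raise ValueError("separation cannot be negative")
    rng = np.random.default_rng(seed)
    span = 1.0 / (1.0 + separation)
    background = rng.uniform(0.0, span, size=n_background)
    presence = 1.0 - rng.uniform(0.0, span, size=n_presence)
    return presence, background
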