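"""Gaussian suitability curves: weighted fitting, evaluation, optimal
ranges, and the substrate (pedotransfer) score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wadihsi.curves import (
    DegenerateNicheError,
    SuitabilityCurve,
    TextureComposition,
    cosby_conductivity,
    gaussian_suitability,
    optimal_range,
    texture_scores,
    weighted_gaussian_fit,
)
from wadihsi.synthetic import TrueModel, generate_sites


class TestWeightedFit:
    def test_unweighted_population_moments(self):
        c = weighted_gaussian_fit([1, 2, 3], [1, 1, 1], "x")
        assert c.mu == pytest.approx(2.0)
        assert c.sigma == pytest.approx(math.sqrt(2.0 / 3.0))
        assert (c.low, c.high) == (1.0, 3.0)

    def test_weighted_moments_hand_computed(self):
        # mu = (1*0 + 3*4)/4 = 3; var = (1*9 + 3*1)/4 = 3
        c = weighted_gaussian_fit([0, 4], [1, 3])
        assert c.mu == pytest.approx(3.0)
        assert c.sigma == pytest.approx(math.sqrt(3.0))

    def test_zero_variance_is_explicit_error(self):
        with pytest.raises(DegenerateNicheError):
            weighted_gaussian_fit([5, 5, 5], [1, 2, 7], "depth")

    @pytest.mark.parametrize(
        "values,weights,err",
        [
            ([1, 2], [0, 0], "zero"),
            ([1], [1], "two"),
            ([1, 2, 3], [1, -1, 1], "nonnegative"),
        ],
    )
    def test_invalid_inputs(self, values, weights, err):
        with pytest.raises(ValueError, match=err):
            weighted_gaussian_fit(values, weights)

    def test_unbiased_variant_inflates_sigma(self):
        v, w = [0.0, 1.0, 2.0, 5.0], [2.0, 1.0, 3.0, 1.0]
        biased = weighted_gaussian_fit(v, w)
        unbiased = weighted_gaussian_fit(v, w, unbiased=True)
        assert unbiased.sigma > biased.sigma
        assert unbiased.mu == pytest.approx(biased.mu)


class TestEvaluation:
    curve = SuitabilityCurve("do", mu=7.54, sigma=1.12, low=5.8, high=10.4)

    @pytest.mark.parametrize(
        "offset,expected",
        [(0.0, 1.0), (1.0, math.exp(-0.5)), (-2.0, math.exp(-2.0))],
    )
    def test_closed_form_at_sigma_offsets(self, offset, expected):
        x = self.curve.mu + offset * self.curve.sigma
        # mu - 2 sigma sits below the observed range, so evaluate raw
        assert gaussian_suitability(x, self.curve, clamp=False) == pytest.approx(
            expected
        )

    def test_clamping_at_observed_bounds(self):
        # beyond the observed range, suitability freezes at the bound value
        at_hi = gaussian_suitability(self.curve.high, self.curve)
        assert gaussian_suitability(99.0, self.curve) == pytest.approx(at_hi)
        assert gaussian_suitability(99.0, self.curve, clamp=False) < at_hi

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gaussian_suitability(float("nan"), self.curve)

    @given(d=st.floats(0.01, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_monotone_decay(self, d):
        c = SuitabilityCurve("x", mu=0.0, sigma=2.0, low=-100.0, high=100.0)
        left, right = c(-d), c(d)
        assert left == pytest.approx(right, rel=1e-12)
        assert 0.0 < right <= 1.0
        assert right < c(d / 2.0)  # strictly decreasing in |x - mu|


class TestOptimalRange:
    def test_do_interval_is_mu_plus_minus_sigma(self):
        c = SuitabilityCurve("do", mu=7.54, sigma=1.12, low=5.8, high=10.4)
        lo, hi = optimal_range(c)
        assert (lo, hi) == pytest.approx((6.42, 8.66))
        assert (lo + hi) / 2.0 == pytest.approx(c.mu)
        assert (hi - lo) / 2.0 == pytest.approx(c.sigma)

    def test_clipped_at_observed_bound(self):
        c = SuitabilityCurve("x", mu=0.0, sigma=1.0, low=-0.5, high=10.0)
        assert optimal_range(c) == pytest.approx((-0.5, 1.0))


class TestCurveRecovery:
    """Noiseless generator -> fit recovers the true niche.

    The envelope is symmetric about the optimum (+- 2.5 widths) so the
    abundance-weighted mean has no truncation bias; the weighted sigma
    shrinks a few percent below the true width because sampling
    concentrates near the optimum.
    """

    def test_recovers_true_optimum_and_width(self):
        mu_t, sig_t = 47.525, 18.815
        half = 2.5 * sig_t
        model = TrueModel(
            parameters={"depth": (mu_t - half, mu_t + half, mu_t, sig_t)},
            noise_dispersion=0.0,
            seed=7,
        )
        ds = generate_sites(model, 200)
        fit = weighted_gaussian_fit(
            ds.sites["depth"].to_numpy(),
            ds.sites["abundance"].to_numpy(dtype=float),
            "depth",
        )
        # brute-force weighted moments with exact (un-rounded) weights
        x = ds.sites["depth"].to_numpy()
        w = np.exp(-0.5 * ((x - mu_t) / sig_t) ** 2)
        mu_bf = np.sum(w * x) / np.sum(w)
        sig_bf = math.sqrt(np.sum(w * (x - mu_bf) ** 2) / np.sum(w))
        assert fit.mu == pytest.approx(mu_bf, rel=1e-3)
        assert fit.sigma == pytest.approx(sig_bf, rel=1e-2)
        assert abs(fit.mu - mu_t) / mu_t < 0.01
        # analytic weighted-moment limit over the symmetric envelope
        xg = np.linspace(mu_t - half, mu_t + half, 200001)
        wg = np.exp(-0.5 * ((xg - mu_t) / sig_t) ** 2)
        mu_lim = np.sum(wg * xg) / np.sum(wg)
        sig_lim = math.sqrt(np.sum(wg * (xg - mu_lim) ** 2) / np.sum(wg))
        assert abs(fit.sigma - sig_lim) / sig_lim < 0.10


class TestTexture:
    def test_normalisation_endpoints(self):
        comps = [
            TextureComposition(0.9, 0.05, 0.05),  # sandy: highest conductivity
            TextureComposition(0.3, 0.3, 0.4),    # clay-rich: lowest
            TextureComposition(0.5, 0.3, 0.2),
        ]
        v = [cosby_conductivity(c) for c in comps]
        scores = texture_scores(comps)
        assert scores[int(np.argmax(v))] == pytest.approx(1.0)
        assert scores[int(np.argmin(v))] == pytest.approx(1e-3)

    def test_identical_compositions_get_identical_scores(self):
        a = TextureComposition(0.6, 0.25, 0.15)
        scores = texture_scores([a, a, TextureComposition(0.2, 0.4, 0.4)])
        assert scores[0] == scores[1]

    def test_single_site_has_no_normalisation_span(self):
        with pytest.raises(ValueError, match="two sites"):
            texture_scores([TextureComposition(0.5, 0.3, 0.2)])

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            TextureComposition(0.9, 0.4, 0.1)  # sums to 1.4
        with pytest.raises(ValueError):
            TextureComposition(-0.1, 0.6, 0.5)

    def test_sandier_substrate_conducts_more(self):
        sandy = cosby_conductivity(TextureComposition(0.8, 0.1, 0.1))
        clayey = cosby_conductivity(TextureComposition(0.1, 0.1, 0.8))
        assert sandy > clayey
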