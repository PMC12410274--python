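"""Gaussian attention-field interaction: closed form, offset variant, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afield.exceptions import DegenerateProfileError, InvalidParameterError
from afield.gaussian_af import (
    AFParams,
    GaussianProfile1D,
    SizeEccRelation,
    af_interaction_analytic,
    af_interaction_offset,
    evaluate_gaussian,
    fit_af_to_differences,
    predict_difference_curve,
)


def product_moments(af: AFParams, sdprf: GaussianProfile1D, n=20001):
    """Independent oracle: center/sd of (gain*A + offset)*S by numeric moments."""
    lo = min(af.center, sdprf.center) - 10 * max(af.sd, sdprf.sd)
    hi = max(af.center, sdprf.center) + 10 * max(af.sd, sdprf.sd)
    x = np.linspace(lo, hi, n)
    p = (af.gain * np.exp(-((x - af.center) ** 2) / (2 * af.sd**2)) + af.offset) * np.exp(
        -((x - sdprf.center) ** 2) / (2 * sdprf.sd**2)
    )
    m = np.trapezoid(p, x)
    c = np.trapezoid(x * p, x) / m
    v = np.trapezoid((x - c) ** 2 * p, x) / m
    return c, np.sqrt(v)


class TestEvaluateGaussian:
    def test_peak_value_at_center(self):
        prof = GaussianProfile1D(0.0, 1.0, 1.0)
        assert evaluate_gaussian(prof, [0.0])[0] == pytest.approx(1.0)

    def test_scalar_evaluation(self):
        prof = GaussianProfile1D(0.0, 2.0, 3.0)
        assert evaluate_gaussian(prof, [2.0])[0] == pytest.approx(3 * np.exp(-0.5), abs=1e-4)

    @given(x=st.floats(0.01, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_about_center(self, x):
        prof = GaussianProfile1D(0.0, 1.0, 1.0)
        left, right = prof(np.array([-x])), prof(np.array([x]))
        assert left[0] == pytest.approx(right[0], rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            GaussianProfile1D(0.0, -1.0)
        prof = GaussianProfile1D(0.0, 1.0)
        with pytest.raises(InvalidParameterError):
            evaluate_gaussian(prof, [])
        with pytest.raises(InvalidParameterError):
            evaluate_gaussian(prof, [1.0, 0.5])


class TestAnalyticInteraction:
    def test_equal_sds_give_midpoint(self):
        r = af_interaction_analytic(AFParams(0, 1), GaussianProfile1D(2, 1))
        assert r.center == pytest.approx(1.0)
        assert r.sd == pytest.approx(np.sqrt(0.5))

    def test_flat_field_leaves_prf_unchanged(self):
        r = af_interaction_analytic(AFParams(0, 1e6), GaussianProfile1D(3, 2))
        assert r.center == pytest.approx(3.0, abs=1e-6)
        assert r.sd == pytest.approx(2.0, abs=1e-6)

    def test_narrow_field_example_matches_numeric_oracle(self):
        af, s = AFParams(0, 0.5), GaussianProfile1D(4, 2)
        r = af_interaction_analytic(af, s)
        assert r.center == pytest.approx(1 / 4.25, abs=1e-4)
        assert r.sd == pytest.approx(0.4851, abs=1e-4)
        c, sd = product_moments(af, s)
        assert r.center == pytest.approx(c, abs=1e-4)
        assert r.sd == pytest.approx(sd, abs=1e-4)

    def test_rejects_offset_field(self):
        with pytest.raises(InvalidParameterError):
            af_interaction_analytic(AFParams(0, 1, 1, 0.5), GaussianProfile1D(1, 1))

    @given(
        sd1=st.floats(0.1, 6.0),
        sd2=st.floats(0.1, 6.0),
        mu2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_betweenness_and_shrinkage(self, sd1, sd2, mu2):
        """The attracted center lies strictly between the field and pRF centers,
        and the attracted sd is below both inputs (product of Gaussians)."""
        r = af_interaction_analytic(AFParams(0, sd1), GaussianProfile1D(mu2, sd2))
        assert 0 < r.center < mu2
        assert r.sd < min(sd1, sd2)

    @given(sd2=st.floats(0.2, 6.0), mu2=st.floats(0.5, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_attraction_grows_as_field_narrows(self, sd2, mu2):
        shifts = [
            mu2 - af_interaction_analytic(AFParams(0, s1), GaussianProfile1D(mu2, sd2)).center
            for s1 in (2.0, 1.0, 0.5)
        ]
        assert shifts[0] < shifts[1] < shifts[2]


class TestOffsetInteraction:
    def test_no_offset_reduces_to_closed_form(self):
        af, s = AFParams(0, 1, 1, 0), GaussianProfile1D(2, 1)
        num = af_interaction_offset(af, s)
        ana = af_interaction_analytic(af, s)
        assert num.center == pytest.approx(ana.center, abs=1e-3)
        assert num.sd == pytest.approx(ana.sd, abs=1e-3)

    def test_pure_offset_returns_prf(self):
        r = af_interaction_offset(AFParams(0, 1, 0, 1), GaussianProfile1D(2, 1))
        assert r.center == pytest.approx(2.0, abs=1e-6)
        assert r.sd == pytest.approx(1.0, abs=1e-6)

    def test_negligible_attraction_far_from_field(self):
        # five pRF sds away, the field term is ~0 relative to the offset
        r = af_interaction_offset(AFParams(0, 1, 1, 1), GaussianProfile1D(5, 0.5))
        assert abs(r.center - 5.0) < 0.05 * 0.5

    def test_degenerate_field_raises(self):
        with pytest.raises(DegenerateProfileError):
            af_interaction_offset(AFParams(0, 1, 0, 0), GaussianProfile1D(1, 1))

    def test_matches_independent_least_squares_oracle(self, rng):
        """Cross-check against an independent scipy Gaussian refit of the
        same (gain*A + offset)*S profile on a fine fixed grid."""
        from scipy.optimize import least_squares as scipy_lsq

        for _ in range(20):
            af = AFParams(0, rng.uniform(0.3, 4), rng.uniform(0.5, 2), rng.uniform(0.05, 1))
            s = GaussianProfile1D(rng.uniform(0.2, 3), rng.uniform(0.3, 3))
            r = af_interaction_offset(af, s)
            x = np.linspace(min(0, s.center) - 10 * s.sd, max(0, s.center) + 10 * s.sd, 6000)
            prof = (af.gain * np.exp(-(x**2) / (2 * af.sd**2)) + af.offset) * np.exp(
                -((x - s.center) ** 2) / (2 * s.sd**2)
            )
            m = (x * prof).sum() / prof.sum()
            v = ((x - m) ** 2 * prof).sum() / prof.sum()
            sol = scipy_lsq(
                lambda p: p[2] * np.exp(-((x - p[0]) ** 2) / (2 * p[1] ** 2)) - prof,
                [m, np.sqrt(v), prof.max()],
            )
            assert r.center == pytest.approx(sol.x[0], abs=2e-3)
            assert r.sd == pytest.approx(abs(sol.x[1]), abs=2e-3)


class TestDifferenceCurve:
    def test_identical_fields_give_zero(self):
        af = AFParams(0, 1.2, 1, 0.2)
        rel = SizeEccRelation(0.2, 0.5, "V1")
        d = predict_difference_curve(af, af, rel, np.linspace(0.2, 5, 8))
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_hand_computed_plain_model_example(self):
        rel = SizeEccRelation(0.0, 1.0, "flat")
        d = predict_difference_curve(AFParams(0, 0.5), AFParams(0, 5.0), rel, [2.0])
        assert d[0] == pytest.approx(2 * 25 / 26 - 2 * 0.25 / 1.25, abs=1e-9)

    def test_positive_everywhere_when_focused_narrower(self):
        rel = SizeEccRelation(0.15, 0.3, "V1")
        d = predict_difference_curve(AFParams(0, 0.5), AFParams(0, 3.0), rel, np.linspace(0.1, 5, 20))
        assert np.all(d > 0)

    def test_requires_centered_fields(self):
        rel = SizeEccRelation(0.15, 0.3, "V1")
        with pytest.raises(InvalidParameterError):
            predict_difference_curve(AFParams(1.0, 0.5), AFParams(0, 3.0), rel, [1.0])


class TestAFFit:
    RELS = {
        "V1": SizeEccRelation(0.12, 0.25, "V1"),
        "hV4": SizeEccRelation(0.35, 0.55, "hV4"),
        "IPS": SizeEccRelation(0.75, 1.00, "IPS"),
    }
    ECC = np.array([0.2, 0.6, 1.2, 2.2, 3.5, 4.6])

    def _observed(self, af_f, af_d, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return {
            roi: (self.ECC, predict_difference_curve(af_f, af_d, rel, self.ECC)
                  + rng.normal(0, noise_sd, self.ECC.size))
            for roi, rel in self.RELS.items()
        }

    def test_plain_variant_recovers_noise_free_parameters(self):
        truth_f, truth_d = AFParams(0, 0.7), AFParams(0, 3.0)
        fit = fit_af_to_differences(self._observed(truth_f, truth_d), self.RELS, variant="af")
        assert fit.focused.sd == pytest.approx(0.7, rel=0.05)
        assert fit.distributed.sd == pytest.approx(3.0, rel=0.05)
        assert fit.loss < 1e-6

    def test_plain_variant_recovers_under_noise(self):
        truth_f, truth_d = AFParams(0, 0.7), AFParams(0, 3.0)
        fit = fit_af_to_differences(
            self._observed(truth_f, truth_d, noise_sd=0.05, seed=7), self.RELS, variant="af"
        )
        assert fit.focused.sd == pytest.approx(0.7, rel=0.20)
        assert fit.distributed.sd == pytest.approx(3.0, rel=0.20)

    def test_zero_curves_fit_with_zero_loss(self):
        observed = {roi: (self.ECC, np.zeros_like(self.ECC)) for roi in self.RELS}
        fit = fit_af_to_differences(observed, self.RELS, variant="af")
        pred = predict_difference_curve(fit.focused, fit.distributed, self.RELS["V1"], self.ECC)
        assert np.allclose(pred, 0.0, atol=1e-4)
        assert fit.loss < 1e-6

    def test_offset_variant_nests_plain_variant(self):
        """The plain model is the offset model at (gain 1, offset 0), so its
        best loss can never undercut the richer model's on the same data."""
        small = {k: self.RELS[k] for k in ("V1", "IPS")}
        ecc = np.array([0.3, 1.0, 2.5, 4.0])
        observed = {
            roi: (ecc, predict_difference_curve(AFParams(0, 0.5, 1, 0.2),
                                                AFParams(0, 4.0, 1, 0.2), rel, ecc))
            for roi, rel in small.items()
        }
        plain = fit_af_to_differences(observed, small, variant="af")
        rich = fit_af_to_differences(observed, small, variant="af_plus", n_starts=3)
        assert plain.loss >= rich.loss - 1e-12

    def test_result_serializes(self):
        import json

        fit = fit_af_to_differences(
            {"V1": (self.ECC, np.zeros_like(self.ECC))},
            {"V1": self.RELS["V1"]},
            variant="af",
        )
        json.dumps(fit.to_dict())
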