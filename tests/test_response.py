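import numpy as np
import pandas as pd
import pytest

import ethopersist as ep
from ethopersist.response import ResponseCurve, mean_response
from ethopersist.simulate import make_additivity_scenario, make_decay_curve

from _oracles import fraction_curve, sliding_mean, windowed_decay_halflife
from conftest import random_ethogram


def _cohort_with_probe_fractions(counts, n_frames=300, fps=30.0, onset_s=5.0):
    eth = []
    w0 = int(onset_s * fps)
    for i, k in enumerate(counts):
        flags = np.zeros((n_frames, 4), dtype=bool)
        flags[w0 : w0 + k, 2] = True
        eth.append(ep.Ethogram(f"m{i}", flags, fps=fps))
    stim = ep.StimulusSeries(channels={"light": [ep.Pulse(onset_s, onset_s + 1)]})
    return ep.align_to_stimulus(ep.CohortDataset(eth, stim), "light", 0)


class TestFractionExhibiting:
    def test_extremes(self):
        all_on = _cohort_with_probe_fractions([150] * 5)
        curve = ep.fraction_exhibiting(all_on, "probe", bin_s=1.0)
        post = curve.values[(curve.times_s >= 0) & (curve.times_s < 5)]
        assert (post == 1.0).all()
        none_on = _cohort_with_probe_fractions([0] * 5)
        assert ep.fraction_exhibiting(none_on, "probe", bin_s=1.0).values.max() == 0.0

    def test_three_of_ten(self):
        cohort = _cohort_with_probe_fractions([30] * 3 + [0] * 7)
        curve = ep.fraction_exhibiting(cohort, "probe", bin_s=1.0)
        assert curve.values[curve.times_s == 0.0][0] == pytest.approx(0.3)
        assert curve.n == 10

    def test_matches_counting_oracle(self, rng):
        eth = [random_ethogram(rng, n_frames=300, animal_id=f"m{i}", with_track=False)
               for i in range(7)]
        cohort = ep.CohortDataset(eth, ep.StimulusSeries())
        for bin_s in (1 / 30.0, 0.5, 1.0):
            curve = ep.fraction_exhibiting(cohort, "walk", bin_s=bin_s)
            stack = [e.flag("walk").tolist() for e in eth]
            np.testing.assert_allclose(
                curve.values, fraction_curve(stack, int(round(bin_s * 30)))
            )

    def test_per_animal_time_variant(self):
        cohort = _cohort_with_probe_fractions([30, 0])
        curve = ep.fraction_exhibiting(cohort, "probe", bin_s=1.0, per_animal_time=True)
        assert curve.values[curve.times_s == 0.0][0] == pytest.approx(0.5)

    def test_empty_cohort_errors(self):
        empty = ep.CohortDataset([], ep.StimulusSeries(),
                                 pd.DataFrame(columns=["animal_id", "sex", "condition", "engorged"]))
        with pytest.raises(ValueError):
            ep.fraction_exhibiting(empty, "probe")


class TestSlidingWindow:
    def test_constant_curve_unchanged(self):
        c = ResponseCurve(np.arange(100.0), np.full(100, 0.4))
        w = ep.sliding_window_response(c, 15.0)
        np.testing.assert_allclose(w.values, 0.4)

    def test_step_becomes_ramp(self):
        t = np.arange(0.0, 60.0)
        v = np.where(t < 30, 1.0, 0.0)
        w = ep.sliding_window_response(ResponseCurve(t, v), 15.0)
        assert np.all(w.values[w.times_s <= 15] == 1.0)
        ramp = w.values[(w.times_s > 15) & (w.times_s < 30)]
        assert np.all(np.diff(ramp) < 0)  # linear decrease
        assert w.values[w.times_s == 30.0][0] == pytest.approx(0.0)

    def test_matches_cumsum_oracle(self, rng):
        t = np.arange(-20.0, 120.0)
        v = rng.random(t.size)
        w = ep.sliding_window_response(ResponseCurve(t, v), 15.0)
        post = v[t >= 0]
        np.testing.assert_allclose(w.values, sliding_mean(post.tolist(), 15))

    def test_window_longer_than_record_errors(self):
        c = ResponseCurve(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            ep.sliding_window_response(c, 15.0)

    def test_commutes_with_truncation(self, rng):
        t = np.arange(0.0, 200.0)
        v = rng.random(t.size)
        full = ep.sliding_window_response(ResponseCurve(t, v), 15.0)
        trunc = ep.sliding_window_response(ResponseCurve(t, v).truncate(0, 100.0), 15.0)
        m = full.times_s < trunc.times_s[-1] + 0.5
        np.testing.assert_allclose(full.values[m], trunc.values)


class TestHalfLife:
    @pytest.mark.parametrize("tau", [30.0, 60.0, 234.0])
    def test_analytic_decay_recovery(self, tau):
        """On noiseless decay curves the windowed half-life statistic
        matches a numeric-integration oracle within one sample."""
        curve = make_decay_curve(0.0, 0.6, tau, duration_s=1500.0, bin_s=0.5)
        res = ep.half_life(curve)
        expected_s = windowed_decay_halflife(0.0, 0.6, tau)
        assert res.censored is None
        assert res.t_half_min * 60 == pytest.approx(expected_s, abs=0.5 + 1e-9)
        assert res.t_half_min * 60 == pytest.approx(tau, abs=15.0)

    def test_flat_curve_censored_no_response(self):
        c = ResponseCurve(np.arange(-120.0, 300.0), np.full(420, 0.2))
        res = ep.half_life(c)
        assert res.censored == "no response"
        assert res.t_half_min is None

    def test_slow_decay_right_censored(self):
        curve = make_decay_curve(0.0, 0.5, 3600.0, duration_s=120.0, bin_s=0.5)
        res = ep.half_life(curve)
        assert res.censored == "right-censored"

    def test_affine_invariance_of_t_half(self):
        """Rescaling the response axis rescales baseline and max together
        and leaves the half-life unchanged."""
        c1 = make_decay_curve(0.1, 0.7, 90.0, duration_s=900.0)
        c2 = ResponseCurve(c1.times_s, 0.25 + 0.5 * c1.values, c1.behavior, c1.n)
        r1, r2 = ep.half_life(c1), ep.half_life(c2)
        assert r1.t_half_min == pytest.approx(r2.t_half_min)
        assert r2.baseline == pytest.approx(0.25 + 0.5 * r1.baseline)

    def test_baseline_is_prestimulus_mean(self):
        curve = make_decay_curve(0.2, 0.8, 60.0)
        assert ep.half_life(curve).baseline == pytest.approx(0.2)


class TestAdditivity:
    def test_predicted_additive_scalars_and_curves(self, rng):
        assert ep.predicted_additive(0.2, 0.3) == pytest.approx(0.5)
        t = np.arange(10.0)
        a = ResponseCurve(t, rng.random(10) / 2)
        b = ResponseCurve(t, rng.random(10) / 2)
        np.testing.assert_allclose(ep.predicted_additive(a, b), a.values + b.values)
        zero = ResponseCurve(t, np.zeros(10))
        np.testing.assert_allclose(ep.predicted_additive(zero, b), b.values)
        with pytest.raises(ValueError):
            ep.predicted_additive(a, ResponseCurve(np.arange(5.0), np.zeros(5)))

    @pytest.mark.parametrize(
        "combined, predicted, expected",
        [(0.5, 0.5, 100.0), (0.0, 0.5, 0.0), (0.75, 0.5, 150.0)],
    )
    def test_percent_additivity_scale(self, combined, predicted, expected):
        assert ep.percent_additivity(combined, predicted) == pytest.approx(expected)

    def test_nonpositive_predicted_rejected(self):
        with pytest.raises(ValueError):
            ep.percent_additivity(0.3, 0.0)

    @pytest.mark.parametrize(
        "mode, expected, tol",
        [("additive", 100.0, 0.0), ("suppressive", 50.0, 0.0), ("enhanced", 150.0, 0.0)],
    )
    def test_constructed_scenarios(self, mode, expected, tol):
        cohort = make_additivity_scenario(mode)
        aligned = ep.align_to_stimulus(cohort, "light", 0)
        res = ep.additivity_from_cohort(aligned)
        assert res.median == pytest.approx(expected, abs=tol + 1e-9)

    def test_zero_response_animal_is_zero_percent(self):
        cohort = make_additivity_scenario("additive")
        aligned = ep.align_to_stimulus(cohort, "light", 0)
        combined = mean_response(
            aligned.subset(aligned.meta["condition"] == "A+B"), "probe", 15.0
        )
        combined[0] = 0.0  # an animal that never responded
        res = ep.percent_additivity(combined, 0.2 + 0.3)
        assert res[0] == 0.0


class TestSmoothing:
    def test_constant_unchanged(self):
        s = np.full(40, 0.7)
        np.testing.assert_allclose(ep.smooth_additivity(s), s)

    def test_unit_spike_spreads_to_ninth(self):
        s = np.zeros(41)
        s[20] = 9.0
        sm = ep.smooth_additivity(s)
        assert sm[20] == pytest.approx(1.0)
        assert sm[16] == pytest.approx(1.0) and sm[24] == pytest.approx(1.0)
        assert sm[15] == 0.0

    def test_matches_convolution_oracle(self, rng):
        s = rng.random(60)
        sm = ep.smooth_additivity(s)
        for i in range(60):
            lo, hi = max(0, i - 4), min(60, i + 5)
            assert sm[i] == pytest.approx(s[lo:hi].mean())


def test_time_resolved_additivity_series():
    """A cohort that is additive bin by bin (combined time fraction =
    sum of the single-stimulus fractions in every bin) has a flat
    time-resolved additivity series at 100%."""
    fps, onset_s, n_frames = 30.0, 10.0, 900
    w0 = int(onset_s * fps)

    def condition(n_probing, cond, n_total=20):
        out = []
        for i in range(n_total):
            flags = np.zeros((n_frames, 4), dtype=bool)
            if i < n_probing:
                flags[w0:, 2] = True
            out.append(ep.Ethogram(f"{cond}{i}", flags, fps=fps))
        return out

    eth = condition(4, "A") + condition(6, "B") + condition(10, "C")
    meta = pd.DataFrame({
        "animal_id": [e.animal_id for e in eth],
        "sex": "F",
        "condition": ["A"] * 20 + ["B"] * 20 + ["A+B"] * 20,
        "engorged": pd.array([pd.NA] * 60),
    })
    stim = ep.StimulusSeries(channels={"light": [ep.Pulse(onset_s, onset_s + 5)]})
    cohort = ep.align_to_stimulus(ep.CohortDataset(eth, stim, meta), "light", 0)
    res = ep.additivity_from_cohort(cohort, time_resolved=True)
    assert res.series is not None
    sel = res.series_times_s >= 0
    np.testing.assert_allclose(res.series[sel], 100.0)
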