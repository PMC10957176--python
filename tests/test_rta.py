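"""Run-off kinetics: summarization, decay fitting, stalled fractions, rates."""

import math

import numpy as np
import pandas as pd
import pytest

from riboaccount import rta
from riboaccount import synthetic as syn

from conftest import rta_spec


def make_events(sample_by_time, background_by_time, condition="c"):
    rows = []
    cid = 0
    for t, values in sample_by_time.items():
        for v in values:
            rows.append((cid, condition, "HAR", t, v))
            cid += 1
    for t, values in background_by_time.items():
        for v in values:
            rows.append((cid, condition, "background", t, v))
            cid += 1
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "treatment", "chase_time_s", "signal"]
    )


class TestSummarizeRpm:
    def test_median_background_subtraction(self):
        events = make_events({0.0: [50, 55, 60]}, {0.0: [4, 5, 6]})
        points = rta.summarize_rpm(events)
        assert points["mfi"].iloc[0] == 50.0

    def test_floor_at_zero(self):
        events = make_events({0.0: [3.0]}, {0.0: [5.0]})
        assert rta.summarize_rpm(events)["mfi"].iloc[0] == 0.0
        assert rta.summarize_rpm(events, floor_at_zero=False)["mfi"].iloc[0] == -2.0

    def test_missing_background_group_raises(self):
        events = make_events({0.0: [50.0]}, {})
        with pytest.raises(ValueError, match="background"):
            rta.summarize_rpm(events)

    def test_lognormal_summary_tracks_generating_curve(self, rta_events):
        events, _, spec = rta_events
        points = rta.summarize_rpm(events)
        for _, row in points.iterrows():
            expected = float(spec.deterministic_signal(row.chase_time_s)) - spec.background_mean
            assert row.mfi == pytest.approx(expected, rel=0.08)


class TestNormalizeToMax:
    def test_scales_max_to_100(self):
        points = pd.DataFrame({"chase_time_s": [0, 1, 2], "mfi": [50.0, 25.0, 10.0]})
        out = rta.normalize_to_max(points)
        assert list(out["mfi"]) == [100.0, 50.0, 20.0]

    def test_idempotent_and_single_point(self):
        single = pd.DataFrame({"chase_time_s": [0], "mfi": [7.0]})
        once = rta.normalize_to_max(single)
        assert once["mfi"].iloc[0] == 100.0
        pd.testing.assert_frame_equal(rta.normalize_to_max(once), once)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rta.normalize_to_max(pd.DataFrame({"chase_time_s": [0], "mfi": [0.0]}))


def exact_points(t_half, span, plateau, times=(0, 30, 60, 120, 300)):
    t = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {"chase_time_s": t, "mfi": span * np.exp(-math.log(2) / t_half * t) + plateau}
    )


class TestFitOnePhaseDecay:
    def test_noiseless_no_plateau(self):
        fit = rta.fit_one_phase_decay(exact_points(70, 100, 0))
        assert fit.t_half_s == pytest.approx(70, rel=1e-6)
        assert fit.plateau == pytest.approx(0, abs=1e-4 * fit.s0)

    def test_noiseless_with_plateau(self):
        fit = rta.fit_one_phase_decay(exact_points(70, 80, 20))
        assert fit.t_half_s == pytest.approx(70, rel=1e-6)
        assert fit.plateau == pytest.approx(20, rel=1e-6)
        assert fit.s0 == pytest.approx(100, rel=1e-6)

    def test_t_half_lambda_identity(self):
        fit = rta.fit_one_phase_decay(exact_points(55, 100, 10))
        assert fit.t_half_s == pytest.approx(math.log(2) / fit.lambda_per_s)

    def test_scale_equivariance(self):
        pts = exact_points(70, 80, 20)
        fit1 = rta.fit_one_phase_decay(pts)
        pts_scaled = pts.assign(mfi=pts.mfi * 7.5)
        fit2 = rta.fit_one_phase_decay(pts_scaled)
        assert fit2.t_half_s == pytest.approx(fit1.t_half_s, rel=1e-6)
        assert fit2.span == pytest.approx(7.5 * fit1.span, rel=1e-6)
        assert fit2.plateau == pytest.approx(7.5 * fit1.plateau, rel=1e-6)

    def test_insufficient_points(self):
        with pytest.raises(rta.FitError, match="distinct chase times"):
            rta.fit_one_phase_decay(exact_points(70, 100, 0, times=(0, 30, 60)))
        # three points suffice with the plateau fixed
        fit = rta.fit_one_phase_decay(
            exact_points(70, 100, 0, times=(0, 30, 60)), fix_plateau=0.0
        )
        assert fit.t_half_s == pytest.approx(70, rel=1e-6)

    def test_flat_signal_unidentifiable(self):
        pts = pd.DataFrame({"chase_time_s": [0, 30, 60, 120], "mfi": [50.0] * 4})
        with pytest.raises(rta.FitError, match="flat"):
            rta.fit_one_phase_decay(pts)

    def test_noisy_recovery_within_ten_percent(self, rta_events):
        events, truth, _ = rta_events
        fit = rta.fit_one_phase_decay(rta.summarize_rpm(events))
        assert fit.t_half_s == pytest.approx(truth.params["t_half_s"], rel=0.10)

    def test_dropping_t0_barely_moves_noiseless_fit(self):
        pts = exact_points(70, 80, 20, times=(0, 30, 60, 120, 300, 600))
        fit_all = rta.fit_one_phase_decay(pts)
        fit_trunc = rta.fit_one_phase_decay(pts.iloc[1:])
        assert fit_trunc.t_half_s == pytest.approx(fit_all.t_half_s, rel=1e-6)


class TestStalledFraction:
    @pytest.mark.parametrize(
        "span,plateau,expected", [(100, 0, 0.0), (0, 50, 1.0), (80, 20, 0.20)]
    )
    def test_ratio(self, span, plateau, expected):
        fit = rta.DecayFit(span=span, plateau=plateau, lambda_per_s=0.01, residual_sse=0, n_points=5)
        assert rta.stalled_fraction(fit) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        fit = rta.DecayFit(span=0, plateau=0, lambda_per_s=0.01, residual_sse=0, n_points=5)
        with pytest.raises(ValueError):
            rta.stalled_fraction(fit)

    @pytest.mark.parametrize("s", [0.0, 0.5, 1.0])
    def test_zero_noise_recovery(self, s):
        spec = rta_spec(cv=0.0, stalled_frac=s, background_mean=0.0, cells_per_timepoint=5)
        events, _ = syn.gen_rta_events(spec)
        points = rta.summarize_rpm(events)
        assert rta.estimate_stalled_fraction(points) == pytest.approx(s, abs=0.03)


class TestElongationRate:
    def test_reference_identity(self):
        est = rta.elongation_rate_from_half_life(70)
        assert est.rate_aa_per_s == pytest.approx(6.0)
        assert est.percent_change == pytest.approx(0.0)

    def test_faster_in_vivo_half_life(self):
        est = rta.elongation_rate_from_half_life(55)
        assert round(est.rate_aa_per_s, 1) == 7.6
        assert round(est.percent_change) == 27

    def test_halving_half_life_doubles_rate(self):
        assert rta.elongation_rate_from_half_life(35).rate_aa_per_s == pytest.approx(12.0)

    def test_rate_times_half_life_invariant(self):
        for th in (10, 55, 70, 200):
            est = rta.elongation_rate_from_half_life(th)
            assert est.rate_aa_per_s * th == pytest.approx(420.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            rta.elongation_rate_from_half_life(0)


@pytest.mark.parametrize(
    "rate,duration,expected", [(6, 900, 5400), (0, 900, 0), (7.6, 900, 6840)]
)
def test_max_orf_cleared(rate, duration, expected):
    assert rta.max_orf_cleared(rate, duration) == pytest.approx(expected)


def test_bootstrap_ci_brackets_point_estimate(rta_events):
    events, truth, _ = rta_events
    fit, draws = rta.bootstrap_t_half_from_events(events, n_boot=100, seed=42)
    lo, hi = fit.ci_t_half
    assert lo < fit.t_half_s < hi
    assert draws.size >= 95
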