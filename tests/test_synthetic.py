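import json
import math

import numpy as np
import pytest
from scipy import integrate, stats

from blebkin import (
    BirthIntensity,
    SimConfig,
    StudyDesign,
    Trajectory,
    ValidationError,
    analytic_mean_blebs,
    calibrate_birth_intensity,
    estimate_detachment_rate,
    generate_study,
    read_frequency_obs,
    read_tracks,
    sample_cross_section,
    sample_timelapse,
    simulate_population,
    simulate_timelapse_cohorts,
)
from blebkin.synthetic import mean_standing_blebs

RATE = 1.0 / 772.0  # per hour
LAM_DAY = RATE * 24.0


def make_config(beta, n_nuclei=1000, rate=RATE, seed=0, **kw):
    return SimConfig(
        n_nuclei=n_nuclei, birth_intensity=beta, detachment_rate=rate, seed=seed, **kw
    )


class TestBirthIntensity:
    def test_constant_and_linear_values(self):
        assert BirthIntensity(kind="constant", value=0.3)(5.0) == 0.3
        lin = BirthIntensity(kind="linear", intercept=0.1, slope=0.02)
        assert lin(5.0) == pytest.approx(0.2)

    def test_negative_spec_rejected(self):
        with pytest.raises(ValidationError):
            BirthIntensity(kind="constant", value=-0.1)
        beta = BirthIntensity(kind="linear", intercept=-0.5, slope=0.01)
        with pytest.raises(ValidationError, match="negative"):
            make_config(beta, horizon=14.0)

    def test_unbounded_calibration_rejected(self):
        target = Trajectory(kind="power_law", t0=1.0, horizon=14.0, b_max=0.35, p=0.5)
        with pytest.raises(ValidationError, match="p >= 1"):
            BirthIntensity(kind="calibrated", target=target, rate_per_hour=RATE)

    def test_sup_bounds_the_intensity(self, calibrated_intensity):
        s = calibrated_intensity.sup(14.0)
        grid = np.linspace(0.0, 14.0, 4001)
        assert all(calibrated_intensity(t) <= s + 1e-9 for t in grid)


class TestAnalyticMean:
    def test_constant_intensity_mmc_infinity_form(self):
        beta = BirthIntensity(kind="constant", value=0.2)
        cfg = make_config(beta, rate=RATE)
        t = 10.0
        expected = (0.2 / LAM_DAY) * (1 - math.exp(-LAM_DAY * t))
        assert analytic_mean_blebs(cfg, t) == pytest.approx(expected, rel=1e-12)

    def test_zero_rate_limit_is_cumulative_births(self):
        beta = BirthIntensity(kind="constant", value=0.2)
        cfg = make_config(beta, rate=0.0)
        assert analytic_mean_blebs(cfg, 10.0) == pytest.approx(2.0)

    def test_linear_closed_form_matches_quadrature(self):
        beta = BirthIntensity(kind="linear", intercept=0.05, slope=0.01)
        closed = mean_standing_blebs(beta, RATE, 12.0)
        quad, _ = integrate.quad(
            lambda s: beta(s) * math.exp(-LAM_DAY * (12.0 - s)), 0.0, 12.0, epsabs=1e-12
        )
        assert closed == pytest.approx(quad, rel=1e-9)

    def test_calibration_identity_at_horizon(self, calibrated_intensity):
        cfg = make_config(calibrated_intensity)
        assert analytic_mean_blebs(cfg, 14.0) == pytest.approx(0.35, abs=1e-8)


class TestCalibration:
    def test_zero_target_gives_zero_intensity(self):
        target = Trajectory(kind="piecewise_linear", knots=((1.0, 0.0), (14.0, 0.0)))
        beta = calibrate_birth_intensity(target, RATE)
        assert all(beta(t) == 0.0 for t in np.linspace(0, 14, 29))

    def test_zero_rate_linear_target_gives_constant_slope(self):
        target = Trajectory(kind="piecewise_linear", knots=((1.0, 0.0), (14.0, 0.26)))
        beta = calibrate_birth_intensity(target, 0.0)
        assert beta(5.0) == pytest.approx(0.02)
        assert beta(12.0) == pytest.approx(0.02)

    def test_round_trip_reproduces_target(self, power_trajectory, calibrated_intensity):
        cfg = make_config(calibrated_intensity)
        for t in (4.0, 9.0, 14.0):
            assert analytic_mean_blebs(cfg, t) == pytest.approx(
                power_trajectory(t), abs=1e-6
            )

    def test_decreasing_target_warns_about_clipping(self):
        target = Trajectory(kind="piecewise_linear", knots=((1.0, 0.3), (5.0, 0.0)))
        with pytest.warns(UserWarning, match="clipped"):
            calibrate_birth_intensity(target, RATE)


class TestSimulatePopulation:
    def test_zero_intensity_yields_no_blebs(self):
        pop = simulate_population(make_config(BirthIntensity(kind="constant", value=0.0)))
        assert all(len(n.blebs) == 0 for n in pop)

    def test_identical_seed_identical_population(self, calibrated_intensity):
        cfg = make_config(calibrated_intensity, n_nuclei=50, seed=9)
        assert simulate_population(cfg) == simulate_population(cfg)

    def test_nucleus_streams_stable_under_population_growth(self, calibrated_intensity):
        small = simulate_population(make_config(calibrated_intensity, n_nuclei=20, seed=5))
        large = simulate_population(make_config(calibrated_intensity, n_nuclei=60, seed=5))
        assert small == large[:20]

    def test_mean_standing_count_matches_mmc_infinity_theory(self):
        """Constant-birth populations behave as M/M/inf queues: the mean
        standing bleb count follows (beta/lam)(1 - exp(-lam t))."""
        beta = BirthIntensity(kind="constant", value=0.25)
        cfg = make_config(beta, n_nuclei=4000, rate=0.005, seed=13)
        pop = simulate_population(cfg)
        for t in (3.0, 10.0):
            counts = np.array([n.standing_blebs(t) for n in pop])
            expected = analytic_mean_blebs(cfg, t)
            se = counts.std(ddof=1) / math.sqrt(len(counts))
            assert abs(counts.mean() - expected) < 3 * se + 1e-12

    def test_detachment_delays_are_exponential(self):
        """Kolmogorov-Smirnov check of birth-to-detachment delays against
        the exponential law at the configured rate."""
        beta = BirthIntensity(kind="constant", value=0.5)
        cfg = make_config(beta, n_nuclei=1200, rate=0.01, seed=21, horizon=14.0)
        pop = simulate_population(cfg)
        delays = np.array(
            [b.detach_time - b.birth_time for n in pop for b in n.blebs]
        )
        assert len(delays) >= 5000
        lam_day = 0.01 * 24.0
        res = stats.kstest(delays, "expon", args=(0.0, 1.0 / lam_day))
        assert res.pvalue > 0.01

    def test_rare_detachment_before_horizon(self, calibrated_intensity):
        """Only a small minority of born blebs detach by AD14: the
        analytic fraction is lam*int E[B] dt / int beta dt = 0.0472 /
        0.397 ~ 11.9% under the calibrated trajectory."""
        pop = simulate_population(make_config(calibrated_intensity, n_nuclei=3000, seed=2))
        blebs = [b for n in pop for b in n.blebs]
        detached = [b for b in blebs if b.detach_time is not None and b.detach_time <= 14.0]
        frac = len(detached) / len(blebs)
        expected = 0.04715 / (0.35 + 0.04715)
        assert frac == pytest.approx(expected, abs=0.03)
        assert frac < 0.15


class TestCrossSection:
    def test_zero_population_frequency_zero(self):
        pop = simulate_population(make_config(BirthIntensity(kind="constant", value=0.0)))
        obs = sample_cross_section(pop, 14.0, 500, seed=0)
        assert obs.frequency == 0.0

    def test_oversampling_rejected(self, calibrated_intensity):
        pop = simulate_population(make_config(calibrated_intensity, n_nuclei=10))
        with pytest.raises(ValidationError, match="population"):
            sample_cross_section(pop, 14.0, 11, seed=0)

    def test_mean_frequency_tracks_target_midlife(self, calibrated_intensity):
        pop = simulate_population(make_config(calibrated_intensity, n_nuclei=10000, seed=3))
        obs = sample_cross_section(pop, 7.5, 10000, seed=4)
        # target trajectory value at AD7.5 is 0.0875 blebs/nucleus
        assert obs.frequency == pytest.approx(8.75, abs=1.0)


class TestTimelapse:
    def test_zero_rate_all_censored(self):
        beta = BirthIntensity(kind="constant", value=0.5)
        pop = simulate_population(make_config(beta, n_nuclei=500, rate=0.0))
        tracks = sample_timelapse(pop, 10.0, 50, 8.0, seed=1)
        assert len(tracks) == 50
        assert not any(t.detached for t in tracks)

    def test_event_times_are_frame_multiples(self):
        beta = BirthIntensity(kind="constant", value=1.0)
        pop = simulate_population(make_config(beta, n_nuclei=2000, rate=0.05, seed=8))
        tracks = sample_timelapse(pop, 7.0, 300, 8.0, frame_interval=0.5, seed=2)
        events = [t.event_time for t in tracks if t.detached]
        assert events, "expected some detachments at this rate"
        for e in events:
            assert e / 0.5 == pytest.approx(round(e / 0.5))

    def test_insufficient_alive_blebs_rejected(self):
        pop = simulate_population(make_config(BirthIntensity(kind="constant", value=0.0)))
        with pytest.raises(ValidationError, match="alive"):
            sample_timelapse(pop, 10.0, 5, 8.0, seed=0)

    def test_cohort_detachment_mean_matches_closed_form(self):
        counts = simulate_timelapse_cohorts(2000, 97, 8.0, RATE, seed=3)
        expected = 97 * (1 - math.exp(-8.0 * RATE))
        assert counts.mean() == pytest.approx(expected, abs=0.08)


class TestGenerateStudy:
    def test_bundle_round_trips_through_tsv(self, calibrated_intensity, tmp_path):
        cfg = make_config(calibrated_intensity, n_nuclei=2000, seed=17)
        bundle = generate_study(cfg, StudyDesign(), tmp_path)
        assert read_tracks(bundle.tracks_path) == bundle.tracks
        assert read_frequency_obs(bundle.frequency_path) == bundle.observations
        truth = json.loads(bundle.truth_path.read_text())
        assert truth["detachment_rate_per_hour"] == pytest.approx(RATE)

    def test_deterministic_per_seed(self, calibrated_intensity, tmp_path):
        cfg = make_config(calibrated_intensity, n_nuclei=1500, seed=23)
        b1 = generate_study(cfg, StudyDesign(), tmp_path / "a")
        b2 = generate_study(cfg, StudyDesign(), tmp_path / "b")
        assert b1.tracks_path.read_bytes() == b2.tracks_path.read_bytes()
        assert b1.frequency_path.read_bytes() == b2.frequency_path.read_bytes()

    def test_rate_recovery_within_ci(self, calibrated_intensity, tmp_path):
        """A handful of generated studies recover the true detachment
        rate inside the 95% CI (the full 200-study experiment runs in
        the acceptance suite)."""
        hits = 0
        for seed in range(10):
            cfg = make_config(calibrated_intensity, n_nuclei=1500, seed=100 + seed)
            bundle = generate_study(cfg, StudyDesign(), tmp_path / str(seed))
            est = estimate_detachment_rate(bundle.tracks)
            lo, hi = est.rate_ci
            hits += lo <= RATE <= hi
        assert hits >= 8
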