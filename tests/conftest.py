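import pytest

from blebkin import BlebTrack, calibrate_birth_intensity, default_power_trajectory


@pytest.fixture
def study_tracks():
    """The reconstructed time-lapse cohort: 96 blebs censored at 8 h and
    one that detached with 4 h at risk (exposure 772 bleb-hours)."""
    tracks = [
        BlebTrack(track_id=f"t{i:03d}", age_at_start=0.0, observed_duration=8.0, detached=False)
        for i in range(96)
    ]
    tracks.append(
        BlebTrack(track_id="t096", age_at_start=0.0, observed_duration=8.0, detached=True, event_time=4.0)
    )
    return tracks


@pytest.fixture
def power_trajectory():
    """Quadratic rise from 0 blebs/nucleus at AD1 to 0.35 at AD14."""
    return default_power_trajectory()


@pytest.fixture
def calibrated_intensity(power_trajectory):
    """Birth intensity whose analytic standing mean equals the default
    power-law trajectory under the estimated detachment rate."""
    return calibrate_birth_intensity(power_trajectory, 1.0 / 772.0)
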