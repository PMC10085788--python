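"""Stochastic generator of bleb birth/detachment data.

The generative model is the minimal one consistent with a mean standing
bleb trajectory and a constant detachment hazard:

* per nucleus, blebs are born according to a nonhomogeneous Poisson
  process with intensity beta(t) (events per nucleus per day), sampled
  by thinning against sup beta;
* each bleb lives an independent Exponential(lambda) time before
  detaching (lambda constant, per hour internally, converted to per day
  on the simulation axis);
* each bleb carries chromatin with probability ``chromatin_prob``
  (default 0.42), assigned at birth.

This is an M/M/inf-type birth-death process, so the expected standing
count obeys dE/dt = beta(t) - lambda*E, i.e.

    E[B(t)] = int_0^t beta(s) * exp(-lambda*(t - s)) ds,

which `analytic_mean_blebs` evaluates in closed form (constant or
linear beta) or by adaptive quadrature.  `calibrate_birth_intensity`
inverts this relation: beta(t) = B'(t) + lambda*B(t) reproduces any
differentiable target trajectory B exactly (clipped at zero where the
target decays faster than lambda*B allows).

Time axis: adult days, with t = 1 the first adult day (AD1); blebbing
targets have onset at t = 1.  Observation samplers reproduce the study
designs: cross-sectional counts of blebs per 100 nuclei at a given
adult day, and frame-quantised censored time-lapse tracks.

Randomness: one root seed; child streams are derived per nucleus (and
per sampler) from numpy ``SeedSequence`` spawn keys, so a given nucleus
generates identical blebs regardless of population size.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import integrate

from .kinetics import (
    HOURS_PER_DAY,
    BlebTrack,
    ValidationError,
)
from .trajectory import FrequencyObservation, Trajectory, evaluate as traj_evaluate

__all__ = [
    "BirthIntensity",
    "SimConfig",
    "Bleb",
    "SimulatedNucleus",
    "StudyDesign",
    "StudyBundle",
    "simulate_population",
    "analytic_mean_blebs",
    "calibrate_birth_intensity",
    "sample_cross_section",
    "sample_timelapse",
    "simulate_timelapse_cohorts",
    "generate_study",
]

# spawn-key stream ids (keep distinct so samplers never share a stream)
_STREAM_NUCLEI = 0
_STREAM_CROSS_SECTION = 1
_STREAM_TIMELAPSE = 2


# ---------------------------------------------------------------------------
# Birth intensity beta(t)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BirthIntensity:
    """Bleb birth intensity beta(t), events per nucleus per day.

    Kinds:

    * ``constant``: beta = value;
    * ``linear``: beta = intercept + slope * t (must stay >= 0 over the
      horizon);
    * ``power_law``: beta = b_max * ((t - t0)/(T - t0))**p on [t0, T],
      0 before t0, b_max beyond T;
    * ``calibrated``: beta = max(0, B'(t) + lambda_day * B(t)) for a
      target trajectory B (see :func:`calibrate_birth_intensity`).
    """

    kind: str
    value: float | None = None
    intercept: float | None = None
    slope: float | None = None
    t0: float | None = None
    horizon: float | None = None
    b_max: float | None = None
    p: float | None = None
    target: Trajectory | None = None
    rate_per_hour: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.value is None or self.value < 0 or not math.isfinite(self.value):
                raise ValidationError(f"constant intensity needs value >= 0, got {self.value!r}")
        elif self.kind == "linear":
            if self.intercept is None or self.slope is None:
                raise ValidationError("linear intensity needs intercept and slope")
        elif self.kind == "power_law":
            if None in (self.t0, self.horizon, self.b_max, self.p):
                raise ValidationError("power_law intensity needs t0, horizon, b_max, p")
            if self.b_max < 0 or self.p < 0 or self.horizon <= self.t0:
                raise ValidationError("invalid power_law intensity parameters")
        elif self.kind == "calibrated":
            if self.target is None or self.rate_per_hour is None:
                raise ValidationError("calibrated intensity needs target and rate_per_hour")
            if self.rate_per_hour < 0:
                raise ValidationError("rate_per_hour must be >= 0")
            if self.target.kind == "power_law" and self.target.p < 1.0:
                raise ValidationError(
                    "calibrated intensity for a power-law target needs p >= 1 "
                    "(the derivative is unbounded at onset otherwise)"
                )
        else:
            raise ValidationError(f"unknown intensity kind {self.kind!r}")

    # -- evaluation -----------------------------------------------------

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.value
        if self.kind == "linear":
            return self.intercept + self.slope * t
        if self.kind == "power_law":
            if t < self.t0:
                return 0.0
            if t >= self.horizon:
                return self.b_max
            u = (t - self.t0) / (self.horizon - self.t0)
            return self.b_max * u**self.p
        # calibrated
        lam_day = self.rate_per_hour * HOURS_PER_DAY
        b = traj_evaluate(self.target, t)
        return max(0.0, self._target_derivative(t) + lam_day * b)

    def _target_derivative(self, t: float) -> float:
        traj = self.target
        if traj.kind == "power_law":
            if t <= traj.t0 or t >= traj.horizon:
                return 0.0
            span = traj.horizon - traj.t0
            u = (t - traj.t0) / span
            return traj.b_max * traj.p * u ** (traj.p - 1.0) / span
        days = [d for d, _ in traj.knots]
        if t <= days[0] or t >= days[-1]:
            return 0.0
        for (d0, v0), (d1, v1) in zip(traj.knots, traj.knots[1:]):
            if d0 <= t < d1:
                return (v1 - v0) / (d1 - d0)
        return 0.0

    # -- bounds and validity over a horizon ------------------------------

    def _breakpoints(self, horizon: float) -> list[float]:
        pts = {0.0, horizon}
        if self.kind == "power_law":
            pts.update(x for x in (self.t0, self.horizon) if 0.0 < x < horizon)
        elif self.kind == "calibrated":
            traj = self.target
            if traj.kind == "power_law":
                pts.update(x for x in (traj.t0, traj.horizon) if 0.0 < x < horizon)
            else:
                pts.update(d for d, _ in traj.knots if 0.0 < d < horizon)
        return sorted(pts)

    def sup(self, horizon: float) -> float:
        """Exact supremum of beta over [0, horizon].

        All supported kinds are piecewise monotone between breakpoints,
        so the supremum is attained at a piece endpoint (evaluated just
        inside each piece to handle jump discontinuities).
        """
        pts = self._breakpoints(horizon)
        eps = 1e-9
        candidates = []
        for a, b in zip(pts, pts[1:]):
            candidates.extend([a, min(a + eps, b), max(b - eps, a), b])
        candidates.append(horizon)
        return max(self(t) for t in candidates)

    def validate_over(self, horizon: float) -> None:
        """Reject specs that are negative or unbounded on [0, horizon]."""
        s = self.sup(horizon)
        if not math.isfinite(s):
            raise ValidationError("birth intensity is unbounded over the horizon")
        if self.kind == "linear":
            if self(0.0) < 0 or self(horizon) < 0:
                raise ValidationError("linear intensity is negative over the horizon")

    def is_clipped(self, horizon: float) -> bool:
        """Whether the calibrated form clips negative values anywhere."""
        if self.kind != "calibrated":
            return False
        lam_day = self.rate_per_hour * HOURS_PER_DAY
        pts = self._breakpoints(horizon)
        eps = 1e-9
        for a, b in zip(pts, pts[1:]):
            for t in (min(a + eps, b), max(b - eps, a)):
                raw = self._target_derivative(t) + lam_day * traj_evaluate(self.target, t)
                if raw < -1e-12:
                    return True
        return False

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for name in ("value", "intercept", "slope", "t0", "horizon", "b_max", "p", "rate_per_hour"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        if self.target is not None:
            d["target"] = self.target.to_dict()
        return d


@dataclass(frozen=True)
class SimConfig:
    """Settings for a simulated bleb population."""

    n_nuclei: int
    birth_intensity: BirthIntensity
    detachment_rate: float  # per hour
    chromatin_prob: float = 0.42
    horizon: float = 14.0  # adult days
    frame_interval: float = 0.5  # hours
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ValidationError(f"n_nuclei must be > 0, got {self.n_nuclei}")
        if self.detachment_rate < 0 or not math.isfinite(self.detachment_rate):
            raise ValidationError(f"detachment_rate must be >= 0, got {self.detachment_rate!r}")
        if not 0.0 <= self.chromatin_prob <= 1.0:
            raise ValidationError(f"chromatin_prob must lie in [0,1], got {self.chromatin_prob!r}")
        if self.horizon <= 0:
            raise ValidationError(f"horizon must be > 0, got {self.horizon!r}")
        if self.frame_interval <= 0:
            raise ValidationError(f"frame_interval must be > 0, got {self.frame_interval!r}")
        self.birth_intensity.validate_over(self.horizon)


@dataclass(frozen=True)
class Bleb:
    birth_time: float  # adult days
    detach_time: float | None  # adult days; None when the rate is 0
    chromatin: bool

    def alive_at(self, t: float) -> bool:
        return self.birth_time <= t and (self.detach_time is None or self.detach_time > t)


@dataclass(frozen=True)
class SimulatedNucleus:
    nucleus_id: int
    blebs: tuple[Bleb, ...]

    def standing_blebs(self, t: float) -> int:
        return sum(1 for b in self.blebs if b.alive_at(t))


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _nucleus_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_NUCLEI, index))
    )


def _sampler_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_population(config: SimConfig) -> list[SimulatedNucleus]:
    """Simulate bleb birth, detachment and chromatin content per nucleus.

    Birth times are drawn by thinning a homogeneous Poisson process at
    rate sup(beta); detachment delays are Exponential(lambda); chromatin
    flags are Bernoulli(chromatin_prob).  Fully reproducible: the same
    seed and config give byte-identical populations, and nucleus ``i``
    is unchanged by the presence of other nuclei.
    """
    beta = config.birth_intensity
    sup = beta.sup(config.horizon)
    lam_day = config.detachment_rate * HOURS_PER_DAY
    nuclei = []
    for i in range(config.n_nuclei):
        rng = _nucleus_rng(config.seed, i)
        blebs: list[Bleb] = []
        if sup > 0:
            n_cand = rng.poisson(sup * config.horizon)
            times = np.sort(rng.uniform(0.0, config.horizon, n_cand))
            keep = rng.uniform(0.0, sup, n_cand) < np.array([beta(t) for t in times])
            for birth in times[keep]:
                if lam_day > 0:
                    detach = birth + rng.exponential(1.0 / lam_day)
                else:
                    detach = None
                chromatin = bool(rng.random() < config.chromatin_prob)
                blebs.append(Bleb(float(birth), detach, chromatin))
        nuclei.append(SimulatedNucleus(nucleus_id=i, blebs=tuple(blebs)))
    return nuclei


def analytic_mean_blebs(config: SimConfig, t: float) -> float:
    """Expected standing blebs per nucleus at adult day ``t``.

    Evaluates E[B(t)] = int_0^t beta(s) exp(-lambda*(t-s)) ds, in closed
    form for constant and linear intensities and by adaptive quadrature
    (absolute tolerance 1e-10) otherwise.
    """
    return mean_standing_blebs(config.birth_intensity, config.detachment_rate, t)


def mean_standing_blebs(beta: BirthIntensity, rate_per_hour: float, t: float) -> float:
    if t <= 0:
        return 0.0
    lam = rate_per_hour * HOURS_PER_DAY  # per day
    if beta.kind == "constant":
        if lam == 0:
            return beta.value * t
        return (beta.value / lam) * -math.expm1(-lam * t)
    if beta.kind == "linear":
        a, m = beta.intercept, beta.slope
        if lam == 0:
            return a * t + 0.5 * m * t * t
        g = -math.expm1(-lam * t)  # 1 - e^{-lam t}
        return a * g / lam + m * (t / lam - g / (lam * lam))
    pts = [p for p in beta._breakpoints(t) if 0.0 < p < t]
    val, _ = integrate.quad(
        lambda s: beta(s) * math.exp(-lam * (t - s)),
        0.0,
        t,
        points=pts or None,
        epsabs=1e-10,
        limit=200,
    )
    return val


def calibrate_birth_intensity(target: Trajectory, detachment_rate: float) -> BirthIntensity:
    """Birth intensity whose mean standing count reproduces ``target``.

    Solves the mean-field balance dB/dt = beta - lambda*B for beta:
    beta(t) = B'(t) + lambda_day * B(t), clipped at zero.  Wherever
    clipping is inactive, `analytic_mean_blebs` of the result equals the
    target exactly; a target decaying faster than lambda*B would require
    a negative birth rate and triggers a warning.
    """
    beta = BirthIntensity(kind="calibrated", target=target, rate_per_hour=detachment_rate)
    horizon = target.horizon if target.kind == "power_law" else target.knots[-1][0]
    if beta.is_clipped(horizon):
        warnings.warn(
            "target trajectory decreases faster than detachment can explain; "
            "the birth intensity was clipped at zero and the realised mean "
            "will sit above the target there",
            stacklevel=2,
        )
    return beta


# ---------------------------------------------------------------------------
# Observation samplers
# ---------------------------------------------------------------------------

def sample_cross_section(
    pop: Sequence[SimulatedNucleus],
    age: float,
    n_nuclei_scored: int,
    seed: int = 0,
) -> FrequencyObservation:
    """Score a random subset of nuclei for standing blebs at one age.

    Samples ``n_nuclei_scored`` nuclei without replacement and counts
    blebs alive at ``age`` (born and not yet detached); the returned
    observation carries the per-100-nuclei frequency.
    """
    if n_nuclei_scored > len(pop):
        raise ValidationError(
            f"cannot score {n_nuclei_scored} nuclei from a population of {len(pop)}"
        )
    rng = _sampler_rng(seed, _STREAM_CROSS_SECTION)
    idx = rng.choice(len(pop), size=n_nuclei_scored, replace=False)
    n_blebs = int(sum(pop[i].standing_blebs(age) for i in idx))
    return FrequencyObservation(adult_day=age, n_nuclei=n_nuclei_scored, n_blebs=n_blebs)


def sample_timelapse(
    pop: Sequence[SimulatedNucleus],
    start_age: float,
    n_tracks: int,
    duration: float,
    frame_interval: float = 0.5,
    seed: int = 0,
) -> list[BlebTrack]:
    """Track alive blebs over a fixed window, frame-quantised.

    Selects ``n_tracks`` blebs alive at ``start_age`` uniformly without
    replacement; each track is censored at ``duration`` hours or ends at
    the first frame boundary at or after the true detachment time.
    """
    alive = [
        (nuc.nucleus_id, j, b)
        for nuc in pop
        for j, b in enumerate(nuc.blebs)
        if b.alive_at(start_age)
    ]
    if len(alive) < n_tracks:
        raise ValidationError(
            f"only {len(alive)} blebs alive at day {start_age}, need {n_tracks}"
        )
    rng = _sampler_rng(seed, _STREAM_TIMELAPSE)
    idx = rng.choice(len(alive), size=n_tracks, replace=False)
    age_h = (start_age - 1.0) * HOURS_PER_DAY  # hours since AD1 onset
    tracks = []
    for k in sorted(idx):
        nid, j, b = alive[k]
        if b.detach_time is not None:
            residual_h = (b.detach_time - start_age) * HOURS_PER_DAY
        else:
            residual_h = math.inf
        if residual_h <= duration:
            # first frame at which the bleb is absent
            event = math.ceil(residual_h / frame_interval - 1e-12) * frame_interval
            event = max(event, frame_interval)
            track = BlebTrack(
                track_id=f"n{nid}_b{j}",
                age_at_start=age_h,
                observed_duration=duration,
                detached=True,
                event_time=min(event, duration),
                frame_interval=frame_interval,
            )
        else:
            track = BlebTrack(
                track_id=f"n{nid}_b{j}",
                age_at_start=age_h,
                observed_duration=duration,
                detached=False,
                frame_interval=frame_interval,
            )
        tracks.append(track)
    return tracks


def simulate_timelapse_cohorts(
    n_cohorts: int,
    n_tracks: int,
    duration: float,
    rate_per_hour: float,
    seed: int = 0,
) -> np.ndarray:
    """Detachment counts for replicate cohorts of tracked blebs.

    Each cohort tracks ``n_tracks`` standing blebs for ``duration``
    hours; by memorylessness of the exponential model the residual
    lifetime of a standing bleb is Exponential(rate), so the number of
    detachments per cohort is Binomial(n_tracks, 1 - exp(-rate*T)).
    Sampled via exponential residuals for direct comparability with the
    track-level simulator.
    """
    if rate_per_hour < 0:
        raise ValidationError("rate_per_hour must be >= 0")
    rng = np.random.default_rng(seed)
    if rate_per_hour == 0:
        return np.zeros(n_cohorts, dtype=np.int64)
    residuals = rng.exponential(1.0 / rate_per_hour, size=(n_cohorts, n_tracks))
    return (residuals <= duration).sum(axis=1)


# ---------------------------------------------------------------------------
# End-to-end study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a simulated study.

    The cross-sectional arm scores ``nuclei_per_day`` nuclei on each of
    ``sample_days``; the time-lapse arm tracks ``n_tracks`` blebs for
    ``track_duration`` hours starting at ``timelapse_age``.  The default
    tracking age (AD9) is late enough that a population of a few
    thousand nuclei reliably carries ~100 standing blebs.
    """

    sample_days: tuple[float, ...] = (1.0, 4.0, 7.0, 9.0, 11.0, 14.0)
    nuclei_per_day: int = 100
    timelapse_age: float = 9.0
    n_tracks: int = 97
    track_duration: float = 8.0  # hours
    frame_interval: float = 0.5  # hours


@dataclass(frozen=True)
class StudyBundle:
    frequency_path: Path
    tracks_path: Path
    truth_path: Path
    observations: list[FrequencyObservation]
    tracks: list[BlebTrack]
    truth: dict


def generate_study(config: SimConfig, design: StudyDesign, out_dir: str | Path) -> StudyBundle:
    """Simulate a population and write the study's data bundle.

    Produces the cross-sectional frequency TSV, the censored track TSV
    and a ground-truth JSON (true rate, intensity spec, chromatin
    probability) for parameter-recovery tests.  Deterministic per seed.
    """
    from .io import write_frequency_obs, write_tracks  # readers/writers live in io

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create study output directory {out}: {exc}") from exc

    pop = simulate_population(config)
    observations = [
        sample_cross_section(pop, day, design.nuclei_per_day, seed=config.seed + 1000 + i)
        for i, day in enumerate(design.sample_days)
    ]
    tracks = sample_timelapse(
        pop,
        start_age=design.timelapse_age,
        n_tracks=design.n_tracks,
        duration=design.track_duration,
        frame_interval=design.frame_interval,
        seed=config.seed,
    )
    truth = {
        "detachment_rate_per_hour": config.detachment_rate,
        "birth_intensity": config.birth_intensity.to_dict(),
        "chromatin_prob": config.chromatin_prob,
        "horizon_days": config.horizon,
        "n_nuclei": config.n_nuclei,
        "seed": config.seed,
    }
    freq_path = out / "frequency.tsv"
    tracks_path = out / "tracks.tsv"
    truth_path = out / "truth.json"
    write_frequency_obs(observations, freq_path)
    write_tracks(tracks, tracks_path)
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return StudyBundle(
        frequency_path=freq_path,
        tracks_path=tracks_path,
        truth_path=truth_path,
        observations=observations,
        tracks=tracks,
        truth=truth,
    )
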