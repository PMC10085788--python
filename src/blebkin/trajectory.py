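"""Age-dependent blebbing-frequency trajectories B(t).

B(t) is the expected number of standing nuclear blebs per hyp7 nucleus
at adult day t.  Cross-sectional counts (blebs per 100 nuclei scored at
a given adult day) rise from close to zero on adult day 1 (AD1) to about
0.35 blebs/nucleus on AD14.  Two trajectory families are supported:

* ``piecewise_linear`` — linear interpolation through knots, typically
  per-day pooled means of observed frequencies;
* ``power_law`` — B(t) = B_max * ((t - t0)/(T - t0))**p on [t0, T],
  zero before onset t0, constant B_max beyond the horizon T.

Combining a trajectory with a constant per-bleb detachment rate lambda
gives the expected number of detachment events per nucleus over an age
window: since the standing bleb pool at age t is B(t) and each standing
bleb detaches with hazard lambda,

    E[detachments per nucleus over [a, b]] = lambda_day * int_a^b B(t) dt.

Ages are adult days with AD1 the origin of blebbing; rates quoted per
hour are converted with 24 h/day at this boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .kinetics import HOURS_PER_DAY, ValidationError

__all__ = [
    "FrequencyObservation",
    "Trajectory",
    "trajectory_from_observations",
    "fit_power_trajectory",
    "evaluate",
    "integrate_trajectory",
    "expected_detachments",
]


@dataclass(frozen=True)
class FrequencyObservation:
    """One cross-sectional blebbing count.

    ``frequency`` is blebs per 100 nuclei and is always recomputed from
    the counts (blebs, not blebbed nuclei: a nucleus may carry several).
    """

    adult_day: float
    n_nuclei: int
    n_blebs: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.adult_day):
            raise ValidationError(f"adult_day must be finite, got {self.adult_day!r}")
        if self.n_nuclei <= 0:
            raise ValidationError(f"n_nuclei must be > 0, got {self.n_nuclei!r}")
        if self.n_blebs < 0:
            raise ValidationError(f"n_blebs must be >= 0, got {self.n_blebs!r}")

    @property
    def frequency(self) -> float:
        """Blebs per 100 nuclei."""
        return 100.0 * self.n_blebs / self.n_nuclei

    @property
    def blebs_per_nucleus(self) -> float:
        return self.n_blebs / self.n_nuclei


@dataclass(frozen=True)
class Trajectory:
    """Expected standing blebs per nucleus as a function of adult day.

    Exactly one of the two parameterisations is populated, selected by
    ``kind``:

    * ``piecewise_linear``: ``knots`` is a sorted tuple of
      ``(adult_day, blebs_per_nucleus)`` pairs;
    * ``power_law``: ``B(t) = b_max * ((t - t0)/(horizon - t0))**p``.

    Evaluation is 0 before the first knot / onset and constant beyond
    the last knot / horizon.
    """

    kind: str
    knots: tuple[tuple[float, float], ...] | None = None
    t0: float | None = None
    horizon: float | None = None
    b_max: float | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "piecewise_linear":
            if not self.knots or len(self.knots) < 1:
                raise ValidationError("piecewise_linear trajectory needs >= 1 knot")
            days = [d for d, _ in self.knots]
            if any(b < a or math.isclose(a, b) for a, b in zip(days, days[1:])):
                raise ValidationError("knot days must be strictly increasing")
            if any(v < 0 for _, v in self.knots):
                raise ValidationError("knot values must be >= 0")
        elif self.kind == "power_law":
            if None in (self.t0, self.horizon, self.b_max, self.p):
                raise ValidationError("power_law trajectory needs t0, horizon, b_max, p")
            if self.horizon <= self.t0:
                raise ValidationError("horizon must exceed onset t0")
            if self.b_max < 0 or self.p < 0:
                raise ValidationError("b_max and p must be >= 0")
        else:
            raise ValidationError(f"unknown trajectory kind {self.kind!r}")

    def __call__(self, t: float) -> float:
        return evaluate(self, t)

    def to_dict(self) -> dict:
        if self.kind == "piecewise_linear":
            return {"kind": self.kind, "knots": [list(k) for k in self.knots]}
        return {
            "kind": self.kind,
            "t0": self.t0,
            "horizon": self.horizon,
            "b_max": self.b_max,
            "p": self.p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        if d.get("kind") == "piecewise_linear":
            return cls(kind="piecewise_linear", knots=tuple((float(a), float(b)) for a, b in d["knots"]))
        return cls(
            kind=d["kind"],
            t0=float(d["t0"]),
            horizon=float(d["horizon"]),
            b_max=float(d["b_max"]),
            p=float(d["p"]),
        )


def default_power_trajectory() -> Trajectory:
    """The documented reconstruction of the observed age trajectory.

    A quadratic rise from 0 blebs/nucleus at AD1 to 0.35 at AD14 — the
    simplest smooth shape consistent with near-zero blebbing on AD1 and
    ~35 blebs per 100 nuclei on AD14.
    """
    return Trajectory(kind="power_law", t0=1.0, horizon=14.0, b_max=0.35, p=2.0)


def trajectory_from_observations(obs: Sequence[FrequencyObservation]) -> Trajectory:
    """Piecewise-linear trajectory through per-day pooled frequencies.

    Observations sharing an adult day are pooled weighted by the number
    of nuclei scored (i.e. counts are summed before dividing).
    """
    if len(obs) == 0:
        raise ValidationError("no observations")
    pooled: dict[float, list[int]] = {}
    for o in obs:
        acc = pooled.setdefault(float(o.adult_day), [0, 0])
        acc[0] += o.n_blebs
        acc[1] += o.n_nuclei
    if len(pooled) < 2:
        raise ValidationError(
            f"need observations at >= 2 distinct days, got {len(pooled)}"
        )
    knots = tuple(
        (day, blebs / nuclei) for day, (blebs, nuclei) in sorted(pooled.items())
    )
    return Trajectory(kind="piecewise_linear", knots=knots)


def fit_power_trajectory(
    obs: Sequence[FrequencyObservation], t0: float, horizon: float
) -> Trajectory:
    """Weighted least-squares fit of (b_max, p) for a power-law trajectory.

    Minimises sum_i n_nuclei_i * (B_max * u_i**p - b_i)**2 with
    u_i = (t_i - t0)/(horizon - t0) and b_i the observed blebs/nucleus,
    over B_max >= 0, p >= 0.
    """
    usable = [o for o in obs if t0 < o.adult_day <= horizon]
    if len(usable) < 3:
        raise ValidationError(
            f"need >= 3 observations in ({t0}, {horizon}], got {len(usable)}"
        )
    u = np.array([(o.adult_day - t0) / (horizon - t0) for o in usable])
    b = np.array([o.blebs_per_nucleus for o in usable])
    w = np.sqrt(np.array([o.n_nuclei for o in usable], dtype=float))

    def residuals(theta: np.ndarray) -> np.ndarray:
        b_max, p = theta
        return w * (b_max * u**p - b)

    x0 = np.array([max(b.max(), 1e-6), 1.0])
    sol = optimize.least_squares(
        residuals, x0, bounds=([0.0, 0.0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14
    )
    if not sol.success:
        raise RuntimeError(f"power-law fit did not converge: {sol.message}")
    b_max, p = sol.x
    return Trajectory(kind="power_law", t0=t0, horizon=horizon, b_max=float(b_max), p=float(p))


def evaluate(traj: Trajectory, t: float) -> float:
    """B(t): expected blebs per nucleus at adult day ``t``.

    Zero before the first knot / onset, constant beyond the last knot /
    horizon.
    """
    if traj.kind == "piecewise_linear":
        days = [d for d, _ in traj.knots]
        vals = [v for _, v in traj.knots]
        if t < days[0]:
            return 0.0
        if t >= days[-1]:
            return vals[-1]
        return float(np.interp(t, days, vals))
    # power_law
    if t < traj.t0:
        return 0.0
    if t >= traj.horizon:
        return float(traj.b_max)
    u = (t - traj.t0) / (traj.horizon - traj.t0)
    return float(traj.b_max * u**traj.p)


def _integrate_from_onset(traj: Trajectory, t: float) -> float:
    """int_{-inf}^{t} B(s) ds in closed form (B = 0 at early ages)."""
    if traj.kind == "power_law":
        if t <= traj.t0:
            return 0.0
        span = traj.horizon - traj.t0
        if t <= traj.horizon:
            u = (t - traj.t0) / span
            return traj.b_max * span * u ** (traj.p + 1) / (traj.p + 1)
        core = traj.b_max * span / (traj.p + 1)
        return core + traj.b_max * (t - traj.horizon)
    # piecewise_linear: trapezoid over knots, constant tail
    days = [d for d, _ in traj.knots]
    vals = [v for _, v in traj.knots]
    if t <= days[0]:
        return 0.0
    total = 0.0
    for (d0, v0), (d1, v1) in zip(traj.knots, traj.knots[1:]):
        if t <= d0:
            break
        hi = min(t, d1)
        # value at hi by linear interpolation on this segment
        v_hi = v0 + (v1 - v0) * (hi - d0) / (d1 - d0)
        total += 0.5 * (v0 + v_hi) * (hi - d0)
    if t > days[-1]:
        total += vals[-1] * (t - days[-1])
    return total


def integrate_trajectory(traj: Trajectory, t_start: float, t_end: float) -> float:
    """int_{t_start}^{t_end} B(t) dt in bleb-days per nucleus (closed form)."""
    if t_end < t_start:
        raise ValidationError(
            f"reversed bounds: t_start={t_start} > t_end={t_end}"
        )
    return float(_integrate_from_onset(traj, t_end) - _integrate_from_onset(traj, t_start))


def expected_detachments(
    traj: Trajectory, rate: float, t_start: float, t_end: float
) -> float:
    """Expected detachments per nucleus over an age window.

    ``rate`` is the per-bleb detachment rate in events/hour; the result
    is ``(rate * 24) * int B(t) dt`` with the integral in bleb-days.
    """
    if rate < 0 or not math.isfinite(rate):
        raise ValidationError(f"rate must be >= 0 and finite, got {rate!r}")
    return (rate * HOURS_PER_DAY) * integrate_trajectory(traj, t_start, t_end)
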