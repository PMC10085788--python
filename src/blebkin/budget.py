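"""Chromatin-loss budget: how much nuclear DNA does blebbing remove?

The budget is a three-factor product.  Over the first two weeks of
adulthood each hyp7 nucleus is expected to shed ``expected_detachments``
blebs (~0.049 under the reconstructed trajectory).  A fraction
``chromatin_fraction`` of blebs carry chromatin (0.42 observed), and a
chromatin-positive bleb is assumed to carry a fraction of the nuclear
DNA equal to its relative volume: with a bleb/nucleus diameter ratio of
1/5, the volume ratio is (1/5)**3 = 1/125 = 0.8%.  Hence

    hyp7_loss = detachments * chromatin_fraction * volume_fraction
              ~ 0.049 * 0.42 * 0.008 = 1.65e-4  (0.016% of hyp7 DNA).

Normalising by the total age-related somatic DNA loss (10-25% of
nuclear DNA; midpoint 15% used as the point value) gives blebbing's
share of the total loss, ~0.1% — a minor contribution.

`propagate_uncertainty` pushes parameter uncertainty (intervals treated
as uniform, or beta/gamma specs) through the budget by seeded Monte
Carlo and reports a percentile interval on the share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinetics import ValidationError

__all__ = [
    "BudgetParams",
    "BudgetResult",
    "volume_fraction",
    "blebbing_dna_loss",
    "share_of_total_loss",
    "budget_report",
    "propagate_uncertainty",
    "format_percent",
    "parse_percent",
]

#: The observed somatic DNA-loss range whose midpoint serves as the
#: default normalisation denominator.
TOTAL_LOSS_RANGE = (0.10, 0.25)


def _check_fraction(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class BudgetParams:
    """Inputs of the chromatin-loss budget.

    ``volume_fraction`` may be omitted, in which case it is derived as
    ``diameter_ratio**3`` (spherical scaling).
    """

    expected_detachments: float = 0.049
    chromatin_fraction: float = 0.42
    diameter_ratio: float = 0.2
    volume_fraction: float | None = None
    total_dna_loss_fraction: float = 0.15
    total_dna_loss_range: tuple[float, float] = TOTAL_LOSS_RANGE

    def __post_init__(self) -> None:
        if self.expected_detachments < 0 or not math.isfinite(self.expected_detachments):
            raise ValidationError(
                f"expected_detachments must be >= 0, got {self.expected_detachments!r}"
            )
        _check_fraction("chromatin_fraction", self.chromatin_fraction)
        _check_fraction("diameter_ratio", self.diameter_ratio)
        if self.volume_fraction is not None:
            _check_fraction("volume_fraction", self.volume_fraction)
        _check_fraction("total_dna_loss_fraction", self.total_dna_loss_fraction)
        if self.total_dna_loss_fraction <= 0:
            raise ValidationError("total_dna_loss_fraction must be > 0")

    @property
    def effective_volume_fraction(self) -> float:
        if self.volume_fraction is not None:
            return self.volume_fraction
        return volume_fraction(self.diameter_ratio)

    def to_dict(self) -> dict:
        return {
            "expected_detachments": self.expected_detachments,
            "chromatin_fraction": self.chromatin_fraction,
            "diameter_ratio": self.diameter_ratio,
            "volume_fraction": self.effective_volume_fraction,
            "total_dna_loss_fraction": self.total_dna_loss_fraction,
            "total_dna_loss_range": list(self.total_dna_loss_range),
        }


@dataclass(frozen=True)
class BudgetResult:
    """Output of the budget: fractions, not percentages.

    ``share_range`` evaluates the share at the endpoints of the total
    DNA-loss range (the larger denominator gives the smaller share).
    ``interval`` is an optional Monte-Carlo percentile interval.
    """

    hyp7_loss_fraction: float
    share_of_total: float
    inputs: BudgetParams
    share_range: tuple[float, float] | None = None
    interval: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "hyp7_loss_fraction": self.hyp7_loss_fraction,
            "share_of_total": self.share_of_total,
            "hyp7_loss_percent": format_percent(self.hyp7_loss_fraction, 3),
            "share_of_total_percent": format_percent(self.share_of_total, 1),
            "inputs": self.inputs.to_dict(),
        }
        if self.share_range is not None:
            d["share_range"] = list(self.share_range)
        if self.interval is not None:
            d["interval"] = list(self.interval)
        return d


def volume_fraction(diameter_ratio: float) -> float:
    """Bleb/nucleus volume ratio from the diameter ratio (cubed)."""
    _check_fraction("diameter_ratio", diameter_ratio)
    return diameter_ratio**3


def blebbing_dna_loss(
    expected_detachments: float, chromatin_fraction: float, volume_fraction: float
) -> float:
    """Fraction of hyp7 nuclear DNA lost through bleb detachment.

    The three-way product: detachments per nucleus x probability the
    detached bleb carries chromatin x fraction of nuclear DNA per
    chromatin-positive bleb.
    """
    if expected_detachments < 0 or not math.isfinite(expected_detachments):
        raise ValidationError(
            f"expected_detachments must be >= 0, got {expected_detachments!r}"
        )
    _check_fraction("chromatin_fraction", chromatin_fraction)
    _check_fraction("volume_fraction", volume_fraction)
    return expected_detachments * chromatin_fraction * volume_fraction


def share_of_total_loss(bleb_loss: float, total_loss: float) -> float:
    """Blebbing's share of the total somatic DNA loss."""
    if total_loss <= 0 or not math.isfinite(total_loss):
        raise ValidationError(f"total_loss must be > 0, got {total_loss!r}")
    if bleb_loss < 0 or not math.isfinite(bleb_loss):
        raise ValidationError(f"bleb_loss must be >= 0, got {bleb_loss!r}")
    return bleb_loss / total_loss


def budget_report(params: BudgetParams) -> BudgetResult:
    """Compose the full budget deterministically from its parameters."""
    vf = params.effective_volume_fraction
    loss = blebbing_dna_loss(params.expected_detachments, params.chromatin_fraction, vf)
    share = share_of_total_loss(loss, params.total_dna_loss_fraction)
    lo_den, hi_den = params.total_dna_loss_range
    share_range = (
        share_of_total_loss(loss, hi_den),  # larger denominator -> smaller share
        share_of_total_loss(loss, lo_den),
    )
    return BudgetResult(
        hyp7_loss_fraction=loss,
        share_of_total=share,
        inputs=params,
        share_range=share_range,
    )


# ---------------------------------------------------------------------------
# Uncertainty propagation
# ---------------------------------------------------------------------------

_UNCERTAIN_FIELDS = (
    "expected_detachments",
    "chromatin_fraction",
    "diameter_ratio",
    "volume_fraction",
    "total_dna_loss_fraction",
)


def _draw(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a parameter: point value, (low, high) uniform, or dist spec."""
    if isinstance(spec, (int, float)):
        return np.full(size, float(spec))
    if isinstance(spec, (tuple, list)) and len(spec) == 2 and all(
        isinstance(x, (int, float)) for x in spec
    ):
        lo, hi = spec
        if hi < lo:
            raise ValidationError(f"interval spec has high < low: {spec!r}")
        return rng.uniform(lo, hi, size)
    if isinstance(spec, Mapping):
        dist = spec.get("dist")
        if dist == "uniform":
            return rng.uniform(spec["low"], spec["high"], size)
        if dist == "beta":
            return rng.beta(spec["a"], spec["b"], size)
        if dist == "gamma":
            return rng.gamma(spec["shape"], spec.get("scale", 1.0), size)
        raise ValidationError(f"unknown distribution spec {spec!r}")
    raise ValidationError(f"invalid parameter spec {spec!r}")


def propagate_uncertainty(
    param_specs: Mapping[str, object],
    n_draws: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Monte-Carlo percentile interval on the share of total DNA loss.

    ``param_specs`` maps budget parameter names to a point value, a
    ``(low, high)`` interval (uniform), or a ``{"dist": ...}`` spec.
    Unspecified parameters take their defaults.  If ``volume_fraction``
    is not given it is derived per-draw from ``diameter_ratio**3``.
    """
    if n_draws < 100:
        raise ValidationError(f"n_draws must be >= 100, got {n_draws}")
    unknown = set(param_specs) - set(_UNCERTAIN_FIELDS)
    if unknown:
        raise ValidationError(f"unknown budget parameters: {sorted(unknown)}")
    defaults = BudgetParams()
    rng = np.random.default_rng(seed)
    det = _draw(param_specs.get("expected_detachments", defaults.expected_detachments), n_draws, rng)
    chrom = _draw(param_specs.get("chromatin_fraction", defaults.chromatin_fraction), n_draws, rng)
    if "volume_fraction" in param_specs:
        vf = _draw(param_specs["volume_fraction"], n_draws, rng)
    else:
        dr = _draw(param_specs.get("diameter_ratio", defaults.diameter_ratio), n_draws, rng)
        vf = dr**3
    total = _draw(
        param_specs.get("total_dna_loss_fraction", defaults.total_dna_loss_fraction),
        n_draws,
        rng,
    )
    if np.any(total <= 0):
        raise ValidationError("total_dna_loss_fraction draws must be > 0")
    share = det * chrom * vf / total
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(share, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Percent formatting (reporting precision; raw fractions are always kept)
# ---------------------------------------------------------------------------

def format_percent(fraction: float, decimals: int = 1) -> str:
    """Format a fraction as a percent string at reporting precision.

    Uses round-half-even, e.g. ``format_percent(1.6464e-4, 3) ==
    '0.016%'`` and ``format_percent(1.0976e-3, 1) == '0.1%'``.
    """
    pct = round(fraction * 100.0, decimals)
    return f"{pct:.{decimals}f}%"


def parse_percent(text: str) -> float:
    """Inverse of :func:`format_percent`: percent string -> fraction."""
    return float(text.strip().rstrip("%")) / 100.0
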