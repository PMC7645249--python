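"""Cumulative SWI incidence as a saturating Hill curve.

The probability that a CABG patient has developed a sternal-wound infection
by post-operative day ``t`` is modelled as

    CI(t) = i_max * t**n / (t50**n + t**n)

with asymptote ``i_max`` (the curve "height"), midpoint ``t50`` (days to
half-maximal cumulative incidence) and Hill coefficient ``n``.  The curve
shape (t50, n) is shared across countries; the height is calibrated per
country so that the curve passes through the observed incidence at that
country's surveillance day.  For the daily-cycle cohort model the curve is
converted to a schedule of conditional per-day onset probabilities
(discrete hazards).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HillCurveParams",
    "HazardSchedule",
    "CalibrationWarning",
    "cumulative_incidence",
    "calibrate_height",
    "to_hazard_schedule",
]


class CalibrationWarning(UserWarning):
    """Raised when height calibration has to clamp i_max to 1."""


@dataclass(frozen=True)
class HillCurveParams:
    """Parameters of the cumulative-incidence Hill curve."""

    i_max: float  # asymptotic cumulative incidence, in [0, 1]
    t50: float    # days to half-maximum, > 0
    n_hill: float  # shape coefficient, > 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.i_max <= 1.0:
            raise ValueError(f"i_max must be in [0, 1], got {self.i_max}")
        if self.t50 <= 0:
            raise ValueError(f"t50 must be > 0, got {self.t50}")
        if self.n_hill <= 0:
            raise ValueError(f"n_hill must be > 0, got {self.n_hill}")


def cumulative_incidence(t, params: HillCurveParams):
    """Cumulative SWI incidence at day(s) ``t``.

    Accepts a scalar or array of non-negative times; returns the same shape.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    tn = np.power(t_arr, params.n_hill)
    with np.errstate(invalid="ignore"):
        ci = params.i_max * tn / (params.t50 ** params.n_hill + tn)
    ci = np.where(t_arr == 0, 0.0, ci)
    return ci if ci.ndim else float(ci)


def calibrate_height(
    observed_incidence: float,
    surveillance_days: float,
    shape: tuple[float, float],
) -> HillCurveParams:
    """Height-calibrate the curve to pass through an observed incidence.

    Solves ``CI(surveillance_days) = observed_incidence`` for ``i_max`` in
    closed form: ``i_max = observed * (t50**n + T**n) / T**n``.  If the
    solution exceeds 1 it is clamped with a :class:`CalibrationWarning`.
    """
    t50, n_hill = shape
    if not 0.0 <= observed_incidence <= 1.0:
        raise ValueError(
            f"observed incidence must be in [0, 1], got {observed_incidence}"
        )
    if surveillance_days < 1:
        raise ValueError(
            f"surveillance_days must be >= 1, got {surveillance_days}"
        )
    if observed_incidence == 0.0:
        return HillCurveParams(0.0, t50, n_hill)
    tn = surveillance_days ** n_hill
    i_max = observed_incidence * (t50 ** n_hill + tn) / tn
    if i_max > 1.0:
        warnings.warn(
            f"calibrated i_max={i_max:.4g} exceeds 1 for incidence "
            f"{observed_incidence} at {surveillance_days} days; clamping to 1",
            CalibrationWarning,
            stacklevel=2,
        )
        i_max = 1.0
    return HillCurveParams(i_max, t50, n_hill)


@dataclass
class HazardSchedule:
    """Per-day conditional SWI onset probabilities over the model horizon.

    ``hazards[d-1]`` is the probability of onset on day ``d`` given no SWI
    before day ``d``.  ``sswi_share`` is carried along for the
    superficial/deep split at onset.
    """

    hazards: np.ndarray
    sswi_share: float
    cumulative: np.ndarray = field(repr=False, default=None)  # CI(1..horizon)

    @property
    def horizon(self) -> int:
        return len(self.hazards)

    def reconstruct_cumulative(self) -> np.ndarray:
        """Cumulative incidence implied by the hazards (survival product)."""
        return 1.0 - np.cumprod(1.0 - self.hazards)


def to_hazard_schedule(
    params: HillCurveParams,
    horizon: int,
    sswi_share: float,
    cap_day: int | None = None,
) -> HazardSchedule:
    """Embed the continuous curve into daily conditional hazards.

    ``h(d) = (CI(d) - CI(d-1)) / (1 - CI(d-1))``, with the convention that
    the hazard is 0 once the at-risk probability ``1 - CI(d-1)`` vanishes.
    With ``cap_day`` set, the curve is frozen at its ``cap_day`` value
    thereafter (no extrapolation beyond the surveillance window).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not 0.0 <= sswi_share <= 1.0:
        raise ValueError(f"sswi_share must be in [0, 1], got {sswi_share}")
    days = np.arange(0, horizon + 1, dtype=float)
    ci = cumulative_incidence(days, params)
    if cap_day is not None:
        cap_val = cumulative_incidence(float(cap_day), params)
        ci = np.minimum(ci, cap_val)
    at_risk = 1.0 - ci[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        hazards = np.where(at_risk > 0, (ci[1:] - ci[:-1]) / at_risk, 0.0)
    hazards = np.clip(hazards, 0.0, 1.0)
    return HazardSchedule(hazards=hazards, sswi_share=sswi_share, cumulative=ci[1:])
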