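"""Thermal environment: season-zone classification, seasonal factors and the
temperature-lag compensation mechanism.

The model divides ambient temperature (ET) into three season zones around the
thermoneutral band [t_low, t_high] = [15, 28] degC by default:

* ``cold``          ET < t_low   — extra maintenance energy for thermoregulation
* ``thermoneutral`` t_low <= ET <= t_high — no temperature term
* ``heat``          ET > t_high  — reduced intake and metabolic rate

Cold compensation is damped during sustained cold spells: after ``n``
consecutive days below ``t_low`` the theoretical compensation is multiplied by
a lag coefficient gamma(n) in (0, 1], a piecewise-constant step function on the
tabulated breakpoints n = 1, 3, 5 with values 0.85, 0.51, 0.32 (gamma = 1 for
n = 0).  Feeding behaviour does not ramp up as fast as the heat-loss theory
predicts, so applying the full theoretical compensation would over-feed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .params import ModelParameters

__all__ = [
    "SeasonZone",
    "Environment",
    "DEFAULT_SF_TABLE",
    "DEFAULT_GAMMA_TABLE",
    "classify_season",
    "seasonal_factor",
    "lag_coefficient",
    "apply_lag",
    "temperature_adjustment",
    "consecutive_cold_days",
]


class SeasonZone(str, enum.Enum):
    """Thermal season zone of a single day."""

    COLD = "cold"
    THERMONEUTRAL = "thermoneutral"
    HEAT = "heat"

    def __str__(self) -> str:  # yaml/csv friendliness
        return self.value


#: Seasonal factor (SF) by zone: winter 1.35, spring/autumn 1.15, summer 1.05.
DEFAULT_SF_TABLE: dict[SeasonZone, float] = {
    SeasonZone.COLD: 1.35,
    SeasonZone.THERMONEUTRAL: 1.15,
    SeasonZone.HEAT: 1.05,
}

#: Lag coefficient gamma by consecutive-cold-day breakpoint.
DEFAULT_GAMMA_TABLE: dict[int, float] = {1: 0.85, 3: 0.51, 5: 0.32}


@dataclass
class Environment:
    """Ambient context of one animal-day.

    Parameters
    ----------
    ambient_temp : float
        Ambient temperature ET in degC.
    consecutive_cold_days : int
        Number of successive days (including today when today is cold) with
        ET below the thermoneutral lower limit.  Feeds the lag damping.
    humidity : float, optional
        Relative humidity in percent.  Parsed and carried for forward
        compatibility; no operation currently consumes it.
    """

    ambient_temp: float
    consecutive_cold_days: int = 0
    humidity: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ambient_temp):
            raise InvalidInputError(f"ambient_temp must be finite, got {self.ambient_temp!r}")
        if self.consecutive_cold_days < 0:
            raise InvalidInputError(
                f"consecutive_cold_days must be >= 0, got {self.consecutive_cold_days}"
            )


def classify_season(et: float, t_low: float = 15.0, t_high: float = 28.0) -> SeasonZone:
    """Classify a daily temperature into its season zone.

    Boundaries are inclusive to the thermoneutral zone: exactly ``t_low`` or
    ``t_high`` is thermoneutral (the zone limits are stated as strict
    inequalities, "<15" and ">28").
    """
    if not math.isfinite(et):
        raise InvalidInputError(f"temperature must be finite, got {et!r}")
    if not t_low < t_high:
        raise InvalidInputError(f"need t_low < t_high, got {t_low} >= {t_high}")
    if et < t_low:
        return SeasonZone.COLD
    if et > t_high:
        return SeasonZone.HEAT
    return SeasonZone.THERMONEUTRAL


def seasonal_factor(
    zone: SeasonZone, sf_table: Mapping[SeasonZone, float] | None = None
) -> float:
    """Look up the seasonal factor SF for a zone (default table above)."""
    table = DEFAULT_SF_TABLE if sf_table is None else sf_table
    zone = SeasonZone(zone)
    try:
        sf = table[zone]
    except KeyError:
        raise ConfigurationError(f"sf_table has no entry for zone {zone.value!r}") from None
    if sf <= 0:
        raise ConfigurationError(f"SF must be positive, got {sf} for zone {zone.value!r}")
    return float(sf)


def lag_coefficient(n: int, gamma_table: Mapping[int, float] | None = None) -> float:
    """Temperature-lag coefficient gamma for ``n`` consecutive cold days.

    Piecewise-constant step function, left-closed on the tabulated
    breakpoints: n = 0 -> 1.0 (no spell, no damping); thereafter the value at
    the largest breakpoint <= n applies, extending flat beyond the last one.
    """
    if n < 0:
        raise InvalidInputError(f"consecutive cold days must be >= 0, got {n}")
    table = DEFAULT_GAMMA_TABLE if gamma_table is None else gamma_table
    if not table:
        raise ConfigurationError("gamma_table is empty")
    gamma = 1.0
    for breakpoint_n in sorted(table):
        if n >= breakpoint_n:
            gamma = float(table[breakpoint_n])
        else:
            break
    if not 0.0 < gamma <= 1.0:
        raise ConfigurationError(f"gamma values must lie in (0, 1], got {gamma}")
    return gamma


def apply_lag(theoretical_compensation: float, gamma: float) -> float:
    """Damp a theoretical cold compensation (any units) by gamma."""
    if not 0.0 < gamma <= 1.0:
        raise InvalidInputError(f"gamma must lie in (0, 1], got {gamma}")
    return gamma * theoretical_compensation


def temperature_adjustment(
    env: Environment, state_w075: float, params: "ModelParameters"
) -> float:
    """Temperature term of the energy equation, in kJ/d.

    Deviation-from-threshold form, scaled by metabolic body weight::

        cold:  +gamma(n) * k3_cold * (t_low - ET) * W^0.75
        heat:  -k3_heat * (ET - t_high) * W^0.75
        thermoneutral: 0

    Positive below ``t_low`` (extra maintenance energy), negative above
    ``t_high`` (reduced intake/metabolism), continuous and zero at both
    thresholds.  The lag damping applies to the cold branch only.
    """
    zone = classify_season(env.ambient_temp, params.t_low, params.t_high)
    if zone is SeasonZone.COLD:
        gamma = lag_coefficient(env.consecutive_cold_days, params.gamma_table)
        return apply_lag(
            params.k3_cold * (params.t_low - env.ambient_temp) * state_w075, gamma
        )
    if zone is SeasonZone.HEAT:
        return -params.k3_heat * (env.ambient_temp - params.t_high) * state_w075
    return 0.0


def consecutive_cold_days(
    temps: Sequence[float] | Iterable[float], t_low: float = 15.0
) -> np.ndarray:
    """Per-day consecutive-cold-day counts for a daily temperature series.

    Day ``i`` gets the count of immediately preceding days, inclusive of day
    ``i`` itself, with ET < ``t_low``; a day at or above ``t_low`` resets the
    count to zero.
    """
    et = np.asarray(list(temps) if not isinstance(temps, np.ndarray) else temps, float)
    out = np.zeros(et.shape[0], dtype=int)
    run = 0
    for i, v in enumerate(et):
        run = run + 1 if v < t_low else 0
        out[i] = run
    return out
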