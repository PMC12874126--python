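"""Model parameters of the coupled energy/protein requirement equations.

The daily metabolizable-energy requirement (kJ/d) is factorial::

    ME = SF * m * alpha_eff * W^0.75  +  beta_eff * BGW  +  T(ET, n)  +  BC

with W the live weight (kg), W^0.75 the metabolic body weight, BGW the daily
gain (g/d), SF the seasonal factor, m the breed maintenance multiplier,
T the lag-damped temperature term and BC an additive breed/energy offset.
(alpha_eff, beta_eff) are the maintenance/growth coefficients after the
rapid-growth reallocation: when BGW exceeds ``rapid_growth_threshold``
(35 g/d) the maintenance coefficient drops 18 % and the growth coefficient
rises 24 %, reflecting energy reallocation toward protein synthesis.

The daily crude-protein requirement (g/d) is::

    CP = a_z * W^0.75  +  b_z * BGW  +  SF * AAI

where AAI is the dimensionless amino-acid balance index and (a_z, b_z) carry
the seasonal coefficient shifts: in the heat (summer) zone the maintenance
coefficient falls 18 % and the growth coefficient rises 23 % relative to the
winter values stored here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

from .environment import DEFAULT_GAMMA_TABLE, DEFAULT_SF_TABLE, SeasonZone
from .exceptions import ConfigurationError, InvalidInputError

__all__ = ["ModelParameters", "FITTABLE_PARAMETERS"]

#: Scalar coefficients the calibration engine may free.
FITTABLE_PARAMETERS = ("alpha", "beta", "k3_cold", "k3_heat", "a", "b", "bc")


@dataclass
class ModelParameters:
    """All coefficients of the coupled requirement equations.

    Attributes
    ----------
    alpha : float
        Maintenance-energy coefficient, kJ/(kg^0.75 d).  Default 541.7, the
        thermoneutral baseline.
    beta : float
        Growth-energy coefficient, kJ/g gain.  Default 19.86.
    k3_cold, k3_heat : float
        Cold-compensation / heat-reduction coefficients, kJ/(kg^0.75 degC d),
        both >= 0; they multiply the deviation of ET below t_low (above
        t_high).  No published magnitude exists; the defaults anchor the
        theoretical +12 % maintenance compensation of a one-day cold spell at
        a representative 5 degC deviation (0.12 * 541.7 / 5 ~ 13) with a
        smaller heat slope.  Both are routinely re-estimated by calibration.
    bc : float
        Additive energy offset, kJ/d (0 for the Cherry Valley baseline);
        freed during calibration it absorbs flock-level level shifts.
    a : float
        Maintenance-protein coefficient, g/(kg^0.75 d).  Default 6.013; the
        summer-published value, which the seasonal shift machinery treats as
        the unmodified (non-summer) stored coefficient — see the seasonal
        modifiers below.
    b : float
        Growth-protein coefficient, g/g gain.  Default 0.18, an engineering
        default of the right physiological magnitude (protein content of
        gain); configurable, and a routine target of calibration.
    sf_table : mapping SeasonZone -> float
        Seasonal factor by zone (defaults 1.35 / 1.15 / 1.05).
    gamma_table : mapping int -> float
        Temperature-lag step table (defaults {1: 0.85, 3: 0.51, 5: 0.32}).
    rapid_growth_threshold : float
        BGW (g/d) above which the adaptive reallocation fires.  Default 35.
    alpha_adjust, beta_adjust : float
        Fractional changes to alpha / beta during rapid growth
        (defaults -0.18 and +0.24).
    summer_maint_cut, summer_bgw_boost : float
        Fractional changes to the protein coefficients a / b in the heat zone
        (defaults -0.18 and +0.23).
    t_low, t_high : float
        Thermoneutral band limits, degC (defaults 15 and 28).
    """

    alpha: float = 541.7
    beta: float = 19.86
    k3_cold: float = 13.0
    k3_heat: float = 8.0
    bc: float = 0.0
    a: float = 6.013
    b: float = 0.18
    sf_table: Mapping[SeasonZone, float] = field(
        default_factory=lambda: dict(DEFAULT_SF_TABLE)
    )
    gamma_table: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GAMMA_TABLE)
    )
    rapid_growth_threshold: float = 35.0
    alpha_adjust: float = -0.18
    beta_adjust: float = 0.24
    summer_bgw_boost: float = 0.23
    summer_maint_cut: float = -0.18
    t_low: float = 15.0
    t_high: float = 28.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidInputError(
                f"alpha and beta must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.k3_cold < 0 or self.k3_heat < 0:
            raise InvalidInputError("k3_cold and k3_heat must be >= 0")
        if self.a <= 0 or self.b <= 0:
            raise InvalidInputError("protein coefficients a and b must be positive")
        if self.rapid_growth_threshold < 0:
            raise InvalidInputError("rapid_growth_threshold must be >= 0")
        if not self.t_low < self.t_high:
            raise InvalidInputError(
                f"need t_low < t_high, got {self.t_low} >= {self.t_high}"
            )
        # normalise keys so yaml-loaded string zones work
        self.sf_table = {SeasonZone(k): float(v) for k, v in dict(self.sf_table).items()}
        for zone in SeasonZone:
            if zone not in self.sf_table:
                raise ConfigurationError(f"sf_table missing zone {zone.value!r}")
            if self.sf_table[zone] <= 0:
                raise ConfigurationError(f"SF for {zone.value!r} must be positive")
        self.gamma_table = {int(k): float(v) for k, v in dict(self.gamma_table).items()}
        for n, g in self.gamma_table.items():
            if not 0.0 < g <= 1.0:
                raise ConfigurationError(f"gamma_table[{n}] = {g} outside (0, 1]")

    # -- calibration plumbing ------------------------------------------------

    def get(self, name: str) -> float:
        """Value of a fittable scalar coefficient by name."""
        if name not in FITTABLE_PARAMETERS:
            raise ConfigurationError(f"{name!r} is not a fittable parameter")
        return float(getattr(self, name))

    def with_values(self, **updates: float) -> "ModelParameters":
        """Return a copy with the named fittable coefficients replaced."""
        for name in updates:
            if name not in FITTABLE_PARAMETERS:
                raise ConfigurationError(f"{name!r} is not a fittable parameter")
        return replace(self, **updates)

    def to_dict(self) -> dict:
        """Plain-python representation (yaml/json serialisable)."""
        d = dataclasses.asdict(self)
        d["sf_table"] = {z.value: v for z, v in self.sf_table.items()}
        d["gamma_table"] = dict(self.gamma_table)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        return cls(**dict(d))
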