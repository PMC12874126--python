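"""Diet description, amino-acid balance index and energy-protein ratio checks.

The amino-acid balance index (AAI) is the dietary lysine:methionine ratio
normalised by a reference balance (default 3.0, the midpoint of the 2.8:1 to
3.2:1 span over which the model was stress-tested): AAI = 1 at the reference
balance, above 1 when lysine is relatively abundant.  Seasonal regulation
shifts the balance by the breed's kappa: in cold weather methionine is
increased (AAI falls by the factor 1 - kappa) to support maintenance
metabolism; in heat lysine is increased (AAI rises by 1 + kappa) against
heat-stress muscle breakdown.

The energy-protein ratio of a feed is its ME density (kcal/kg) divided by its
CP concentration (%); the optimal interval is 125-135:1, and protein
utilisation degrades at energy densities above 2950 kcal/kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .environment import SeasonZone
from .exceptions import InvalidInputError

__all__ = [
    "DietSpec",
    "DEFAULT_REFERENCE_RATIO",
    "EP_OPTIMAL_INTERVAL",
    "ENERGY_DENSITY_THRESHOLD",
    "compute_aai",
    "seasonal_aai_adjustment",
    "check_ep_interval",
    "energy_density_warning",
]

DEFAULT_REFERENCE_RATIO = 3.0
EP_OPTIMAL_INTERVAL = (125.0, 135.0)
ENERGY_DENSITY_THRESHOLD = 2950.0  # kcal/kg
_LYS_MET_SANITY_BAND = (1.5, 5.0)


@dataclass
class DietSpec:
    """A feed: ME density (kcal/kg), CP (%), lysine and methionine (% of diet)."""

    me_density: float
    cp_pct: float
    lysine_pct: float
    methionine_pct: float

    def __post_init__(self) -> None:
        for name in ("me_density", "cp_pct", "lysine_pct", "methionine_pct"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        ratio = self.lysine_pct / self.methionine_pct
        lo, hi = _LYS_MET_SANITY_BAND
        if not lo <= ratio <= hi:
            raise InvalidInputError(
                f"lysine:methionine ratio {ratio:.2f} outside sanity band [{lo}, {hi}]"
            )

    @property
    def lys_met_ratio(self) -> float:
        return self.lysine_pct / self.methionine_pct


def compute_aai(
    lysine_pct: float,
    methionine_pct: float,
    reference_ratio: float = DEFAULT_REFERENCE_RATIO,
) -> float:
    """Amino-acid balance index: (lysine/methionine) / reference_ratio.

    Dimensionless, equal to 1 at the reference balance; depends on the
    lysine and methionine levels only through their ratio.
    """
    if methionine_pct <= 0:
        raise InvalidInputError("methionine_pct must be positive")
    if lysine_pct <= 0:
        raise InvalidInputError("lysine_pct must be positive")
    if reference_ratio <= 0:
        raise InvalidInputError("reference_ratio must be positive")
    return (lysine_pct / methionine_pct) / reference_ratio


def seasonal_aai_adjustment(aai: float, zone: SeasonZone, kappa: float) -> float:
    """Seasonal shift of the amino-acid balance by the breed's kappa.

    cold -> aai * (1 - kappa); heat -> aai * (1 + kappa); thermoneutral
    unchanged.  A kappa outside the published [0.12, 0.35] envelope is
    accepted with a warning (kappa = 0 is then the exact identity).
    """
    if aai <= 0:
        raise InvalidInputError(f"aai must be positive, got {aai}")
    if not 0.12 <= kappa <= 0.35:
        warnings.warn(
            f"kappa = {kappa} outside the published envelope [0.12, 0.35]",
            stacklevel=2,
        )
    if kappa >= 1.0:
        raise InvalidInputError("kappa >= 1 would drive the cold-zone AAI non-positive")
    zone = SeasonZone(zone)
    if zone is SeasonZone.COLD:
        return aai * (1.0 - kappa)
    if zone is SeasonZone.HEAT:
        return aai * (1.0 + kappa)
    return aai


def check_ep_interval(ratio: float) -> str:
    """Classify an energy-protein ratio against the optimal 125-135:1 band:
    returns ``"below"``, ``"optimal"`` or ``"above"`` (bounds inclusive)."""
    if ratio <= 0:
        raise InvalidInputError(f"ratio must be positive, got {ratio}")
    lo, hi = EP_OPTIMAL_INTERVAL
    if ratio < lo:
        return "below"
    if ratio > hi:
        return "above"
    return "optimal"


def energy_density_warning(me_density: float) -> bool:
    """True when the feed's energy density exceeds 2950 kcal/kg, the point
    past which protein utilisation declines (strict inequality)."""
    if me_density <= 0:
        raise InvalidInputError(f"me_density must be positive, got {me_density}")
    return me_density > ENERGY_DENSITY_THRESHOLD
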