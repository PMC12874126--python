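"""The coupled daily requirement equations and their orchestration.

``daily_requirement`` assembles one animal-day's metabolizable-energy (ME,
kJ/d) and crude-protein (CP, g/d) requirement from the animal state, the
thermal environment, the breed profile and (optionally) the diet:

* season zone and seasonal factor SF from :mod:`duckreq.environment`;
* the lag-damped temperature term from the same module;
* the breed maintenance multiplier and additive offset from
  :mod:`duckreq.breeds`;
* the seasonally adjusted amino-acid balance index from :mod:`duckreq.diet`
  (AAI defaults to 1 when no diet is supplied).

SF multiplies the maintenance-energy term (the winter maintenance baseline is
the thermoneutral 541.7 kJ/kg^0.75 scaled by 1.35) and, in the protein
equation, the AAI term.  ``predict_frame`` is the vectorised equivalent over
a flock-record DataFrame; it is the workhorse of calibration and simulation
and is tested to agree row-wise with ``daily_requirement``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import breeds as breeds_mod
from . import diet as diet_mod
from .breeds import BreedProfile, breed_energy_multiplier
from .diet import DietSpec, compute_aai, seasonal_aai_adjustment
from .environment import (
    Environment,
    SeasonZone,
    classify_season,
    consecutive_cold_days,
    lag_coefficient,
    seasonal_factor,
    temperature_adjustment,
)
from .exceptions import InvalidInputError
from .params import ModelParameters

__all__ = [
    "DuckState",
    "RequirementResult",
    "effective_growth_coefficients",
    "compute_me",
    "compute_cp",
    "daily_requirement",
    "energy_protein_ratio",
    "predict_frame",
]


@dataclass
class DuckState:
    """One animal-day: live weight W (kg), daily gain BGW (g/d), age (d)."""

    body_weight: float
    daily_gain: float = 0.0
    age: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.body_weight) and self.body_weight > 0):
            raise InvalidInputError(f"body_weight must be positive, got {self.body_weight!r}")
        if not (math.isfinite(self.daily_gain) and self.daily_gain >= 0):
            raise InvalidInputError(f"daily_gain must be >= 0, got {self.daily_gain!r}")
        if self.age < 0:
            raise InvalidInputError(f"age must be >= 0, got {self.age}")

    @property
    def metabolic_weight(self) -> float:
        """Metabolic body weight W^0.75, kg^0.75."""
        return self.body_weight ** 0.75


@dataclass
class RequirementResult:
    """A computed daily requirement with its component breakdown.

    ``me_components`` holds maintenance / growth / temperature / breed energy
    terms (kJ/d); ``cp_components`` holds maintenance / growth / aa_balance
    protein terms (g/d).  Each total equals the sum of its components.
    ``ep_ratio`` is populated only when a diet was supplied.
    """

    me: float
    cp: float
    zone: SeasonZone
    me_components: dict[str, float] = field(default_factory=dict)
    cp_components: dict[str, float] = field(default_factory=dict)
    ep_ratio: float | None = None


def effective_growth_coefficients(
    bgw: float, params: ModelParameters
) -> tuple[float, float]:
    """(alpha_eff, beta_eff) after the adaptive rapid-growth reallocation.

    Above the rapid-growth threshold (default 35 g/d) the maintenance
    coefficient's marginal contribution drops by 18 % while the growth
    coefficient's weight rises by 24 %; below it the stored pair is returned
    unchanged.
    """
    if not (math.isfinite(bgw) and bgw >= 0):
        raise InvalidInputError(f"bgw must be >= 0, got {bgw!r}")
    if bgw > params.rapid_growth_threshold:
        return (
            params.alpha * (1.0 + params.alpha_adjust),
            params.beta * (1.0 + params.beta_adjust),
        )
    return params.alpha, params.beta


def compute_me(
    state: DuckState,
    env_adjustment: float,
    sf_m: float,
    params: ModelParameters,
    breed_offset: float = 0.0,
    maintenance_multiplier: float = 1.0,
) -> float:
    """Daily metabolizable-energy requirement, kJ/d.

    ``sf_m * m * alpha_eff * W^0.75 + beta_eff * BGW + env_adjustment +
    breed_offset`` with ``m`` the breed maintenance multiplier (1 for the
    baseline breed) and the effective coefficients from
    :func:`effective_growth_coefficients`.
    """
    return sum(
        _me_components(
            state, env_adjustment, sf_m, params, breed_offset, maintenance_multiplier
        ).values()
    )


def _me_components(
    state: DuckState,
    env_adjustment: float,
    sf_m: float,
    params: ModelParameters,
    breed_offset: float,
    maintenance_multiplier: float,
) -> dict[str, float]:
    for name, v in (("env_adjustment", env_adjustment), ("sf_m", sf_m),
                    ("breed_offset", breed_offset),
                    ("maintenance_multiplier", maintenance_multiplier)):
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")
    if sf_m <= 0:
        raise InvalidInputError(f"sf_m must be positive, got {sf_m}")
    alpha_eff, beta_eff = effective_growth_coefficients(state.daily_gain, params)
    maintenance = sf_m * alpha_eff * state.metabolic_weight
    # the breed component carries the additive offset plus the multiplier's
    # excess over baseline, so components still sum to the total
    return {
        "maintenance": maintenance,
        "growth": beta_eff * state.daily_gain,
        "temperature": env_adjustment,
        "breed": breed_offset + (maintenance_multiplier - 1.0) * maintenance,
    }


def compute_cp(
    state: DuckState,
    sf: float,
    aai: float,
    params: ModelParameters,
    zone: SeasonZone = SeasonZone.THERMONEUTRAL,
) -> float:
    """Daily crude-protein requirement, g/d.

    ``a_z * W^0.75 + b_z * BGW + sf * aai`` where (a_z, b_z) carry the summer
    coefficient shifts in the heat zone (maintenance -18 %, growth +23 %) and
    the stored winter values otherwise.
    """
    return sum(_cp_components(state, sf, aai, params, zone).values())


def _cp_components(
    state: DuckState,
    sf: float,
    aai: float,
    params: ModelParameters,
    zone: SeasonZone,
) -> dict[str, float]:
    if not (math.isfinite(sf) and sf > 0):
        raise InvalidInputError(f"sf must be positive and finite, got {sf!r}")
    if not (math.isfinite(aai) and aai > 0):
        raise InvalidInputError(f"aai must be positive and finite, got {aai!r}")
    a_z, b_z = params.a, params.b
    if SeasonZone(zone) is SeasonZone.HEAT:
        a_z *= 1.0 + params.summer_maint_cut
        b_z *= 1.0 + params.summer_bgw_boost
    return {
        "maintenance": a_z * state.metabolic_weight,
        "growth": b_z * state.daily_gain,
        "aa_balance": sf * aai,
    }


def energy_protein_ratio(me_density: float, cp_pct: float) -> float:
    """Energy-protein ratio of a feed: ME density (kcal/kg) / CP (%)."""
    if cp_pct <= 0:
        raise InvalidInputError(f"cp_pct must be positive, got {cp_pct}")
    if not math.isfinite(me_density):
        raise InvalidInputError(f"me_density must be finite, got {me_density!r}")
    return me_density / cp_pct


def daily_requirement(
    state: DuckState,
    env: Environment,
    breed: BreedProfile | str | None = None,
    diet: DietSpec | None = None,
    params: ModelParameters | None = None,
) -> RequirementResult:
    """Full daily ME/CP requirement for one animal-day.

    ``breed`` may be a profile, a registry label, or None (Cherry Valley
    baseline).  Without a diet, AAI starts at 1 before the seasonal
    adjustment and ``ep_ratio`` is None.
    """
    params = ModelParameters() if params is None else params
    if breed is None:
        profile = breeds_mod.builtin_profiles()["cherry_valley"]
    elif isinstance(breed, str):
        profile = breeds_mod.get_profile(breed)
    else:
        profile = breed

    zone = classify_season(env.ambient_temp, params.t_low, params.t_high)
    sf = seasonal_factor(zone, params.sf_table)
    temp_term = temperature_adjustment(env, state.metabolic_weight, params)

    aai = 1.0 if diet is None else compute_aai(diet.lysine_pct, diet.methionine_pct)
    aai = seasonal_aai_adjustment(aai, zone, profile.season_aa_interaction)

    multiplier = breed_energy_multiplier(profile, zone)
    offset = params.bc + profile.bc

    me_parts = _me_components(state, temp_term, sf, params, offset, multiplier)
    cp_parts = _cp_components(state, sf, aai, params, zone)

    ep = None
    if diet is not None:
        ep = energy_protein_ratio(diet.me_density, diet.cp_pct)

    return RequirementResult(
        me=sum(me_parts.values()),
        cp=sum(cp_parts.values()),
        zone=zone,
        me_components=me_parts,
        cp_components=cp_parts,
        ep_ratio=ep,
    )


# -- vectorised path ---------------------------------------------------------

def predict_frame(
    df: pd.DataFrame,
    params: ModelParameters | None = None,
    registry: Mapping[str, BreedProfile] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (ME, CP) predictions over a flock-record DataFrame.

    Expects the flock CSV schema columns ``weight_kg``, ``bgw_g_per_d``,
    ``et_c`` plus optional ``breed``, ``lysine_pct``/``methionine_pct`` and
    ``cold_days`` (consecutive cold days; recomputed per duck from the
    temperature series when absent).  Agrees row-wise with
    :func:`daily_requirement`.
    """
    params = ModelParameters() if params is None else params
    registry = breeds_mod.builtin_profiles() if registry is None else registry

    w = df["weight_kg"].to_numpy(float)
    bgw = df["bgw_g_per_d"].to_numpy(float)
    et = df["et_c"].to_numpy(float)
    if not (np.isfinite(w).all() and np.isfinite(bgw).all() and np.isfinite(et).all()):
        raise InvalidInputError("weight_kg, bgw_g_per_d and et_c must be finite")
    if (w <= 0).any() or (bgw < 0).any():
        raise InvalidInputError("need weight_kg > 0 and bgw_g_per_d >= 0")
    w75 = w ** 0.75

    cold = et < params.t_low
    heat = et > params.t_high

    if "cold_days" in df.columns:
        n_cold = df["cold_days"].to_numpy(int)
    else:
        n_cold = _grouped_cold_days(df, et, params.t_low)
    gamma = np.ones(len(df))
    if cold.any():
        breaks = np.array(sorted(params.gamma_table))
        values = np.array([params.gamma_table[int(b)] for b in breaks])
        idx = np.searchsorted(breaks, n_cold[cold], side="right") - 1
        gamma[cold] = np.where(idx >= 0, values[np.clip(idx, 0, None)], 1.0)

    sf = np.where(
        cold,
        params.sf_table[SeasonZone.COLD],
        np.where(heat, params.sf_table[SeasonZone.HEAT], params.sf_table[SeasonZone.THERMONEUTRAL]),
    )

    rapid = bgw > params.rapid_growth_threshold
    alpha_eff = params.alpha * np.where(rapid, 1.0 + params.alpha_adjust, 1.0)
    beta_eff = params.beta * np.where(rapid, 1.0 + params.beta_adjust, 1.0)

    if "breed" in df.columns:
        labels = df["breed"].fillna("cherry_valley")
    else:
        labels = pd.Series("cherry_valley", index=df.index)
    profs = {name: breeds_mod.get_profile(name, registry) for name in labels.unique()}
    mult = np.where(
        cold,
        labels.map({n: breed_energy_multiplier(p, SeasonZone.COLD) for n, p in profs.items()}).to_numpy(float),
        labels.map({n: breed_energy_multiplier(p, SeasonZone.THERMONEUTRAL) for n, p in profs.items()}).to_numpy(float),
    )
    offset = params.bc + labels.map({n: p.bc for n, p in profs.items()}).to_numpy(float)
    kappa = labels.map({n: p.season_aa_interaction for n, p in profs.items()}).to_numpy(float)

    temp_term = (
        gamma * params.k3_cold * np.maximum(params.t_low - et, 0.0) * w75
        - params.k3_heat * np.maximum(et - params.t_high, 0.0) * w75
    )

    me = sf * mult * alpha_eff * w75 + beta_eff * bgw + temp_term + offset

    if "lysine_pct" in df.columns and "methionine_pct" in df.columns:
        lys = df["lysine_pct"].to_numpy(float)
        met = df["methionine_pct"].to_numpy(float)
        have = np.isfinite(lys) & np.isfinite(met) & (met > 0)
        aai = np.where(have, np.divide(lys, np.where(met > 0, met, 1.0)) / diet_mod.DEFAULT_REFERENCE_RATIO, 1.0)
    else:
        aai = np.ones(len(df))
    aai = aai * np.where(cold, 1.0 - kappa, np.where(heat, 1.0 + kappa, 1.0))

    a_eff = params.a * np.where(heat, 1.0 + params.summer_maint_cut, 1.0)
    b_eff = params.b * np.where(heat, 1.0 + params.summer_bgw_boost, 1.0)
    cp = a_eff * w75 + b_eff * bgw + sf * aai
    return me, cp


def _grouped_cold_days(df: pd.DataFrame, et: np.ndarray, t_low: float) -> np.ndarray:
    """Consecutive-cold-day scan per duck (by house_id/duck_id, day order)."""
    keys = [k for k in ("house_id", "duck_id") if k in df.columns]
    if not keys:
        return consecutive_cold_days(et, t_low)
    out = np.zeros(len(df), dtype=int)
    order_df = df.reset_index(drop=True)
    for _, grp in order_df.groupby(keys, sort=False):
        if "day" in grp.columns:
            grp = grp.sort_values("day", kind="stable")
        idx = grp.index.to_numpy()
        out[idx] = consecutive_cold_days(et[idx], t_low)
    return out
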