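"""Synthetic flock-data generator.

Emulates the statistical structure the requirement model assumes, so the
calibration engine and the full pipeline can be exercised and validated by
parameter recovery without any external dataset:

* Gompertz growth backbone ``W(t) = A * exp(-exp(-k (t - t_i)))`` — the
  standard sigmoid for poultry growth — with per-duck lognormal
  heterogeneity on the asymptotic weight ``A`` (CV 5 %).  The defaults
  (A = 3.2 kg, k = 0.08 /d, inflection day 18, 42-day cycle) give peak daily
  gains well above the 35 g/d rapid-growth threshold, so the adaptive
  coefficient reallocation is exercised.
* Scenario temperature series: constant-mean winter (8 degC), summer
  (31 degC), transition (21 degC) or an annual sinusoid spanning all three
  zones, plus Gaussian noise; consecutive cold days by the documented scan.
* Observations: the model-true ME/CP requirement of each animal-day times
  independent multiplicative noise ``1 + eps``, ``eps ~ N(0, sd)`` —
  requirements are positive and heteroscedastic, so multiplicative noise is
  the natural error model.

Everything is driven by one seeded generator: a config plus seed fixes every
byte of the emitted CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .core import predict_frame
from .environment import consecutive_cold_days
from .exceptions import InvalidInputError
from .params import ModelParameters

__all__ = ["SimulationConfig", "growth_trajectory", "temperature_series", "generate_observations"]

SCENARIO_MEANS = {"winter": 8.0, "summer": 31.0, "transition": 21.0}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated flock.

    ``seed`` is mandatory: there is no unseeded path through the generator.
    """

    seed: int
    n_ducks: int = 200
    n_days: int = 42
    asymptotic_weight: float = 3.2  # kg
    growth_rate: float = 0.08  # /d
    inflection_day: float = 18.0  # d
    heterogeneity_cv: float = 0.05  # lognormal CV on A across ducks
    scenario: str = "winter"  # winter | summer | transition | annual-sinusoid
    temp_noise_sd: float = 3.0  # degC
    obs_noise_sd: float = 0.05  # multiplicative fraction
    breed: str = "cherry_valley"
    params: ModelParameters = field(default_factory=ModelParameters)
    house_id: str = "H1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidInputError("seed is mandatory")
        if self.n_ducks < 1 or self.n_days < 1:
            raise InvalidInputError("n_ducks and n_days must be >= 1")
        if min(self.asymptotic_weight, self.growth_rate) <= 0 or self.inflection_day <= 0:
            raise InvalidInputError("growth curve parameters must be positive")
        if self.temp_noise_sd < 0 or self.obs_noise_sd < 0 or self.heterogeneity_cv < 0:
            raise InvalidInputError("noise levels must be >= 0")
        if self.scenario not in (*SCENARIO_MEANS, "annual-sinusoid"):
            raise InvalidInputError(f"unknown scenario {self.scenario!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _gompertz(t: np.ndarray, a: float, k: float, ti: float) -> np.ndarray:
    return a * np.exp(-np.exp(-k * (t - ti)))


def growth_trajectory(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-duck, per-day weights W (kg) and gains BGW (g/d).

    Returns arrays of shape (n_ducks, n_days) for days 1..n_days;
    BGW(t) = W(t) - W(t-1) scaled to g/d.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cv = config.heterogeneity_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        a = config.asymptotic_weight * rng.lognormal(-0.5 * sigma**2, sigma, config.n_ducks)
    else:
        a = np.full(config.n_ducks, config.asymptotic_weight)
    t = np.arange(0, config.n_days + 1, dtype=float)
    w_full = _gompertz(t[None, :], a[:, None], config.growth_rate, config.inflection_day)
    w = w_full[:, 1:]
    bgw = np.diff(w_full, axis=1) * 1000.0
    return w, bgw


def temperature_series(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Daily ambient temperatures and consecutive-cold-day counts.

    Constant scenario mean (winter 8, summer 31, transition 21 degC) or an
    annual sinusoid (mean 18, amplitude 14 degC, coldest at day 0) evaluated
    on days 1..n_days, plus N(0, temp_noise_sd) noise.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    days = np.arange(1, config.n_days + 1, dtype=float)
    if config.scenario == "annual-sinusoid":
        mean = 18.0 - 14.0 * np.cos(2.0 * np.pi * days / 365.0)
    else:
        mean = np.full(config.n_days, SCENARIO_MEANS[config.scenario])
    et = mean + rng.normal(0.0, config.temp_noise_sd, config.n_days)
    return et, consecutive_cold_days(et, config.params.t_low)


def generate_observations(
    config: SimulationConfig, csv_path: str | Path | None = None
) -> ObservationSet:
    """Simulate a flock and return its records as an :class:`ObservationSet`.

    One shared house temperature series; per-duck growth; observed ME/CP are
    the model-true requirements times independent multiplicative noise.  The
    frame follows the flock CSV schema (including the precomputed
    ``cold_days`` column); ``csv_path`` optionally writes it.
    """
    rng = np.random.default_rng(config.seed)
    w, bgw = growth_trajectory(config, rng)
    et, cold = temperature_series(config, rng)

    n, d = config.n_ducks, config.n_days
    frame = pd.DataFrame(
        {
            "house_id": config.house_id,
            "duck_id": np.repeat([f"D{i + 1:04d}" for i in range(n)], d),
            "day": np.tile(np.arange(1, d + 1), n),
            "weight_kg": w.ravel(),
            "bgw_g_per_d": np.maximum(bgw.ravel(), 0.0),
            "et_c": np.tile(et, n),
            "humidity_pct": np.round(np.tile(rng.uniform(50.0, 70.0, d), n), 1),
            "breed": config.breed,
            "cold_days": np.tile(cold, n),
        }
    )
    true_me, true_cp = predict_frame(frame, config.params)
    eps_me = rng.normal(0.0, config.obs_noise_sd, len(frame)) if config.obs_noise_sd else 0.0
    eps_cp = rng.normal(0.0, config.obs_noise_sd, len(frame)) if config.obs_noise_sd else 0.0
    frame["observed_me_kj"] = true_me * (1.0 + eps_me)
    frame["observed_cp_g"] = true_cp * (1.0 + eps_cp)

    obs = ObservationSet(frame, provenance="synthetic")
    if csv_path is not None:
        from .io import write_flock_csv

        write_flock_csv(frame, csv_path)
    return obs
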