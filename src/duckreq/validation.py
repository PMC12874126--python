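"""Worked-example suite: the printed table arithmetic the model must
reproduce exactly.

Each entry recomputes one published worked value from its printed inputs
through the package's own operations and compares after rounding half-up to
the printed number of decimals.  The ``duckreq validate`` subcommand runs
this suite; it doubles as the exact-arithmetic acceptance surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .breeds import energy_diff_coefficient, interaction_term
from .core import DuckState, compute_me, energy_protein_ratio
from .calibration import error_reduction
from .environment import apply_lag, lag_coefficient
from .params import ModelParameters
from .utils import round_half_up

__all__ = ["WorkedExample", "worked_examples", "run_worked_examples"]


@dataclass(frozen=True)
class WorkedExample:
    name: str
    description: str
    compute: Callable[[], float]
    expected: float
    decimals: int

    def run(self) -> dict:
        value = round_half_up(float(self.compute()), self.decimals)
        return {
            "name": self.name,
            "description": self.description,
            "computed": value,
            "expected": self.expected,
            "passed": value == round_half_up(self.expected, self.decimals),
        }


def _winter_maintenance() -> float:
    # thermoneutral maintenance baseline scaled by the winter SF for a 1 kg bird
    state = DuckState(body_weight=1.0, daily_gain=0.0)
    return compute_me(state, env_adjustment=0.0, sf_m=1.35, params=ModelParameters())


def worked_examples() -> list[WorkedExample]:
    return [
        WorkedExample(
            "beijing_interaction",
            "Beijing duck breed-environment interaction term lambda x delta",
            lambda: interaction_term(1.08, 0.85),
            0.92,
            2,
        ),
        WorkedExample(
            "muscovy_interaction",
            "Muscovy duck breed-environment interaction term lambda x delta",
            lambda: interaction_term(0.94, 1.12),
            1.05,
            2,
        ),
        WorkedExample(
            "cherry_valley_interaction",
            "Cherry Valley baseline interaction term",
            lambda: interaction_term(1.00, 1.00),
            1.00,
            2,
        ),
        WorkedExample(
            "lag_damped_compensation_n5",
            "Cold compensation after 5 consecutive cold days: 0.32 x 60 %",
            lambda: apply_lag(60.0, lag_coefficient(5)),
            19.2,
            1,
        ),
        WorkedExample(
            "muscovy_energy_diff_coeff",
            "Muscovy metabolic-energy difference coefficient, 1 - 0.12",
            lambda: energy_diff_coefficient(0.12),
            0.88,
            2,
        ),
        WorkedExample(
            "cmd_energy_diff_coeff",
            "CMD metabolic-energy difference coefficient, 1 - 0.10",
            lambda: energy_diff_coefficient(0.10),
            0.90,
            2,
        ),
        WorkedExample(
            "winter_maintenance_energy",
            "Winter maintenance ME for a 1 kg bird: 541.7 x 1.35 kJ/d",
            _winter_maintenance,
            731.3,
            1,
        ),
        WorkedExample(
            "ep_ratio_lower_bound",
            "Energy-protein ratio 2800 kcal/kg at 22.4 % CP",
            lambda: energy_protein_ratio(2800.0, 22.4),
            125.0,
            1,
        ),
        WorkedExample(
            "ep_ratio_optimised",
            "Energy-protein ratio 2730 kcal/kg at 21 % CP (inside 125-135:1)",
            lambda: energy_protein_ratio(2730.0, 21.0),
            130.0,
            1,
        ),
        WorkedExample(
            "error_reduction_ep125",
            "Error reduction at ratio 125:1, traditional 18 % vs dynamic 6 %",
            lambda: error_reduction(18.0, 6.0),
            67,
            0,
        ),
        WorkedExample(
            "protein_waste_reduction",
            "Protein waste rate reduction, 22 % vs 18.9 %",
            lambda: error_reduction(22.0, 18.9),
            14,
            0,
        ),
        WorkedExample(
            "conventional_allocation_ratio",
            "Conventional-growth energy allocation ratio 0.62 : 0.38",
            lambda: 0.62 / 0.38,
            1.63,
            2,
        ),
    ]


def run_worked_examples() -> list[dict]:
    """Run every worked example; returns a list of result dicts."""
    return [ex.run() for ex in worked_examples()]
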