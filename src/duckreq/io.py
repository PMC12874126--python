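"""Flock-record CSV I/O and configuration files.

Schema (comma-delimited, UTF-8, header mandatory; units fixed — no
autodetection):

====================  ==========================================
column                meaning / unit
====================  ==========================================
house_id              house label
duck_id               animal label
day                   day of the cycle (non-decreasing per duck)
weight_kg             live weight W, kg
bgw_g_per_d           daily gain BGW, g/d
et_c                  ambient temperature ET, degC
humidity_pct          optional, %
breed                 optional registry label (default cherry_valley)
lysine_pct            optional, % of diet
methionine_pct        optional, % of diet
observed_me_kj        optional observed ME requirement, kJ/d
observed_cp_g         optional observed CP requirement, g/d
cold_days             optional consecutive-cold-day count
====================  ==========================================
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ObservationSet
from .core import _grouped_cold_days
from .exceptions import InvalidInputError, SchemaError
from .params import ModelParameters

__all__ = ["read_flock_csv", "write_flock_csv", "load_simulation_config", "REQUIRED_COLUMNS"]

log = logging.getLogger("duckreq")

REQUIRED_COLUMNS = ("house_id", "duck_id", "day", "weight_kg", "bgw_g_per_d", "et_c")
NUMERIC_COLUMNS = (
    "day",
    "weight_kg",
    "bgw_g_per_d",
    "et_c",
    "humidity_pct",
    "lysine_pct",
    "methionine_pct",
    "observed_me_kj",
    "observed_cp_g",
    "cold_days",
)
OBSERVED_COLUMNS = ("observed_me_kj", "observed_cp_g")


def read_flock_csv(
    path: str | Path, strict: bool = True, t_low: float = 15.0
) -> ObservationSet | pd.DataFrame:
    """Read and validate a flock-record CSV.

    Returns an :class:`~duckreq.calibration.ObservationSet` when both
    observed requirement columns are present, otherwise the validated
    DataFrame.  ``strict=True`` raises on the first invariant violation;
    lenient mode drops offending rows and logs the count.  ``cold_days`` is
    computed per duck from the temperature series when absent.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"house_id": str, "duck_id": str, "breed": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")

    bad = pd.Series(False, index=df.index)
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        unparseable = coerced.isna() & df[col].notna()
        if unparseable.any():
            lineno = int(unparseable.idxmax()) + 2  # header + 1-based
            msg = f"{path.name}: unparseable {col!r} at line {lineno}"
            if strict:
                raise SchemaError(msg)
            log.warning(msg)
            bad |= unparseable
        df[col] = coerced

    invalid = (
        df["weight_kg"].isna()
        | (df["weight_kg"] <= 0)
        | df["bgw_g_per_d"].isna()
        | (df["bgw_g_per_d"] < 0)
        | df["et_c"].isna()
    )
    has_obs = all(c in df.columns for c in OBSERVED_COLUMNS)
    if has_obs:
        for c in OBSERVED_COLUMNS:
            invalid |= df[c].isna() | (df[c] <= 0)
    if strict and bool((invalid & ~bad).any()):
        lineno = int((invalid & ~bad).idxmax()) + 2
        raise InvalidInputError(f"{path.name}: invalid record at line {lineno}")
    bad |= invalid
    if bad.any():
        log.warning("%s: dropped %d invalid row(s) of %d", path.name, int(bad.sum()), len(df))
        df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise InvalidInputError(f"{path.name}: no valid records")

    day_ok = df.groupby(["house_id", "duck_id"], sort=False)["day"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    )
    if not day_ok.all():
        offender = day_ok[~day_ok].index[0]
        msg = f"{path.name}: day not non-decreasing for duck {offender}"
        if strict:
            raise InvalidInputError(msg)
        log.warning(msg)

    if "cold_days" not in df.columns:
        df["cold_days"] = _grouped_cold_days(df, df["et_c"].to_numpy(float), t_low)

    if has_obs:
        return ObservationSet.from_dataframe(df, provenance="file")
    return df


def write_flock_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write flock records (12 significant digits, lossless round trip)."""
    df.to_csv(path, index=False, float_format="%.12g")


def load_simulation_config(path: str | Path):
    """Build a :class:`~duckreq.synthetic.SimulationConfig` from a YAML/JSON
    file; a ``params`` sub-mapping overrides model coefficients."""
    from .synthetic import SimulationConfig

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    if "params" in raw and raw["params"] is not None:
        raw["params"] = ModelParameters.from_dict(raw["params"])
    return SimulationConfig(**raw)
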