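"""Vapor pressure and vapor pressure deficit from glasshouse weather records.

Saturation vapor pressure follows the Tetens-type exponential

    es(Ta) = 0.6108 * exp(17.27 * Ta / (Ta + 237.3))   [kPa]

with actual vapor pressure ea = (RH/100) * es and deficit VPD = es - ea.
All pressures are in kilopascals throughout; the 0.6108 leading constant
fixes that unit and no implicit conversion is ever performed.  Relative
humidity is accepted in percent (0-100), never as a fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "VpdResult",
    "saturation_vapor_pressure",
    "vpd",
    "vpd_table",
    "read_weather_csv",
]

#: Denominator offset of the Tetens formula; es diverges as Ta -> -237.3 °C.
_TETENS_OFFSET = 237.3

WEATHER_COLUMNS = ["day", "temp_c", "rh_pct", "solar_mj_m2"]


@dataclass(frozen=True)
class WeatherDay:
    """One day of glasshouse weather.

    Solar radiation is carried along for reporting but plays no role in the
    vapor pressure computation.
    """

    day: int
    temp_c: float
    rh_pct: float
    solar_mj_m2: float = float("nan")

    def __post_init__(self) -> None:
        if not self.rh_pct == self.rh_pct or not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError(
                f"relative humidity must be in [0, 100] percent, got {self.rh_pct!r}"
            )
        if self.temp_c <= -_TETENS_OFFSET:
            raise ValueError(
                f"temperature must exceed {-_TETENS_OFFSET} °C, got {self.temp_c!r}"
            )


@dataclass(frozen=True)
class VpdResult:
    """Saturation pressure, actual pressure and their deficit, all in kPa."""

    es_kpa: float
    ea_kpa: float
    vpd_kpa: float


def saturation_vapor_pressure(temp_c):
    """Saturation vapor pressure es in kPa at air temperature ``temp_c`` (°C).

    Strictly increasing in temperature; es(0 °C) = 0.6108 kPa exactly.
    Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any temperature is at or below -237.3 °C, where the exponent's
        denominator vanishes.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= -_TETENS_OFFSET):
        raise ValueError(f"temperature must exceed {-_TETENS_OFFSET} °C")
    es = 0.6108 * np.exp(17.27 * t / (t + _TETENS_OFFSET))
    return es if es.ndim else float(es)


def vpd(temp_c: float, rh_pct: float) -> VpdResult:
    """Vapor pressure deficit for one (temperature, relative humidity) pair.

    Returns es, ea = (RH/100)*es and vpd = es - ea.  The deficit is zero
    exactly at RH = 100 and equals es at RH = 0.

    Raises
    ------
    ValueError
        If ``rh_pct`` lies outside [0, 100].
    """
    if not (0.0 <= rh_pct <= 100.0):
        raise ValueError(f"relative humidity must be in [0, 100] percent, got {rh_pct!r}")
    es = saturation_vapor_pressure(temp_c)
    ea = (rh_pct / 100.0) * es
    return VpdResult(es_kpa=es, ea_kpa=ea, vpd_kpa=es * (1.0 - rh_pct / 100.0))


def vpd_table(weather: pd.DataFrame) -> pd.DataFrame:
    """Add ``es_kpa``, ``ea_kpa`` and ``vpd_kpa`` columns to a weather table.

    ``weather`` must carry ``temp_c`` and ``rh_pct`` columns (the schema of
    :func:`read_weather_csv`).  If every humidity value is <= 1 the series
    looks like fractions rather than percent; a warning is emitted but the
    values are used as given — silent unit guessing corrupts results.
    """
    missing = [c for c in ("temp_c", "rh_pct") if c not in weather.columns]
    if missing:
        raise ValueError(f"weather table missing columns: {missing}")
    rh = weather["rh_pct"].to_numpy(dtype=float)
    if len(rh) and np.nanmax(rh) <= 1.0:
        warnings.warn(
            "all rh_pct values are <= 1.0; relative humidity is expected in "
            "percent, not as a fraction — values used as given",
            UserWarning,
            stacklevel=2,
        )
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("rh_pct outside [0, 100]")
    out = weather.copy()
    es = saturation_vapor_pressure(weather["temp_c"].to_numpy(dtype=float))
    out["es_kpa"] = es
    out["ea_kpa"] = es * rh / 100.0
    out["vpd_kpa"] = es * (1.0 - rh / 100.0)
    return out


def read_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV with columns ``day,temp_c,rh_pct,solar_mj_m2``."""
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV {path} missing columns: {missing}")
    return df[WEATHER_COLUMNS].astype(
        {"day": int, "temp_c": float, "rh_pct": float, "solar_mj_m2": float}
    )
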