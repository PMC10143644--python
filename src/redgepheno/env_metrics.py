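"""Gravimetric evapotranspiration and vapour-pressure deficit.

Daily ET of a potted plant is the morning-to-morning weight difference,
corrected for any water restored after weighing:

    ET_d = (TW_d + water_added_d) − TW_{d+1}        [grams]

VPD (kPa) is saturation minus actual vapour pressure; es(T) uses the
Tetens formula and ea applies the concurrent relative humidity.  The daily
VPD averages the instantaneous deficits at the day's maximum and minimum
temperatures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "et_daily",
    "saturation_vp",
    "actual_vp",
    "vpd_instant",
    "vpd_daily",
    "read_weights_csv",
    "read_weather_csv",
]

# Tetens constants for water over a liquid surface
_TETENS_A = 0.6108  # kPa
_TETENS_B = 17.27
_TETENS_C = 237.3   # °C


def saturation_vp(t_c):
    """Saturation vapour pressure es(T), kPa (Tetens)."""
    t = np.asarray(t_c, dtype=float)
    if np.any(t <= -20) or np.any(t >= 60):
        raise ValueError("temperature outside (-20, 60) °C")
    out = _TETENS_A * np.exp(_TETENS_B * t / (t + _TETENS_C))
    return float(out) if np.isscalar(t_c) else out


def actual_vp(t_c, rh_pct):
    """Actual vapour pressure ea = es(T)·RH/100, kPa."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("RH must be in (0, 100] %")
    out = saturation_vp(t_c) * rh / 100.0
    return float(out) if np.isscalar(rh_pct) else out


def vpd_instant(t_c, rh_pct):
    """Instantaneous VPD = es − ea, kPa."""
    out = saturation_vp(t_c) - actual_vp(t_c, rh_pct)
    return float(out) if np.isscalar(t_c) and np.isscalar(rh_pct) else out


def et_daily(series: pd.DataFrame, use_water_added: bool = True) -> pd.DataFrame:
    """Daily ET per pot from a morning weight series.

    ``series`` columns: pot_id, date, weight_g and (optionally)
    water_added_g — water restored right after the weighing.  Returns one
    row per pot per day interval with the ET of the day starting at
    ``date``.  Negative ET (possible with balance noise) is kept, with a
    warning, so the telescoping mass balance stays exact.
    """
    df = series.copy()
    required = {"pot_id", "date", "weight_g"}
    if not required.issubset(df.columns):
        raise ValueError(f"weight series needs columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    if not use_water_added or "water_added_g" not in df.columns:
        df["water_added_g"] = 0.0
    df["water_added_g"] = df["water_added_g"].fillna(0.0)
    out = []
    for pot_id, grp in df.sort_values("date").groupby("pot_id", sort=False):
        if len(grp) < 2:
            raise ValueError(f"pot {pot_id}: need at least 2 days of weights")
        gaps = grp["date"].diff().dropna()
        if not (gaps == pd.Timedelta(days=1)).all():
            raise ValueError(f"pot {pot_id}: non-daily gaps in weight series")
        w = grp["weight_g"].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"pot {pot_id}: non-positive weights")
        added = grp["water_added_g"].to_numpy(dtype=float)
        et = (w[:-1] + added[:-1]) - w[1:]
        out.append(
            pd.DataFrame(
                {"pot_id": pot_id, "date": grp["date"].iloc[:-1].to_numpy(), "et_g": et}
            )
        )
    result = pd.concat(out, ignore_index=True)
    n_neg = int((result["et_g"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} negative daily ET value(s) retained", UserWarning, stacklevel=2)
    return result


def vpd_daily(records: pd.DataFrame) -> pd.DataFrame:
    """Daily VPD (kPa) from sub-daily RH/T records.

    For each calendar day, takes the records at the daily maximum and
    minimum temperature (with their concurrent RH) and averages the two
    instantaneous deficits.  Columns required: timestamp, rh_pct, t_c.
    """
    df = records.copy()
    required = {"timestamp", "rh_pct", "t_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"weather records need columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.empty:
        raise ValueError("no weather records")
    rows = []
    for day, grp in df.groupby(df["timestamp"].dt.normalize()):
        if len(grp) < 2:
            raise ValueError(f"{day.date()}: need at least 2 records per day")
        hot = grp.loc[grp["t_c"].idxmax()]
        cold = grp.loc[grp["t_c"].idxmin()]
        vpd = 0.5 * (
            vpd_instant(float(hot["t_c"]), float(hot["rh_pct"]))
            + vpd_instant(float(cold["t_c"]), float(cold["rh_pct"]))
        )
        rows.append({"date": day, "vpd_kpa": vpd, "t_max_c": float(hot["t_c"]),
                     "t_min_c": float(cold["t_c"])})
    return pd.DataFrame(rows)


def read_weights_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"pot_id", "date", "weight_g"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "rh_pct", "t_c"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
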