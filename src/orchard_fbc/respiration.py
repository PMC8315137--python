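"""Fruit dark respiration as a function of development stage and temperature.

Dark respiration of detached fruit, measured in the lab over a grid of days
after full bloom (DAFB) and temperatures, is modelled log-linearly:

    ln Rd = b0 + b1 * DAFB + b2 * T

which is an exponential decline over fruit development combined with a Q10
temperature response (Q10 = exp(10 * b2)).  Applied to daily orchard mean
temperature it yields the in-field respiration rate, and the daily
respiratory carbon loss per fruit

    RC_daily (g C d**-1) = Rd_field * FM_kg * 24 * 0.27

with 0.27 the mass fraction of carbon in CO2.  Diurnal temperature
variation is neglected; the model is for pre-climacteric fruit and an
optional mask excludes the last (climacteric-rise) sampling date from the
fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

#: Mass fraction of carbon in CO2 (12.011 / 44.01, rounded as applied).
C_IN_CO2 = 0.27
HOURS_PER_DAY = 24.0


class RespirationFitError(ValueError):
    pass


@dataclass
class RespirationModel:
    ln_intercept: float  # ln(g CO2 kg**-1 h**-1) at DAFB 0 and 0 degC
    dafb_slope: float  # d**-1 (negative: decline over development)
    temp_slope: float  # degC**-1
    r2: float = float("nan")
    n_obs: int = 0

    @property
    def q10(self) -> float:
        return float(np.exp(10.0 * self.temp_slope))

    def rd(self, dafb, temp_c):
        """Dark respiration rate (g CO2 kg**-1 h**-1)."""
        return np.exp(
            self.ln_intercept
            + self.dafb_slope * np.asarray(dafb, float)
            + self.temp_slope * np.asarray(temp_c, float)
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({**asdict(self), "q10": self.q10}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RespirationModel":
        with open(path) as fh:
            raw = json.load(fh)
        raw.pop("q10", None)
        return cls(**raw)


def fit_respiration(
    measurements: pd.DataFrame, mask_last_date: bool = False
) -> RespirationModel:
    """Log-linear least-squares fit of Rd against DAFB and temperature.

    ``measurements`` needs columns ``dafb``, ``temp_c``, ``rd`` (rd > 0).
    ``mask_last_date`` drops the final sampling date (onset of the
    climacteric respiration rise) before fitting.
    """
    df = measurements
    if mask_last_date:
        df = df[df["dafb"] < df["dafb"].max()]
    dafb = np.asarray(df["dafb"], float)
    temp = np.asarray(df["temp_c"], float)
    rd = np.asarray(df["rd"], float)
    if np.any(rd <= 0):
        raise RespirationFitError("respiration rates must be positive")
    if np.unique(temp).size < 2:
        raise RespirationFitError(
            "temperature effect unidentifiable: need >= 2 distinct temperatures"
        )
    if np.unique(dafb).size < 3:
        raise RespirationFitError("need >= 3 distinct DAFB values")

    X = np.column_stack([np.ones_like(dafb), dafb, temp])
    y = np.log(rd)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    model = RespirationModel(*map(float, beta), r2=r2, n_obs=len(y))
    if not 1.0 <= model.q10 <= 4.0:
        raise RespirationFitError(f"fitted Q10 {model.q10:.2f} outside [1, 4]")
    return model


def rc_daily(rd_field, fm_kg):
    """Daily respiratory carbon loss per fruit (g C d**-1).

    ``rd_field`` in g CO2 kg**-1 h**-1 (already evaluated at the day's mean
    temperature), ``fm_kg`` the fruit fresh mass in kg.
    """
    rd_field = np.asarray(rd_field, float)
    fm_kg = np.asarray(fm_kg, float)
    if np.any(rd_field < 0) or np.any(fm_kg < 0):
        raise ValueError("rd_field and fm must be non-negative")
    return rd_field * fm_kg * HOURS_PER_DAY * C_IN_CO2


def seasonal_respiration(
    model: RespirationModel,
    weather: pd.DataFrame,
    fm_curve: pd.DataFrame,
    window: tuple[float, float] | None = None,
) -> dict:
    """Total respiratory C loss per fruit over a DAFB window and its share.

    ``weather`` needs ``dafb`` and ``t_mean``; ``fm_curve`` needs ``dafb``,
    ``fm`` (g) and ``agr_c`` (g d**-1).  The default window is 50 DAFB to
    harvest.  Returns ``total_g`` (sum of RC_daily), ``demand_g`` (sum of
    AGR_C + RC_daily) and ``fraction`` (their ratio).
    """
    merged = pd.merge(
        weather[["dafb", "t_mean"]], fm_curve[["dafb", "fm", "agr_c"]], on="dafb"
    )
    if window is None:
        window = (50.0, float(merged["dafb"].max()))
    lo, hi = window
    merged = merged[(merged["dafb"] >= lo) & (merged["dafb"] <= hi)]
    rd_field = model.rd(merged["dafb"], merged["t_mean"])
    rc = rc_daily(rd_field, np.asarray(merged["fm"], float) / 1000.0)
    total = float(np.sum(rc))
    demand = float(np.sum(rc + np.asarray(merged["agr_c"], float)))
    return {
        "total_g": total,
        "demand_g": demand,
        "fraction": total / demand if demand > 0 else 0.0,
        "window": (float(lo), float(hi)),
    }
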