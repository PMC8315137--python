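"""The canopy carbon-balance core: from weather and leaf area to FBC.

The chain, per tree and per target harvest diameter D:

1. ``lai``: per-tree leaf area index = LA / ground area allotted per tree.
2. ``light_interception``: Beer-Lambert-type saturating fraction
   LI = LImax * (1 - exp(-k * LAI / LImax)).
3. ``p_daily``: daily net canopy carbon assimilation per unit ground area
   from the big-leaf daily hyperbola

       P = (A * S * B) / (A * k * S + B) * LI * 0.27        [g C m**-2 d**-1]

   with A the quantum yield on an energy basis (g CO2 per MJ of solar
   radiation), B = DL * maxJ * PT the temperature-corrected daily
   light-saturated capacity (g CO2 m**-2 d**-1), S the daily solar
   radiation integral (MJ m**-2 d**-1), DL the day length (s) and 0.27 the
   carbon mass fraction of CO2.
4. ``la_demand_series``: leaf area a single fruit "demands" each day,
   0.95 * (AGR_C + RC_daily) / (P_daily * C_part / LAI) * 1e4   [cm**2],
   smoothed with a Savitzky-Golay filter (order 1, window 9).
5. ``peak_window``/``fbc``: the 31-day window centred on the seasonal
   maximum of the per-fruit carbon requirement; FBC = LA * 1e4 / mean
   windowed demand, truncated to a whole fruit.
6. ``fit_demand_regression``: the bilinear surface
   LA_demand ~ 1 + D + LA + D*LA summarizing the full model over a
   (D, LA) grid, and ``tape``: total absorbed photosynthetic energy from
   canopy closure (1,200 growing degree days after bud break) to harvest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import OrchardParams
from .respiration import RespirationModel, rc_daily

MOLAR_MASS_CO2 = 44.0  # g mol**-1, as applied in the unit conversions
M2_TO_CM2 = 1.0e4
HALF_WINDOW_DAYS = 15  # peak-demand window = argmax +/- 15 d


# ---------------------------------------------------------------------------
# elementary relations

def pt_correction(t_mean_day):
    """Temperature correction of the light-saturated capacity.

    Cubic in the daytime mean temperature (degC):
    0.535 + 0.0384*T - 0.0004126*T**2 - 0.00001576*T**3,
    clamped to [0, 1.05]: the fitted cubic peaks at 1.013 near its 21 degC
    optimum, so a hard cap at 1 would clip the fitted optimum itself.
    """
    t = np.asarray(t_mean_day, float)
    p = 0.535 + 0.0384 * t - 0.0004126 * t**2 - 0.00001576 * t**3
    return np.clip(p, 0.0, 1.05)


def lai(la_lidar, g_allotted: float = 3.2):
    """Per-tree leaf area index: LA (m**2) over allotted ground area (m**2)."""
    return np.asarray(la_lidar, float) / g_allotted


def light_interception(lai_value, k: float = 0.5, li_max: float = 0.7):
    """Intercepted fraction of incident radiation, saturating at ``li_max``."""
    return li_max * (1.0 - np.exp(-k * np.asarray(lai_value, float) / li_max))


def alpha_energy_basis(max_alpha: float, ppfr_to_s: float = 0.4376) -> float:
    """Quantum yield mol CO2 / mol photons -> g CO2 per MJ solar radiation."""
    return max_alpha / ppfr_to_s * MOLAR_MASS_CO2


def p_daily(
    s,
    dl,
    t_mean_day,
    max_alpha: float,
    max_j: float,
    li,
    params: OrchardParams | None = None,
):
    """Daily net canopy carbon assimilation (g C m**-2 ground d**-1).

    ``s`` MJ m**-2 d**-1, ``dl`` s, ``max_alpha`` mol mol**-1,
    ``max_j`` umol CO2 m**-2 s**-1.  Vectorized over days.
    """
    params = params or OrchardParams()
    s = np.asarray(s, float)
    dl = np.asarray(dl, float)
    if np.any(s < 0) or np.any(dl < 0):
        raise ValueError("S and DL must be non-negative")
    a = alpha_energy_basis(max_alpha, params.ppfr_to_s)  # g CO2 MJ**-1
    b = dl * max_j * MOLAR_MASS_CO2 * 1e-6 * pt_correction(t_mean_day)
    denom = a * params.k * s + b
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = np.where(denom > 0, (a * s * b) / np.where(denom > 0, denom, 1.0), 0.0)
    return hyper * np.asarray(li, float) * 0.27


def gdd_canopy_date(
    weather: pd.DataFrame, base: float = 4.0, threshold: float = 1200.0
) -> float:
    """DAFB at which the canopy is fully developed (GDD accumulation).

    Accumulates max(T_mean - base, 0) over the whole weather series (which
    may start before full bloom, at bud break) and returns the ``dafb`` of
    the first day the cumulative sum reaches ``threshold``.
    """
    t = np.asarray(weather["t_mean"], float)
    gdd = np.cumsum(np.maximum(t - base, 0.0))
    idx = np.nonzero(gdd >= threshold)[0]
    if idx.size == 0:
        raise ValueError(
            f"{threshold} growing degree days never reached "
            f"(accumulated {gdd[-1]:.0f})"
        )
    return float(weather["dafb"].iloc[idx[0]])


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing with edge-window truncation

def savgol_truncated(y: np.ndarray, window: int = 9, order: int = 1) -> np.ndarray:
    """Savitzky-Golay filter whose window shrinks at the series edges.

    Interior points match ``scipy.signal.savgol_filter``; at the edges the
    fit window is truncated to the available samples instead of padding or
    extrapolating, preserving series length.
    """
    y = np.asarray(y, float)
    n = y.size
    if n == 0:
        return y.copy()
    half = window // 2
    out = np.empty(n)
    x = np.arange(n, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if hi - lo <= order:
            out[i] = y[lo:hi].mean()
            continue
        coeffs = np.polyfit(x[lo:hi], y[lo:hi], order)
        out[i] = np.polyval(coeffs, x[i])
    return out


# ---------------------------------------------------------------------------
# demand series, window, FBC

@dataclass
class DemandSeries:
    """Daily per-fruit leaf-area demand for one tree (or one LA level).

    ``table`` has one row per (dafb, target_d) with columns ``agr_c``,
    ``rc_daily``, ``p_daily``, ``p_tree``, ``la_demand_raw``,
    ``la_demand_smooth``; ``window`` is the 31-day peak-demand interval
    used for FBC.
    """

    table: pd.DataFrame
    window: tuple[float, float]
    la_lidar: float
    lai: float
    li: float
    params: OrchardParams = field(default_factory=OrchardParams)

    def mean_windowed_demand(self, target_d: float) -> float:
        lo, hi = self.window
        sub = self.table[
            (self.table["target_d"] == target_d)
            & (self.table["dafb"] >= lo)
            & (self.table["dafb"] <= hi)
        ]
        if sub.empty:
            raise ValueError(f"no demand rows for target diameter {target_d}")
        return float(sub["la_demand_smooth"].mean())

    def fbc(self, target_d: float) -> int:
        return fbc(self.la_lidar, self, target_d)


def la_demand_series(
    agr_c: np.ndarray,
    rc: np.ndarray,
    p_daily_values: np.ndarray,
    lai_value: float,
    params: OrchardParams | None = None,
    smooth: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and smoothed daily leaf-area demand per fruit (cm**2).

    Demand side: 0.95 * (AGR_C + RC_daily) g C d**-1 per fruit.  Supply
    side: P_daily * C_part / LAI, the carbon fixed per m**2 of leaf that is
    available to fruit.  Their ratio (m**2) is scaled to cm**2.
    """
    params = params or OrchardParams()
    need = params.fruit_photo_correction * (
        np.asarray(agr_c, float) + np.asarray(rc, float)
    )
    supply = np.asarray(p_daily_values, float) * params.c_part / lai_value
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(supply > 0, need / np.where(supply > 0, supply, 1.0), np.nan)
    raw = raw * M2_TO_CM2
    smoothed = savgol_truncated(np.nan_to_num(raw, nan=0.0)) if smooth else raw
    return raw, smoothed


def peak_window(
    table: pd.DataFrame,
    reference_d: float | None = None,
    half_width: int = HALF_WINDOW_DAYS,
) -> tuple[float, float]:
    """31-day window around the maximum per-fruit carbon requirement.

    The requirement AGR_C + RC_daily is smoothed and its argmax located for
    the reference target diameter (default: the smallest); the window is
    argmax +/- ``half_width`` days, clipped to the season.
    """
    if reference_d is None:
        reference_d = float(table["target_d"].min())
    sub = table[table["target_d"] == reference_d].sort_values("dafb")
    req = savgol_truncated(
        np.asarray(sub["agr_c"], float) + np.asarray(sub["rc_daily"], float)
    )
    dafb = np.asarray(sub["dafb"], float)
    peak = dafb[int(np.argmax(req))]
    return (max(float(dafb.min()), peak - half_width),
            min(float(dafb.max()), peak + half_width))


def build_demand_series(
    weather: pd.DataFrame,
    curves: pd.DataFrame,
    resp_model: RespirationModel,
    la_lidar: float,
    max_alpha: float,
    max_j: float,
    params: OrchardParams | None = None,
) -> DemandSeries:
    """Assemble the full DemandSeries for one tree.

    ``weather``: columns dafb, s, dl, t_mean_day, t_mean (dafb >= 0 rows are
    used).  ``curves``: long format with one row per (dafb, target_d) and
    columns ``fm`` (g), ``agr_c`` (g d**-1) from the growth module.
    """
    params = params or OrchardParams()
    w = weather[weather["dafb"] >= 0].sort_values("dafb")
    lai_value = float(lai(la_lidar, params.g_allotted))
    li_value = float(light_interception(lai_value, params.k, params.li_max))
    p = p_daily(w["s"], w["dl"], w["t_mean_day"], max_alpha, max_j, li_value, params)
    pday = pd.DataFrame(
        {"dafb": np.asarray(w["dafb"], float), "p_daily": p,
         "t_mean": np.asarray(w["t_mean"], float)}
    )

    rows = []
    for d, grp in curves.groupby("target_d", sort=True):
        merged = pd.merge(grp.sort_values("dafb"), pday, on="dafb", how="inner")
        rd_field = resp_model.rd(merged["dafb"], merged["t_mean"])
        rc = rc_daily(rd_field, np.asarray(merged["fm"], float) / 1000.0)
        raw, smooth = la_demand_series(
            merged["agr_c"], rc, merged["p_daily"], lai_value, params
        )
        rows.append(
            pd.DataFrame(
                {
                    "dafb": merged["dafb"],
                    "target_d": float(d),
                    "agr_c": merged["agr_c"],
                    "rc_daily": rc,
                    "p_daily": merged["p_daily"],
                    "p_tree": merged["p_daily"] * params.g_allotted,
                    "la_demand_raw": raw,
                    "la_demand_smooth": smooth,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    window = peak_window(table)
    return DemandSeries(table, window, float(la_lidar), lai_value, li_value, params)


def fbc(la_lidar: float, demand: DemandSeries, target_d: float) -> int:
    """Fruit-bearing capacity: whole fruit the leaf area can supply.

    FBC = LA (cm**2) / mean smoothed demand over the peak window, truncated
    (floored) to an integer number of fruit.
    """
    mean_demand = demand.mean_windowed_demand(target_d)
    if mean_demand <= 0:
        raise ValueError("non-positive mean leaf-area demand")
    return int(math.floor(la_lidar * M2_TO_CM2 / mean_demand))


def fbc_table(
    weather: pd.DataFrame,
    curves: pd.DataFrame,
    resp_model: RespirationModel,
    trees_la: pd.DataFrame,
    max_alpha: float,
    max_j: float,
    params: OrchardParams | None = None,
) -> tuple[pd.DataFrame, DemandSeries]:
    """Per-tree FBC for every target diameter, for a whole orchard.

    Exploits that the daily demand of a tree factors as a tree-independent
    base series times LAI/LI: the base series (and the peak window) is
    computed once from a reference tree, then rescaled per tree.  Returns
    (table indexed by tree with one ``fbc_<D>`` column per target diameter
    plus ``lai``/``li``, the reference DemandSeries).
    """
    params = params or OrchardParams()
    la_ref = float(np.median(trees_la["la_m2"]))
    ref = build_demand_series(
        weather, curves, resp_model, la_ref, max_alpha, max_j, params
    )
    base = {
        float(d): ref.mean_windowed_demand(float(d)) * ref.li / ref.lai
        for d in sorted(curves["target_d"].unique())
    }
    la = np.asarray(trees_la["la_m2"], float)
    lai_v = lai(la, params.g_allotted)
    li_v = light_interception(lai_v, params.k, params.li_max)
    out = pd.DataFrame({"tree_id": trees_la["tree_id"], "la_m2": la,
                        "lai": lai_v, "li": li_v})
    for d, b in base.items():
        demand = b * lai_v / li_v
        out[f"fbc_{d:g}"] = np.floor(la * M2_TO_CM2 / demand).astype(int)
        out[f"demand_{d:g}"] = demand
    return out, ref


# ---------------------------------------------------------------------------
# bilinear demand regression (the season summary surface)

@dataclass
class DemandRegression:
    """LA_demand ~ 1 + D + LA + D*LA over a (diameter, leaf-area) grid."""

    intercept: float
    d_coef: float
    la_coef: float
    dla_coef: float
    r2: float = float("nan")
    year_tag: str = ""

    def demand(self, d, la):
        d = np.asarray(d, float)
        la = np.asarray(la, float)
        return self.intercept + self.d_coef * d + self.la_coef * la + self.dla_coef * d * la

    def fbc(self, d, la) -> int:
        """FBC from the regression surface (floored to whole fruit)."""
        dem = float(self.demand(d, la))
        if dem <= 0:
            raise ValueError("regression demand non-positive")
        return int(math.floor(float(la) * M2_TO_CM2 / dem))


#: Published season regression surfaces (cm**2 demand per fruit).
DEMAND_REGRESSION_2018 = DemandRegression(-714.6813, 14.4682, -113.006, 2.2882,
                                          year_tag="2018")
DEMAND_REGRESSION_2019 = DemandRegression(-667.0759, 13.5078, -105.5594, 2.1374,
                                          year_tag="2019")
PUBLISHED_DEMAND_REGRESSIONS = {
    "2018": DEMAND_REGRESSION_2018,
    "2019": DEMAND_REGRESSION_2019,
}


def fit_demand_regression(grid: pd.DataFrame, year_tag: str = "") -> DemandRegression:
    """OLS fit of mean windowed demand over a (D, LA) grid.

    ``grid`` columns: ``d`` (mm), ``la`` (m**2), ``la_demand`` (cm**2).
    """
    d = np.asarray(grid["d"], float)
    la = np.asarray(grid["la"], float)
    y = np.asarray(grid["la_demand"], float)
    X = sm.add_constant(np.column_stack([d, la, d * la]))
    res = sm.OLS(y, X).fit()
    b0, b1, b2, b3 = (float(v) for v in res.params)
    return DemandRegression(b0, b1, b2, b3, float(res.rsquared), year_tag)


def eval_demand_regression(coeffs: DemandRegression, d: float, la: float) -> float:
    """Evaluate a demand regression surface (cm**2 per fruit)."""
    return float(coeffs.demand(d, la))


# ---------------------------------------------------------------------------
# absorbed energy

def tape(
    li_value: float,
    weather: pd.DataFrame,
    window: tuple[float, float],
    params: OrchardParams | None = None,
) -> float:
    """Total absorbed photosynthetic energy of a tree (MJ).

    TAPE = LI * sum(S) * PAR fraction * ground area, with the radiation sum
    over ``window`` (full-canopy date to harvest, in DAFB).
    """
    params = params or OrchardParams()
    lo, hi = window
    sub = weather[(weather["dafb"] >= lo) & (weather["dafb"] <= hi)]
    s_sum = float(np.asarray(sub["s"], float).sum())
    return li_value * s_sum * params.par_fraction * params.g_allotted


def tape_per_fruit(tape_mj: float, fruit_count: int) -> float:
    if fruit_count <= 0:
        raise ValueError("fruit count must be positive for TAPE per fruit")
    return tape_mj / fruit_count
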