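"""Sigmoid fruit-growth modelling and target-diameter scaling.

Fruit fresh mass (FM) and fruit carbon content (C_fruit = FM * DM_rel *
C_rel) are interpolated over days after full bloom (DAFB) with a
three-parameter logistic.  The fitted curves are normalized with the
*measured* mean at the harvest date and re-scaled to the fresh mass a
target harvest diameter implies (via a power-law diameter-to-mass
conversion), producing daily growth curves and absolute growth rates
(AGR, the analytic derivative) for each target diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """A growth-curve fit failed to converge or the data carry no signal."""


def logistic(t, asymptote, midpoint, rate):
    """Three-parameter logistic A / (1 + exp(-r*(t - t0)))."""
    return asymptote / (1.0 + np.exp(-rate * (np.asarray(t, float) - midpoint)))


def logistic_derivative(t, asymptote, midpoint, rate):
    """Analytic d/dt of :func:`logistic` (the absolute growth rate)."""
    e = np.exp(-rate * (np.asarray(t, float) - midpoint))
    return asymptote * rate * e / (1.0 + e) ** 2


def c_fruit(fm: float, dm_rel: float, c_rel: float):
    """Absolute fruit carbon content (g): FM * DM_rel * C_rel."""
    return np.asarray(fm, float) * dm_rel * c_rel


@dataclass
class GrowthModel:
    """A fitted logistic growth curve with its harvest-date anchor.

    ``value_at_harvest`` is the measured mean of the response at the harvest
    DAFB (not the fitted asymptote); the normalized curve divides by the
    *fitted* value at harvest so that it equals 1 at ``harvest_dafb`` by
    construction.
    """

    asymptote: float
    midpoint: float
    rate: float
    harvest_dafb: float
    value_at_harvest: float  # measured mean at harvest
    response: str = "fm"
    rss: float = 0.0

    def __post_init__(self):
        if self.asymptote <= 0 or self.rate <= 0:
            raise FitError("non-physical logistic parameters")
        if not 0 < self.midpoint < self.harvest_dafb:
            raise FitError(
                f"midpoint {self.midpoint:.1f} outside (0, {self.harvest_dafb})"
            )

    def predict(self, dafb):
        return logistic(dafb, self.asymptote, self.midpoint, self.rate)

    def normalized(self, dafb):
        """Curve scaled so its value at the harvest date is exactly 1."""
        return self.predict(dafb) / self.predict(self.harvest_dafb)

    def agr(self, dafb):
        """Absolute growth rate of the un-normalized fitted curve (g d**-1)."""
        return logistic_derivative(dafb, self.asymptote, self.midpoint, self.rate)


def fit_sigmoid(
    observations: pd.DataFrame,
    response: str = "fm",
    harvest_dafb: float | None = None,
) -> GrowthModel:
    """Least-squares logistic fit of ``fm`` or ``c_fruit`` against ``dafb``.

    Parameters
    ----------
    observations : DataFrame
        Columns ``dafb`` and ``fm`` (plus ``dm_rel``/``c_rel`` when fitting
        ``c_fruit``, unless a ``c_fruit`` column is already present).
    response : {"fm", "c_fruit"}
    harvest_dafb : float, optional
        Harvest date; defaults to the last observed DAFB.

    Raises
    ------
    FitError
        For < 4 distinct sampling dates, dates spanning less than half the
        season, constant observations, or non-convergence.
    """
    obs = observations.copy()
    if response == "c_fruit" and "c_fruit" not in obs:
        obs["c_fruit"] = c_fruit(obs["fm"], obs["dm_rel"], obs["c_rel"])
    if response not in obs:
        raise FitError(f"no column {response!r} in observations")

    t = np.asarray(obs["dafb"], float)
    y = np.asarray(obs[response], float)
    dates = np.unique(t)
    if harvest_dafb is None:
        harvest_dafb = float(dates.max())
    if dates.size < 4:
        raise FitError(f"need >= 4 distinct DAFB values, got {dates.size}")
    if dates.max() - dates.min() < 0.5 * harvest_dafb:
        raise FitError("sampling dates span less than half the season")
    if np.std(y) < 1e-12 * max(1.0, abs(np.mean(y))):
        raise FitError("constant observations: no sigmoid signature")

    y_max = float(y.max())
    p0 = (y_max * 1.2, float(np.median(t)), 4.0 / (dates.max() - dates.min()))
    try:
        popt, _ = curve_fit(
            logistic,
            t,
            y,
            p0=p0,
            bounds=([1e-9, 1.0, 1e-4], [50 * y_max, 5 * harvest_dafb, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"logistic fit did not converge: {exc}") from exc

    a, t0, r = (float(v) for v in popt)
    rss = float(np.sum((logistic(t, a, t0, r) - y) ** 2))
    # harvest anchor: measured mean at the latest sampling date
    at_harvest = float(y[t == dates.max()].mean())
    return GrowthModel(a, t0, r, float(harvest_dafb), at_harvest, response, rss)


@dataclass
class DiameterMassConversion:
    """Power-law conversion FM = a * D**b between harvest diameter and mass."""

    coefficient: float
    exponent: float
    calibration_pairs: list = field(default_factory=list)

    def fm(self, diameter_mm):
        return self.coefficient * np.asarray(diameter_mm, float) ** self.exponent

    def diameter(self, fm_g):
        """Inverse conversion: harvest diameter (mm) for a fresh mass (g)."""
        return (np.asarray(fm_g, float) / self.coefficient) ** (1.0 / self.exponent)

    @property
    def calibration_range(self) -> tuple[float, float]:
        d = [p[0] for p in self.calibration_pairs]
        return (min(d), max(d)) if d else (50.0, 90.0)


#: Published diameter/fresh-mass anchor pairs (mm, g) used by default.
DEFAULT_DIAMETER_PAIRS = [(65.0, 102.0), (70.0, 129.0), (75.0, 161.0), (80.0, 198.0)]


def fit_diameter_conversion(
    pairs: list[tuple[float, float]] | None = None,
) -> DiameterMassConversion:
    """Fit FM = a * D**b in log-log space to (diameter, mass) pairs."""
    if pairs is None:
        pairs = DEFAULT_DIAMETER_PAIRS
    if len(pairs) < 3:
        raise ValueError("need >= 3 (diameter, mass) pairs")
    d = np.log([p[0] for p in pairs])
    m = np.log([p[1] for p in pairs])
    b, ln_a = np.polyfit(d, m, 1)
    return DiameterMassConversion(float(np.exp(ln_a)), float(b), list(pairs))


def scaled_growth_curve(
    model_fm: GrowthModel,
    model_c: GrowthModel,
    conversion: DiameterMassConversion,
    target_d: float,
    dafb: np.ndarray | None = None,
    dm_rel: float | tuple[float, float] = 0.15,
    c_rel: float | tuple[float, float] = (0.51, 0.48),
) -> pd.DataFrame:
    """Daily FM(t), C_fruit(t) and their growth rates for a target diameter.

    The normalized FM curve is multiplied by the mass the conversion assigns
    to ``target_d``; the normalized carbon curve by that mass times DM_rel
    and C_rel.  ``dm_rel``/``c_rel`` may be constants or (start, end) pairs
    interpolated linearly over the season (the end value anchors harvest).

    Returns a DataFrame with columns ``dafb, fm, c, agr_fm, agr_c``.
    """
    lo, hi = conversion.calibration_range
    span = hi - lo
    if not lo - 0.1 * span <= target_d <= hi + 0.1 * span:
        raise ValueError(
            f"target diameter {target_d} mm outside calibration range "
            f"[{lo}, {hi}] +/- 10%"
        )
    if dafb is None:
        dafb = np.arange(0.0, model_fm.harvest_dafb + 1.0)
    dafb = np.asarray(dafb, float)
    h = model_fm.harvest_dafb

    def seasonal(v):
        if np.isscalar(v):
            return np.full_like(dafb, float(v)), float(v)
        start, end = v
        frac = np.clip(dafb / h, 0.0, 1.0)
        return start + (end - start) * frac, float(end)

    dm_t, dm_h = seasonal(dm_rel)
    c_t, c_h = seasonal(c_rel)

    fm_target_harvest = float(conversion.fm(target_d))
    fm_curve = model_fm.normalized(dafb) * fm_target_harvest
    c_scale = fm_target_harvest / model_c.predict(model_c.harvest_dafb)
    c_curve = model_c.predict(dafb) * c_scale * dm_t * c_t

    agr_fm = model_fm.agr(dafb) / model_fm.predict(h) * fm_target_harvest
    # carbon AGR: analytic product rule of the scaled curve with the
    # linearly varying composition factors
    core = model_c.predict(dafb) * c_scale
    d_core = model_c.agr(dafb) * c_scale
    if np.isscalar(dm_rel):
        d_dm = 0.0
    else:
        d_dm = (dm_rel[1] - dm_rel[0]) / h
    if np.isscalar(c_rel):
        d_c = 0.0
    else:
        d_c = (c_rel[1] - c_rel[0]) / h
    agr_c = d_core * dm_t * c_t + core * d_dm * c_t + core * dm_t * d_c

    return pd.DataFrame(
        {
            "dafb": dafb,
            "target_d": target_d,
            "fm": fm_curve,
            "c": c_curve,
            "agr_fm": agr_fm,
            "agr_c": agr_c,
        }
    )


def agr(curve: pd.DataFrame, column: str = "c") -> np.ndarray:
    """Absolute growth rate column of a scaled curve (g d**-1)."""
    col = {"fm": "agr_fm", "c": "agr_c"}[column]
    return np.asarray(curve[col], float)
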