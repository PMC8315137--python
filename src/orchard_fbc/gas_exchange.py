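"""Leaf light-response analysis: quantum yield and light-saturated uptake.

Net leaf CO2 exchange J against photosynthetic photon flux rate (PPFR, I)
is fitted with a saturating exponential

    J(I) = Jmax * (1 - exp(-alpha * I / Jmax)) - Rd_leaf

whose initial slope is the maximum quantum yield (max-alpha, mol CO2 per
mol photons) and whose asymptote is the light-saturated gross exchange
rate (max-J, umol m**-2 s**-1).  Because stomatal closure depresses
individual-date max-J estimates, the non-stomatal-limited value is read
off as the asymptote of a rectangular hyperbola of max-J against stomatal
conductance; curves with a low internal-to-ambient CO2 ratio (ci/ca) are
flagged as stomatally limited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Theoretical upper bound on the quantum yield of CO2 fixation (1/8).
QUANTUM_LIMIT = 0.125

#: ci/ca below this marks a curve as stomatally limited (midpoint between
#: the observed limited range, <= 0.22, and the unlimited range, >= 0.62).
CI_CA_THRESHOLD = 0.5


class LightResponseError(ValueError):
    pass


@dataclass
class LightResponseFit:
    leaf_id: str
    max_alpha: float  # mol CO2 mol**-1 photons (initial slope, gross)
    max_j: float  # umol m**-2 s**-1 (asymptote, gross)
    rd_leaf: float  # umol m**-2 s**-1 leaf dark respiration
    fit_rmse: float
    gs: float | None = None  # stomatal conductance, if recorded
    ci_ca: float | None = None
    dafb: float | None = None

    @property
    def max_alpha_net(self) -> float:
        """Initial slope of the *net* curve equals the gross slope here;
        retained for the alternative convention of reporting alpha net of
        the dark-respiration offset at the light compensation point."""
        return self.max_alpha

    @property
    def stomatally_limited(self) -> bool:
        return self.ci_ca is not None and self.ci_ca < CI_CA_THRESHOLD


def _sat_exp(i, max_j, alpha, rd):
    return max_j * (1.0 - np.exp(-alpha * np.asarray(i, float) / max_j)) - rd


def fit_light_response(curve: pd.DataFrame, leaf_id: str | None = None) -> LightResponseFit:
    """Fit one leaf's light-response curve.

    ``curve`` needs columns ``ppfr`` and ``j``; optional scalar metadata
    columns ``gs``, ``ci_ca``, ``dafb``, ``leaf_id``.  Requires a dark
    point (ppfr = 0) and a saturating point (ppfr >= 1000).
    """
    i = np.asarray(curve["ppfr"], float)
    j = np.asarray(curve["j"], float)
    if np.any(i < 0):
        raise LightResponseError("negative PPFR")
    if not np.any(i == 0):
        raise LightResponseError("curve lacks a dark (PPFR = 0) point")
    if not np.any(i >= 1000):
        raise LightResponseError("curve lacks a light-saturated (>= 1000) point")
    if np.unique(i).size < 3:
        raise LightResponseError("need >= 3 distinct PPFR levels")

    rd0 = max(-float(j[i == 0].mean()), 0.01)
    jmax0 = max(float(j.max()) + rd0, 1.0)
    alpha0 = 0.05
    try:
        popt, _ = curve_fit(
            _sat_exp,
            i,
            j,
            p0=(jmax0, alpha0, rd0),
            bounds=([0.1, 1e-4, 0.0], [200.0, QUANTUM_LIMIT, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise LightResponseError(
            f"light-response fit failed for leaf {leaf_id!r}: {exc}"
        ) from exc
    max_j, alpha, rd = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_sat_exp(i, *popt) - j) ** 2)))

    def meta(col):
        if col in curve and curve[col].notna().any():
            return float(curve[col].iloc[0])
        return None

    if leaf_id is None:
        leaf_id = str(curve["leaf_id"].iloc[0]) if "leaf_id" in curve else "leaf"
    return LightResponseFit(
        leaf_id=leaf_id,
        max_alpha=alpha,
        max_j=max_j,
        rd_leaf=rd,
        fit_rmse=rmse,
        gs=meta("gs"),
        ci_ca=meta("ci_ca"),
        dafb=meta("dafb"),
    )


def fit_panel(table: pd.DataFrame) -> list[LightResponseFit]:
    """Fit every (leaf_id, dafb) curve in a long-format measurement table."""
    fits = []
    for (leaf, dafb), grp in table.groupby(["leaf_id", "dafb"], sort=True):
        fits.append(fit_light_response(grp, leaf_id=f"{leaf}@{dafb:g}"))
    return fits


def pool_alpha(fits: list[LightResponseFit]) -> tuple[float, float]:
    """Unweighted mean (and SD) of max-alpha over all leaves and dates."""
    vals = np.array([f.max_alpha for f in fits], float)
    if vals.size == 0:
        raise LightResponseError("no fits to pool")
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0


def nonstomatal_jmax(fits: list[LightResponseFit]) -> float:
    """Non-stomatal-limited max-J: asymptote of max-J against gs.

    Fits the rectangular hyperbola J = Jsat * gs / (K + gs) across per-curve
    (gs, max_j) pairs and returns Jsat, the value max-J approaches when
    stomata impose no limitation.  Raises if every curve is stomatally
    limited or gs carries no spread.
    """
    pts = [(f.gs, f.max_j) for f in fits if f.gs is not None]
    if len(pts) < 5:
        raise LightResponseError("need >= 5 fits with stomatal conductance")
    if all(f.stomatally_limited for f in fits if f.ci_ca is not None) and any(
        f.ci_ca is not None for f in fits
    ):
        raise LightResponseError("all curves stomatally limited; Jsat unidentifiable")
    gs = np.array([p[0] for p in pts], float)
    jm = np.array([p[1] for p in pts], float)
    if np.std(gs) < 1e-12:
        raise LightResponseError("constant stomatal conductance; Jsat unidentifiable")

    def hyper(g, jsat, k):
        return jsat * g / (k + g)

    try:
        popt, _ = curve_fit(
            hyper,
            gs,
            jm,
            p0=(float(jm.max()) * 1.2, float(np.median(gs))),
            bounds=([0.1, 1e-6], [500.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise LightResponseError(f"gs regression failed: {exc}") from exc
    return float(popt[0])


def fits_to_frame(fits: list[LightResponseFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "leaf_id": [f.leaf_id for f in fits],
            "dafb": [f.dafb for f in fits],
            "max_alpha": [f.max_alpha for f in fits],
            "max_j": [f.max_j for f in fits],
            "rd_leaf": [f.rd_leaf for f in fits],
            "fit_rmse": [f.fit_rmse for f in fits],
            "gs": [f.gs for f in fits],
            "ci_ca": [f.ci_ca for f in fits],
        }
    )
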