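"""Spatial hot/cold-spot classification and fruit-quality regressions.

The per-tree fruit-bearing capacity field is classified with the local
Getis-Ord Gi* statistic (self-inclusive, binary distance-band weights):

    Gi* = (sum_j w_ij x_j - xbar * W_i)
          / (S * sqrt((n * sum_j w_ij**2 - W_i**2) / (n - 1)))

with xbar and S the global mean and standard deviation.  Trees with
z > 1.96 are hot spots, z < -1.96 cold spots (95% two-sided; 90% optional).
Separately, per-tree fruit-quality summaries (mean FM, its SD, percentage
of marketable fruit above 65 mm, SSC, yield) are regressed on the tree's
seasonally absorbed photosynthetic energy (TAPE) per fruit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_95 = 1.959963984540054
Z_90 = 1.6448536269514722

#: Default neighbourhood: reaches within-row neighbours (1 m) and the
#: adjacent rows (3.2 m), but not diagonal cross-row trees.
DEFAULT_RADIUS = 3.5


@dataclass
class GiStarResult:
    tree_id: str
    z: float
    category: str  # "hot" | "cold" | "none"
    n_neighbors: int


def gi_star(
    values,
    positions,
    tree_ids=None,
    neighborhood_radius: float = DEFAULT_RADIUS,
    confidence: float = 0.95,
) -> list[GiStarResult]:
    """Self-inclusive Getis-Ord Gi* with binary distance-band weights.

    ``values``: one scalar per tree; ``positions``: (n, 2) metric
    coordinates.  Trees without any neighbour inside the band (other than
    themselves) are flagged with category ``"isolated"`` and excluded from
    hot/cold classification.  A zero-variance field returns all-"none"
    (z = 0).  No multiple-testing correction is applied.
    """
    x = np.asarray(values, float)
    pos = np.asarray(positions, float).reshape(-1, 2)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 trees")
    if tree_ids is None:
        tree_ids = [f"tree_{i:04d}" for i in range(n)]
    zcrit = Z_95 if confidence >= 0.95 else Z_90

    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)

    d2 = (
        (pos[:, None, 0] - pos[None, :, 0]) ** 2
        + (pos[:, None, 1] - pos[None, :, 1]) ** 2
    )
    w = (d2 <= neighborhood_radius**2).astype(float)  # includes self (d=0)

    wi = w.sum(axis=1)
    wx = w @ x
    s1 = (w**2).sum(axis=1)  # binary weights: equals wi

    results = []
    denom_scale = np.sqrt(np.maximum((n * s1 - wi**2) / (n - 1.0), 0.0))
    for i in range(n):
        if wi[i] <= 1:  # only itself in the band
            results.append(GiStarResult(str(tree_ids[i]), float("nan"), "isolated", 0))
            continue
        if s < 1e-12 * max(1.0, abs(xbar)):
            results.append(GiStarResult(str(tree_ids[i]), 0.0, "none", int(wi[i]) - 1))
            continue
        denom = s * denom_scale[i]
        z = (wx[i] - xbar * wi[i]) / denom if denom > 0 else 0.0
        cat = "hot" if z > zcrit else "cold" if z < -zcrit else "none"
        results.append(GiStarResult(str(tree_ids[i]), float(z), cat, int(wi[i]) - 1))
    return results


def classify_spots(
    results: list[GiStarResult],
    positions,
    values,
    path: str | None = None,
) -> tuple[dict, pd.DataFrame]:
    """GeoJSON point layer of the classification plus per-category means."""
    pos = np.asarray(positions, float).reshape(-1, 2)
    vals = np.asarray(values, float)
    colors = {"hot": "#d7191c", "cold": "#2c7bb6", "none": "#ffffff",
              "isolated": "#bdbdbd"}
    features = []
    for r, p, v in zip(results, pos, vals):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(p[0]), float(p[1])]},
                "properties": {
                    "tree_id": r.tree_id,
                    "value": float(v),
                    "z": None if np.isnan(r.z) else float(r.z),
                    "category": r.category,
                    "color": colors[r.category],
                },
            }
        )
    layer = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(layer, fh)
    summary = (
        pd.DataFrame({"category": [r.category for r in results], "value": vals})
        .groupby("category")["value"]
        .agg(["mean", "count"])
        .reset_index()
    )
    return layer, summary


# ---------------------------------------------------------------------------
# quality regressions

@dataclass
class QualityRegression:
    response: str
    predictor: str  # "tape" or "tape_per_fruit"
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


def summarize_harvest(harvest: pd.DataFrame) -> pd.DataFrame:
    """Per-tree quality summary from fruit-level grader records.

    Input columns: ``tree_id, fm, diameter, ssc``.  Output per tree:
    ``fruit_count, mean_fm, sd_fm, pct_gt65, mean_ssc, pct_ssc12, yield_kg``.
    """
    g = harvest.groupby("tree_id")
    out = pd.DataFrame(
        {
            "fruit_count": g.size(),
            "mean_fm": g["fm"].mean(),
            "sd_fm": g["fm"].std(ddof=1),
            "pct_gt65": g["diameter"].apply(lambda d: 100.0 * np.mean(d > 65.0)),
            "mean_ssc": g["ssc"].mean(),
            "pct_ssc12": g["ssc"].apply(lambda s: 100.0 * np.mean(s >= 12.0)),
            "yield_kg": g["fm"].sum() / 1000.0,
        }
    ).reset_index()
    return out


def quality_regressions(
    harvest_summary: pd.DataFrame,
    tape: pd.DataFrame,
    responses: tuple[str, ...] = (
        "mean_fm", "sd_fm", "pct_gt65", "mean_ssc", "pct_ssc12", "yield_kg"
    ),
) -> list[QualityRegression]:
    """OLS of each per-tree quality summary on TAPE and TAPE per fruit.

    ``tape`` columns: ``tree_id, tape, tape_per_fruit``.  Yield regresses
    on total TAPE; the per-fruit responses on TAPE per fruit.
    """
    df = pd.merge(harvest_summary, tape, on="tree_id", how="inner")
    if len(df) < 3:
        raise ValueError("need >= 3 trees for a quality regression")
    out = []
    for resp in responses:
        predictor = "tape" if resp == "yield_kg" else "tape_per_fruit"
        sub = df[[resp, predictor]].dropna()
        x = np.asarray(sub[predictor], float)
        y = np.asarray(sub[resp], float)
        if y.std() < 1e-12:  # constant response: slope 0 by definition
            out.append(QualityRegression(resp, predictor, 0.0, float(y.mean()),
                                         0.0, 1.0, len(y)))
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        out.append(
            QualityRegression(
                response=resp,
                predictor=predictor,
                slope=float(res.params[1]),
                intercept=float(res.params[0]),
                r2=float(res.rsquared),
                p_value=float(res.pvalues[1]),
                n=int(res.nobs),
            )
        )
    return out


def marketable_threshold(
    regression: QualityRegression, target_pct: float = 80.0
) -> float:
    """TAPE per fruit (MJ) at which the marketable percentage is reached.

    Inverse prediction on the (linear) percentage-above-65-mm regression;
    undefined for a flat or negative response.  Warns when the target lies
    outside the fitted percentage range.
    """
    if regression.slope <= 0:
        raise ValueError("non-positive slope: threshold undefined")
    x = (target_pct - regression.intercept) / regression.slope
    lo = regression.predict(0.0)
    if not lo <= target_pct <= 100.0:
        warnings.warn("target percentage outside fitted range; extrapolating",
                      stacklevel=2)
    return float(x)


def fbc_vs_harvest_ratio(
    harvest_summary: pd.DataFrame, fbc_actual: pd.DataFrame
) -> tuple[pd.DataFrame, float, float]:
    """Per-tree (harvested fruit > 65 mm) / FBC ratio, with mean and SD.

    ``fbc_actual`` columns: ``tree_id, fbc`` (FBC at the actual mean
    harvest diameter).  Trees with zero marketable fruit are excluded with
    a warning.
    """
    df = pd.merge(
        harvest_summary[["tree_id", "fruit_count", "pct_gt65"]],
        fbc_actual,
        on="tree_id",
    )
    df["n_gt65"] = df["fruit_count"] * df["pct_gt65"] / 100.0
    empty = df["n_gt65"] <= 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} trees without marketable fruit",
                      stacklevel=2)
        df = df[~empty]
    df["ratio"] = df["n_gt65"] / df["fbc"]
    return df, float(df["ratio"].mean()), float(df["ratio"].std(ddof=1))
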