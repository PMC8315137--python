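"""Synthetic orchard generator: every input the pipeline consumes.

Emulates a two-season trial in a slender-spindle apple orchard (5 rows of
~200 trees at 3.2 m x 1.0 m): daily weather, per-tree leaf areas with
optional spatial patches, per-tree LiDAR-style point clouds, fruit
growth/composition samples, dark-respiration grids, leaf light-response
curves, and grader-style harvest records.  All truth parameters live in
:class:`~orchard_fbc.config.SyntheticConfig`; every output is reproducible
from the seed (independent named substreams per generator, so adding one
generator never perturbs another).

What it does *not* emulate: radiative transfer within canopies, real LiDAR
beam geometry/occlusion, and year-to-year physiological carry-over.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SyntheticConfig, ConfigurationError
from .growth import logistic, fit_diameter_conversion
from .lidar import CalibrationModel, write_cloud

# fixed substream ids: adding a generator must not shift existing streams
_STREAMS = {
    "weather": 1,
    "orchard": 2,
    "cloud": 3,
    "fruit": 4,
    "respiration": 5,
    "light": 6,
    "harvest": 7,
}

PPFR_LEVELS = (2000.0, 250.0, 100.0, 50.0, 20.0, 0.0)


def _rng(config: SyntheticConfig, stream: str, extra: int = 0) -> np.random.Generator:
    seed = 0 if config.seed is None else config.seed
    return np.random.default_rng([seed, _STREAMS[stream], extra])


def _season_phase(dafb: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Half-sine phase over bud break .. harvest, peaking mid-interval."""
    total = config.budbreak_offset + config.season_length
    tau = np.asarray(dafb, float) + config.budbreak_offset
    return np.sin(np.pi * tau / total)


# ---------------------------------------------------------------------------
# weather

def generate_weather(
    config: SyntheticConfig,
    year_tag: str = "2018",
    cloud_override: float | None = None,
    flat_photoperiod_h: float | None = None,
) -> pd.DataFrame:
    """Daily weather from bud break (negative DAFB) to harvest.

    Columns: ``dafb, s, dl, t_mean_day, t_mean``.  Solar radiation is a
    seasonal half-sine (clear sky) times a beta-distributed cloudiness
    factor in (0.2, 1.0]; day length follows a mid-latitude photoperiod
    curve; daily mean temperature tracks the season and co-varies with
    cloudiness.  ``cloud_override`` pins the cloudiness factor (e.g. 1.0
    for clear-sky tests); ``flat_photoperiod_h`` pins the day length.
    """
    config.validate()
    wp = config.weather_params
    rng = _rng(config, "weather", extra=_year_extra(year_tag))
    dafb = np.arange(-config.budbreak_offset, config.season_length + 1, dtype=float)
    phase = _season_phase(dafb, config)

    if cloud_override is None:
        a, b = wp["cloud_beta"]
        cloud = 0.2 + 0.8 * rng.beta(a, b, size=dafb.size)
        cloud_mean = 0.2 + 0.8 * a / (a + b)
    else:
        cloud = np.full(dafb.size, float(cloud_override))
        cloud_mean = float(cloud_override)

    s_clear = wp["s_base"] + wp["s_amp"] * phase
    s = np.maximum(s_clear * cloud, 0.0)

    if flat_photoperiod_h is None:
        dl = (wp["dl_base_h"] + wp["dl_amp_h"] * phase) * 3600.0
    else:
        dl = np.full(dafb.size, flat_photoperiod_h * 3600.0)

    t_noise = rng.normal(0.0, wp["t_noise_sd"], size=dafb.size)
    t_mean = wp["t_base"] + wp["t_amp"] * phase + 4.0 * (cloud - cloud_mean) + t_noise
    t_mean_day = t_mean + wp["t_day_offset"]

    out = pd.DataFrame(
        {"dafb": dafb, "s": s, "dl": dl, "t_mean_day": t_mean_day, "t_mean": t_mean}
    )
    if not np.isfinite(out.to_numpy()).all():  # pragma: no cover - guard
        raise ConfigurationError("non-finite weather values generated")
    return out


def _year_extra(year_tag: str) -> int:
    return sum(ord(c) for c in str(year_tag)) % (2**16)


# ---------------------------------------------------------------------------
# orchard layout and leaf areas

def generate_orchard(config: SyntheticConfig) -> pd.DataFrame:
    """Tree grid with ground-truth leaf areas.

    Columns: ``tree_id, row, pos, x, y, la_true``.  LA is log-normal with
    parameters solved from the target 5th/50th/95th percentiles, truncated
    to ``la_bounds``; optional ``hotspot_spec`` patches offset LA in
    rectangular row/position blocks to plant spatial clusters.
    """
    config.validate()
    rng = _rng(config, "orchard")
    n = config.n_rows * config.trees_per_row
    if n < 1:
        raise ConfigurationError("empty orchard")
    rows = np.repeat(np.arange(config.n_rows), config.trees_per_row)
    pos = np.tile(np.arange(config.trees_per_row), config.n_rows)
    mu, sigma = config.la_lognormal_mu_sigma
    la = rng.lognormal(mu, sigma, size=n)
    for spec in config.hotspot_spec or []:
        r0, r1 = spec["row_range"]
        p0, p1 = spec["tree_range"]
        mask = (rows >= r0) & (rows <= r1) & (pos >= p0) & (pos <= p1)
        la[mask] += spec["delta_la"]
    la = np.clip(la, *config.la_bounds)
    return pd.DataFrame(
        {
            "tree_id": [f"r{r:02d}t{p:03d}" for r, p in zip(rows, pos)],
            "row": rows,
            "pos": pos,
            "x": rows * config.row_spacing,
            "y": pos * config.tree_spacing,
            "la_true": la,
        }
    )


# ---------------------------------------------------------------------------
# point clouds

def generate_point_cloud(
    la_true: float,
    trunk_xy: tuple[float, float],
    calibration: CalibrationModel,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One tree's xyz cloud whose cylinder count inverts to its leaf area.

    The expected canopy point count is the inverse of the calibration line,
    drawn with Poisson dispersion and placed uniformly in an ellipsoidal
    canopy volume around the trunk; a dense vertical trunk line is added,
    and a configurable fraction of canopy points spills beyond the 0.5 m
    segmentation radius.  A leaf area at or below the calibration intercept
    yields a trunk-only cloud (with a warning).
    """
    if rng is None:
        rng = _rng(config, "cloud")
    cn = config.cloud_noise
    expected = calibration.ppt(la_true)
    if expected <= 0:
        warnings.warn(
            f"leaf area {la_true:.2f} m**2 at or below the calibration "
            "intercept: emitting trunk-only cloud",
            stacklevel=2,
        )
        n_canopy = 0
    else:
        n_canopy = int(rng.poisson(expected))

    x0, y0 = trunk_xy
    z0, z1 = cn["canopy_height"]
    r_xy = cn["canopy_radius"]

    n_spill = int(round(n_canopy * cn["spill_fraction"]))
    n_in = n_canopy - n_spill

    # uniform in an ellipsoid: sample in unit ball, scale axes
    u = rng.normal(size=(n_in, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True) + 1e-12
    rad = rng.uniform(0.0, 1.0, size=(n_in, 1)) ** (1.0 / 3.0)
    ball = u * rad
    canopy = np.column_stack(
        [
            x0 + ball[:, 0] * r_xy,
            y0 + ball[:, 1] * r_xy,
            0.5 * (z0 + z1) + ball[:, 2] * 0.5 * (z1 - z0),
        ]
    )

    theta = rng.uniform(0, 2 * np.pi, size=n_spill)
    rr = rng.uniform(0.52, 0.85, size=n_spill)
    spill = np.column_stack(
        [
            x0 + rr * np.cos(theta),
            y0 + rr * np.sin(theta),
            rng.uniform(z0, z1, size=n_spill),
        ]
    )

    n_trunk = int(cn["trunk_points"])
    trunk = np.column_stack(
        [
            x0 + rng.normal(0, 0.02, size=n_trunk),
            y0 + rng.normal(0, 0.02, size=n_trunk),
            rng.uniform(0.0, z0, size=n_trunk),
        ]
    )
    return np.vstack([canopy, spill, trunk])


def generate_row_cloud(
    orchard: pd.DataFrame,
    row: int,
    calibration: CalibrationModel,
    config: SyntheticConfig,
) -> np.ndarray:
    """Concatenated cloud of one orchard row (for segmentation tests)."""
    sub = orchard[orchard["row"] == row]
    rng = _rng(config, "cloud", extra=int(row))
    clouds = [
        generate_point_cloud(
            float(t.la_true), (float(t.x), float(t.y)), calibration, config, rng
        )
        for t in sub.itertuples()
    ]
    return np.vstack(clouds)


# ---------------------------------------------------------------------------
# fruit growth and composition samples

def truth_growth_params(config: SyntheticConfig) -> tuple[float, float, float]:
    """(asymptote, midpoint, rate) of the ground-truth FM logistic."""
    t0 = config.fm_midpoint_frac * config.season_length
    r = config.fm_rate
    frac_at_harvest = 1.0 / (1.0 + np.exp(-r * (config.season_length - t0)))
    return config.fm_harvest_mean / frac_at_harvest, t0, r


def truth_fm(dafb, config: SyntheticConfig) -> np.ndarray:
    a, t0, r = truth_growth_params(config)
    return logistic(dafb, a, t0, r)


def truth_c_rel(dafb, config: SyntheticConfig) -> np.ndarray:
    start, end = config.c_rel_start_end
    frac = np.clip(np.asarray(dafb, float) / config.season_length, 0.0, 1.0)
    return start + (end - start) * frac


def generate_fruit_series(
    config: SyntheticConfig,
    n_dates: int = 8,
    n_per_date: int = 30,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Destructive fruit samples at ~8 dates from 30 DAFB to harvest.

    Columns: ``dafb, fm, diameter, dm_rel, c_rel``.  FM observations sit on
    the truth logistic with a multiplicative per-fruit CV; diameter comes
    from the default mass-diameter conversion; DM fraction is Gaussian and
    relative carbon content declines linearly over the season.
    """
    config.validate()
    rng = _rng(config, "fruit")
    dates = np.unique(np.round(np.linspace(30, config.season_length, n_dates)))
    conv = fit_diameter_conversion()
    rows = []
    for d in dates:
        mean_fm = float(truth_fm(d, config))
        fm = mean_fm * np.clip(
            1.0 + noise_scale * config.fm_cv * rng.standard_normal(n_per_date),
            0.05,
            None,
        )
        dm = np.clip(
            config.dm_rel_mean
            + noise_scale * config.dm_rel_sd * rng.standard_normal(n_per_date),
            0.01,
            0.99,
        )
        c_rel = np.clip(
            float(truth_c_rel(d, config))
            + noise_scale * 0.005 * rng.standard_normal(n_per_date),
            0.01,
            0.99,
        )
        rows.append(
            pd.DataFrame(
                {
                    "dafb": float(d),
                    "fm": fm,
                    "diameter": conv.diameter(fm),
                    "dm_rel": dm,
                    "c_rel": c_rel,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# respiration measurements

def generate_respiration_series(
    config: SyntheticConfig,
    n_dates: int = 5,
    temps: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0),
    n_per_cell: int = 3,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Lab dark-respiration grid over DAFB x temperature.

    Truth: Rd = rd_ref * exp(-lambda * DAFB) * q10**((T - 20)/10) with
    multiplicative log-normal noise.  Columns: ``dafb, temp_c, rd``.
    """
    config.validate()
    rng = _rng(config, "respiration")
    dates = np.unique(np.round(np.linspace(30, config.season_length, n_dates)))
    rows = []
    for d in dates:
        for t in temps:
            truth = (
                config.rd_ref
                * np.exp(-config.rd_dafb_decline * d)
                * config.q10 ** ((t - 20.0) / 10.0)
            )
            rd = truth * np.exp(
                noise_scale * config.rd_noise_sd * rng.standard_normal(n_per_cell)
            )
            rows.append(pd.DataFrame({"dafb": float(d), "temp_c": t, "rd": rd}))
    return pd.concat(rows, ignore_index=True)


def truth_rd(dafb, temp_c, config: SyntheticConfig) -> np.ndarray:
    return (
        config.rd_ref
        * np.exp(-config.rd_dafb_decline * np.asarray(dafb, float))
        * config.q10 ** ((np.asarray(temp_c, float) - 20.0) / 10.0)
    )


# ---------------------------------------------------------------------------
# leaf light-response curves

def generate_light_response(
    config: SyntheticConfig,
    n_leaves: int = 9,
    n_dates: int = 4,
    gs_range: tuple[float, float] = (0.03, 0.6),
    gs_k: float = 0.04,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Leaf light-response panel at the six standard PPFR levels.

    Each (leaf, date) curve is a saturating exponential with quantum yield
    near ``alpha_true``; its saturated rate is drawn on the rectangular
    hyperbola Jsat * gs / (gs_k + gs) against a leaf-specific stomatal
    conductance, so that regressing fitted max-J on gs recovers
    ``jmax_true`` as the non-stomatal-limited asymptote.  The ci/ca ratio
    co-varies with gs (low gs = stomatally limited).  Columns:
    ``leaf_id, dafb, t_leaf, ppfr, j, gs, ci_ca``.
    """
    config.validate()
    rng = _rng(config, "light")
    dates = np.round(np.linspace(30, config.season_length - 10, n_dates))
    levels = np.array(PPFR_LEVELS)
    rows = []
    for d in dates:
        for leaf in range(n_leaves):
            alpha = config.alpha_true * (1.0 + noise_scale * 0.03 * rng.standard_normal())
            gs = rng.uniform(*gs_range)
            jmax = config.jmax_true * gs / (gs_k + gs)
            ci_ca = float(np.clip(0.95 * gs / (gs + 0.05) + 0.05 * rng.standard_normal(), 0.02, 0.95))
            rd = config.rd_leaf_true * (1.0 + noise_scale * 0.1 * rng.standard_normal())
            j = (
                jmax * (1.0 - np.exp(-alpha * levels / jmax))
                - rd
                + noise_scale * config.leaf_noise_sd * rng.standard_normal(levels.size)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "leaf_id": f"L{leaf}",
                        "dafb": float(d),
                        "t_leaf": 22.0 + 4.0 * rng.standard_normal(),
                        "ppfr": levels,
                        "j": j,
                        "gs": gs,
                        "ci_ca": ci_ca,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# harvest / grader records

def generate_harvest(
    trees: pd.DataFrame,
    tape_per_fruit: np.ndarray | None = None,
    config: SyntheticConfig | None = None,
    crop_load: np.ndarray | None = None,
) -> pd.DataFrame:
    """Grader records: one row per fruit with tree id, FM, diameter, SSC.

    Individual fruit FM is Gaussian around a linear function of the tree's
    absorbed energy per fruit (TAPE per fruit, MJ); diameter derives from
    the inverse mass-diameter conversion; SSC is linear in TAPE per fruit
    with its own slope.  ``crop_load`` fixes the exact per-tree fruit count
    (default: Poisson around the configured mean).
    """
    config = config or SyntheticConfig()
    rng = _rng(config, "harvest")
    n_trees = len(trees)
    if tape_per_fruit is None:
        tape_per_fruit = np.full(n_trees, 7.0)
    tape_per_fruit = np.asarray(tape_per_fruit, float)
    if crop_load is None:
        counts = rng.poisson(config.crop_load_mean, size=n_trees)
        counts = np.maximum(counts, 1)
    else:
        counts = np.asarray(crop_load, int)
    conv = fit_diameter_conversion()
    rows = []
    for i, tree in enumerate(trees.itertuples()):
        k = int(counts[i])
        mean_fm = config.fm_tape_intercept + config.fm_tape_slope * tape_per_fruit[i]
        fm = np.clip(mean_fm + config.fm_tree_sd * rng.standard_normal(k), 20.0, None)
        ssc = (
            config.ssc_tape_intercept
            + config.ssc_tape_slope * tape_per_fruit[i]
            + config.ssc_sd * rng.standard_normal(k)
        )
        rows.append(
            pd.DataFrame(
                {
                    "tree_id": tree.tree_id,
                    "fm": fm,
                    "diameter": conv.diameter(fm),
                    "ssc": ssc,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# file interface

def write_inputs(
    config: SyntheticConfig,
    outdir: str | Path,
    year_tag: str = "2018",
    write_clouds: bool = False,
    calibration: CalibrationModel | None = None,
) -> dict:
    """Write weather/fruit/respiration/light/trees CSVs plus a manifest.

    Returns the manifest dict (seed, truth parameters, file list).  Point
    clouds (one xyz file per tree of row 0) are only written on request:
    they are large and downstream stages can work from points-per-tree.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    weather = generate_weather(config, year_tag)
    weather.to_csv(outdir / "weather.csv", index=False)
    files["weather"] = "weather.csv"

    orchard = generate_orchard(config)
    orchard.to_csv(outdir / "trees.csv", index=False)
    files["trees"] = "trees.csv"

    generate_fruit_series(config).to_csv(outdir / "fruit.csv", index=False)
    files["fruit"] = "fruit.csv"

    generate_respiration_series(config).to_csv(outdir / "respiration.csv", index=False)
    files["respiration"] = "respiration.csv"

    generate_light_response(config).to_csv(outdir / "light_response.csv", index=False)
    files["light_response"] = "light_response.csv"

    if write_clouds:
        from .lidar import PUBLISHED_CALIBRATIONS

        cal = calibration or PUBLISHED_CALIBRATIONS.get(year_tag)
        clouds_dir = outdir / "clouds"
        clouds_dir.mkdir(exist_ok=True)
        sub = orchard[orchard["row"] == 0]
        rng = _rng(config, "cloud", extra=0)
        for t in sub.itertuples():
            cloud = generate_point_cloud(
                float(t.la_true), (float(t.x), float(t.y)), cal, config, rng
            )
            write_cloud(clouds_dir / f"{t.tree_id}.xyz", cloud)
        files["clouds"] = "clouds/"

    manifest = {
        "seed": config.seed,
        "year_tag": year_tag,
        "truth": config.to_dict(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
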