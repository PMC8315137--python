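"""Stage orchestration: synthesize -> fit -> balance -> spatial -> report.

Each stage reads only files written by earlier stages (or by the user),
writes its outputs into the run directory, and records a SHA-256 hash of
every output in the run manifest, so a rerun with the same configuration
and seed reproduces the manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance, gas_exchange, growth, respiration, spatial, synthetic
from .config import PipelineConfig, ConfigurationError
from .lidar import fit_calibration, trees_la_frame, SegmentedTree

log = logging.getLogger("orchard_fbc")

STAGE_ORDER = ("synth", "fit", "balance", "spatial", "report")

# files each stage requires before it can run
_STAGE_INPUTS = {
    "synth": (),
    "fit": ("fruit.csv", "respiration.csv", "light_response.csv"),
    "balance": ("weather.csv", "trees_la.csv", "growth_curves.csv",
                "respiration_model.json", "gas_exchange_summary.json"),
    "spatial": ("fbc.csv", "trees_la.csv", "weather.csv"),
    "report": (),
}


class StageDependencyError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def _require(outdir: Path, stage: str) -> None:
    missing = [f for f in _STAGE_INPUTS[stage] if not (outdir / f).exists()]
    if missing:
        raise StageDependencyError(
            f"stage {stage!r} missing upstream outputs: {missing}"
        )


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and range checks on the configuration and any existing inputs."""
    config.validate()
    report: dict = {"errors": [], "warnings": []}
    p = config.params
    if not 0.5 <= p.c_part <= 0.9:
        report["warnings"].append(f"c_part={p.c_part} outside the usual [0.5, 0.9]")
    outdir = Path(config.outdir)
    weather_path = outdir / "weather.csv"
    if weather_path.exists():
        w = pd.read_csv(weather_path)
        if (w["s"] < 0).any():
            report["errors"].append("weather.csv: negative solar radiation")
        if ((w["dl"] < 0) | (w["dl"] > 86400)).any():
            report["errors"].append("weather.csv: day length outside [0, 86400] s")
    fruit_path = outdir / "fruit.csv"
    if fruit_path.exists():
        f = pd.read_csv(fruit_path)
        for col in ("dm_rel", "c_rel"):
            if ((f[col] <= 0) | (f[col] >= 1)).any():
                report["errors"].append(f"fruit.csv: {col} outside (0, 1)")
        if (f["fm"] <= 0).any():
            report["errors"].append("fruit.csv: non-positive fresh mass")
    report["ok"] = not report["errors"]
    return report


# ---------------------------------------------------------------------------
# stages

def stage_synth(config: PipelineConfig, outdir: Path) -> None:
    synthetic.write_inputs(
        config.synthetic, outdir, config.year_tag,
        write_clouds=config.write_point_clouds,
    )
    # emulate the LiDAR reading: a season calibration fitted on reference
    # trees, then calibration-inverse point counts with Poisson dispersion
    orchard = pd.read_csv(outdir / "trees.csv")
    rng = np.random.default_rng([config.synthetic.seed, 97])
    truth_cal = _truth_calibration(config)
    ref_idx = rng.choice(len(orchard), size=config.n_reference_trees, replace=False)
    ref = orchard.iloc[np.sort(ref_idx)]
    ref_ppt = rng.poisson(np.maximum(truth_cal.ppt(ref["la_true"]), 0.0))
    ref_la_manual = ref["la_true"] * (1 + 0.02 * rng.standard_normal(len(ref)))
    cal = fit_calibration(ref_ppt, ref_la_manual, config.year_tag)

    ppt = rng.poisson(np.maximum(truth_cal.ppt(orchard["la_true"]), 0.0))
    trees = [
        SegmentedTree(t.tree_id, (float(t.x), float(t.y)), int(p))
        for t, p in zip(orchard.itertuples(), ppt)
    ]
    df = trees_la_frame(trees, cal)
    _write_csv(df, outdir / "trees_la.csv")
    with open(outdir / "calibration.json", "w") as fh:
        json.dump(
            {"slope": cal.slope, "intercept": cal.intercept, "r2": cal.r2,
             "year_tag": cal.year_tag, "n_reference": cal.n_reference},
            fh, indent=2,
        )


def _truth_calibration(config: PipelineConfig):
    from .lidar import PUBLISHED_CALIBRATIONS, CalibrationModel

    cal = PUBLISHED_CALIBRATIONS.get(config.year_tag)
    if cal is None:
        cal = CalibrationModel(9.719e-5, 1.84, config.year_tag)
    return cal


def stage_fit(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "fit")
    fruit = pd.read_csv(outdir / "fruit.csv")
    model_fm = growth.fit_sigmoid(fruit, "fm")
    model_c = growth.fit_sigmoid(fruit, "c_fruit")
    conv = growth.fit_diameter_conversion()

    harvest_rows = fruit[fruit["dafb"] == fruit["dafb"].max()]
    dm_h = float(harvest_rows["dm_rel"].mean())
    c_rel_h = float(harvest_rows["c_rel"].mean())
    dm_0 = float(fruit[fruit["dafb"] == fruit["dafb"].min()]["dm_rel"].mean())
    c_rel_0 = float(fruit[fruit["dafb"] == fruit["dafb"].min()]["c_rel"].mean())

    curves = pd.concat(
        [
            growth.scaled_growth_curve(
                model_fm, model_c, conv, d,
                dm_rel=(dm_0, dm_h), c_rel=(c_rel_0, c_rel_h),
            )
            for d in config.target_diameters
        ],
        ignore_index=True,
    )
    _write_csv(curves, outdir / "growth_curves.csv")

    resp = pd.read_csv(outdir / "respiration.csv")
    resp_model = respiration.fit_respiration(resp)
    resp_model.to_json(str(outdir / "respiration_model.json"))

    light = pd.read_csv(outdir / "light_response.csv")
    fits = gas_exchange.fit_panel(light)
    _write_csv(gas_exchange.fits_to_frame(fits), outdir / "gas_exchange_fits.csv")
    alpha_mean, alpha_sd = gas_exchange.pool_alpha(fits)
    jmax = gas_exchange.nonstomatal_jmax(fits)
    with open(outdir / "gas_exchange_summary.json", "w") as fh:
        json.dump(
            {"max_alpha": alpha_mean, "max_alpha_sd": alpha_sd,
             "max_j_nonstomatal": jmax, "n_curves": len(fits)},
            fh, indent=2,
        )
    with open(outdir / "growth_models.json", "w") as fh:
        json.dump(
            {
                "fm": vars(model_fm) | {"response": "fm"},
                "c_fruit": vars(model_c) | {"response": "c_fruit"},
                "conversion": {"coefficient": conv.coefficient,
                               "exponent": conv.exponent},
            },
            fh, indent=2,
        )


def stage_balance(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "balance")
    weather = pd.read_csv(outdir / "weather.csv")
    trees_la = pd.read_csv(outdir / "trees_la.csv")
    curves = pd.read_csv(outdir / "growth_curves.csv")
    resp_model = respiration.RespirationModel.from_json(
        str(outdir / "respiration_model.json")
    )
    with open(outdir / "gas_exchange_summary.json") as fh:
        gx = json.load(fh)

    table, ref = balance.fbc_table(
        weather, curves, resp_model, trees_la,
        gx["max_alpha"], gx["max_j_nonstomatal"], config.params,
    )
    _write_csv(table, outdir / "fbc.csv")
    _write_csv(ref.table, outdir / "demand_series.csv")

    # season summary surface over the default (D, LA) grid: the leaf-area
    # percentile levels of the orchard plus the span ends
    la_grid = np.array([2.7, 3.6, 5.5, 7.7, 9.5])
    rows = []
    for la_v in la_grid:
        ds = balance.build_demand_series(
            weather, curves, resp_model, float(la_v),
            gx["max_alpha"], gx["max_j_nonstomatal"], config.params,
        )
        for d in config.target_diameters:
            rows.append({"d": float(d), "la": float(la_v),
                         "la_demand": ds.mean_windowed_demand(float(d))})
    grid = pd.DataFrame(rows)
    reg = balance.fit_demand_regression(grid, config.year_tag)
    _write_csv(grid, outdir / "demand_grid.csv")
    with open(outdir / "demand_regression.json", "w") as fh:
        json.dump(vars(reg), fh, indent=2)

    # absorbed energy per tree from canopy closure to harvest
    canopy_date = balance.gdd_canopy_date(weather)
    harvest_dafb = float(weather["dafb"].max())
    tape_vals = [
        balance.tape(float(li), weather, (canopy_date, harvest_dafb), config.params)
        for li in table["li"]
    ]
    tape_df = pd.DataFrame(
        {"tree_id": table["tree_id"], "li": table["li"], "tape": tape_vals,
         "canopy_date_dafb": canopy_date}
    )
    _write_csv(tape_df, outdir / "tape.csv")
    with open(outdir / "window.json", "w") as fh:
        json.dump({"window": list(ref.window), "canopy_date": canopy_date}, fh)


def stage_spatial(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "spatial")
    fbc_df = pd.read_csv(outdir / "fbc.csv")
    trees_la = pd.read_csv(outdir / "trees_la.csv")
    tape_df = pd.read_csv(outdir / "tape.csv")
    with open(outdir / "demand_regression.json") as fh:
        reg = balance.DemandRegression(**json.load(fh))

    ref_d = min(config.target_diameters)
    merged = pd.merge(fbc_df, trees_la[["tree_id", "x", "y"]], on="tree_id")
    values = np.asarray(merged[f"fbc_{ref_d:g}"], float)
    positions = merged[["x", "y"]].to_numpy()
    results = spatial.gi_star(values, positions, merged["tree_id"].tolist())
    _, summary = spatial.classify_spots(
        results, positions, values, path=str(outdir / "hotspots.geojson")
    )
    _write_csv(summary, outdir / "hotspot_summary.csv")
    zdf = pd.DataFrame(
        {"tree_id": [r.tree_id for r in results],
         "z": [r.z for r in results],
         "category": [r.category for r in results]}
    )
    _write_csv(zdf, outdir / "gi_star.csv")

    # synthetic harvest at the self-consistent crop load, then quality
    conv = growth.fit_diameter_conversion()
    sc = config.synthetic
    df = pd.merge(merged, tape_df[["tree_id", "tape"]], on="tree_id")
    count = np.asarray(df[f"fbc_{ref_d:g}"], float)
    for _ in range(8):  # fixed point: count = FBC(diameter(fm(TAPE/count)))
        tape_pf = df["tape"] / np.maximum(count, 1.0)
        fm_mean = sc.fm_tape_intercept + sc.fm_tape_slope * tape_pf
        d_mean = conv.diameter(fm_mean)
        demand = reg.demand(d_mean, df["la_m2"])
        count = np.floor(df["la_m2"] * balance.M2_TO_CM2 / np.maximum(demand, 1.0))
    rng = np.random.default_rng([sc.seed, 98])
    crop_load = np.maximum(rng.poisson(np.maximum(count, 1.0)), 1)
    tape_pf = np.asarray(df["tape"] / crop_load, float)
    harvest = synthetic.generate_harvest(df, tape_pf, sc, crop_load)
    harvest.to_csv(outdir / "harvest.csv", index=False)

    hsum = spatial.summarize_harvest(harvest)
    tape_tbl = pd.DataFrame(
        {"tree_id": df["tree_id"], "tape": df["tape"], "tape_per_fruit": tape_pf}
    )
    regs = spatial.quality_regressions(hsum, tape_tbl)
    _write_csv(pd.DataFrame([vars(r) for r in regs]),
               outdir / "quality_regressions.csv")

    # validation ratio: harvested fruit > 65 mm vs FBC at the actual mean D
    actual = pd.merge(hsum, df[["tree_id", "la_m2"]], on="tree_id")
    mean_d = conv.diameter(np.asarray(actual["mean_fm"], float))
    dem = reg.demand(mean_d, actual["la_m2"])
    fbc_actual = pd.DataFrame(
        {"tree_id": actual["tree_id"],
         "fbc": np.floor(actual["la_m2"] * balance.M2_TO_CM2 / dem)}
    )
    _, ratio_mean, ratio_sd = spatial.fbc_vs_harvest_ratio(hsum, fbc_actual)
    with open(outdir / "validation_ratio.json", "w") as fh:
        json.dump({"ratio_mean": ratio_mean, "ratio_sd": ratio_sd,
                   "n_trees": int(len(actual))}, fh, indent=2)


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    summary: dict = {"year_tag": config.year_tag, "seed": config.seed}
    fbc_path = outdir / "fbc.csv"
    if fbc_path.exists():
        fbc_df = pd.read_csv(fbc_path)
        for d in config.target_diameters:
            col = f"fbc_{d:g}"
            if col in fbc_df:
                summary[f"fbc_{d:g}_mean"] = float(fbc_df[col].mean())
                summary[f"fbc_{d:g}_range"] = [int(fbc_df[col].min()),
                                               int(fbc_df[col].max())]
        summary["la_percentiles_5_50_95"] = [
            float(np.percentile(fbc_df["la_m2"], q)) for q in (5, 50, 95)
        ]
        summary["li_mean"] = float(fbc_df["li"].mean())
    for name in ("validation_ratio.json", "window.json", "gas_exchange_summary.json"):
        p = outdir / name
        if p.exists():
            with open(p) as fh:
                summary[name.removesuffix(".json")] = json.load(fh)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


_STAGE_FN = {
    "synth": stage_synth,
    "fit": stage_fit,
    "balance": stage_balance,
    "spatial": stage_spatial,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if not report["ok"]:
        raise ConfigurationError(f"input validation failed: {report['errors']}")

    ran = []
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FN[stage](config, outdir)
        dt = time.perf_counter() - t0
        log.info("stage %-8s finished in %.2f s", stage, dt)
        ran.append({"stage": stage, "seconds": round(dt, 3)})

    hashes = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {
        "seed": config.seed,
        "year_tag": config.year_tag,
        "stages": ran,
        "outputs": hashes,
        "validation": report,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
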