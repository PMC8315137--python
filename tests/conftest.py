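import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from orchard_fbc.config import PipelineConfig, SyntheticConfig
from orchard_fbc.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_synth() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> Path:
    """One full synthetic end-to-end run at the package defaults."""
    outdir = tmp_path_factory.mktemp("orchard") / "run"
    cfg = PipelineConfig(outdir=str(outdir), seed=0)
    run_pipeline(cfg)
    return outdir


@pytest.fixture(scope="session")
def default_run_tables(default_run):
    """Frequently used outputs of the default run, loaded once."""
    out = {
        "fbc": pd.read_csv(default_run / "fbc.csv"),
        "weather": pd.read_csv(default_run / "weather.csv"),
        "curves": pd.read_csv(default_run / "growth_curves.csv"),
        "grid": pd.read_csv(default_run / "demand_grid.csv"),
        "trees_la": pd.read_csv(default_run / "trees_la.csv"),
    }
    with open(default_run / "demand_regression.json") as fh:
        out["regression"] = json.load(fh)
    with open(default_run / "gas_exchange_summary.json") as fh:
        out["gas_exchange"] = json.load(fh)
    with open(default_run / "validation_ratio.json") as fh:
        out["ratio"] = json.load(fh)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
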