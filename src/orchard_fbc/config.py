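"""Configuration objects for the synthetic orchard and the carbon-balance model.

Two parameter blocks drive everything:

``OrchardParams``
    The physical/physiological constants of the big-leaf canopy model
    (ground area allotted per tree, light-extinction coefficient, maximum
    light interception, carbon partitioning to fruit, PAR fraction, the
    PPFR-to-irradiance energy conversion, and the fruit-photosynthesis
    correction).  Defaults are the reference parameterization of the model.

``SyntheticConfig``
    Ground-truth parameters of the synthetic orchard generator: orchard
    geometry, the per-tree leaf-area distribution, fruit growth/respiration
    truth curves, leaf light-response truth parameters and weather-process
    parameters.  The generator is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration block violates its invariants."""


@dataclass
class OrchardParams:
    """Constants of the canopy carbon-balance model.

    Attributes
    ----------
    g_allotted : float
        Orchard ground area allotted per tree (m**2); 3.2 for a
        3.2 m x 1.0 m planting.
    k : float
        Canopy light-extinction coefficient (dimensionless).
    li_max : float
        Maximum fraction of incident radiation the canopy row can intercept.
    c_part : float
        Fraction of daily assimilated carbon partitioned to fruit once the
        canopy is fully developed.
    par_fraction : float
        Fraction of global solar radiation that is photosynthetically active.
    ppfr_to_s : float
        Energy content of one micromole of PAR photons in direct sunlight
        (J umol**-1); converts quantum yield to an energy basis.
    fruit_photo_correction : float
        Multiplier (< 1) on the fruit carbon requirement crediting fruit
        skin photosynthesis.
    """

    g_allotted: float = 3.2
    k: float = 0.5
    li_max: float = 0.7
    c_part: float = 0.8
    par_fraction: float = 0.5
    ppfr_to_s: float = 0.4376
    fruit_photo_correction: float = 0.95

    def validate(self) -> None:
        if not 0 < self.g_allotted:
            raise ConfigurationError("g_allotted must be positive")
        if not 0 < self.k <= 2:
            raise ConfigurationError("k outside physical range (0, 2]")
        if not 0 < self.li_max <= 1:
            raise ConfigurationError("li_max must be in (0, 1]")
        for name in ("c_part", "par_fraction", "fruit_photo_correction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        if self.ppfr_to_s <= 0:
            raise ConfigurationError("ppfr_to_s must be positive")


# Log-normal parameters solved by least squares on the log of the three
# leaf-area percentile targets (5th/50th/95th = 3.6/5.5/7.7 m**2).
_LA_MU = 1.6756
_LA_SIGMA = 0.2311


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic orchard generator.

    ``seed = None`` means "inherit from the enclosing PipelineConfig";
    standalone use treats it as 0.
    """

    seed: int | None = 0
    n_rows: int = 5
    trees_per_row: int = 200
    row_spacing: float = 3.2
    tree_spacing: float = 1.0
    season_length: int = 116
    budbreak_offset: int = 38  # days from bud break to full bloom

    # per-tree leaf area (m**2): log-normal, truncated to [2, 10]
    la_lognormal_mu_sigma: tuple[float, float] = (_LA_MU, _LA_SIGMA)
    la_bounds: tuple[float, float] = (2.0, 10.0)

    # fruit growth truth (logistic in DAFB)
    fm_harvest_mean: float = 145.0  # g at harvest
    fm_midpoint_frac: float = 0.8  # logistic midpoint as fraction of season
    fm_rate: float = 0.075  # d**-1
    fm_cv: float = 0.15  # per-fruit coefficient of variation
    dm_rel_mean: float = 0.15
    dm_rel_sd: float = 0.01
    c_rel_start_end: tuple[float, float] = (0.51, 0.48)

    # fruit dark respiration truth: rd_ref * exp(-lambda*DAFB) * q10**((T-20)/10)
    q10: float = 2.0
    rd_ref: float = 0.11  # g CO2 kg**-1 h**-1 at 20 degC, 0 DAFB
    rd_dafb_decline: float = 0.008  # d**-1
    rd_noise_sd: float = 0.08  # log-normal sigma

    # leaf light-response truth
    alpha_true: float = 0.054  # mol CO2 mol**-1 photons
    jmax_true: float = 19.8  # umol m**-2 s**-1
    rd_leaf_true: float = 1.0  # umol m**-2 s**-1
    leaf_noise_sd: float = 0.3  # umol m**-2 s**-1, additive

    # weather process
    weather_params: dict = field(
        default_factory=lambda: {
            "t_base": 8.0,  # degC, 24-h mean baseline
            "t_amp": 12.0,  # seasonal amplitude
            "t_noise_sd": 1.5,
            "t_day_offset": 5.0,  # daytime mean above 24-h mean
            "s_base": 16.0,  # MJ m**-2 d**-1 clear sky baseline
            "s_amp": 10.0,
            "dl_base_h": 14.0,
            "dl_amp_h": 2.0,
            "cloud_beta": (5.0, 2.0),  # beta params; scaled to (0.2, 1.0]
        }
    )

    # point clouds
    cloud_noise: dict = field(
        default_factory=lambda: {
            "spill_fraction": 0.05,  # points beyond the 0.5 m cylinder
            "canopy_radius": 0.45,  # m, horizontal
            "canopy_height": (0.8, 2.3),  # m band of the canopy ellipsoid
            "trunk_points": 400,
        }
    )

    # optional spatial leaf-area patches: list of dicts with keys
    # row_range=(lo, hi), tree_range=(lo, hi), delta_la (m**2)
    hotspot_spec: list | None = None

    # harvest / quality truth
    crop_load_mean: float = 110.0  # fruit per tree
    fm_tape_slope: float = 6.0  # g per (MJ fruit**-1)
    fm_tape_intercept: float = 100.0  # g at zero TAPE per fruit
    fm_tree_sd: float = 18.0  # within-tree fruit FM spread (g)
    ssc_tape_slope: float = 0.45  # % per (MJ fruit**-1)
    ssc_tape_intercept: float = 9.0  # %
    ssc_sd: float = 1.0

    def validate(self) -> None:
        if self.n_rows <= 0 or self.trees_per_row <= 0:
            raise ConfigurationError("tree counts must be positive")
        if self.season_length < 30:
            raise ConfigurationError("season_length must be >= 30 days")
        if self.row_spacing <= 0 or self.tree_spacing <= 0:
            raise ConfigurationError("spacings must be positive")
        for name in ("dm_rel_mean",):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        for v in self.c_rel_start_end:
            if not 0 < v < 1:
                raise ConfigurationError("c_rel values must be in (0, 1)")
        if self.q10 < 1 or self.q10 > 4:
            raise ConfigurationError("q10 outside accepted range [1, 4]")
        if not 0 < self.alpha_true < 0.125:
            raise ConfigurationError("alpha_true outside quantum limit (0, 0.125)")

    @property
    def harvest_dafb(self) -> int:
        return self.season_length

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """One run of the full pipeline: stage toggles, targets, paths."""

    outdir: str = "orchard_run"
    seed: int = 0
    year_tag: str = "2018"
    target_diameters: Sequence[float] = (65.0, 70.0, 75.0, 80.0)
    stages: Sequence[str] = ("synth", "fit", "balance", "spatial", "report")
    synthetic: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(seed=None)
    )
    params: OrchardParams = field(default_factory=OrchardParams)
    write_point_clouds: bool = False
    n_reference_trees: int = 7  # trees with manual leaf area for calibration

    def __post_init__(self) -> None:
        if self.synthetic.seed is None:
            self.synthetic.seed = self.seed

    def validate(self) -> None:
        self.synthetic.validate()
        self.params.validate()
        if not self.target_diameters:
            raise ConfigurationError("at least one target diameter required")
        for d in self.target_diameters:
            if not 40 <= d <= 120:
                raise ConfigurationError(f"target diameter {d} mm implausible")
        known = {"synth", "fit", "balance", "spatial", "report"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synthetic", {}) or {}
        synth = SyntheticConfig(**synth_raw)
        params = OrchardParams(**(raw.pop("params", {}) or {}))
        cfg = cls(synthetic=synth, params=params, **raw)
        # propagate the top-level seed into the generator unless overridden
        if "seed" in raw and "seed" not in synth_raw:
            cfg.synthetic.seed = cfg.seed
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        raw["target_diameters"] = list(self.target_diameters)
        raw["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
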