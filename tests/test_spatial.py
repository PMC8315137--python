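"""Getis-Ord Gi* classification and fruit-quality regressions."""

import math

import numpy as np
import pandas as pd
import pytest

from orchard_fbc.spatial import (
    QualityRegression,
    fbc_vs_harvest_ratio,
    gi_star,
    classify_spots,
    marketable_threshold,
    quality_regressions,
    summarize_harvest,
)


def brute_force_gi_star(values, positions, radius):
    """Independent loop implementation of the self-inclusive Gi* z-score."""
    x = list(map(float, values))
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)
    out = []
    for i in range(n):
        wsum = 0.0
        wxsum = 0.0
        s1 = 0.0
        for j in range(n):
            dx = positions[i][0] - positions[j][0]
            dy = positions[i][1] - positions[j][1]
            if dx * dx + dy * dy <= radius * radius:
                wsum += 1.0
                wxsum += x[j]
                s1 += 1.0
        denom = s * math.sqrt((n * s1 - wsum * wsum) / (n - 1))
        out.append((wxsum - xbar * wsum) / denom if denom > 0 else 0.0)
    return out


def _grid_positions(nx, ny, dx=1.0, dy=1.0):
    return [(i * dx, j * dy) for i in range(nx) for j in range(ny)]


class TestGiStar:
    @pytest.mark.parametrize("n,seed", [(10, 0), (30, 1), (50, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 12, size=(n, 2))
        vals = rng.normal(100, 15, size=n)
        ours = gi_star(vals, pos, neighborhood_radius=3.5)
        oracle = brute_force_gi_star(vals, pos.tolist(), 3.5)
        for r, z_ref in zip(ours, oracle):
            if r.category == "isolated":
                continue
            assert r.z == pytest.approx(z_ref, abs=1e-9)

    def test_planted_patch_on_5x5_grid_is_hot(self):
        pos = _grid_positions(5, 5)
        vals = np.full(25, 100.0)
        for i, (x, y) in enumerate(pos):
            if 1 <= x <= 3 and 1 <= y <= 3:
                vals[i] = 160.0
        res = gi_star(vals, pos, neighborhood_radius=1.5)
        center = next(r for r, p in zip(res, pos) if p == (2.0, 2.0))
        assert center.z > 1.96
        assert center.category == "hot"
        corner = next(r for r, p in zip(res, pos) if p == (0.0, 0.0))
        assert corner.category in ("none", "cold")

    def test_constant_field_all_none(self):
        pos = _grid_positions(4, 4)
        res = gi_star(np.full(16, 7.0), pos, neighborhood_radius=1.5)
        assert all(r.category == "none" and r.z == 0.0 for r in res)

    def test_isolated_tree_flagged_and_excluded(self):
        pos = [(0, 0), (1, 0), (2, 0), (50, 50)]
        res = gi_star([1.0, 2.0, 3.0, 99.0], pos, neighborhood_radius=3.5)
        assert res[3].category == "isolated"
        assert all(r.category != "isolated" for r in res[:3])

    def test_z_scores_center_near_zero(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 20, size=(200, 2))
        vals = rng.normal(size=200)
        res = gi_star(vals, pos)
        z = np.array([r.z for r in res if not np.isnan(r.z)])
        assert abs(z.mean()) < 0.2

    def test_classification_monotone_in_value(self):
        rng = np.random.default_rng(4)
        pos = _grid_positions(6, 6)
        vals = rng.normal(100, 10, size=36)
        before = gi_star(vals, pos, neighborhood_radius=1.5)
        bumped = vals.copy()
        bumped[14] += 50.0
        after = gi_star(bumped, pos, neighborhood_radius=1.5)
        assert after[14].z >= before[14].z - 1e-9
        assert not (before[14].category == "hot" and after[14].category == "cold")


class TestClassifySpots:
    def test_category_means_ordered_on_planted_field(self, tmp_path):
        rng = np.random.default_rng(5)
        pos = np.array(_grid_positions(12, 12))
        vals = rng.normal(100, 5, size=144)
        vals[(pos[:, 0] < 4) & (pos[:, 1] < 4)] += 40  # hot patch
        vals[(pos[:, 0] > 8) & (pos[:, 1] > 8)] -= 40  # cold patch
        res = gi_star(vals, pos, neighborhood_radius=1.5)
        layer, summary = classify_spots(res, pos, vals,
                                        path=str(tmp_path / "spots.geojson"))
        means = summary.set_index("category")["mean"]
        assert means["hot"] > means["none"] > means["cold"]
        assert (tmp_path / "spots.geojson").exists()
        assert len(layer["features"]) == 144

    def test_two_independent_seasons_share_few_hot_spots(self):
        rng1, rng2 = np.random.default_rng(6), np.random.default_rng(7)
        pos = np.array(_grid_positions(15, 15))
        hot = []
        for rng in (rng1, rng2):
            vals = rng.normal(100, 10, size=len(pos))
            res = gi_star(vals, pos, neighborhood_radius=1.5)
            hot.append({r.tree_id for r in res if r.category == "hot"})
        union = hot[0] | hot[1]
        if union:
            assert len(hot[0] & hot[1]) / len(union) < 0.30


def _synthetic_summary(rng, n=60, slope=5.0, intercept=100.0, crossing=None):
    tape_pf = rng.uniform(4.0, 11.0, size=n)
    mean_fm = intercept + slope * tape_pf + rng.normal(0, 2.0, size=n)
    df = pd.DataFrame(
        {
            "tree_id": [f"t{i}" for i in range(n)],
            "mean_fm": mean_fm,
            "sd_fm": rng.uniform(10, 20, size=n),
            "pct_gt65": np.clip(20 + 8.1 * tape_pf + rng.normal(0, 2, n), 0, 100)
            if crossing is None
            else np.clip(80 + 10 * (tape_pf - crossing) + rng.normal(0, 2, n), 0, 100),
            "mean_ssc": 9 + 0.4 * tape_pf + rng.normal(0, 0.3, n),
            "pct_ssc12": np.clip(30 + 6 * tape_pf + rng.normal(0, 5, n), 0, 100),
            "yield_kg": rng.uniform(8, 20, size=n),
        }
    )
    tape = pd.DataFrame(
        {"tree_id": df["tree_id"], "tape": tape_pf * 100, "tape_per_fruit": tape_pf}
    )
    return df, tape


class TestQualityRegressions:
    def test_slope_recovered_within_15pct(self, rng):
        hsum, tape = _synthetic_summary(rng, slope=5.0)
        regs = {r.response: r for r in quality_regressions(hsum, tape)}
        assert regs["mean_fm"].slope == pytest.approx(5.0, rel=0.15)
        assert regs["mean_fm"].predictor == "tape_per_fruit"

    def test_null_slope_not_significant(self, rng):
        hsum, tape = _synthetic_summary(rng, slope=0.0)
        regs = {r.response: r for r in quality_regressions(hsum, tape)}
        assert regs["mean_fm"].p_value > 0.05

    def test_single_tree_rejected(self, rng):
        hsum, tape = _synthetic_summary(rng, n=1)
        with pytest.raises(ValueError):
            quality_regressions(hsum, tape)


class TestMarketableThreshold:
    def test_recovers_calibrated_crossing(self, rng):
        hsum, tape = _synthetic_summary(rng, crossing=7.4)
        regs = {r.response: r for r in quality_regressions(hsum, tape)}
        est = marketable_threshold(regs["pct_gt65"], target_pct=80.0)
        assert est == pytest.approx(7.4, rel=0.10)

    def test_flat_response_undefined(self):
        reg = QualityRegression("pct_gt65", "tape_per_fruit", 0.0, 50.0, 0.0, 1.0, 10)
        with pytest.raises(ValueError):
            marketable_threshold(reg)


class TestHarvestRatio:
    def test_exact_harvest_at_fbc_gives_unit_ratio(self):
        hsum = pd.DataFrame(
            {
                "tree_id": ["a", "b"],
                "fruit_count": [100, 120],
                "pct_gt65": [100.0, 100.0],
            }
        )
        fbc = pd.DataFrame({"tree_id": ["a", "b"], "fbc": [100, 120]})
        _, mean, sd = fbc_vs_harvest_ratio(hsum, fbc)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_zero_fruit_tree_excluded_with_warning(self):
        hsum = pd.DataFrame(
            {"tree_id": ["a", "b"], "fruit_count": [100, 50], "pct_gt65": [100.0, 0.0]}
        )
        fbc = pd.DataFrame({"tree_id": ["a", "b"], "fbc": [100, 50]})
        with pytest.warns(UserWarning):
            df, mean, _ = fbc_vs_harvest_ratio(hsum, fbc)
        assert len(df) == 1


def test_summarize_harvest_counts_and_percentages():
    harvest = pd.DataFrame(
        {
            "tree_id": ["a"] * 4 + ["b"] * 2,
            "fm": [100.0, 120, 140, 160, 90, 95],
            "diameter": [64.0, 66, 70, 72, 60, 62],
            "ssc": [11.0, 12, 13, 14, 10, 11],
        }
    )
    out = summarize_harvest(harvest).set_index("tree_id")
    assert out.loc["a", "fruit_count"] == 4
    assert out.loc["a", "pct_gt65"] == pytest.approx(75.0)
    assert out.loc["a", "pct_ssc12"] == pytest.approx(75.0)
    assert out.loc["b", "yield_kg"] == pytest.approx(0.185)
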