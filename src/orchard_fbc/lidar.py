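"""Per-tree segmentation of row point clouds and the PPT-to-leaf-area line.

A mobile LiDAR scan of an orchard row yields a 3-D point cloud.  Trunk
positions are located from a bivariate (x, y) density histogram of points
inside a trunk-height band; a vertical cylinder of 0.5 m radius around each
trunk assigns points to trees ("points per tree", PPT); a linear
calibration against manually defoliated reference trees converts PPT to
total leaf area (LA, m**2).  Published season calibrations:

    LA_2018 = 9.719e-5 * PPT + 1.84
    LA_2019 = 11.712e-5 * PPT + 0.75

Clouds are plain whitespace ``x y z`` text or ASCII PLY; coordinates are
row-aligned metres (registration/georeferencing is assumed done upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class SegmentationError(RuntimeError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationModel:
    """Linear PPT -> LA conversion for one season."""

    slope: float  # m**2 per point
    intercept: float  # m**2
    year_tag: str = ""
    r2: float = float("nan")
    n_reference: int = 0
    ppt_range: tuple[float, float] | None = None  # PPT span of reference trees

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")

    def la(self, ppt):
        ppt = np.asarray(ppt, float)
        if self.ppt_range is not None and np.any(ppt > 2 * self.ppt_range[1]):
            warnings.warn(
                "PPT beyond 2x the calibration range; extrapolated LA",
                stacklevel=2,
            )
        return self.slope * ppt + self.intercept

    def ppt(self, la):
        """Inverse of the calibration line (expected points for a leaf area)."""
        return (np.asarray(la, float) - self.intercept) / self.slope


#: Published season calibrations (slope m**2/point, intercept m**2).
CAL_2018 = CalibrationModel(9.719e-5, 1.84, "2018", r2=0.96, n_reference=6)
CAL_2019 = CalibrationModel(11.712e-5, 0.75, "2019", r2=0.96, n_reference=7)
PUBLISHED_CALIBRATIONS = {"2018": CAL_2018, "2019": CAL_2019}


@dataclass
class SegmentedTree:
    tree_id: str
    trunk_xy: tuple[float, float]
    ppt: int
    cylinder_radius: float = 0.5


# ---------------------------------------------------------------------------
# cloud I/O

def read_cloud(path: str) -> np.ndarray:
    """Read an (n, 3) xyz cloud from whitespace text or ASCII PLY."""
    path = str(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first == "ply":
        return _read_ascii_ply(path)
    return np.loadtxt(path, ndmin=2)[:, :3]


def write_cloud(path: str, points: np.ndarray, fmt: str = "xyz") -> None:
    points = np.asarray(points, float).reshape(-1, 3)
    if fmt == "xyz":
        np.savetxt(path, points, fmt="%.4f")
    elif fmt == "ply":
        header = (
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(points)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, points, fmt="%.4f")
    else:
        raise ValueError(f"unknown cloud format {fmt!r}")


def _read_ascii_ply(path: str) -> np.ndarray:
    with open(path) as fh:
        n = None
        for line in fh:
            tok = line.split()
            if tok[:2] == ["element", "vertex"]:
                n = int(tok[2])
            if tok and tok[0] == "end_header":
                break
        else:
            raise ValueError(f"{path}: no PLY header terminator")
        data = np.loadtxt(fh, ndmin=2)
    if n is not None:
        data = data[:n]
    return data[:, :3]


# ---------------------------------------------------------------------------
# segmentation

def locate_trunks(
    cloud: np.ndarray,
    expected_spacing: float = 1.0,
    bin_size: float = 0.1,
    trunk_band: tuple[float, float] = (0.2, 0.8),
    min_trunks: int = 1,
) -> np.ndarray:
    """Trunk (x, y) positions from a density histogram of trunk-band points.

    Points inside the trunk height band are histogrammed on a 2-D grid of
    ``bin_size``; local density peaks are accepted if separated by at least
    60% of ``expected_spacing`` (denser duplicates merge into the stronger
    peak).  Returns an (m, 2) array ordered along the row axis (the first
    principal direction of the cloud).
    """
    cloud = np.asarray(cloud, float)
    if cloud.size == 0:
        raise SegmentationError("empty cloud")
    band = cloud[(cloud[:, 2] >= trunk_band[0]) & (cloud[:, 2] <= trunk_band[1])]
    if band.size == 0:
        raise SegmentationError("no points in the trunk height band")

    xy = band[:, :2]
    # row axis = first principal direction of the horizontal coordinates
    centred = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]

    x_edges = np.arange(xy[:, 0].min() - bin_size, xy[:, 0].max() + 2 * bin_size, bin_size)
    y_edges = np.arange(xy[:, 1].min() - bin_size, xy[:, 1].max() + 2 * bin_size, bin_size)
    hist, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])

    ii, jj = np.nonzero(hist)
    counts = hist[ii, jj]
    order = np.argsort(counts)[::-1]
    min_sep = 0.6 * expected_spacing
    peaks: list[np.ndarray] = []
    weights: list[float] = []
    for idx in order:
        p = np.array([xc[ii[idx]], yc[jj[idx]]])
        w = counts[idx]
        for q_i, q in enumerate(peaks):
            if np.hypot(*(p - q)) < min_sep:
                # merge into the stronger existing peak (density-weighted)
                peaks[q_i] = (q * weights[q_i] + p * w) / (weights[q_i] + w)
                weights[q_i] += w
                break
        else:
            peaks.append(p)
            weights.append(float(w))
    if len(peaks) < min_trunks:
        raise SegmentationError(
            f"found {len(peaks)} trunks, expected at least {min_trunks}"
        )
    pk = np.array(peaks)
    return pk[np.argsort(pk @ axis)]


def segment_tree(
    cloud: np.ndarray, trunk_xy: tuple[float, float], radius: float = 0.5,
    tree_id: str = "tree",
) -> SegmentedTree:
    """Count points inside the vertical cylinder around one trunk."""
    cloud = np.asarray(cloud, float)
    d = np.hypot(cloud[:, 0] - trunk_xy[0], cloud[:, 1] - trunk_xy[1])
    return SegmentedTree(tree_id, (float(trunk_xy[0]), float(trunk_xy[1])),
                         int(np.sum(d <= radius)), radius)


def segment_row(
    cloud: np.ndarray, trunks: np.ndarray, radius: float = 0.5
) -> list[SegmentedTree]:
    """Partition a row cloud over its trunks.

    Each point inside at least one cylinder is assigned to the *nearest*
    trunk only (adjacent cylinders touch at 1 m spacing with 0.5 m radius),
    so the segmentation is a partition: no point is counted twice.
    """
    cloud = np.asarray(cloud, float)
    trunks = np.asarray(trunks, float).reshape(-1, 2)
    d = np.hypot(
        cloud[:, 0, None] - trunks[None, :, 0],
        cloud[:, 1, None] - trunks[None, :, 1],
    )
    nearest = np.argmin(d, axis=1)
    inside = d[np.arange(len(cloud)), nearest] <= radius
    out = []
    for t in range(len(trunks)):
        ppt = int(np.sum(inside & (nearest == t)))
        out.append(
            SegmentedTree(f"tree_{t:04d}", (float(trunks[t, 0]), float(trunks[t, 1])),
                          ppt, radius)
        )
    return out


# ---------------------------------------------------------------------------
# calibration

def fit_calibration(
    ppt_list, manual_la_list, year_tag: str = ""
) -> CalibrationModel:
    """Ordinary least squares LA = slope * PPT + intercept on reference trees."""
    ppt = np.asarray(ppt_list, float)
    la = np.asarray(manual_la_list, float)
    if ppt.size < 3:
        raise CalibrationError("need >= 3 reference trees")
    if np.unique(ppt).size < 2:
        raise CalibrationError("degenerate design: all reference PPT identical")
    slope, intercept = np.polyfit(ppt, la, 1)
    pred = slope * ppt + intercept
    ss_res = float(np.sum((la - pred) ** 2))
    ss_tot = float(np.sum((la - la.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(
        float(slope), float(intercept), year_tag, r2, int(ppt.size),
        (float(ppt.min()), float(ppt.max())),
    )


def ppt_to_la(ppt, model: CalibrationModel):
    """Evaluate the calibration line (m**2); warns beyond 2x its PPT range."""
    return model.la(ppt)


def trees_la_frame(trees: list[SegmentedTree], model: CalibrationModel) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [t.tree_id for t in trees],
            "x": [t.trunk_xy[0] for t in trees],
            "y": [t.trunk_xy[1] for t in trees],
            "ppt": [t.ppt for t in trees],
            "la_m2": model.la([t.ppt for t in trees]),
        }
    )
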