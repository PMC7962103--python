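"""Circular-window scan for positivity extremes and heatmaps.

The scored compartments beyond the full section are fixed-size circular
windows of diameter 0.5 mm (area π·0.25² ≈ 0.196 mm², one 400× high-power
field):

* **hot spot** — the window with the highest proportion of positive cells
  anywhere in the tumor;
* **cold spot** — the window with the lowest proportion anywhere;
* **scleral margin spot** — the lowest-proportion window whose center lies
  within 1 mm of the tumor base toward the sclera.

Candidate window centers are a regular grid (default spacing 50 µm)
clipped to the ROI — the reproducible surrogate for repeated manual
placement of a circle over a heatmap.  Windows may protrude past the ROI
boundary (a circle at the tumor edge is legitimate); only classifiable
in-ROI cells are ever counted, because excluded cells carry the
``excluded`` label.  A minimum-cellularity floor (default 100 classifiable
cells) prevents degenerate one-cell "extremes" at the tumor edge.

Ties between equally extreme windows are broken deterministically: larger
classifiable-cell count first, then smaller y, then smaller x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, NoValidSpotError, ValidationError
from .io_formats import TumorGeometry


@dataclass(frozen=True)
class ScanParams:
    """Geometry of the window scan.

    ``spot_diameter`` is fixed by the scoring protocol at 500 µm;
    ``margin_distance`` is the width of the peri-scleral band measured
    from the tumor base polyline.
    """

    spot_diameter: float = 500.0      # µm
    candidate_spacing: float = 50.0   # µm; grid pitch of candidate centers
    min_cells_per_spot: int = 100     # classifiable cells required per window
    margin_distance: float = 1000.0   # µm; scleral band width

    def __post_init__(self) -> None:
        if not self.candidate_spacing <= self.spot_diameter / 2:
            raise ValidationError("candidate_spacing must be <= spot_diameter / 2")
        if self.min_cells_per_spot < 1:
            raise ValidationError("min_cells_per_spot must be >= 1")

    @property
    def window_area_mm2(self) -> float:
        """Window area in mm² (≈ 0.196 for the 0.5 mm default)."""
        r_mm = self.spot_diameter / 2 / 1000.0
        return float(np.pi * r_mm**2)


@dataclass(frozen=True)
class Spot:
    """One scored circular window."""

    center: tuple[float, float]
    diameter: float
    n_positive: int
    n_negative: int
    proportion: float  # percent positive, [0, 100]
    compartment: str   # hot | cold | scleral

    @property
    def n_cells(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class Heatmap:
    """Gridded local positivity, percent in [0, 100]; NaN where the window
    held fewer than the required number of classifiable cells."""

    grid_origin: tuple[float, float]
    cell_size: float
    values: np.ndarray  # shape (ny, nx), row i ~ y = origin_y + i*cell_size

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.grid_origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.grid_origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


def _classified_xy(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) arrays of positive and negative cells respectively."""
    lab = cells["label"].to_numpy()
    xy = cells[["x", "y"]].to_numpy(float)
    return xy[lab == "positive"], xy[lab == "negative"]


def spot_proportion(
    cells: pd.DataFrame, center: tuple[float, float], diameter: float
) -> tuple[int, int, float]:
    """Counts and percent positive within one circular window.

    Counts classifiable cells whose centroid lies within ``diameter/2`` of
    ``center`` (boundary inclusive); excluded cells are ignored.  Returns
    ``(n_positive, n_negative, proportion)``; the proportion is NaN when
    the window holds no classifiable cell (empty-window sentinel).
    """
    if not diameter > 0:
        raise ValidationError("diameter must be > 0")
    pos_xy, neg_xy = _classified_xy(cells)
    c = np.asarray(center, float)
    r = diameter / 2.0
    n_pos = int((np.hypot(*(pos_xy - c).T) <= r).sum()) if len(pos_xy) else 0
    n_neg = int((np.hypot(*(neg_xy - c).T) <= r).sum()) if len(neg_xy) else 0
    if n_pos + n_neg == 0:
        return 0, 0, float("nan")
    return n_pos, n_neg, 100.0 * n_pos / (n_pos + n_neg)


def candidate_centers(
    geometry: TumorGeometry,
    spacing: float,
    constraint_region: BaseGeometry | None = None,
) -> np.ndarray:
    """Regular grid of candidate window centers clipped to the ROI.

    The grid is anchored at the ROI bounding-box corner, so it depends only
    on the geometry and spacing (deterministic).  When ``constraint_region``
    is given, centers must also fall inside it (boundary inclusive).
    """
    minx, miny, maxx, maxy = geometry.roi.bounds
    xs = np.arange(minx, maxx + spacing / 2, spacing)
    ys = np.arange(miny, maxy + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    pts = shapely.points(centers[:, 0], centers[:, 1])
    keep = shapely.covers(geometry.roi, pts)
    if constraint_region is not None:
        keep &= shapely.covers(constraint_region, pts)
    return centers[keep]


def _window_counts(
    pos_xy: np.ndarray, neg_xy: np.ndarray, centers: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-center counts of positive and negative cells within radius
    (boundary inclusive), via KD-trees."""
    n = len(centers)
    n_pos = np.zeros(n, dtype=np.int64)
    n_neg = np.zeros(n, dtype=np.int64)
    if len(pos_xy):
        n_pos[:] = cKDTree(pos_xy).query_ball_point(centers, radius, return_length=True)
    if len(neg_xy):
        n_neg[:] = cKDTree(neg_xy).query_ball_point(centers, radius, return_length=True)
    return n_pos, n_neg


def _pick_extreme(
    centers: np.ndarray,
    n_pos: np.ndarray,
    n_neg: np.ndarray,
    mode: Literal["max", "min"],
    min_cells: int,
) -> int:
    """Index of the extreme window under the deterministic tie order:
    extreme proportion, then larger cell count, then smaller y, then
    smaller x."""
    n_tot = n_pos + n_neg
    valid = n_tot >= min_cells
    if not valid.any():
        raise NoValidSpotError(
            f"no candidate window holds >= {min_cells} classifiable cells"
        )
    prop = np.full(len(centers), np.nan)
    prop[valid] = n_pos[valid] / n_tot[valid]
    key = -prop if mode == "max" else prop
    key[~valid] = np.inf
    # lexsort: last key is most significant
    order = np.lexsort((centers[:, 0], centers[:, 1], -n_tot, key))
    return int(order[0])


def find_extreme_spot(
    cells: pd.DataFrame,
    geometry: TumorGeometry,
    params: ScanParams | None = None,
    mode: Literal["max", "min"] = "max",
    constraint_region: BaseGeometry | None = None,
    compartment: str | None = None,
) -> Spot:
    """The candidate window with the highest (``max``) or lowest (``min``)
    proportion of positive cells.

    Only windows holding at least ``params.min_cells_per_spot``
    classifiable cells compete; raises :class:`NoValidSpotError` when none
    does.  Deterministic for fixed inputs regardless of cell ordering.
    """
    params = params or ScanParams()
    if mode not in ("max", "min"):
        raise ValidationError(f"mode must be 'max' or 'min', got {mode!r}")
    centers = candidate_centers(geometry, params.candidate_spacing, constraint_region)
    if len(centers) == 0:
        raise NoValidSpotError("no candidate centers inside the searched region")
    pos_xy, neg_xy = _classified_xy(cells)
    n_pos, n_neg = _window_counts(pos_xy, neg_xy, centers, params.spot_diameter / 2)
    i = _pick_extreme(centers, n_pos, n_neg, mode, params.min_cells_per_spot)
    np_i, nn_i = int(n_pos[i]), int(n_neg[i])
    return Spot(
        center=(float(centers[i, 0]), float(centers[i, 1])),
        diameter=params.spot_diameter,
        n_positive=np_i,
        n_negative=nn_i,
        proportion=100.0 * np_i / (np_i + nn_i),
        compartment=compartment or ("hot" if mode == "max" else "cold"),
    )


def base_band(geometry: TumorGeometry, margin_distance: float) -> BaseGeometry:
    """The peri-scleral band: points within ``margin_distance`` of the
    tumor base polyline (point-to-segment Euclidean distance)."""
    if geometry.base_polyline is None:
        raise GeometryError("geometry has no base polyline")
    return geometry.base_polyline.buffer(margin_distance)


def find_scleral_margin_spot(
    cells: pd.DataFrame, geometry: TumorGeometry, params: ScanParams | None = None
) -> Spot:
    """Lowest-proportion window whose *center* lies within
    ``params.margin_distance`` of the tumor base (the window itself may
    protrude beyond the band or the ROI)."""
    params = params or ScanParams()
    band = base_band(geometry, params.margin_distance)
    return find_extreme_spot(
        cells, geometry, params, mode="min", constraint_region=band,
        compartment="scleral",
    )


def coldspot_within_base_band(
    cold: Spot, geometry: TumorGeometry, margin_distance: float = 1000.0
) -> bool:
    """Whether the cold spot sits in the peri-scleral band
    (distance from its center to the base polyline ≤ ``margin_distance``,
    boundary inclusive)."""
    if geometry.base_polyline is None:
        raise GeometryError("geometry has no base polyline")
    d = geometry.base_polyline.distance(shapely.Point(cold.center))
    return bool(d <= margin_distance)


def build_heatmap(
    cells: pd.DataFrame,
    geometry: TumorGeometry,
    cell_size: float = 100.0,
    window_radius: float = 250.0,
    min_cells: int = 20,
) -> Heatmap:
    """Local positivity on a regular grid for visualization.

    Each grid cell stores the window proportion at its center; NaN where
    the window holds fewer than ``min_cells`` classifiable cells or the
    center falls outside the ROI.
    """
    minx, miny, maxx, maxy = geometry.roi.bounds
    nx = max(1, int(np.ceil((maxx - minx) / cell_size)))
    ny = max(1, int(np.ceil((maxy - miny) / cell_size)))
    xs = minx + (np.arange(nx) + 0.5) * cell_size
    ys = miny + (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.covers(geometry.roi, shapely.points(centers[:, 0], centers[:, 1]))

    pos_xy, neg_xy = _classified_xy(cells)
    n_pos, n_neg = _window_counts(pos_xy, neg_xy, centers, window_radius)
    n_tot = n_pos + n_neg
    vals = np.full(len(centers), np.nan)
    ok = inside & (n_tot >= max(1, min_cells))
    vals[ok] = 100.0 * n_pos[ok] / n_tot[ok]
    return Heatmap(grid_origin=(float(minx), float(miny)), cell_size=float(cell_size),
                   values=vals.reshape(ny, nx))


def plot_heatmap(heatmap: Heatmap, ax=None, spots: list[Spot] | None = None):
    """Render the heatmap with the conventional blue→green→red colormap
    (low → high positivity); optionally overlay scored spots."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots()
    ny, nx = heatmap.values.shape
    x0, y0 = heatmap.grid_origin
    extent = (x0, x0 + nx * heatmap.cell_size, y0 + ny * heatmap.cell_size, y0)
    im = ax.imshow(heatmap.values, cmap="jet", vmin=0, vmax=100, extent=extent,
                   origin="upper", interpolation="nearest")
    for spot in spots or []:
        ax.add_patch(Circle(spot.center, spot.diameter / 2, fill=False,
                            ec="black", lw=1.5))
        ax.annotate(spot.compartment, spot.center, ha="center", fontsize=8)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.figure.colorbar(im, ax=ax, label="% positive cells")
    return ax


def spots_table(tumor_id: str, spots: list[Spot]) -> pd.DataFrame:
    """Spots as one CSV-ready row per compartment."""
    return pd.DataFrame(
        [
            {
                "tumor_id": tumor_id,
                "compartment": s.compartment,
                "center_x": s.center[0],
                "center_y": s.center[1],
                "n_pos": s.n_positive,
                "n_neg": s.n_negative,
                "proportion": s.proportion,
            }
            for s in spots
        ]
    )
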