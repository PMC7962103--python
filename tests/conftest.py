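"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from bap1scan.io_formats import CELL_COLUMNS, TumorGeometry
from bap1scan.scan import ScanParams, candidate_centers


def make_cells(x, y, *, area=50.0, od=None, label=None) -> pd.DataFrame:
    """Build a canonical cell table from coordinate arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": x,
        "y": y,
        "nucleus_area": np.broadcast_to(np.asarray(area, float), n).copy(),
        "chromogen_od": np.broadcast_to(np.asarray(0.5 if od is None else od, float), n).copy(),
        "counterstain_od": np.full(n, 0.5),
        "label": np.broadcast_to(np.asarray("unclassified" if label is None else label, object), n).copy(),
    })
    return df[CELL_COLUMNS]


@pytest.fixture
def square_geometry() -> TumorGeometry:
    """A 4 x 4 mm square ROI with its base along the bottom edge."""
    roi = Polygon([(0, 0), (4000, 0), (4000, 4000), (0, 4000)])
    base = LineString([(0, 4000), (4000, 4000)])
    return TumorGeometry(roi=roi, base_polyline=base)


def brute_force_extreme_spot(
    cells: pd.DataFrame,
    geometry: TumorGeometry,
    params: ScanParams,
    mode: str,
    constraint_region=None,
):
    """Exhaustive scan oracle: plain-Python loop over the candidate grid
    with per-center numpy distance counts and the documented tie order
    (extreme proportion, larger cell count, smaller y, smaller x).

    Returns ``(center, n_pos, n_neg)`` or None when no window meets the
    minimum-cellularity floor.
    """
    centers = candidate_centers(geometry, params.candidate_spacing, constraint_region)
    lab = cells["label"].to_numpy()
    x = cells["x"].to_numpy(float)
    y = cells["y"].to_numpy(float)
    pos = lab == "positive"
    neg = lab == "negative"
    r = params.spot_diameter / 2.0
    sign = 1.0 if mode == "max" else -1.0
    best_key, best = None, None
    for cx, cy in centers:
        within = np.hypot(x - cx, y - cy) <= r
        n_pos = int((within & pos).sum())
        n_neg = int((within & neg).sum())
        n_tot = n_pos + n_neg
        if n_tot < params.min_cells_per_spot:
            continue
        key = (sign * n_pos / n_tot, n_tot, -cy, -cx)
        if best_key is None or key > best_key:
            best_key, best = key, ((float(cx), float(cy)), n_pos, n_neg)
    return best
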