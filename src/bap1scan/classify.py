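"""Per-slide exemplar calibration and per-cell positivity classification.

The scoring protocol mirrors routine chromogenic IHC review: on each slide
one clearly positive cell (red chromogen in the nucleus) and one clearly
negative cell (hematoxylin only) are designated, and any cell whose
chromogen signal exceeds the calibrated background is counted positive —
staining intensity is binarized, never graded.  A nucleus-size window
(default 30–300 µm²) removes tumor-infiltrating lymphocytes and
segmentation artifacts, and cells inside pathologist-drawn exclusion
regions (necrosis, hemorrhage, inflammation, heavy pigment) are dropped.

The threshold between the two exemplars is their midpoint, which makes
calibration symmetric: swapping in a brighter positive exemplar never
reclassifies a cell dimmer than the negative exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import CalibrationError, EmptyCompartmentError, ValidationError
from .io_formats import TumorGeometry, points_of, validate_cell_table


@dataclass(frozen=True)
class CalibrationPair:
    """Chromogen intensities of the designated positive and negative exemplar."""

    positive_exemplar_od: float
    negative_exemplar_od: float


@dataclass(frozen=True)
class ClassificationParams:
    """Detection parameters.

    ``cell_expansion`` is the upstream detector's cytoplasm expansion; it
    is carried as provenance metadata only and plays no role downstream.
    """

    min_nucleus_area: float = 30.0   # µm²; excludes lymphocyte-sized nuclei
    max_nucleus_area: float = 300.0  # µm²
    cell_expansion: float = 6.0      # µm; metadata only

    def __post_init__(self) -> None:
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise ValidationError("need 0 < min_nucleus_area < max_nucleus_area")


def calibrate_threshold(pair: CalibrationPair) -> float:
    """Positivity threshold from one positive and one negative exemplar.

    Returns the midpoint of the two exemplar intensities.  Raises
    :class:`CalibrationError` when the designated positive cell is not
    strictly brighter than the negative one — the situation that calls for
    re-picking exemplars (e.g. melanin pigment mistaken for chromogen).
    """
    pos, neg = float(pair.positive_exemplar_od), float(pair.negative_exemplar_od)
    if not pos > neg:
        raise CalibrationError(
            f"positive exemplar OD ({pos}) must exceed negative exemplar OD ({neg})"
        )
    return 0.5 * (pos + neg)


def classify_cells(
    cells: pd.DataFrame,
    geometry: TumorGeometry,
    threshold: float,
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Label every cell ``positive``, ``negative`` or ``excluded``.

    A cell is *excluded* when its centroid falls outside the tumor ROI,
    inside any exclusion polygon, or its nucleus area lies outside
    ``[min_nucleus_area, max_nucleus_area]``.  Remaining cells are
    *positive* iff ``chromogen_od > threshold`` (strict: intensity exactly
    at background is not "above" it).  Membership is decided by the
    centroid; polygon boundaries count as inside.

    Returns a new frame; the input is not modified.  The three labels
    partition the cells: ``|positive| + |negative| + |excluded| == |cells|``.
    """
    params = params or ClassificationParams()
    validate_cell_table(cells)
    out = cells.copy()
    if len(out) == 0:
        return out

    pts = points_of(out)
    in_roi = shapely.covers(geometry.roi, pts)
    in_exclusion = np.zeros(len(out), dtype=bool)
    for excl in geometry.exclusions:
        in_exclusion |= shapely.covers(excl, pts)
    area = out["nucleus_area"].to_numpy(float)
    size_ok = (area >= params.min_nucleus_area) & (area <= params.max_nucleus_area)

    excluded = ~in_roi | in_exclusion | ~size_ok
    positive = ~excluded & (out["chromogen_od"].to_numpy(float) > float(threshold))

    label = np.where(excluded, "excluded", np.where(positive, "positive", "negative"))
    out["label"] = label
    return out


def full_section_proportion(labeled: pd.DataFrame) -> float:
    """Percent positive cells over the whole section, ignoring excluded cells.

    ``100 · |positive| / (|positive| + |negative|)``; raises
    :class:`EmptyCompartmentError` when no cell is classifiable.
    """
    n_pos = int((labeled["label"] == "positive").sum())
    n_neg = int((labeled["label"] == "negative").sum())
    if n_pos + n_neg == 0:
        raise EmptyCompartmentError("no classifiable (positive/negative) cells")
    return 100.0 * n_pos / (n_pos + n_neg)
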