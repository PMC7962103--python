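"""Per-tumor orchestration: calibrate, classify, scan, measure."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import (
    CalibrationPair,
    ClassificationParams,
    calibrate_threshold,
    classify_cells,
    full_section_proportion,
)
from .heterogeneity import TumorMeasurements, heterogeneity, tumor_volume
from .io_formats import TumorGeometry
from .scan import (
    ScanParams,
    Spot,
    coldspot_within_base_band,
    find_extreme_spot,
    find_scleral_margin_spot,
)


@dataclass(frozen=True)
class TumorScore:
    """Everything measured on one tumor section."""

    measurements: TumorMeasurements
    hot: Spot
    cold: Spot
    scleral: Spot | None
    threshold: float
    n_cells: int
    n_excluded: int
    cold_in_base_band: bool | None


def score_tumor(
    cells: pd.DataFrame,
    geometry: TumorGeometry,
    calibration: CalibrationPair,
    tumor_id: str = "tumor",
    class_params: ClassificationParams | None = None,
    scan_params: ScanParams | None = None,
    thickness_mm: float | None = None,
    lbd_mm: float | None = None,
) -> TumorScore:
    """Run the full per-tumor measurement: exemplar calibration, cell
    classification, the four compartment scores and heterogeneity.

    The scleral-margin compartment requires a base polyline; without one
    it is reported as missing rather than failing the tumor.
    """
    scan_params = scan_params or ScanParams()
    threshold = calibrate_threshold(calibration)
    labeled = classify_cells(cells, geometry, threshold, class_params)
    full_pct = full_section_proportion(labeled)
    hot = find_extreme_spot(labeled, geometry, scan_params, mode="max")
    cold = find_extreme_spot(labeled, geometry, scan_params, mode="min")
    scleral = None
    in_band = None
    if geometry.base_polyline is not None:
        scleral = find_scleral_margin_spot(labeled, geometry, scan_params)
        in_band = coldspot_within_base_band(cold, geometry, scan_params.margin_distance)
    volume = tumor_volume(thickness_mm, lbd_mm) if thickness_mm and lbd_mm else None
    measurements = TumorMeasurements(
        tumor_id=tumor_id,
        full_pct=full_pct,
        hot_pct=hot.proportion,
        cold_pct=cold.proportion,
        scleral_pct=scleral.proportion if scleral else float("nan"),
        heterogeneity_pp=heterogeneity(hot.proportion, cold.proportion),
        thickness_t=thickness_mm,
        diameter_lbd=lbd_mm,
        volume_mm3=volume,
    )
    return TumorScore(
        measurements=measurements,
        hot=hot,
        cold=cold,
        scleral=scleral,
        threshold=threshold,
        n_cells=len(labeled),
        n_excluded=int((labeled["label"] == "excluded").sum()),
        cold_in_base_band=in_band,
    )
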