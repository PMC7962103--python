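"""Readers and writers for the pipeline's on-disk dialects.

Three kinds of input are handled:

* **Cell detection tables** — tab-separated exports of an upstream
  whole-slide cell detector (one row per detected cell).  Column names
  vary between tools, so a :class:`CellTableDialect` maps the canonical
  fields (``x``, ``y``, ``nucleus_area``, ``chromogen_od``,
  ``counterstain_od``) onto the source columns.  Coordinates are converted
  to micrometres on ingestion.
* **Tumor geometry** — a GeoJSON ``FeatureCollection`` whose features carry
  a ``classification`` property in ``{tumor, base, exclusion}``: exactly one
  tumor ROI polygon, at most one base polyline (the scleral side of the
  tumor), and any number of exclusion polygons (necrosis, hemorrhage,
  inflammation, heavy pigment ...).
* **Cohort tables** — one CSV row per patient with clinical covariates,
  follow-up and the per-compartment positivity scores.

All coordinates are micrometres in image convention: origin top-left,
y increasing downward.  Cells are held in a :class:`pandas.DataFrame` with
the canonical columns of :data:`CELL_COLUMNS`; a row is one cell record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import LineString, Polygon, mapping, shape

from .errors import FormatError, GeometryError, ValidationError

#: canonical columns of a cell table, in order
CELL_COLUMNS = [
    "cell_id",
    "x",
    "y",
    "nucleus_area",
    "chromogen_od",
    "counterstain_od",
    "label",
]

#: allowed cell labels; cells start life unclassified
CELL_LABELS = ("positive", "negative", "excluded", "unclassified")

COMPARTMENTS = ("full", "hot", "cold", "scleral")

#: AJCC tumor size categories accepted in cohort tables (sub-letters
#: collapse onto the numeric category)
T_CATEGORIES = ("1", "2", "3", "4")

GEP_CLASSES = ("1a", "1b", "2")


@dataclass(frozen=True)
class CellTableDialect:
    """Column mapping from canonical cell fields to a detector's export.

    ``microns_per_unit`` rescales the source coordinates to micrometres
    (1.0 when the export is already in µm; the pixel size in µm/px when
    the export is in pixels).
    """

    x: str = "x"
    y: str = "y"
    nucleus_area: str = "nucleus_area"
    chromogen_od: str = "chromogen_od"
    counterstain_od: str = "counterstain_od"
    cell_id: str | None = None
    microns_per_unit: float = 1.0

    def required_columns(self) -> dict[str, str]:
        return {
            "x": self.x,
            "y": self.y,
            "nucleus_area": self.nucleus_area,
            "chromogen_od": self.chromogen_od,
            "counterstain_od": self.counterstain_od,
        }


@dataclass
class TumorGeometry:
    """Tumor ROI, optional base polyline (scleral side) and exclusions.

    Invariants: the ROI is a simple (non-self-intersecting) closed polygon;
    every exclusion polygon intersects the ROI; the base polyline lies on
    or near the ROI boundary.
    """

    roi: Polygon
    base_polyline: LineString | None = None
    exclusions: list[Polygon] = field(default_factory=list)
    microns_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.roi, Polygon) or self.roi.is_empty:
            raise GeometryError("ROI must be a non-empty polygon")
        if not self.roi.is_valid:
            raise GeometryError("ROI polygon is not simple (self-intersecting)")
        for k, excl in enumerate(self.exclusions):
            if not excl.is_valid:
                raise GeometryError(f"exclusion polygon {k} is not simple")
            if not excl.intersects(self.roi):
                raise GeometryError(f"exclusion polygon {k} does not intersect the ROI")

    @property
    def area_um2(self) -> float:
        return float(self.roi.area)


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64") for c in CELL_COLUMNS}).astype(
        {"cell_id": object, "label": object}
    )


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the canonical cell-table invariants; returns the frame."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"cell table missing canonical columns: {missing}")
    for col in ("x", "y"):
        if len(cells) and not np.isfinite(cells[col].to_numpy(float)).all():
            raise ValidationError(f"non-finite values in column {col!r}")
    if len(cells) and not (cells["nucleus_area"].to_numpy(float) > 0).all():
        raise ValidationError("nucleus_area must be > 0")
    bad = set(cells["label"].unique()) - set(CELL_LABELS)
    if bad:
        raise ValidationError(f"unknown cell labels: {sorted(bad)}")
    return cells


def read_cell_table(path: str | Path, dialect: CellTableDialect | None = None) -> pd.DataFrame:
    """Read a detector export into the canonical cell table.

    One output row per input row; coordinates are multiplied by
    ``dialect.microns_per_unit``; all labels start ``unclassified``.
    """
    dialect = dialect or CellTableDialect()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cell table not found: {path}")
    raw = pd.read_csv(path, sep="\t")
    colmap = dialect.required_columns()
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise FormatError(f"cell table {path.name} lacks mapped column(s): {missing}")

    out = pd.DataFrame(index=raw.index)
    for canon, src in colmap.items():
        vals = pd.to_numeric(raw[src], errors="coerce")
        bad = vals.index[vals.isna() & raw[src].notna()]
        if len(bad):
            raise FormatError(
                f"non-numeric value in column {src!r} at row index {int(bad[0])}"
            )
        out[canon] = vals.astype(float)
    m = float(dialect.microns_per_unit)
    if not m > 0:
        raise ValidationError("microns_per_unit must be > 0")
    out["x"] *= m
    out["y"] *= m
    out["nucleus_area"] *= m * m
    if dialect.cell_id and dialect.cell_id in raw.columns:
        out.insert(0, "cell_id", raw[dialect.cell_id].astype(str))
    else:
        out.insert(0, "cell_id", [f"c{i}" for i in range(len(raw))])
    out["label"] = "unclassified"
    return validate_cell_table(out[CELL_COLUMNS])


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical tab-separated cell table (µm units, identity dialect)."""
    validate_cell_table(cells)
    cells.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_geometry(path: str | Path) -> TumorGeometry:
    """Read a GeoJSON FeatureCollection into a :class:`TumorGeometry`.

    Features are routed by their ``classification`` property: exactly one
    ``tumor`` polygon is required; ``base`` (LineString) and ``exclusion``
    (Polygon) features are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"geometry file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    roi = None
    base = None
    exclusions: list[Polygon] = []
    for feat in feats:
        cls = (feat.get("properties") or {}).get("classification", "tumor")
        geom = shape(feat["geometry"])
        if cls == "tumor":
            if roi is not None:
                raise FormatError("multiple tumor ROI features")
            if not isinstance(geom, Polygon):
                raise FormatError("tumor ROI feature is not a polygon")
            roi = geom
        elif cls == "base":
            base = LineString(geom)
        elif cls == "exclusion":
            exclusions.append(Polygon(geom))
        else:
            raise FormatError(f"unknown feature classification {cls!r}")
    if roi is None:
        raise FormatError("geometry file contains no tumor ROI feature")
    return TumorGeometry(roi=roi, base_polyline=base, exclusions=exclusions)


def write_geometry(geom: TumorGeometry, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"classification": "tumor"},
            "geometry": mapping(geom.roi),
        }
    ]
    if geom.base_polyline is not None:
        feats.append(
            {
                "type": "Feature",
                "properties": {"classification": "base"},
                "geometry": mapping(geom.base_polyline),
            }
        )
    for excl in geom.exclusions:
        feats.append(
            {
                "type": "Feature",
                "properties": {"classification": "exclusion"},
                "geometry": mapping(excl),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# cohort tables

COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "ajcc_t_category",
    "gep_class",
    "follow_up_months",
    "metastasis_event",
    "full_pct",
    "hot_pct",
    "cold_pct",
    "scleral_pct",
]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    if (cohort["follow_up_months"].to_numpy(float) < 0).any():
        raise ValidationError("follow_up_months must be >= 0")
    tcat = cohort["ajcc_t_category"].astype(str).str.strip()
    # sub-letters (3a, 3b ...) collapse onto the numeric category
    collapsed = tcat.str.replace(r"^([1-4])[a-e]$", r"\1", regex=True)
    unknown = set(collapsed.unique()) - set(T_CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown AJCC T-category value(s): {sorted(unknown)}")
    cohort = cohort.copy()
    cohort["ajcc_t_category"] = collapsed.astype(int)
    gep = cohort["gep_class"].astype("string").str.strip()
    gep = gep.where(~gep.str.fullmatch("NA|Na|na|nan|None|").fillna(True), other=pd.NA)
    gep = gep.astype(object).where(gep.notna(), other=np.nan)
    unknown = set(gep.dropna().unique()) - set(GEP_CLASSES)
    if unknown:
        raise ValidationError(f"unknown gene expression class value(s): {sorted(unknown)}")
    cohort["gep_class"] = gep
    cohort["metastasis_event"] = cohort["metastasis_event"].astype(int).astype(bool)
    for comp in ("full_pct", "hot_pct", "cold_pct", "scleral_pct"):
        vals = cohort[comp].to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 100))
        if not ok.all():
            raise ValidationError(f"{comp} outside [0, 100]")
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-patient cohort CSV.

    A missing gene expression class is encoded ``NA`` in the file and kept
    as missing (NaN) in memory.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort file not found: {path}")
    cohort = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return validate_cohort(cohort)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["gep_class"] = out["gep_class"].fillna("NA")
    out["metastasis_event"] = out["metastasis_event"].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def load_config(path: str | Path) -> dict:
    """Load the flat YAML run configuration (dialect mapping + parameters)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("configuration must be a mapping")
    return cfg


def dialect_from_config(cfg: dict) -> CellTableDialect:
    return CellTableDialect(**cfg.get("cell_table_dialect", {}))


def points_of(cells: pd.DataFrame) -> np.ndarray:
    """Cell centroids as shapely point geometries (vectorized)."""
    return shapely.points(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
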