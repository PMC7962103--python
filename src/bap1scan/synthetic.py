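"""Synthetic tumors, marked cell point patterns and survival-linked cohorts.

The study measured ~40 enucleated uveal melanomas whose raw data are not
public, so every pipeline stage is exercised on simulated material that
emulates the measured scale and structure:

* **geometry** — a dome-shaped tumor cross-section (half-ellipse with a
  gently wavy boundary) sitting on a flat scleral base; the base edge is
  the base polyline.
* **cells** — a homogeneous Poisson point pattern clipped to the ROI.
  Each cell's true positivity probability comes from a logit background,
  optionally perturbed by a smooth random field, and overridden inside
  planted circular discs (nearest-disc precedence when discs overlap).
  The *observable* table carries only stain intensities drawn from
  label-conditional Gaussians (negative chromogen mean 0.2, positive mean
  0.2 + ``od_separation``, SD ``od_noise``, floored at 0) and nucleus
  areas of which a configured fraction falls below the 30 µm² filter —
  classification must be earned through the intensities; ground truth is
  returned separately.
* **cohort** — per-patient compartment scores with a controllable
  hot−cold heterogeneity distribution, and exponential metastasis times
  whose hazard depends log-linearly on the percent of BAP-1 negative
  cells in a chosen compartment and on gene expression class 2, with
  administrative censoring.

Default scale is desk-sized (a 6 × 3 mm section at 2,500 cells/mm² ≈
3.5 × 10⁴ cells — full cohorts run in minutes); ``paper_scale`` switches
to ~2 × 10⁵ cells per tumor for stress testing.  Every output is a pure
function of its spec (all randomness flows through the spec's seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon

from .classify import CalibrationPair
from .errors import ValidationError
from .io_formats import CELL_COLUMNS, TumorGeometry


@dataclass(frozen=True)
class PlantedSpot:
    """A circular region of overridden positivity."""

    center: tuple[float, float]  # µm
    radius: float                # µm
    positivity: float            # [0, 1]


@dataclass(frozen=True)
class PatternSpec:
    """Everything needed to simulate one tumor's cell pattern."""

    width_mm: float = 6.0
    height_mm: float = 3.0
    cell_density: float = 2500.0          # cells / mm²
    background_positivity: float = 0.5
    planted_spots: tuple[PlantedSpot, ...] = ()
    smooth_field: tuple[float, float] | None = None  # (length scale µm, logit amplitude)
    od_separation: float = 0.6
    od_noise: float = 0.1
    small_cell_fraction: float = 0.05     # nuclei planted below the 30 µm² filter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.width_mm > 0 and self.height_mm > 0):
            raise ValidationError("tumor width and height must be > 0")
        if not self.cell_density > 0:
            raise ValidationError("cell_density must be > 0")
        if not 0 <= self.background_positivity <= 1:
            raise ValidationError("background_positivity must lie in [0, 1]")
        for s in self.planted_spots:
            if not 0 <= s.positivity <= 1:
                raise ValidationError("planted positivity must lie in [0, 1]")
            if not s.radius > 0:
                raise ValidationError("planted radius must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one cohort.

    The metastasis hazard of patient *i* is
    ``h_i = baseline_hazard · exp(η_i + class2_log_hr · c2_i)`` where
    ``c2_i`` indicates gene expression class 2 and ``η_i`` depends on
    ``neg_i``, the percent of negative cells in the driving compartment:
    log-linear (``score_form="linear"``, ``η = score_log_hr · neg``) or a
    two-risk-group step (``score_form="threshold"``,
    ``η = group_log_hr · 1[neg ≥ score_threshold_pct_negative]`` — the
    high/low dichotomy of the measured cohorts).  Times are exponential,
    censored administratively at ``horizon_months``.
    """

    n_patients: int = 40
    class2_fraction: float = 1 / 3        # among patients with a known class
    gep_na_fraction: float = 1 / 3
    baseline_hazard: float = 0.0008       # events / month at neg score 0
    score_log_hr: float = 0.045           # log-HR per percentage point negative
    class2_log_hr: float = 0.5
    driving_compartment: str = "full"
    score_form: str = "linear"            # or "threshold"
    score_threshold_pct_negative: float = 90.0
    group_log_hr: float = 2.7             # ≈ ln 15, used by the threshold form
    horizon_months: float = 120.0
    heterogeneity_mean_pp: float = 41.0
    heterogeneity_sd_pp: float = 29.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        if not self.baseline_hazard > 0:
            raise ValidationError("baseline_hazard must be > 0")
        if self.horizon_months < 0:
            raise ValidationError("horizon_months must be >= 0")


def generate_geometry(
    width_mm: float, height_mm: float, seed: int = 0,
    waviness: float = 0.02, n_vertices: int = 129,
) -> TumorGeometry:
    """Dome-shaped tumor ROI over a flat scleral base.

    The outline is a half-ellipse of the given basal width and apical
    height (image convention: base at the bottom, y increasing downward),
    with a seeded low-frequency radial perturbation of relative amplitude
    ``waviness``.  The base polyline is the flat bottom edge.
    """
    if not (width_mm > 0 and height_mm > 0):
        raise ValidationError("width and height must be > 0")
    w = width_mm * 1000.0
    h = height_mm * 1000.0
    rng = np.random.default_rng(seed)
    theta = np.linspace(np.pi, 0.0, n_vertices)
    # low-frequency waviness, pinned to zero at both base corners
    phases = rng.uniform(0, 2 * np.pi, 3)
    wave = sum(np.sin((k + 2) * theta + phases[k]) for k in range(3)) / 3.0
    scale = 1.0 + waviness * wave * np.sin(theta)
    xs = w / 2 + (w / 2) * np.cos(theta) * scale
    ys = h - h * np.sin(theta) * scale
    ring = list(zip(xs, ys))
    ring[0] = (0.0, h)
    ring[-1] = (w, h)
    roi = Polygon(ring)
    base = LineString([(0.0, h), (w, h)])
    return TumorGeometry(roi=roi, base_polyline=base, exclusions=[])


def _smooth_field(xy: np.ndarray, length_scale: float, amplitude: float,
                  rng: np.random.Generator, n_waves: int = 24) -> np.ndarray:
    """Stationary random field as a sum of random plane waves (values on
    the logit scale, SD ≈ ``amplitude``)."""
    k = 2 * np.pi / length_scale
    angles = rng.uniform(0, 2 * np.pi, n_waves)
    mags = k * np.exp(rng.normal(0, 0.3, n_waves))
    phases = rng.uniform(0, 2 * np.pi, n_waves)
    field = np.zeros(len(xy))
    for a, m, p in zip(angles, mags, phases):
        field += np.cos(m * (xy[:, 0] * np.cos(a) + xy[:, 1] * np.sin(a)) + p)
    return amplitude * field * np.sqrt(2.0 / n_waves)


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def generate_cells(
    geometry: TumorGeometry, spec: PatternSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one tumor's observable cell table plus its ground truth.

    Returns ``(cells, truth)``: ``cells`` is a canonical unclassified cell
    table (no ground-truth columns — positivity must be recovered from the
    chromogen intensities); ``truth`` carries ``true_label`` and the
    latent positivity probability ``p_true`` for the same rows.
    """
    rng = np.random.default_rng(spec.seed)
    minx, miny, maxx, maxy = geometry.roi.bounds
    bbox_area_mm2 = (maxx - minx) * (maxy - miny) / 1e6
    n_bbox = rng.poisson(spec.cell_density * bbox_area_mm2)
    if n_bbox == 0:
        raise ValidationError("expected cell count is zero; raise the density")
    xy = np.column_stack([
        rng.uniform(minx, maxx, n_bbox),
        rng.uniform(miny, maxy, n_bbox),
    ])
    keep = shapely.covers(geometry.roi, shapely.points(xy[:, 0], xy[:, 1]))
    xy = xy[keep]
    n = len(xy)
    if n == 0:
        raise ValidationError("no cells fell inside the ROI")

    # latent positivity probability
    logit_p = np.full(n, _logit(spec.background_positivity))
    if spec.smooth_field is not None:
        length_scale, amplitude = spec.smooth_field
        logit_p += _smooth_field(xy, length_scale, amplitude, rng)
    p_true = 1.0 / (1.0 + np.exp(-logit_p))
    if spec.planted_spots:
        centers = np.array([s.center for s in spec.planted_spots], float)
        d = np.hypot(xy[:, 0, None] - centers[None, :, 0],
                     xy[:, 1, None] - centers[None, :, 1])
        nearest = np.argmin(d, axis=1)  # nearest-center precedence on overlap
        for j, s in enumerate(spec.planted_spots):
            inside = (d[:, j] <= s.radius) & (nearest == j)
            p_true[inside] = s.positivity

    is_pos = rng.uniform(size=n) < p_true

    chromogen = rng.normal(0.2 + spec.od_separation * is_pos, spec.od_noise)
    chromogen = np.clip(chromogen, 0.0, None)
    counterstain = np.clip(rng.normal(0.55, 0.08, n), 0.05, None)

    # nucleus areas: a planted fraction below the 30 µm² lymphocyte filter
    small = rng.uniform(size=n) < spec.small_cell_fraction
    area = np.where(
        small,
        rng.uniform(12.0, 29.5, n),
        np.clip(rng.normal(60.0, 20.0, n), 31.0, 295.0),
    )

    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": xy[:, 0],
        "y": xy[:, 1],
        "nucleus_area": area,
        "chromogen_od": chromogen,
        "counterstain_od": counterstain,
        "label": "unclassified",
    })[CELL_COLUMNS]
    truth = pd.DataFrame({
        "cell_id": cells["cell_id"],
        "true_label": np.where(is_pos, "positive", "negative"),
        "p_true": p_true,
    })
    return cells, truth


def pick_exemplars(cells: pd.DataFrame, truth: pd.DataFrame,
                   spec: PatternSpec) -> CalibrationPair:
    """Designate one positive and one negative exemplar cell, as the
    reviewing pathologist would on each slide.

    The exemplar intensity is the median chromogen OD of the true class;
    when a class is absent from the section (an extreme tumor), the
    nominal class mean stands in — the analogue of consulting a control
    slide.
    """
    od = cells["chromogen_od"].to_numpy(float)
    pos = od[(truth["true_label"] == "positive").to_numpy()]
    neg = od[(truth["true_label"] == "negative").to_numpy()]
    pos_od = float(np.median(pos)) if len(pos) else 0.2 + spec.od_separation
    neg_od = float(np.median(neg)) if len(neg) else 0.2
    return CalibrationPair(positive_exemplar_od=pos_od, negative_exemplar_od=neg_od)


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a per-patient cohort table with ground-truth compartment
    scores and survival outcomes.

    Compartment scores: the hot−cold gap is drawn from the configured
    heterogeneity distribution (clipped to [0, 95] pp), the cold score
    uniformly below it, the full-section score uniformly between cold and
    hot, and the scleral score just above the cold score.  Demographics
    echo a typical enucleation cohort (age ≈ 64 ± 14, slight female
    majority, mostly T3 tumors, thickness ≈ 8.8 mm, basal diameter
    ≈ 15.1 mm).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    gap = np.clip(rng.normal(spec.heterogeneity_mean_pp, spec.heterogeneity_sd_pp, n),
                  0.0, 95.0)
    cold = rng.uniform(0.0, 100.0 - gap)
    hot = cold + gap
    full = cold + gap * rng.uniform(size=n)
    scleral = cold + gap * rng.beta(1.0, 7.0, n)

    age = np.clip(rng.normal(64.0, 14.0, n), 20.0, 95.0)
    sex = np.where(rng.uniform(size=n) < 0.55, "F", "M")
    t_category = rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.20, 0.50, 0.15])
    gep_known = rng.uniform(size=n) >= spec.gep_na_fraction
    class2 = gep_known & (rng.uniform(size=n) < spec.class2_fraction)
    gep = np.where(~gep_known, None,
                   np.where(class2, "2", np.where(rng.uniform(size=n) < 0.5, "1a", "1b")))
    thickness = np.clip(rng.normal(8.8, 3.4, n), 2.0, 18.0)
    lbd = np.clip(rng.normal(15.1, 3.7, n), 6.0, 25.0)

    comp = {"full": full, "hot": hot, "cold": cold, "scleral": scleral}
    if spec.driving_compartment not in comp:
        raise ValidationError(f"unknown driving compartment {spec.driving_compartment!r}")
    neg_score = 100.0 - comp[spec.driving_compartment]
    if spec.score_form == "linear":
        eta = spec.score_log_hr * neg_score
    elif spec.score_form == "threshold":
        eta = spec.group_log_hr * (neg_score >= spec.score_threshold_pct_negative)
    else:
        raise ValidationError(f"unknown score_form {spec.score_form!r}")
    hazard = spec.baseline_hazard * np.exp(eta + spec.class2_log_hr * class2)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= spec.horizon_months
    follow_up = np.minimum(t_event, spec.horizon_months)

    return pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(n)],
        "age_years": np.round(age, 1),
        "sex": sex,
        "ajcc_t_category": t_category,
        "gep_class": gep,
        "follow_up_months": np.round(follow_up, 2),
        "metastasis_event": event,
        "full_pct": np.round(full, 2),
        "hot_pct": np.round(hot, 2),
        "cold_pct": np.round(cold, 2),
        "scleral_pct": np.round(scleral, 2),
        "thickness_mm": np.round(thickness, 1),
        "lbd_mm": np.round(lbd, 1),
    })


def _interior_point(geometry: TumorGeometry, clearance: float,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Random point at least ``clearance`` inside the ROI (rejection sampling)."""
    eroded = geometry.roi.buffer(-clearance)
    if eroded.is_empty:
        raise ValidationError("tumor too small for the requested disc clearance")
    minx, miny, maxx, maxy = eroded.bounds
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if eroded.covers(shapely.Point(x, y)):
            return float(x), float(y)
    raise ValidationError("could not place a planted disc")  # pragma: no cover


def pattern_for_patient(
    row: pd.Series,
    base_spec: PatternSpec | None = None,
    seed: int = 0,
    disc_radius: float = 400.0,
    coldspot_near_base_probability: float = 0.55,
) -> PatternSpec:
    """A per-patient :class:`PatternSpec` whose planted discs realize the
    patient's ground-truth compartment scores.

    The background positivity equals the full-section score; one disc
    carries the hot-spot and one the cold-spot positivity.  With the
    configured probability the cold disc is placed near the scleral base,
    echoing the peri-scleral preference of measured cold spots.
    """
    base_spec = base_spec or PatternSpec()
    rng = np.random.default_rng(seed)
    geom = generate_geometry(base_spec.width_mm, base_spec.height_mm, seed=seed)
    clearance = disc_radius + 150.0
    hot_c = _interior_point(geom, clearance, rng)
    h_um = base_spec.height_mm * 1000.0
    w_um = base_spec.width_mm * 1000.0
    for _ in range(1000):
        if rng.uniform() < coldspot_near_base_probability:
            cold_c = (rng.uniform(clearance, w_um - clearance),
                      h_um - clearance)
            if not geom.roi.buffer(-clearance + 1.0).covers(shapely.Point(cold_c)):
                continue
        else:
            cold_c = _interior_point(geom, clearance, rng)
        if np.hypot(cold_c[0] - hot_c[0], cold_c[1] - hot_c[1]) > 2.5 * disc_radius:
            break
    return replace(
        base_spec,
        background_positivity=float(row["full_pct"]) / 100.0,
        planted_spots=(
            PlantedSpot(hot_c, disc_radius, float(row["hot_pct"]) / 100.0),
            PlantedSpot(cold_c, disc_radius, float(row["cold_pct"]) / 100.0),
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
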