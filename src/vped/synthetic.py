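"""Synthetic endometrial-surface data with ground truth.

Everything downstream (segmentation, morphometry, ensemble modelling,
cycle-day inference, method concordance) is testable without clinical data
through three generators:

* :func:`sample_features` — draws per-element feature values for a given
  cycle day by inverse-transform sampling from the per-day three-parameter
  Weibull trajectory table (x = b + lam * (-ln U)^(1/gamma));
* :func:`render_image` — renders a sampled feature table into a
  brightfield-style image (dark pores with Fourier-perturbed elliptical
  rims, dark curvilinear vessels, Gaussian background texture, optional
  defocused patch) together with a :class:`SceneTruth` record;
* :func:`generate_cohort` — builds whole synthetic cohorts: true cycle
  days, noisy patient reports, histology consensus days with an integer
  noise kernel, hormone panels drawn from the reference profile, and per
  patient either a direct feature table or rendered specimens.

The default trajectory table lives in :mod:`vped.config`; it is synthetic
(constrained by the qualitative shape-parameter regimes, not by published
per-day values) and fully editable via YAML.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (ALL_FEATURES, DEFAULT_DAY_RANGE, FEATURE_UNITS,
                     PORE_FEATURES, VESSEL_FEATURES, HistologyNoise,
                     RenderConfig, default_trajectory_table)
from .ensembles import WeibullParams
from .morphometry import (pore_features as _measure_pore,
                          vessel_features as _measure_vessel,
                          polygon_perimeter, resample_closed_boundary,
                          _smooth_closed)
from .reference_dating import (HormonePanel, HormoneReference,
                               REFERENCE_CYCLE_LENGTH,
                               inverse_renormalize_day)
from scipy.spatial import ConvexHull

__all__ = [
    "TrajectoryTable",
    "ImageSpec",
    "SceneTruth",
    "SyntheticPatient",
    "SyntheticCohort",
    "CohortNoise",
    "sample_features",
    "render_image",
    "generate_cohort",
    "build_hormone_reference",
]


# ---------------------------------------------------------------------------
# trajectory table
# ---------------------------------------------------------------------------

class TrajectoryTable:
    """Per-(feature, day) Weibull parameters describing feature evolution."""

    def __init__(self, table: dict | None = None,
                 day_range: tuple[int, int] = DEFAULT_DAY_RANGE):
        self.day_range = (int(day_range[0]), int(day_range[1]))
        self.table = table if table is not None else \
            default_trajectory_table(self.day_range)
        for feature, per_day in self.table.items():
            for day, (b, lam, gam) in per_day.items():
                if lam <= 0 or gam <= 0:
                    raise ValueError(
                        f"invalid trajectory for {feature} day {day}: "
                        f"lambda={lam}, gamma={gam}")
                if b < 0:
                    raise ValueError(f"negative location for {feature}")

    @property
    def days(self) -> np.ndarray:
        lo, hi = self.day_range
        return np.arange(lo, hi + 1)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.table.keys())

    def params(self, day: int, feature: str) -> WeibullParams:
        """The configured (b, lambda, gamma) for one (day, feature)."""
        if feature not in self.table:
            raise KeyError(f"unknown feature {feature!r}; valid features: "
                           f"{sorted(self.table)}")
        lo, hi = self.day_range
        if not (lo <= day <= hi):
            raise ValueError(f"day {day} outside supported range [{lo}, {hi}]")
        b, lam, gam = self.table[feature][int(day)]
        return WeibullParams(b=b, lam=lam, gamma=gam)


def _draw_weibull(params: WeibullParams, n: int, rng: np.random.Generator):
    u = rng.uniform(size=n)
    return params.b + params.lam * (-np.log1p(-u)) ** (1.0 / params.gamma)


def sample_features(day: int, n_elements: int, seed=None,
                    table: TrajectoryTable | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a feature table for one specimen at cycle day ``day``.

    Returns ``n_elements`` pore rows (pore_* columns) and ``n_elements``
    vessel rows (bv_* columns); features are drawn independently per element
    by inverse-transform sampling.  Reproducible under ``seed``.
    """
    if n_elements < 0:
        raise ValueError("n_elements must be >= 0")
    table = table or TrajectoryTable()
    rng = rng if rng is not None else np.random.default_rng(seed)
    cols = {f: np.full(2 * n_elements, np.nan) for f in ALL_FEATURES
            if f in table.features}
    kinds = ["pore"] * n_elements + ["vessel"] * n_elements
    for f in cols:
        sl = slice(0, n_elements) if f in PORE_FEATURES \
            else slice(n_elements, 2 * n_elements)
        cols[f][sl] = _draw_weibull(table.params(day, f), n_elements, rng)
    out = pd.DataFrame({"kind": kinds, **cols})
    out.insert(1, "day", day)
    return out


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

@dataclass
class ImageSpec:
    shape: tuple[int, int]        # rows, cols (px)
    pixel_size: float             # um / px
    magnification: str = "4X"

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass
class SceneTruth:
    """Ground truth for one rendered image (coordinates in um, (x, y))."""

    image_spec: ImageSpec
    pore_polygons: list = field(default_factory=list)
    vessel_centerlines: list = field(default_factory=list)
    vessel_widths: list = field(default_factory=list)
    features: pd.DataFrame | None = None      # measured features of the truth
    in_focus_mask: np.ndarray | None = None   # bool, True where sharp

    def to_json(self) -> str:
        return json.dumps({
            "image_spec": {"shape": list(self.image_spec.shape),
                           "pixel_size": self.image_spec.pixel_size,
                           "magnification": self.image_spec.magnification},
            "pore_polygons": [p.tolist() for p in self.pore_polygons],
            "vessel_centerlines": [c.tolist() for c in self.vessel_centerlines],
            "vessel_widths": [w.tolist() for w in self.vessel_widths],
            "features": None if self.features is None
            else self.features.to_dict(orient="list"),
        })

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        spec = ImageSpec(tuple(d["image_spec"]["shape"]),
                         d["image_spec"]["pixel_size"],
                         d["image_spec"].get("magnification", "4X"))
        return cls(
            image_spec=spec,
            pore_polygons=[np.asarray(p) for p in d["pore_polygons"]],
            vessel_centerlines=[np.asarray(c) for c in d["vessel_centerlines"]],
            vessel_widths=[np.asarray(w) for w in d["vessel_widths"]],
            features=None if d["features"] is None
            else pd.DataFrame(d["features"]),
        )


def _tortuosity_of(poly: np.ndarray) -> float:
    res = resample_closed_boundary(poly)
    smooth = _smooth_closed(res, max(3, int(round(0.05 * len(res)))))
    perim = polygon_perimeter(smooth)
    try:
        hullp = polygon_perimeter(smooth[ConvexHull(smooth).vertices])
    except Exception:
        hullp = perim
    return max(1.0, perim / hullp)


def _pore_boundary(area: float, length: float, tortuosity: float,
                   rng: np.random.Generator, n_theta: int = 96) -> np.ndarray:
    """Fourier-perturbed ellipse with exact target area, centred at origin.

    The semi-major axis targets ``length``/2 (clamped so the ellipse is
    valid); rim irregularity is a radial Fourier perturbation (modes 3-7)
    whose amplitude is bisected numerically until the measured tortuosity
    matches the target (the measure is the same resample-smooth-hull
    procedure morphometry uses).  The polygon is finally rescaled so its
    shoelace area equals ``area`` exactly.
    """
    r_eq = np.sqrt(area / np.pi)
    a = max(length / 2.0, r_eq)
    b_ax = area / (np.pi * a)
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    modes = np.arange(3, 8)
    amp = rng.uniform(0.4, 1.0, size=modes.size) / modes
    phase = rng.uniform(0, 2 * np.pi, size=modes.size)
    profile = np.sum(amp[:, None] * np.cos(modes[:, None] * theta[None, :]
                                           + phase[:, None]), axis=0)
    profile = profile / np.max(np.abs(profile))

    def poly_at(eps: float) -> np.ndarray:
        rho = 1.0 + eps * profile
        p = np.column_stack([a * np.cos(theta) * rho, b_ax * np.sin(theta) * rho])
        ang = rng_angle
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        return p @ rot.T

    rng_angle = rng.uniform(0, 2 * np.pi)
    target = max(1.0, float(tortuosity))
    lo_e, hi_e = 0.0, 0.45
    if _tortuosity_of(poly_at(hi_e)) <= target:
        eps = hi_e                      # clamp: target beyond achievable range
    else:
        for _ in range(18):
            mid = 0.5 * (lo_e + hi_e)
            if _tortuosity_of(poly_at(mid)) < target:
                lo_e = mid
            else:
                hi_e = mid
        eps = 0.5 * (lo_e + hi_e)
    poly = poly_at(eps)
    # exact-area rescale (does not change tortuosity)
    from .morphometry import polygon_area
    poly *= np.sqrt(area / polygon_area(poly))
    return poly


def _vessel_path(length_um: float, width_um: float, spec: ImageSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Smooth random path of the requested arc length, staying in-frame."""
    step = max(2.0 * spec.pixel_size, length_um / 400.0)
    n_steps = max(2, int(np.ceil(length_um / step)))
    h, w = spec.extent_um
    margin = width_um / 2 + 3 * spec.pixel_size
    pos = np.array([rng.uniform(margin, w - margin),
                    rng.uniform(margin, h - margin)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.06)
        nxt = pos + step * np.array([np.cos(heading), np.sin(heading)])
        if not (margin < nxt[0] < w - margin and margin < nxt[1] < h - margin):
            # steer back toward the image centre
            centre = np.array([w / 2, h / 2])
            heading = np.arctan2(*(centre - pos)[::-1])
            nxt = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pos = nxt
        pts.append(pos.copy())
    return np.asarray(pts)


def render_image(feature_sample: pd.DataFrame,
                 spec: ImageSpec | None = None,
                 seed=None,
                 render: RenderConfig | None = None,
                 rng: np.random.Generator | None = None):
    """Render a feature sample to an image, returning ``(image, SceneTruth)``.

    Pores are dark blobs with perturbed elliptical rims matching the sampled
    area exactly and length/tortuosity within rendering tolerance; vessels
    are dark curvilinear bands of the sampled diameter.  Elements are
    rejection-placed without overlap; an overcrowded request (filling factor
    above the configured maximum) raises ``ValueError``.
    """
    from skimage.draw import polygon as draw_polygon, disk as draw_disk

    render = render or RenderConfig()
    spec = spec or ImageSpec(render.image_size, render.pixel_size)
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows, cols = spec.shape
    px = spec.pixel_size
    img_area_um2 = rows * cols * px * px

    pores = feature_sample[feature_sample["kind"] == "pore"] \
        if len(feature_sample) else feature_sample
    vessels = feature_sample[feature_sample["kind"] == "vessel"] \
        if len(feature_sample) else feature_sample

    fill = 0.0
    if len(pores):
        fill += float(pores["pore_area"].sum()) / img_area_um2
    if len(vessels):
        fill += float((vessels["bv_diameter"] *
                       vessels["bv_segment_length"]).sum()) / img_area_um2
    if fill > render.max_fill_factor:
        raise ValueError(f"requested filling factor {fill:.3f} exceeds "
                         f"configured maximum {render.max_fill_factor}")

    image = np.full((rows, cols), render.background, dtype=float)
    occupied = np.zeros((rows, cols), dtype=bool)

    truth = SceneTruth(image_spec=spec)
    feat_rows = []

    # vessels first: pores are then placed clear of them
    for _, row in vessels.iterrows():
        w_um = float(row["bv_diameter"])
        l_um = float(row["bv_segment_length"])
        line = _vessel_path(l_um, w_um, spec, rng)
        r_px = max(1.0, (w_um / 2) / px)
        for pt in line:
            rr, cc = draw_disk((pt[1] / px, pt[0] / px), r_px,
                               shape=(rows, cols))
            image[rr, cc] = np.minimum(image[rr, cc], render.vessel_intensity)
            occupied[rr, cc] = True
        widths = np.full(len(line), w_um)
        truth.vessel_centerlines.append(line)
        truth.vessel_widths.append(widths)
        vf = _measure_vessel(line, widths, pixel_size=1.0)
        feat_rows.append({"kind": "vessel", "bv_diameter": vf.diameter,
                          "bv_segment_length": vf.segment_length})

    grown = None
    if occupied.any():
        grown = gaussian_filter(occupied.astype(float), 2.0) > 1e-3

    # place large pores first: rejection placement then stays feasible
    if len(pores):
        pores = pores.sort_values("pore_area", ascending=False)
    for _, row in pores.iterrows():
        area = float(row["pore_area"])
        max_r_um = 0.25 * min(rows, cols) * px
        area = min(area, np.pi * max_r_um ** 2)      # cap: must fit the frame
        # clamp the sampled length so the ellipse aspect stays renderable;
        # independently-sampled (area, length) pairs can imply slivers
        length = float(row.get("pore_length", 0.0))
        max_len = 2.0 * np.sqrt(render.max_pore_aspect * area / np.pi)
        poly = _pore_boundary(area, min(length, max_len),
                              float(row.get("pore_tortuosity", 1.0)), rng)
        radius_um = np.max(np.linalg.norm(poly, axis=1))
        gap_um = render.min_gap_px * px
        margin = radius_um + gap_um + 2 * px
        # spacing test uses the polygon scaled outward by the minimum gap
        test_poly = poly * (1.0 + gap_um / radius_um)
        placed = False
        for _ in range(render.max_place_retries):
            centre = np.array([rng.uniform(margin, cols * px - margin),
                               rng.uniform(margin, rows * px - margin)])
            tt = test_poly + centre
            tr, tc = draw_polygon(tt[:, 1] / px, tt[:, 0] / px,
                                  shape=(rows, cols))
            if tr.size == 0:
                continue
            if occupied[tr, tc].any() or (grown is not None and
                                          grown[tr, tc].any()):
                continue
            cand = poly + centre
            rr, cc = draw_polygon(cand[:, 1] / px, cand[:, 0] / px,
                                  shape=(rows, cols))
            image[rr, cc] = np.minimum(image[rr, cc], render.pore_intensity)
            occupied[rr, cc] = True
            truth.pore_polygons.append(cand)
            pf = _measure_pore(cand, pixel_size=1.0, check_simple=False)
            feat_rows.append({"kind": "pore", "pore_area": pf.area,
                              "pore_length": pf.length,
                              "pore_curvature": pf.curvature,
                              "pore_tortuosity": pf.tortuosity})
            placed = True
            break
        if not placed:
            raise RuntimeError("failed to place a pore without overlap; "
                               "reduce element count or filling factor")

    truth.features = pd.DataFrame(feat_rows) if feat_rows else \
        pd.DataFrame(columns=["kind"] + list(ALL_FEATURES))

    if render.edge_softness > 0:
        image = gaussian_filter(image, render.edge_softness)
    image = image + rng.normal(0.0, render.background_noise, image.shape)

    in_focus = np.ones((rows, cols), dtype=bool)
    if render.blur_fraction > 0:
        side_r = int(round(rows * np.sqrt(render.blur_fraction)))
        side_c = int(round(cols * np.sqrt(render.blur_fraction)))
        blurred = gaussian_filter(image, render.blur_sigma)
        image[:side_r, :side_c] = blurred[:side_r, :side_c]
        in_focus[:side_r, :side_c] = False
    truth.in_focus_mask = in_focus

    return np.clip(image, 0.0, 1.0), truth


# ---------------------------------------------------------------------------
# hormone reference profile (synthetic)
# ---------------------------------------------------------------------------

# anchor points (day, value) on the 30-day reference cycle, LH peak at day 16.
# Curves are designed so the 4-hormone trajectory never nearly revisits
# itself and keeps a day-to-day gradient of order one tabulated sigma,
# which is what makes chi-square dating well-posed on every day.
_HORMONE_ANCHORS = {
    "E2":  ([1, 5, 10, 14, 15, 16, 18, 20, 23, 26, 28, 30],
            [40, 60, 120, 190, 200, 165, 115, 135, 160, 140, 90, 45], 100.0),
    "P4":  ([1, 15, 16, 17, 18, 19, 20, 21, 22, 25, 27, 29, 30],
            [0.5, 0.5, 1.0, 2.5, 4.0, 6.0, 8.0, 10.5, 13.0, 14.0, 10.0,
             4.0, 1.5], 0.49),
    "LH":  ([1, 5, 10, 13, 14, 15, 16, 17, 18, 19, 21, 24, 27, 30],
            [4.5, 5, 5.5, 7, 12, 25, 40, 24, 12, 8, 6.5, 5.5, 4.8, 4.5], 2.25),
    "FSH": ([1, 3, 6, 9, 12, 14, 15, 16, 17, 18, 20, 23, 26, 30],
            [10, 9, 7, 5.5, 4.5, 5, 8, 15, 9, 6, 4.5, 3.8, 3.2, 2.5], 0.64),
}


def build_hormone_reference() -> HormoneReference:
    """Synthetic smooth 30-day hormone reference profile.

    A stand-in for the proprietary manufacturer table: mid-cycle LH/FSH
    surge (peak at reference day 16 = ovulation of the 30-day cycle), a
    luteal progesterone plateau and a biphasic estradiol curve, with
    constant tabulated variances per hormone.
    """
    days = np.arange(1, REFERENCE_CYCLE_LENGTH + 1)
    rows = []
    for hormone, (xd, xv, var) in _HORMONE_ANCHORS.items():
        means = np.interp(days, xd, xv)
        for d, m in zip(days, means):
            rows.append({"day": int(d), "hormone": hormone,
                         "mean": float(m), "variance": float(var)})
    return HormoneReference(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortNoise:
    """Noise configuration for synthetic cohorts (all independently settable)."""

    histology: HistologyNoise = field(default_factory=HistologyNoise)
    hormone_scale: float = 1.0          # multiple of the tabulated sigma
    report_sd_days: float = 1.0         # reporting error, own-cycle days
    cycle_length_mean: float = 28.0
    cycle_length_sd: float = 2.5        # population spread, clipped to 25-35

    @classmethod
    def zero(cls) -> "CohortNoise":
        return cls(histology=HistologyNoise(p0=1.0, p1=0.0, p2=0.0),
                   hormone_scale=0.0, report_sd_days=0.0, cycle_length_sd=0.0)


@dataclass
class SyntheticPatient:
    patient_id: str
    true_day: int                         # standard 28-day calendar
    cycle_length: float
    reported_raw_day: int                 # own-cycle day as reported
    last_menses_date: _dt.date
    sampling_date: _dt.date
    histology_day: int
    histology_error_low: float
    histology_error_high: float
    hormone_panel: HormonePanel
    endometrial_thickness_mm: float
    features: pd.DataFrame | None = None       # direct feature table
    scenes: list | None = None                 # [(image, SceneTruth), ...]


@dataclass
class SyntheticCohort:
    patients: list

    def __len__(self) -> int:
        return len(self.patients)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "true_day": p.true_day,
                "cycle_length": p.cycle_length,
                "reported_raw_day": p.reported_raw_day,
                "last_menses_date": p.last_menses_date.isoformat(),
                "sampling_date": p.sampling_date.isoformat(),
                "histology_day": p.histology_day,
                "histology_error_low": p.histology_error_low,
                "histology_error_high": p.histology_error_high,
                "endometrial_thickness_mm": p.endometrial_thickness_mm,
            }
            for h, v in p.hormone_panel.values.items():
                row[f"hormone_{h}"] = v
                row[f"hormone_{h}_err"] = p.hormone_panel.errors[h]
            rows.append(row)
        return pd.DataFrame(rows)

    def feature_table(self) -> pd.DataFrame:
        parts = []
        for p in self.patients:
            if p.features is not None:
                t = p.features.copy()
                t.insert(0, "patient_id", p.patient_id)
                parts.append(t)
        if not parts:
            raise ValueError("cohort has no direct feature tables")
        return pd.concat(parts, ignore_index=True)


def generate_cohort(n_patients: int,
                    day_assignment=None,
                    noise: CohortNoise | None = None,
                    seed=None,
                    table: TrajectoryTable | None = None,
                    reference: HormoneReference | None = None,
                    elements_per_patient: int = 300,
                    images: bool = False,
                    images_per_patient: int = 3,
                    elements_per_image: int = 40,
                    vessels_per_image: int = 8,
                    render: RenderConfig | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort with all record fields populated.

    ``day_assignment`` is a sequence of true (standard) cycle days, or None
    for a deterministic round-robin over the supported day range.  With
    ``images=False`` each patient carries a direct feature table of
    ``elements_per_patient`` elements per kind; with ``images=True`` each
    patient carries rendered specimen images plus their SceneTruth.
    """
    table = table or TrajectoryTable()
    noise = noise or CohortNoise()
    reference = reference or build_hormone_reference()
    render = render or RenderConfig()
    lo, hi = table.day_range
    if day_assignment is None:
        days = [lo + (i % (hi - lo + 1)) for i in range(n_patients)]
    else:
        days = [int(d) for d in day_assignment]
        if len(days) != n_patients:
            raise ValueError("day_assignment length must equal n_patients")
    for d in days:
        if not (lo <= d <= hi):
            raise ValueError(f"assigned day {d} outside supported range")

    streams = np.random.SeedSequence(seed).spawn(n_patients)
    offsets, probs = noise.histology.offsets_probs()
    probs = probs / probs.sum()
    sampling_date = _dt.date(2021, 6, 15)

    patients = []
    for i, (day, ss) in enumerate(zip(days, streams)):
        rng = np.random.default_rng(ss)
        L = float(np.clip(rng.normal(noise.cycle_length_mean,
                                     noise.cycle_length_sd), 25.0, 35.0)) \
            if noise.cycle_length_sd > 0 else noise.cycle_length_mean
        raw_true = inverse_renormalize_day(day, L)
        raw_report = int(np.clip(round(raw_true + rng.normal(0.0, noise.report_sd_days))
                                 if noise.report_sd_days > 0 else round(raw_true),
                                 1, int(L)))
        hist = int(np.clip(day + rng.choice(offsets, p=probs), lo, hi))
        ref_day = int(np.clip(round(inverse_renormalize_day(
            day, REFERENCE_CYCLE_LENGTH)), 1, REFERENCE_CYCLE_LENGTH))
        values, errors = {}, {}
        for h in reference.hormones:
            var = reference.variance(ref_day, h)
            values[h] = reference.mean(ref_day, h) + \
                (rng.normal(0.0, np.sqrt(var)) * noise.hormone_scale)
            errors[h] = 0.5 * np.sqrt(var)
        panel = HormonePanel(values=values, errors=errors)
        thickness = float(np.clip(rng.normal(9.5, 1.8), 4.0, 16.0))

        feats = None
        scenes = None
        if images:
            scenes = []
            for _ in range(images_per_patient):
                fs = sample_features(day, elements_per_image, table=table, rng=rng)
                pore_part = fs[fs["kind"] == "pore"]
                vessel_part = fs[fs["kind"] == "vessel"].head(vessels_per_image)
                scenes.append(render_image(
                    pd.concat([pore_part, vessel_part], ignore_index=True),
                    render=render, rng=rng))
        else:
            feats = sample_features(day, elements_per_patient, table=table, rng=rng)

        patients.append(SyntheticPatient(
            patient_id=f"P{i:03d}",
            true_day=day,
            cycle_length=L,
            reported_raw_day=raw_report,
            last_menses_date=sampling_date - _dt.timedelta(days=raw_report - 1),
            sampling_date=sampling_date,
            histology_day=hist,
            histology_error_low=1.0,
            histology_error_high=1.0,
            hormone_panel=panel,
            endometrial_thickness_mm=thickness,
            features=feats,
            scenes=scenes,
        ))
    return SyntheticCohort(patients=patients)
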