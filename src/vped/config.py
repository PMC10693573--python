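"""Default configuration: feature trajectories, rendering, segmentation, binning.

All tunables live here so that a single YAML file can override any of them.
The per-day Weibull trajectory table is synthetic: the study that motivates
this package reports only the qualitative regimes of the shape parameter
(pore-area gamma < 1 throughout the secretory phase, pore-length gamma > 1
only around the peak pore-merging days ~20-22, vessel-diameter gamma > 1
throughout), so the defaults are smooth curves honouring those regimes with
day-to-day drift large enough for per-day ensembles to be distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# standard 28-day calendar; secretory phase
DEFAULT_DAY_RANGE = (15, 28)

PORE_FEATURES = ("pore_area", "pore_length", "pore_curvature", "pore_tortuosity")
VESSEL_FEATURES = ("bv_diameter", "bv_segment_length")
ALL_FEATURES = PORE_FEATURES + VESSEL_FEATURES

FEATURE_UNITS = {
    "pore_area": "um^2",
    "pore_length": "um",
    "pore_curvature": "1/um",
    "pore_tortuosity": "",
    "bv_diameter": "um",
    "bv_segment_length": "um",
}

# location parameter b per feature: smallest value attainable given biology
# and the optical resolution limit (um-based units)
FEATURE_LOCATION = {
    "pore_area": 50.0,
    "pore_length": 8.0,
    "pore_curvature": 0.01,
    "pore_tortuosity": 1.0,
    "bv_diameter": 3.0,
    "bv_segment_length": 15.0,
}


def default_trajectory_table(day_range=DEFAULT_DAY_RANGE) -> dict:
    """Per-day (b, lambda, gamma) for every feature, as a nested dict.

    Shapes follow the qualitative secretory-phase narrative: pore areas grow
    and stay left-skewed (gamma < 1); pore length develops an interior PDF
    mode only in the merging window (~days 20-22); rim curvature falls as
    pores enlarge; tortuosity rises as rims grow jagged; vessel diameters
    keep an interior mode (gamma > 1) with a dip near day 19; vessel segment
    lengths stretch.  Values are editable per (feature, day).
    """
    lo, hi = day_range
    days = np.arange(lo, hi + 1)
    t = (days - lo) / max(hi - lo, 1)          # 0..1 across the range
    table: dict[str, dict[int, tuple[float, float, float]]] = {}

    def put(feature, lam, gam):
        b = FEATURE_LOCATION[feature]
        lam = np.asarray(lam, float)
        gam = np.asarray(gam, float)
        table[feature] = {int(d): (b, float(l), float(g))
                          for d, l, g in zip(days, lam, gam)}

    put("pore_area",
        lam=700.0 * (1.0 + 1.8 * t),
        gam=0.80 - 0.25 * np.exp(-((days - 20.5) / 2.5) ** 2))
    put("pore_length",
        lam=30.0 * (1.0 + 1.5 * t),
        gam=0.85 + 0.35 * np.exp(-((days - 21.0) / 1.3) ** 2))
    put("pore_curvature",
        lam=0.075 * (1.0 - 0.45 * t),
        gam=1.15 + 0.50 * np.exp(-((days - 18.0) / 2.0) ** 2)
            + 0.20 * np.exp(-((days - 24.0) / 2.0) ** 2))
    put("pore_tortuosity",
        lam=0.05 * (1.0 + 4.5 * t),
        gam=1.60 + 0.30 * np.sin(np.pi * t))
    put("bv_diameter",
        lam=7.0 * (1.0 + 1.2 * t),
        gam=1.30 + 0.35 * ((days - 19.0) / 4.5) ** 2)
    put("bv_segment_length",
        lam=45.0 * (1.0 + t),
        gam=1.35 + 0.25 * np.sin(np.pi * t))
    return table


@dataclass
class RenderConfig:
    """Synthetic image rendering parameters (intensities in [0, 1])."""

    image_size: tuple[int, int] = (800, 800)   # rows, cols (px); ~800 um ROI side
    pixel_size: float = 1.0                    # um / px
    background: float = 0.75
    background_noise: float = 0.02             # Gaussian sigma
    pore_intensity: float = 0.35
    vessel_intensity: float = 0.45
    edge_softness: float = 1.0                 # px, Gaussian edge smoothing
    max_pore_aspect: float = 4.0               # clamp length so rims stay wide
    min_gap_px: float = 4.0                    # clearance between elements
    max_fill_factor: float = 0.30              # reject overcrowded scenes
    max_place_retries: int = 200
    blur_fraction: float = 0.0                 # area fraction defocused
    blur_sigma: float = 4.0                    # px


@dataclass
class SegmentationConfig:
    """Classical-pipeline thresholds; all deliberately explicit."""

    # focus gating: local variance of the Laplacian response
    focus_window: int = 31                     # px, sliding window
    focus_threshold: float = 5e-4              # on images normalised to [0,1]
    focus_opening: int = 5                     # px, morphological cleanup
    # pores
    pore_min_area_um2: float = 20.0
    pore_max_area_um2: float = 5.0e4
    pore_min_solidity: float = 0.75
    pore_max_elongation: float = 6.0           # max Feret / min Feret
    pore_threshold_offset: float = 0.10        # below background estimate
    pore_min_core_contrast: float = 0.35       # pores are darker than vessels
    # vessels
    vessel_scales: tuple[float, ...] = (2.0, 4.0, 6.0)
    vessel_threshold: float = 0.15             # on normalised tubeness
    vessel_min_skeleton_px: int = 10
    vessel_min_aspect: float = 2.5             # skeleton length / mean width
    vessel_min_contrast: float = 0.10          # centreline depth below background
    quality_filter: bool = False
    min_quality: float = 0.0


@dataclass
class BinningConfig:
    """Shared per-feature histogram axes (Fig.-3-style common bins)."""

    n_bins: int = 24
    upper_quantile: float = 0.99


@dataclass
class HistologyNoise:
    """Discrete kernel for histology-day error around the true day."""

    p0: float = 0.6
    p1: float = 0.15       # each of +-1
    p2: float = 0.05       # each of +-2

    def offsets_probs(self):
        return np.array([-2, -1, 0, 1, 2]), np.array(
            [self.p2, self.p1, self.p0, self.p1, self.p2])


@dataclass
class VpedConfig:
    day_range: tuple[int, int] = DEFAULT_DAY_RANGE
    trajectories: dict = field(default_factory=default_trajectory_table)
    render: RenderConfig = field(default_factory=RenderConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    histology_noise: HistologyNoise = field(default_factory=HistologyNoise)


def load_config(path) -> VpedConfig:
    """Load a YAML override file on top of the defaults.

    Recognised top-level keys: ``day_range``, ``trajectories`` (nested
    feature -> day -> [b, lambda, gamma]), ``render``, ``segmentation``,
    ``binning``, ``histology_noise``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = VpedConfig()
    if "day_range" in raw:
        cfg.day_range = tuple(raw["day_range"])
        cfg.trajectories = default_trajectory_table(cfg.day_range)
    for feature, days in (raw.get("trajectories") or {}).items():
        cfg.trajectories.setdefault(feature, {})
        for day, blg in days.items():
            cfg.trajectories[feature][int(day)] = tuple(float(x) for x in blg)
    for key, cls in (("render", RenderConfig),
                     ("segmentation", SegmentationConfig),
                     ("binning", BinningConfig),
                     ("histology_noise", HistologyNoise)):
        if key in raw:
            base = asdict(getattr(cfg, key))
            base.update(raw[key])
            for k in ("image_size", "vessel_scales"):
                if k in base and isinstance(base[k], list):
                    base[k] = tuple(base[k])
            setattr(cfg, key, cls(**base))
    return cfg
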