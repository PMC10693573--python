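"""Cycle-day inference from feature ensembles (the image-based dating core).

A per-day, per-feature reference dictionary is built by pooling the
ensembles of all specimens sharing a (histology-labelled) cycle day.  A new
specimen is dated by comparing each of its pore-feature ensembles with every
dictionary day via the two-sample KS test and combining the per-feature
p-values with equal weights; a five-day top-hat window encodes the prior
that neighbouring days resemble each other; the windowed profile's argmax
is the inferred day.  Per-day accuracy comes from the day-vs-day KS
confusion matrix (3x3 Gaussian smoothed, rows normalised to their maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve

from .config import PORE_FEATURES
from .ensembles import (EmpiricalDistribution, build_empirical, ks_two_sample,
                        pool_day_distribution)
from .reference_dating import DatingEstimate

__all__ = [
    "CycleDayDictionary",
    "DayProbabilityProfile",
    "build_dictionary",
    "score_sample",
    "tophat_convolve",
    "infer_day",
    "day_confusion_matrix",
    "day_error_estimate",
]


@dataclass
class CycleDayDictionary:
    """Per-day, per-feature pooled reference distributions."""

    days: np.ndarray                       # supported days, contiguous
    features: tuple                        # configured feature names
    distributions: dict                    # (day, feature) -> EmpiricalDistribution
    missing_days: tuple = ()
    magnification: str = "4X"

    def distribution(self, day: int, feature: str) -> EmpiricalDistribution:
        return self.distributions[(int(day), feature)]

    def effective_n(self, day: int) -> float:
        return float(np.mean([self.distributions[(int(day), f)].effective_n
                              for f in self.features]))

    def to_json(self) -> str:
        return json.dumps({
            "schema": "vped-dictionary-1",
            "days": self.days.tolist(),
            "features": list(self.features),
            "missing_days": list(self.missing_days),
            "magnification": self.magnification,
            "distributions": {
                f"{d}:{f}": dist.to_dict() | {
                    "values": dist.values.tolist(),
                    "weights": dist.weights.tolist()}
                for (d, f), dist in self.distributions.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "CycleDayDictionary":
        d = json.loads(text)
        dists = {}
        for key, dd in d["distributions"].items():
            day, feat = key.split(":", 1)
            dists[(int(day), feat)] = build_empirical(
                dd["values"], dd["weights"], feature=dd["feature"],
                units=dd["units"])
        return cls(days=np.asarray(d["days"], int),
                   features=tuple(d["features"]),
                   distributions=dists,
                   missing_days=tuple(d["missing_days"]),
                   magnification=d.get("magnification", "4X"))


@dataclass
class DayProbabilityProfile:
    """Combined per-day match scores for one specimen."""

    days: np.ndarray
    scores: np.ndarray
    normalized: bool = False
    window_applied: bool = False

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, int)
        self.scores = np.asarray(self.scores, float)
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")


def build_dictionary(samples: dict, config=None,
                     features: tuple = PORE_FEATURES,
                     magnification: str = "4X") -> CycleDayDictionary:
    """Build the per-day dictionary from labelled per-patient feature tables.

    ``samples`` maps a (histology-labelled) day to a list of per-patient
    feature DataFrames (as produced by the synthetic generator or the
    segmentation->morphometry pipeline).  Days without any sample are
    flagged missing and excluded from the supported range.
    """
    if not samples:
        raise ValueError("empty cohort: no labelled samples to pool")
    all_days = np.arange(min(samples), max(samples) + 1)
    present = [d for d in all_days if samples.get(d)]
    missing = tuple(int(d) for d in all_days if not samples.get(d))
    dists = {}
    for day in present:
        for feature in features:
            per_patient = []
            for tab in samples[day]:
                vals = tab.loc[tab[feature].notna(), feature].to_numpy()
                if vals.size:
                    per_patient.append(build_empirical(vals, feature=feature))
            if not per_patient:
                raise ValueError(f"no values for feature {feature!r} on day {day}")
            dists[(int(day), feature)] = pool_day_distribution(per_patient)
    return CycleDayDictionary(days=np.asarray(present, int), features=tuple(features),
                              distributions=dists, missing_days=missing,
                              magnification=magnification)


def score_sample(sample: dict, dictionary: CycleDayDictionary,
                 feature_set: tuple | None = None,
                 combine: str = "mean") -> DayProbabilityProfile:
    """Equal-weight KS score of one specimen against every dictionary day.

    ``sample`` maps feature name -> EmpiricalDistribution (or array of
    values).  score(d) is the arithmetic mean over features of the KS
    p-value between the sample and the day-d pooled distribution
    (``combine="geometric"`` switches to the geometric mean).  The profile
    is unnormalised and un-windowed at this stage.
    """
    feature_set = tuple(feature_set or dictionary.features)
    missing = [f for f in feature_set if f not in sample]
    if missing:
        raise ValueError(f"sample is missing features: {missing}")
    dists = {f: (s if isinstance(s, EmpiricalDistribution)
                 else build_empirical(np.asarray(s, float), feature=f))
             for f, s in sample.items() if f in feature_set}
    scores = np.empty(len(dictionary.days))
    for i, day in enumerate(dictionary.days):
        ps = [ks_two_sample(dists[f], dictionary.distribution(day, f)).pvalue
              for f in feature_set]
        if combine == "mean":
            scores[i] = float(np.mean(ps))
        elif combine == "geometric":
            scores[i] = float(np.exp(np.mean(np.log(np.maximum(ps, 1e-300)))))
        else:
            raise ValueError(f"unknown combination rule {combine!r}")
    return DayProbabilityProfile(days=dictionary.days.copy(), scores=scores)


def tophat_convolve(profile: DayProbabilityProfile,
                    width_days: int = 5) -> DayProbabilityProfile:
    """Smooth the profile with a truncated top-hat window and normalise.

    score'(d) is the mean of the raw scores over [d - w//2, d + w//2]
    intersected with the day range (edge windows renormalise by their actual
    size); the smoothed profile is then normalised to sum to 1.
    """
    if width_days % 2 == 0:
        raise ValueError("top-hat window width must be odd")
    half = width_days // 2
    n = len(profile.days)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = profile.scores[lo:hi].mean()
    total = out.sum()
    if total > 0:
        out = out / total
    return DayProbabilityProfile(days=profile.days.copy(), scores=out,
                                 normalized=total > 0, window_applied=True)


def infer_day(profile: DayProbabilityProfile,
              confusion: np.ndarray | None = None) -> DatingEstimate:
    """Most probable cycle day from a (windowed) probability profile.

    Ties across a maximal plateau break to the score-weighted centroid of
    the plateau, rounded to the nearest day.  The +- day error is attached
    from :func:`day_error_estimate` when a confusion matrix is supplied.
    """
    s = profile.scores
    if not np.any(s > 0):
        raise ValueError("unclassifiable: all-zero probability profile")
    peak = s.max()
    at_max = np.isclose(s, peak, rtol=1e-12, atol=1e-15)
    idx = np.flatnonzero(at_max)
    # maximal plateau containing the first argmax
    run = [idx[0]]
    for j in idx[1:]:
        if j == run[-1] + 1:
            run.append(j)
        else:
            break
    run = np.asarray(run)
    centroid = float(np.sum(profile.days[run] * s[run]) / np.sum(s[run]))
    day = int(round(centroid))
    err_lo = err_hi = 0.0
    if confusion is not None:
        i = int(np.flatnonzero(profile.days == day)[0])
        err_lo, err_hi = day_error_estimate(confusion, i)
    return DatingEstimate(day=float(day), method="vped",
                          error_low=err_lo, error_high=err_hi,
                          profile={int(d): float(v)
                                   for d, v in zip(profile.days, s)})


# 3x3 Gaussian smoothing kernel (binomial approximation)
_GAUSS3 = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0


def day_confusion_matrix(dictionary: CycleDayDictionary,
                         feature_set: tuple | None = None,
                         smooth: bool = True) -> np.ndarray:
    """Day-vs-day relative match probability matrix.

    M[i, j] is the mean-over-features KS p-value between the pooled
    distributions of days i and j (symmetric with unit diagonal).  With
    ``smooth=True`` it is convolved with a 3x3 Gaussian kernel and each row
    rescaled to its maximum, giving the diagonal-dominant relative
    probability of assigning day j to a day-i specimen.
    """
    feature_set = tuple(feature_set or dictionary.features)
    days = dictionary.days
    n = len(days)
    if n < 2:
        raise ValueError("confusion matrix needs at least two dictionary days")
    M = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ps = [ks_two_sample(dictionary.distribution(days[i], f),
                                dictionary.distribution(days[j], f)).pvalue
                  for f in feature_set]
            M[i, j] = M[j, i] = float(np.mean(ps))
    if not smooth:
        return M
    sm = convolve(M, _GAUSS3, mode="nearest")
    row_max = sm.max(axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0
    return sm / row_max


def day_error_estimate(matrix: np.ndarray, day_index: int):
    """Asymmetric +- day error: contiguous half-widths of the row region
    around the diagonal where the relative probability stays >= 0.5."""
    row = np.asarray(matrix)[day_index]
    n = row.size
    if not (0 <= day_index < n):
        raise ValueError("day index outside matrix range")
    lo = 0
    while day_index - lo - 1 >= 0 and row[day_index - lo - 1] >= 0.5:
        lo += 1
    hi = 0
    while day_index + hi + 1 < n and row[day_index + hi + 1] >= 0.5:
        hi += 1
    return float(lo), float(hi)
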