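"""Traditional cycle-dating methods used as comparators.

Three reference datings are supported alongside the image-based method:

* patient report — days since the reported first day of the last menses,
  mapped onto the standard 28-day calendar;
* histology — the two-pathologist consensus day, ingested as-is with its
  asymmetric error (histological dating is already calendar-normalised);
* serum hormones — chi-square matching of a four-hormone panel (estradiol,
  progesterone, LH, FSH) against a per-day reference profile tabulated on a
  30-day cycle anchored at the LH peak.

Cycle renormalization maps day ``d`` of a cycle of length ``L`` onto the
28-day standard by rescaling the proliferative phase to 14 days under the
fixed-14-day-luteal convention: with ovulation at O = L - 14,
d' = d * 14/O for d <= O and d' = 14 + (d - O) otherwise.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("vped")

__all__ = [
    "HormonePanel",
    "HormoneReference",
    "PatientRecord",
    "DatingEstimate",
    "renormalize_day",
    "inverse_renormalize_day",
    "chi2_hormone_day",
    "report_day",
    "histology_day",
]

HORMONES = ("E2", "P4", "LH", "FSH")

REFERENCE_CYCLE_LENGTH = 30        # days in the hormone reference profile
LUTEAL_DAYS = 14                   # fixed luteal-phase length assumption


@dataclass
class DatingEstimate:
    """A cycle-day estimate on the standard 28-day calendar."""

    day: float
    method: str                               # vped | histology | hormones | report
    error_low: float = 0.0                    # days below the estimate
    error_high: float = 0.0                   # days above
    profile: dict | None = None               # per-candidate-day score, if any
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.error_low < 0 or self.error_high < 0:
            raise ValueError("error bounds must be non-negative")


@dataclass
class HormonePanel:
    """Measured serum levels with per-assay measurement errors."""

    values: dict                  # hormone -> measured level
    errors: dict                  # hormone -> measurement error (1 sigma)

    def __post_init__(self) -> None:
        for h in self.values:
            v = self.values[h]
            e = self.errors.get(h, 0.0)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for {h}")
            if e < 0:
                raise ValueError(f"negative measurement error for {h}")


class HormoneReference:
    """Per-day means and tabulated variances on the 30-day reference cycle.

    Backed by a long-format DataFrame with columns ``day`` (1..30),
    ``hormone``, ``mean``, ``variance``.  Day numbering is the reference
    cycle's own; the LH-peak ("day 0") convention is encoded in the profile
    shape, with ovulation at day ``REFERENCE_CYCLE_LENGTH - LUTEAL_DAYS``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"day", "hormone", "mean", "variance"}
        if not required.issubset(table.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        if (table["variance"] < 0).any():
            raise ValueError("reference variances must be non-negative")
        days = np.sort(table["day"].unique())
        if len(days) != REFERENCE_CYCLE_LENGTH or not np.array_equal(
                days, np.arange(1, REFERENCE_CYCLE_LENGTH + 1)):
            raise ValueError("reference must cover contiguous days 1..30")
        self.table = table
        self._means = table.pivot(index="day", columns="hormone", values="mean")
        self._vars = table.pivot(index="day", columns="hormone", values="variance")

    @property
    def hormones(self):
        return tuple(self._means.columns)

    @property
    def days(self):
        return self._means.index.to_numpy()

    def mean(self, day: int, hormone: str) -> float:
        return float(self._means.at[day, hormone])

    def variance(self, day: int, hormone: str) -> float:
        return float(self._vars.at[day, hormone])

    @classmethod
    def from_csv(cls, path) -> "HormoneReference":
        return cls(pd.read_csv(path))


@dataclass
class PatientRecord:
    """One patient's clinical record (ISO dates; durations in days)."""

    patient_id: str
    last_menses_date: _dt.date | None = None
    cycle_length: float | None = None
    cycle_length_var: float = 0.0
    menses_length: float | None = None
    next_menses_date: _dt.date | None = None
    histology_day: float | None = None
    histology_error_low: float = 0.0
    histology_error_high: float = 0.0
    hormone_panel: HormonePanel | None = None
    endometrial_thickness_mm: float | None = None


# ---------------------------------------------------------------------------
# cycle renormalization
# ---------------------------------------------------------------------------

def renormalize_day(day: float, cycle_length: float) -> float:
    """Map day ``day`` of a ``cycle_length``-day cycle to the 28-day standard.

    Fixed 14-day luteal phase: ovulation at O = cycle_length - 14; the
    proliferative phase [1, O] is rescaled to 14 days and the luteal offset
    is preserved.  Result rounded to 2 decimals (not an integer).
    """
    if cycle_length <= LUTEAL_DAYS:
        raise ValueError(f"cycle length must exceed {LUTEAL_DAYS} days")
    if not (0 < day <= cycle_length):
        raise ValueError(f"day {day} outside cycle of length {cycle_length}")
    ovulation = cycle_length - LUTEAL_DAYS
    if day <= ovulation:
        out = day * LUTEAL_DAYS / ovulation
    else:
        out = LUTEAL_DAYS + (day - ovulation)
    return round(float(out), 2)


def inverse_renormalize_day(standard_day: float, cycle_length: float) -> float:
    """Inverse of :func:`renormalize_day`: standard day -> own-cycle day."""
    if cycle_length <= LUTEAL_DAYS:
        raise ValueError(f"cycle length must exceed {LUTEAL_DAYS} days")
    ovulation = cycle_length - LUTEAL_DAYS
    if standard_day <= LUTEAL_DAYS:
        return standard_day * ovulation / LUTEAL_DAYS
    return ovulation + (standard_day - LUTEAL_DAYS)


# ---------------------------------------------------------------------------
# hormone chi-square dating
# ---------------------------------------------------------------------------

def chi2_hormone_day(panel: HormonePanel, reference: HormoneReference) -> DatingEstimate:
    """Date a hormone panel by chi-square matching against the reference.

    chi2(d) = sum_h (measured_h - mean_{h,d})^2 / (sigma_meas^2 + sigma_ref^2);
    hormones whose total variance is zero at a day are excluded from that
    day's sum (logged).  The best reference day (argmin) is converted to the
    28-day standard via :func:`renormalize_day`; the +- error covers the
    reference days within Delta-chi2 <= 1 of the minimum.
    """
    hormones = [h for h in reference.hormones if h in panel.values]
    if not hormones:
        raise ValueError("panel shares no hormones with the reference")
    days = reference.days
    chi2 = np.zeros(len(days))
    used_any = np.zeros(len(days), dtype=bool)
    for h in hormones:
        meas = panel.values[h]
        var = panel.errors.get(h, 0.0) ** 2 + \
            np.array([reference.variance(int(d), h) for d in days])
        means = np.array([reference.mean(int(d), h) for d in days])
        ok = var > 0
        if not ok.all():
            logger.warning("chi2_hormone_day: %s excluded on %d day(s) "
                           "(zero total variance)", h, int((~ok).sum()))
        chi2[ok] += (meas - means[ok]) ** 2 / var[ok]
        used_any |= ok
    if not used_any.any():
        raise ValueError("all hormone variances are zero on every day")

    best = int(np.argmin(chi2))
    ref_day = int(days[best])
    within = days[chi2 <= chi2[best] + 1.0]
    err_low = float(ref_day - within.min())
    err_high = float(within.max() - ref_day)
    std_day = renormalize_day(ref_day, REFERENCE_CYCLE_LENGTH)
    return DatingEstimate(
        day=std_day, method="hormones",
        error_low=err_low, error_high=err_high,
        profile={int(d): float(c) for d, c in zip(days, chi2)},
        extra={"reference_day": ref_day, "convention": "delta_chi2<=1"},
    )


# ---------------------------------------------------------------------------
# patient report and histology ingestion
# ---------------------------------------------------------------------------

def report_day(record: PatientRecord, sampling_date: _dt.date) -> DatingEstimate:
    """Cycle day from the patient's reported last-menses date.

    Raw day = days since the reported first day, counting that day as day 1,
    renormalized with the reported average cycle length.  The reported
    cycle-length variance propagates through the local renormalization slope.
    """
    if record.last_menses_date is None or record.cycle_length is None:
        raise ValueError("record is missing last-menses date or cycle length")
    if sampling_date < record.last_menses_date:
        raise ValueError("sampling date precedes the reported first menses day")
    raw = (sampling_date - record.last_menses_date).days + 1
    L = record.cycle_length
    day = renormalize_day(min(raw, L), L)
    # d(day')/dL at fixed raw day: proliferative -14*raw/O^2 - wait via O=L-14
    ovulation = L - LUTEAL_DAYS
    if raw <= ovulation:
        slope = -LUTEAL_DAYS * raw / ovulation ** 2
    else:
        slope = -1.0
    err = abs(slope) * np.sqrt(record.cycle_length_var)
    return DatingEstimate(day=day, method="report",
                          error_low=float(err), error_high=float(err),
                          extra={"raw_day": raw, "cycle_length": L})


def histology_day(record: PatientRecord) -> DatingEstimate:
    """Pass the histology consensus day through with its asymmetric error."""
    if record.histology_day is None:
        raise ValueError("record has no histology consensus day")
    if record.histology_error_low < 0 or record.histology_error_high < 0:
        raise ValueError("histology error bounds must be non-negative")
    return DatingEstimate(day=float(record.histology_day), method="histology",
                          error_low=float(record.histology_error_low),
                          error_high=float(record.histology_error_high))
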