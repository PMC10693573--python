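"""Feature ensembles: empirical distributions, Weibull cPDF models, KS comparison.

Each morphometric feature of a specimen (pore areas, vessel diameters, ...)
is treated as a statistical ensemble.  The ensemble is represented by a
weighted empirical distribution; its cumulative distribution (cPDF) is
modelled by a three-parameter Weibull function

    We(x) = 1 - exp(-((x - b) / lambda) ** gamma),   x > b

where ``b`` is the location (smallest attainable / detectable value, set by
biology and by the optical resolution limit), ``lambda`` the scale and
``gamma`` the shape.  Two ensembles are compared with a two-sample
Kolmogorov-Smirnov statistic evaluated on the union of their support points,
which is the primitive the cycle-day classifier is built on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger("vped")

__all__ = [
    "EmpiricalDistribution",
    "WeibullParams",
    "KSResult",
    "weibull_cdf",
    "weibull_ppf",
    "build_empirical",
    "fit_weibull",
    "ks_two_sample",
    "pool_day_distribution",
]


# ---------------------------------------------------------------------------
# empirical distributions
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalDistribution:
    """Weighted sample of a single feature, with histogram PDF and step cPDF.

    ``values`` and ``weights`` are stored sorted by value; the step cPDF is
    the weighted ECDF.  A histogram on explicit bin edges is available for
    per-day pooled curves that must share axes across days.
    """

    values: np.ndarray
    weights: np.ndarray
    feature: str = ""
    units: str = ""
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empirical distribution needs at least one value")
        if v.shape != w.shape:
            raise ValueError("values and weights must have equal length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        order = np.argsort(v, kind="stable")
        self.values = v[order]
        self.weights = w[order]
        self._cumw = np.cumsum(self.weights)
        total = self._cumw[-1]
        if total <= 0:
            raise ValueError("total weight must be positive")
        self._total = float(total)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def effective_n(self) -> float:
        """Kish effective sample size (sum w)^2 / sum w^2."""
        w = self.weights
        return float(self._total ** 2 / np.sum(w ** 2))

    def cdf(self, x) -> np.ndarray:
        """Weighted step ECDF evaluated at ``x`` (right-continuous)."""
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        cum = np.concatenate([[0.0], self._cumw]) / self._total
        return cum[idx]

    def histogram(self, bin_edges: Sequence[float] | None = None):
        """Density-normalised weighted histogram ``(edges, heights)``."""
        edges = np.asarray(self.bin_edges if bin_edges is None else bin_edges, float)
        if edges is None or edges.size < 2:
            edges = np.histogram_bin_edges(self.values, bins="auto")
        heights, edges = np.histogram(self.values, bins=edges,
                                      weights=self.weights, density=True)
        return edges, heights

    def histogram_cdf(self, x, bin_edges: Sequence[float] | None = None) -> np.ndarray:
        """cPDF as the cumulative integral of the histogram (piecewise linear)."""
        edges, heights = self.histogram(bin_edges)
        cum = np.concatenate([[0.0], np.cumsum(heights * np.diff(edges))])
        if cum[-1] > 0:
            cum = cum / cum[-1]
        return np.interp(np.asarray(x, float), edges, cum, left=0.0, right=1.0)

    def to_dict(self) -> dict:
        edges, heights = (None, None)
        if self.bin_edges is not None:
            e, h = self.histogram()
            edges, heights = e.tolist(), h.tolist()
        return {
            "feature": self.feature,
            "units": self.units,
            "values": self.values.tolist(),
            "weights": self.weights.tolist(),
            "bin_edges": edges,
            "heights": heights,
        }


def build_empirical(values, weights=None, feature: str = "", units: str = "",
                    bin_edges=None) -> EmpiricalDistribution:
    """Build an :class:`EmpiricalDistribution`, dropping non-finite values.

    Raises ``ValueError`` on empty input; the number of dropped non-finite
    entries is logged.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot build a distribution from an empty sample")
    w = np.ones_like(v) if weights is None else np.asarray(weights, float).ravel()
    finite = np.isfinite(v)
    dropped = int(v.size - finite.sum())
    if dropped:
        logger.warning("build_empirical: dropped %d non-finite value(s)", dropped)
    if not finite.any():
        raise ValueError("no finite values in sample")
    return EmpiricalDistribution(v[finite], w[finite], feature=feature,
                                 units=units, bin_edges=bin_edges)


def pool_day_distribution(samples: Sequence[EmpiricalDistribution],
                          bin_edges=None) -> EmpiricalDistribution:
    """Pool per-patient samples sharing a cycle day into one distribution.

    The pooled histogram is the weighted average of the patients' histograms
    with each patient weighted by its effective element count; with unit
    element weights this is exactly the concatenation of all elements, which
    is how it is implemented.  The cPDF is recomputed from the pooled sample.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample to pool")
    feats = {s.feature for s in samples}
    units = {s.units for s in samples}
    if len(feats) > 1 or len(units) > 1:
        raise ValueError(f"cannot pool incompatible samples: features={feats}, units={units}")
    values = np.concatenate([s.values for s in samples])
    weights = np.concatenate([s.weights for s in samples])
    if bin_edges is None:
        bin_edges = samples[0].bin_edges
    return EmpiricalDistribution(values, weights, feature=samples[0].feature,
                                 units=samples[0].units, bin_edges=bin_edges)


# ---------------------------------------------------------------------------
# three-parameter Weibull model
# ---------------------------------------------------------------------------

@dataclass
class WeibullParams:
    """Location/scale/shape of a Weibull cPDF, with fit diagnostics."""

    b: float            # location, feature units; cPDF(x <= b) = 0
    lam: float          # scale, feature units, > 0
    gamma: float        # shape, dimensionless, > 0
    sup_distance: float | None = None   # sup |fit - empirical cPDF|
    n: int | None = None                # observations used in the fit
    method: str | None = None           # "mle" or "cdf-lsq"

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.gamma > 0):
            raise ValueError(f"scale and shape must be positive, got "
                             f"lambda={self.lam}, gamma={self.gamma}")

    def to_dict(self) -> dict:
        return {"b": self.b, "lambda": self.lam, "gamma": self.gamma,
                "sup_distance": self.sup_distance, "n": self.n,
                "method": self.method}


def weibull_cdf(x, params: WeibullParams) -> np.ndarray | float:
    """Three-parameter Weibull cPDF: 0 for x <= b, 1 - exp(-((x-b)/lam)^gamma)."""
    x = np.asarray(x, dtype=float)
    z = np.clip((x - params.b) / params.lam, 0.0, None)
    out = -np.expm1(-(z ** params.gamma))
    return float(out) if out.ndim == 0 else out


def weibull_ppf(q, params: WeibullParams) -> np.ndarray | float:
    """Quantile function: b + lam * (-ln(1-q))^(1/gamma)."""
    q = np.asarray(q, dtype=float)
    out = params.b + params.lam * (-np.log1p(-q)) ** (1.0 / params.gamma)
    return float(out) if out.ndim == 0 else out


def _fit_diagnostics(dist: EmpiricalDistribution, params: WeibullParams) -> float:
    """Sup distance between the fitted cPDF and the empirical step cPDF."""
    x = dist.values
    fit = weibull_cdf(x, params)
    cum = np.concatenate([[0.0], dist._cumw]) / dist._total
    # ECDF jumps: compare model with the ECDF just before and at each point
    return float(np.max(np.maximum(np.abs(fit - cum[1:]), np.abs(fit - cum[:-1]))))


def fit_weibull(dist: EmpiricalDistribution, location_policy="min-offset",
                min_n: int = 20) -> WeibullParams:
    """Fit (lambda, gamma) of the Weibull cPDF with the location fixed by policy.

    ``location_policy`` is either ``("fixed", b0)`` / a float (location pinned
    at the configured resolution limit) or ``"min-offset"`` (location just
    below the sample minimum).  Jointly fitting the location is unstable and
    deliberately not offered as a default.  Maximum likelihood on the shifted
    values is the primary method; a least-squares fit to the empirical cPDF
    is the fallback when MLE fails to converge.
    """
    if dist.n < min_n:
        raise ValueError(f"need at least {min_n} observations, got {dist.n}")
    # weights enter the diagnostics through the ECDF; the point estimate uses
    # the raw values (all pipeline ensembles carry unit element weights)
    vals = dist.values
    if np.ptp(vals) == 0:
        raise ValueError("degenerate distribution: all values identical")

    if isinstance(location_policy, (int, float)):
        b = float(location_policy)
        fixed = True
    elif isinstance(location_policy, tuple) and location_policy[0] == "fixed":
        b = float(location_policy[1])
        fixed = True
    elif location_policy == "min-offset":
        span = np.ptp(vals)
        b = float(vals.min() - 1e-3 * span)
        fixed = False
    else:
        raise ValueError(f"unknown location policy: {location_policy!r}")

    shifted = vals - b
    if fixed and np.any(shifted <= 0):
        raise ValueError("values at or below the fixed location b")

    method = "mle"
    try:
        gamma_hat, _, lam_hat = stats.weibull_min.fit(shifted, floc=0.0)
        if not (np.isfinite(gamma_hat) and np.isfinite(lam_hat)
                and gamma_hat > 0 and lam_hat > 0):
            raise RuntimeError("MLE returned invalid parameters")
    except Exception:                                    # pragma: no cover - rare
        method = "cdf-lsq"
        ecdf_x = np.sort(shifted)
        ecdf_y = (np.arange(1, ecdf_x.size + 1) - 0.5) / ecdf_x.size

        def resid(p):
            lam, gam = np.exp(p)
            return -np.expm1(-(ecdf_x / lam) ** gam) - ecdf_y

        res = optimize.least_squares(
            resid, x0=[np.log(np.median(shifted) + 1e-12), 0.0])
        lam_hat, gamma_hat = np.exp(res.x)
        logger.info("fit_weibull: MLE failed, used cPDF least squares")

    params = WeibullParams(b=b, lam=float(lam_hat), gamma=float(gamma_hat),
                           n=dist.n, method=method)
    params.sup_distance = _fit_diagnostics(dist, params)
    return params


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov comparison
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    """Two-sample KS statistic D, asymptotic p-value and effective n."""

    statistic: float
    pvalue: float
    effective_n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= 1.0 + 1e-12):
            raise ValueError(f"D out of [0,1]: {self.statistic}")
        self.statistic = float(min(self.statistic, 1.0))
        self.pvalue = float(min(max(self.pvalue, 0.0), 1.0))


def ks_two_sample(d1: EmpiricalDistribution, d2: EmpiricalDistribution) -> KSResult:
    """Two-sample KS test between weighted empirical distributions.

    D is the supremum of |cPDF1 - cPDF2| over the union of support points;
    the p-value comes from the asymptotic Kolmogorov distribution with the
    effective sample size n1*n2/(n1+n2), where each sample's n is its
    weight-based (Kish) effective count.
    """
    support = np.union1d(d1.values, d2.values)
    d = float(np.max(np.abs(d1.cdf(support) - d2.cdf(support))))
    n1, n2 = d1.effective_n, d2.effective_n
    ne = n1 * n2 / (n1 + n2)
    if d == 0.0:
        p = 1.0
    else:
        p = float(special.kolmogorov(math.sqrt(ne) * d))
    return KSResult(statistic=d, pvalue=p, effective_n=ne)
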