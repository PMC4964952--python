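"""Descriptive statistics for left-censored concentrations.

Substituting half the detection limit for nondetects biases means and
standard deviations of skewed concentration data, so two standard
censored-data estimators are provided instead:

* :func:`ros_summary` — lognormal Regression on Order Statistics with
  Hirsch–Stedinger / Helsel–Cohn plotting positions (handles multiple
  detection limits); nondetects are imputed from the regression of
  log-detects on normal scores and summary statistics are taken over the
  combined observed + imputed sample.
* :func:`km_summary` — the product-limit estimator applied after flipping
  left-censored data to right-censored form about a constant exceeding the
  sample maximum.

Both reduce exactly to ordinary sample statistics when nothing is censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["CensoredSummary", "ros_summary", "km_summary", "hc_plotting_positions"]

_DEFAULT_Q = (0.10, 0.25, 0.50, 0.75, 0.90)


@dataclass
class CensoredSummary:
    method: str                      # "ROS" or "KM"
    mean: float
    sd: float
    percentiles: dict[float, float]
    n: int
    n_censored: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be nonnegative")
        qs = sorted(self.percentiles)
        vals = [self.percentiles[q] for q in qs]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("percentiles must be nondecreasing in quantile")


def _split(t, delta):
    t = np.asarray(t, float)
    delta = np.asarray(delta, int)
    if t.shape != delta.shape:
        raise ValueError("value and censoring arrays must align")
    return t[delta == 1], t[delta == 0]


def hc_plotting_positions(t, delta):
    """Helsel–Cohn plotting positions for left-censored data.

    Returns ``(p_detect, detects_sorted, p_censored, tau_sorted)`` where the
    probabilities are cumulative (non-exceedance) plotting positions.  The
    recursion runs over distinct detection limits ``DL_1 < ... < DL_m`` with
    exceedance probabilities ``pe_j = pe_{j+1} + A_j/(A_j+B_j)*(1-pe_{j+1})``
    where ``A_j`` counts detects in ``[DL_j, DL_{j+1})`` and ``B_j`` counts
    all observations below ``DL_j`` (detects below and nondetects at or
    below).  Ties between a detection limit and a detect rank the nondetect
    lower.
    """
    det, cen = _split(t, delta)
    det_sorted = np.sort(det)
    taus = np.sort(np.unique(cen)) if cen.size else np.array([])
    # boundaries: DL_0 = 0 below everything, DL_{m+1} = +inf
    bounds = np.concatenate(([0.0], taus, [np.inf]))
    m = len(taus)
    pe = np.zeros(m + 2)  # pe[j] = P(X > bounds[j]); pe[m+1] = 0
    for j in range(m, -1, -1):
        a_j = np.sum((det_sorted >= bounds[j]) & (det_sorted < bounds[j + 1]))
        b_j = np.sum(det_sorted < bounds[j]) + np.sum(cen <= bounds[j])
        if a_j + b_j == 0:
            pe[j] = pe[j + 1]
        else:
            pe[j] = pe[j + 1] + a_j / (a_j + b_j) * (1.0 - pe[j + 1])
    p_det = np.empty(det_sorted.size)
    for j in range(m + 1):
        in_j = (det_sorted >= bounds[j]) & (det_sorted < bounds[j + 1])
        a_j = int(in_j.sum())
        if a_j:
            r = np.arange(1, a_j + 1)
            p_det[in_j] = (1.0 - pe[j]) + r / (a_j + 1) * (pe[j] - pe[j + 1])
    cen_sorted = np.sort(cen)
    p_cen = np.empty(cen_sorted.size)
    for j, dl in enumerate(taus, start=1):
        at = cen_sorted == dl
        c_j = int(at.sum())
        k = np.arange(1, c_j + 1)
        p_cen[at] = (1.0 - pe[j]) * k / (c_j + 1)
    return p_det, det_sorted, p_cen, cen_sorted


def ros_summary(t, delta, quantiles=_DEFAULT_Q) -> CensoredSummary:
    """Lognormal ROS mean/sd/percentiles for left-censored data.

    ``t`` holds the measured value for detects and the detection limit for
    nondetects; ``delta`` is 1 for detects.  Requires at least 3 detects and
    a censoring fraction below 80%.  With zero censoring this is exactly the
    arithmetic mean/sd (ddof=1).
    """
    det, cen = _split(t, delta)
    if det.size < 3:
        raise ValueError("ROS needs at least 3 uncensored values")
    if cen.size / (det.size + cen.size) >= 0.80:
        raise ValueError("censoring fraction must be < 80% for ROS")
    if np.any(det <= 0):
        raise ValueError("uncensored concentrations must be positive")
    p_det, det_sorted, p_cen, _ = hc_plotting_positions(t, delta)
    imputed = np.array([])
    if cen.size:
        z_det = stats.norm.ppf(p_det)
        slope, intercept = np.polyfit(z_det, np.log(det_sorted), 1)
        imputed = np.exp(intercept + slope * stats.norm.ppf(p_cen))
    full = np.sort(np.concatenate([imputed, det_sorted]))
    return CensoredSummary(
        method="ROS",
        mean=float(full.mean()),
        sd=float(full.std(ddof=1)) if full.size > 1 else 0.0,
        percentiles={q: float(np.quantile(full, q)) for q in quantiles},
        n=full.size,
        n_censored=int(cen.size),
        detail={"imputed": imputed},
    )


def _km_distribution(t, delta):
    """Probability masses of the flipped product-limit estimate.

    Left-censored values are reflected about M = max(all) + 1 so nondetects
    become right-censored; the KM survival curve of the flipped variable is
    converted back to point masses on the original scale.  Any survival mass
    remaining beyond the largest flipped event time is assigned to the
    smallest original value (the restricted-mean convention).
    """
    t = np.asarray(t, float)
    delta = np.asarray(delta, int)
    if delta.sum() == 0:
        raise ValueError("Kaplan-Meier needs at least one uncensored value")
    m_const = float(np.max(t)) + 1.0
    flipped = m_const - t
    kmf = KaplanMeierFitter()
    kmf.fit(flipped, event_observed=delta)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(float)
    surv = sf.to_numpy(float)
    prev = np.concatenate([[1.0], surv[:-1]])
    mass = prev - surv                      # jump at each flipped event time
    keep = mass > 0
    w_times, w_mass = times[keep], mass[keep]
    resid = surv[-1]
    if resid > 0:  # unresolved mass beyond the last event -> largest flip time
        w_times = np.append(w_times, np.max(flipped))
        w_mass = np.append(w_mass, resid)
    orig = m_const - w_times
    order = np.argsort(orig)
    return orig[order], w_mass[order]


def km_summary(t, delta, quantiles=_DEFAULT_Q) -> CensoredSummary:
    """Flipped Kaplan–Meier mean/sd/percentiles for left-censored data.

    With zero censoring this equals the empirical mean and sd (the sd here
    is the population form of the KM distribution, rescaled to ddof=1).
    """
    values, mass = _km_distribution(t, delta)
    n = len(np.asarray(t))
    mean = float(np.sum(values * mass))
    var = float(np.sum(mass * (values - mean) ** 2))
    if n > 1:  # small-sample rescale so the uncensored case matches ddof=1
        var *= n / (n - 1)
    cdf = np.cumsum(mass)
    pct = {}
    for q in quantiles:
        idx = int(np.searchsorted(cdf, q, side="left"))
        pct[q] = float(values[min(idx, len(values) - 1)])
    return CensoredSummary(
        method="KM",
        mean=mean,
        sd=float(np.sqrt(var)),
        percentiles=pct,
        n=n,
        n_censored=int(np.sum(np.asarray(delta, int) == 0)),
    )


def substitution_mean(t, delta, factor: float = 0.5) -> float:
    """Naive DL-substitution mean (nondetects replaced by factor*DL).

    Provided only as the biased comparator the censored estimators replace.
    """
    t = np.asarray(t, float)
    delta = np.asarray(delta, int)
    return float(np.where(delta == 1, t, factor * t).mean())
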