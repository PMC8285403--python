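"""Two-sample MR causal-effect estimators on a harmonized instrument set.

All estimators consume per-variant exposure effects (beta_X, se_X) and
outcome effects (beta_Y, se_Y) expressed for a common effect allele and
return the causal effect of the exposure on the outcome on the log-odds
scale (for a binary outcome).

Implemented methods
-------------------
* Wald ratio — single-variant estimate beta_Y/beta_X with first- or
  second-order delta-method standard error.
* IVW — inverse-variance weighted combination of Wald ratios, equivalent to
  weighted through-origin regression of beta_Y on beta_X with weights
  1/se_Y^2; fixed-effect or multiplicative random-effects standard error.
* MR-Egger — the same weighted regression with an unconstrained intercept;
  the slope is the pleiotropy-adjusted causal estimate and the intercept the
  average directional pleiotropy, inference on t(k-2).
* Simple / weighted median — median of the per-variant ratios, consistent
  when at least half the weight comes from valid instruments; standard error
  by parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, DomainError, InsufficientInstrumentsError
from .summary_stats import HarmonizedInstrumentSet

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (or raw outcome) scale."""

    method: str
    beta: float
    se: float
    p_value: float
    k: int
    scale_factor: float = 1.0

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.method}: se must be > 0")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.method}: p_value outside (0, 1]")


def _two_sided_normal_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), _TINY_P, 1.0))


def _arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, HarmonizedInstrumentSet):
        df = instruments.instruments
    elif isinstance(instruments, pd.DataFrame):
        df = instruments
    else:
        raise TypeError("expected HarmonizedInstrumentSet or DataFrame")
    return (
        df["beta_exposure"].to_numpy(float),
        df["se_exposure"].to_numpy(float),
        df["beta_outcome"].to_numpy(float),
        df["se_outcome"].to_numpy(float),
    )


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, se_order: str = "first"
) -> MREstimate:
    """Single-variant causal estimate by/bx.

    First-order se is sy/|bx|; second-order adds the delta-method term for
    noise in bx: sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise DomainError("wald_ratio undefined for bx = 0")
    if sx <= 0 or sy <= 0:
        raise DomainError("standard errors must be > 0")
    if se_order not in ("first", "second"):
        raise ValueError(f"unknown se_order {se_order!r}")
    beta = by / bx
    if se_order == "first":
        se = sy / abs(bx)
    else:
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    return MREstimate("wald_ratio", float(beta), se, _two_sided_normal_p(beta / se), k=1)


def ivw(instruments, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(w bx by) / sum(w bx^2) with w = 1/sy^2; the fixed-effect se is
    1/sqrt(sum(w bx^2)).  The multiplicative random-effects model inflates the
    se by max(1, sqrt(Q/(k-1))) where Q is the weighted residual sum of
    squares of the through-origin fit (the se never drops below the
    fixed-effect se).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    bx, _sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k == 0:
        raise InsufficientInstrumentsError("IVW requires at least 1 instrument")
    if model == "random" and k < 2:
        raise DomainError("random-effects IVW requires k >= 2")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise DegenerateDesignError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    if model == "random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, float(np.sqrt(q / (k - 1))))
    return MREstimate(
        f"ivw_{model}", beta, se, _two_sided_normal_p(beta / se), k=k
    )


def egger(instruments) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted fit of by on bx with intercept.

    Exposure orientation is recoded so every bx >= 0 (negating both bx and by
    where bx < 0) before fitting.  Weights are 1/sy^2; standard errors are
    scaled by max(1, sqrt(RSS_w/(k-2))) and p-values use t(k-2).  Returns
    (slope, intercept); a nonzero intercept indicates average directional
    pleiotropy.
    """
    bx, _sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires k >= 3")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise DegenerateDesignError("all exposure effects equal; slope unidentifiable")
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx**2))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swxx * swy - swx * swxy) / denom
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    inflation = max(1.0, rss_w / (k - 2))
    se_slope = float(np.sqrt(inflation * sw / denom))
    se_int = float(np.sqrt(inflation * swxx / denom))
    df = k - 2

    def _t_p(est, se):
        return float(np.clip(2.0 * stats.t.sf(abs(est / se), df), _TINY_P, 1.0))

    return (
        MREstimate("egger_slope", float(slope), se_slope, _t_p(slope, se_slope), k=k),
        MREstimate("egger_intercept", float(intercept), se_int, _t_p(intercept, se_int), k=k),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Values are sorted; with normalized weights w_j the standardized cumulative
    weight is p_j = cumsum(w)_j - w_j/2, and the median interpolates linearly
    between the two values whose p_j bracket 0.5.
    """
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    pq = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, pq, v))


def _median_point(bx, by, sy, weighting: str) -> float:
    ratios = by / bx
    if weighting == "simple":
        weights = np.ones_like(ratios)
    else:
        weights = bx**2 / sy**2
    return weighted_median(ratios, weights)


def median_estimate(
    instruments,
    weighting: str = "weighted",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Simple or weighted median of the per-variant Wald ratios.

    The weighted variant uses inverse-variance weights bx^2/sy^2 (the Wald
    ratio precision to first order).  The standard error comes from a
    parametric bootstrap: bx_j ~ N(bx_j, sx_j^2), by_j ~ N(by_j, sy_j^2)
    redrawn ``n_boot`` times, the estimate recomputed for each draw, and the
    se taken as the standard deviation of the draws.  ``seed`` is required
    for reproducibility.
    """
    if weighting not in ("simple", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if seed is None:
        raise ValueError("median_estimate requires an explicit seed")
    if n_boot < 2:
        raise DomainError("n_boot must be >= 2")
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise InsufficientInstrumentsError("median estimators require k >= 3")
    if np.any(bx == 0):
        raise DomainError("median estimators undefined when any bx = 0")

    beta = _median_point(bx, by, sy, weighting)

    rng = np.random.default_rng(seed)
    bx_draw = rng.normal(bx, sx, size=(n_boot, k))
    by_draw = rng.normal(by, sy, size=(n_boot, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = by_draw / bx_draw
        if weighting == "simple":
            wts = np.ones_like(ratios)
        else:
            wts = bx_draw**2 / sy**2
    order = np.argsort(ratios, axis=1, kind="mergesort")
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(wts, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    pq = np.cumsum(w_sorted, axis=1) - w_sorted / 2.0
    draws = np.array([np.interp(0.5, pq[i], r_sorted[i]) for i in range(n_boot)])
    se = float(np.std(draws, ddof=1))
    if se == 0:  # degenerate bootstrap (e.g. all ratios identical)
        se = float(np.finfo(float).tiny)
    method = f"{weighting}_median"
    return MREstimate(method, float(beta), se, _two_sided_normal_p(beta / se), k=k)


def confidence_interval(est: MREstimate, level: float = 0.95) -> tuple[float, float]:
    """Symmetric CI on the beta scale; Egger methods use t(k-2), others normal."""
    if not 0 < level < 1:
        raise DomainError(f"level {level} outside (0, 1)")
    if est.method.startswith("egger"):
        crit = float(stats.t.ppf(0.5 + level / 2.0, est.k - 2))
    else:
        crit = float(stats.norm.ppf(0.5 + level / 2.0))
    return est.beta - crit * est.se, est.beta + crit * est.se


def estimates_to_frame(estimates, exposure: str = "", outcome: str = "") -> pd.DataFrame:
    """Serialize a collection of MREstimate to the standard TSV row layout."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": est.method,
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "p": est.p_value,
                "scale_factor": est.scale_factor,
            }
        )
    return pd.DataFrame(rows)
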