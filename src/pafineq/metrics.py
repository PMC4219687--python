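"""Inequality metrics: age-adjusted rates, rate differences/ratios,
scenario reductions, median summary rows and impact bands.

Absolute inequality is the rate difference (RD) and relative inequality
the rate ratio (RR) between low and high educated, computed from
age-adjusted mortality rates with high education as the reference.  A
scenario's impact is the drop in RD (deaths per 100,000 person-years) and
the percentage of the excess rate ratio (RR - 1) removed.
"""

from __future__ import annotations

import decimal
import math

import numpy as np

from .data import AGE_GROUPS


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero).

    Published tables round half-up; numpy/python banker's rounding would
    turn a median of 67.5 into 68 but 66.5 into 66, which does not match.
    """
    d = decimal.Decimal(repr(float(value))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


def age_adjusted_rate(rates: np.ndarray, weights: np.ndarray) -> float:
    """Directly standardised rate ``sum_a w_a rate_a`` over the age groups."""
    rates = np.asarray(rates, float)
    weights = np.asarray(weights, float)
    if rates.shape != weights.shape or rates.shape != (len(AGE_GROUPS),):
        raise ValueError("rates and weights must both cover the four age groups")
    return float(rates @ weights)


def validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, float)
    if w.shape != (len(AGE_GROUPS),) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
        raise ValueError("standard weights must be 4 nonnegative values summing to 1")
    return w


def rd_rr(low_rate: float, high_rate: float) -> tuple[float, float]:
    """Rate difference and rate ratio, high education as reference."""
    if high_rate <= 0:
        raise ValueError("high-educated rate must be positive")
    return low_rate - high_rate, low_rate / high_rate


def scenario_reductions(rd_obs: float, rr_obs: float, rd_cf: float,
                        rr_cf: float) -> tuple[float, float]:
    """Absolute and relative inequality reduction of a scenario.

    Returns ``(delta_rd, relative_reduction_pct)`` where
    ``delta_rd = RD_obs - RD_cf`` (deaths per 100,000 person-years) and the
    relative reduction is the percentage of the excess rate ratio removed,
    ``100 (RR_obs - RR_cf) / (RR_obs - 1)`` — 100% exactly when the
    counterfactual removes all excess risk (RR_cf = 1).  When RR_obs = 1
    there is no excess to remove and the relative reduction is NaN.
    """
    delta_rd = rd_obs - rd_cf
    if math.isclose(rr_obs, 1.0, abs_tol=1e-12):
        return delta_rd, float("nan")
    return delta_rd, 100.0 * (rr_obs - rr_cf) / (rr_obs - 1.0)


def median_summary(values, precision: int | None = None) -> float:
    """Median over non-missing, non-reference values (summary "All" row).

    ``values`` may contain NaN/None (data not available) and the string
    ``"ref"`` (reference/donor population); both are excluded.  An even
    count yields the mean of the two central values.  NaN is returned when
    nothing remains.
    """
    clean: list[float] = []
    for v in values:
        if v is None or (isinstance(v, str) and v.strip().lower() in ("na", "ref", "")):
            continue
        v = float(v)
        if math.isnan(v):
            continue
        clean.append(v)
    if not clean:
        return float("nan")
    med = float(np.median(clean))
    if precision is not None:
        med = round_half_up(med, precision)
    return med


#: impact band thresholds, lower-inclusive
_BANDS = {
    "paf": ((3.0, 10.0), "%"),                 # PAF of the low educated, in %
    "rd_reduction": ((20.0, 80.0), " per 100k"),  # drop in RD, deaths/100k py
}


def band(value: float, kind: str = "paf") -> str:
    """Impact band label: ``minor`` / ``moderate`` / ``major``.

    PAFs band at 3% and 10%; rate-difference reductions at 20 and 80
    deaths per 100,000 person-years.  Values below the first threshold
    (including negative ones) are ``minor``.
    """
    try:
        (lo, hi), _ = _BANDS[kind]
    except KeyError:
        raise ValueError(f"unknown band kind {kind!r}") from None
    if isinstance(value, float) and math.isnan(value):
        return "na"
    if value < lo:
        return "minor"
    if value < hi:
        return "moderate"
    return "major"
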