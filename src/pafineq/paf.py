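"""Generalised population attributable fractions.

The PAF against an arbitrary counterfactual exposure distribution is

    PAF = (sum_i P_i RR_i - sum_i P'_i RR_i) / sum_i P_i RR_i

with P the current and P' the counterfactual category proportions and RR_i
the relative mortality risk of category i.  It is the fraction of deaths
avoided when the population moves from P to P' under a multiplicative
hazard model; it is negative when the counterfactual is *less* favourable.

Age aggregation follows the two-step convention used for stratified
mortality data: age-specific PAFs produce age-specific saved deaths, which
are summed over 30-79 and divided by total deaths to give the overall PAF
of an education group.
"""

from __future__ import annotations

import numpy as np


def rr_weighted_sum(p: np.ndarray, rr: np.ndarray) -> float:
    """``sum_i P_i RR_i`` — the average relative risk under distribution P.

    Equals 1 when all mass sits on the reference category.  Used both in
    the PAF numerator/denominator and as the scalar ordering that decides
    which of two distributions is "more favourable".
    """
    p = np.asarray(p, float)
    rr = np.asarray(rr, float)
    if p.shape != rr.shape:
        raise ValueError(f"category mismatch: {p.shape} proportions vs "
                         f"{rr.shape} relative risks")
    return float(p @ rr)


def paf(current: np.ndarray, counterfactual: np.ndarray,
        rr: np.ndarray) -> float:
    """Attributable fraction of deaths for a move from one exposure
    distribution to another.

    Parameters
    ----------
    current, counterfactual
        Category proportions, each summing to 1 over the same categories.
    rr
        Relative risk per category (positive, reference 1).

    Returns
    -------
    float
        Dimensionless fraction in (-inf, 1); 0 when the RR-weighted sums
        coincide, negative when the counterfactual is less favourable.
    """
    current = np.asarray(current, float)
    counterfactual = np.asarray(counterfactual, float)
    rr = np.asarray(rr, float)
    if not (current.shape == counterfactual.shape == rr.shape):
        raise ValueError("current, counterfactual and rr must share one "
                         "category axis")
    if current.size < 2:
        raise ValueError("need at least 2 exposure categories")
    s_cur = rr_weighted_sum(current, rr)
    s_cf = rr_weighted_sum(counterfactual, rr)
    return (s_cur - s_cf) / s_cur


def counterfactual_mortality(deaths: float, person_years: float,
                             paf_value: float,
                             per: float = 100_000.0) -> tuple[float, float]:
    """New mortality rate and saved deaths in one cell under a given PAF.

    Returns ``(new_rate, saved_deaths)`` with ``new_rate = rate * (1 - PAF)``
    (per `per` person-years) and ``saved_deaths = deaths * PAF``; saved
    deaths are negative when the PAF is (mortality rises under the
    counterfactual).  Saved deaths are kept as reals; reports round last.
    """
    if paf_value >= 1:
        raise ValueError(f"PAF {paf_value} >= 1 would imply non-positive deaths")
    rate = deaths / person_years * per
    return rate * (1.0 - paf_value), deaths * paf_value


def overall_paf(age_pafs: np.ndarray, deaths: np.ndarray) -> float:
    """Aggregate age-specific PAFs into one overall PAF.

    Age-specific saved deaths ``PAF_a * D_a`` are summed and divided by the
    total deaths, i.e. a deaths-weighted mean of the age-specific PAFs.
    """
    age_pafs = np.asarray(age_pafs, float)
    deaths = np.asarray(deaths, float)
    if age_pafs.shape != deaths.shape:
        raise ValueError("age_pafs and deaths must align on age groups")
    total = deaths.sum()
    if total <= 0:
        raise ValueError("overall PAF undefined: zero total deaths")
    return float((age_pafs * deaths).sum() / total)


def age_specific_pafs(current: np.ndarray, counterfactual: np.ndarray,
                      rr: np.ndarray) -> np.ndarray:
    """Vector of PAFs per age group from (n_ages, k) distribution arrays."""
    current = np.asarray(current, float)
    counterfactual = np.asarray(counterfactual, float)
    rr = np.asarray(rr, float)
    if rr.ndim == 1:
        rr = np.broadcast_to(rr, current.shape)
    s_cur = (current * rr).sum(axis=1)
    s_cf = (counterfactual * rr).sum(axis=1)
    return (s_cur - s_cf) / s_cur
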