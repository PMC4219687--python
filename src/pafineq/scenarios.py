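"""Counterfactual exposure scenarios and the scenario engine.

Two counterfactuals are supported:

* **upward levelling** — within each population, the low- and mid-educated
  adopt the risk-factor distribution of the high educated.  This bounds
  what eliminating the exposure gradient could achieve.  Where the low
  educated are already the more favourable group (reverse gradient), the
  reported reduction of mortality inequality is zero by convention.
* **best practice** — every population adopts the low- *and* high-educated
  distributions of a donor population, chosen per sex and risk factor as
  the one with the smallest educational inequality (smallest low-educated
  upward-levelling PAF) among populations whose high-educated exposure is
  not above the cross-population median.  Because the high educated change
  too, inequality can widen; such negative reductions are reported as
  negative unless the donor's high-educated distribution is less
  favourable than the target's, in which case the reduction is zero by
  convention.

Clamping acts on reported reductions, never by mutating distributions, so
the PAF algebra stays pure and bootstrap intervals can reproduce exact 0.0
lower bounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import (AGE_GROUPS, EDUCATION_LEVELS, SEXES, CounterfactualExposure,
                   ExposureTable, RelativeRiskTable, StratifiedMortality,
                   ValidationError)
from .metrics import age_adjusted_rate, rd_rr, scenario_reductions, validate_weights
from .paf import age_specific_pafs, overall_paf, rr_weighted_sum

UPWARD_LEVELLING = "upward_levelling"
BEST_PRACTICE = "best_practice"


@dataclasses.dataclass
class ScenarioSpec:
    """Which counterfactual to build, for which risk factor.

    ``donors`` maps sex to the donor population id; it must be resolved
    (via :func:`select_best_practice` or a config override) before a
    best-practice run and must be empty for upward levelling.
    """

    type: str
    risk_factor: str
    donors: dict = dataclasses.field(default_factory=dict)
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.type not in (UPWARD_LEVELLING, BEST_PRACTICE):
            raise ValidationError(f"unknown scenario type {self.type!r}")
        if self.type == UPWARD_LEVELLING and self.donors:
            raise ValidationError("upward levelling names no donor population")


def rr_weighted_exposure(dist: np.ndarray, rr: np.ndarray) -> float:
    """Average relative risk implied by an exposure distribution.

    For a (4, k) age-by-category array the unweighted mean over age groups
    is returned.  This is the scalar that orders distributions by
    favourability: lower means less exposed to harmful categories, and it
    equals 1 when all mass is on the reference category.
    """
    dist = np.asarray(dist, float)
    rr = np.asarray(rr, float)
    if dist.ndim == 1:
        return rr_weighted_sum(dist, rr)
    if rr.ndim == 1:
        rr = np.broadcast_to(rr, dist.shape)
    if dist.shape != rr.shape:
        raise ValueError("category mismatch between distribution and RRs")
    return float((dist * rr).sum(axis=1).mean())


def _weighted_paf(current: np.ndarray, counterfactual: np.ndarray,
                  rr: np.ndarray, deaths: np.ndarray | None) -> float:
    pafs = age_specific_pafs(current, counterfactual, rr)
    if deaths is None:
        return float(pafs.mean())
    return overall_paf(pafs, deaths)


def build_upward_levelling(exposure: ExposureTable, rr: RelativeRiskTable,
                           population: str, sex: str, risk_factor: str,
                           low_deaths: np.ndarray | None = None,
                           ) -> CounterfactualExposure:
    """Counterfactual where low and mid educated get the high-educated
    distribution of the same population, sex and age group.

    The clamp flag is set when the low educated are already the more
    favourable group, i.e. the overall PAF of levelling them up is
    negative (deaths-weighted over age groups when ``low_deaths`` is
    given, unweighted otherwise).
    """
    cf = CounterfactualExposure(risk_factor=risk_factor,
                                scenario=UPWARD_LEVELLING, dist={},
                                clamped={}, missing=set())
    if not exposure.available(population, sex, risk_factor):
        cf.missing.add((population, sex))
        return cf
    cats = exposure.categories[risk_factor]
    rr_mat = rr.matrix(risk_factor, cats, sex)
    high = exposure.distributions(population, sex, "high", risk_factor)
    for edu in EDUCATION_LEVELS:
        cf.dist[(population, sex, edu)] = high if edu != "high" else \
            exposure.distributions(population, sex, "high", risk_factor)
    low = exposure.distributions(population, sex, "low", risk_factor)
    cf.clamped[(population, sex)] = _weighted_paf(low, high, rr_mat,
                                                  low_deaths) < 0
    return cf


def build_best_practice(exposure: ExposureTable, rr: RelativeRiskTable,
                        population: str, donor: str, sex: str,
                        risk_factor: str,
                        high_deaths: np.ndarray | None = None,
                        ) -> CounterfactualExposure:
    """Counterfactual where a population adopts the donor's low- and
    high-educated distributions (mid gets the donor's mid).

    The clamp flag is set when the donor's high-educated distribution is
    less favourable than the target's own, i.e. the PAF of moving the
    target's high educated onto the donor's distribution is negative.
    """
    cf = CounterfactualExposure(risk_factor=risk_factor, scenario=BEST_PRACTICE,
                                dist={}, clamped={}, missing=set(),
                                donors={sex: donor})
    if (not exposure.available(population, sex, risk_factor)
            or not exposure.available(donor, sex, risk_factor)):
        cf.missing.add((population, sex))
        return cf
    cats = exposure.categories[risk_factor]
    rr_mat = rr.matrix(risk_factor, cats, sex)
    for edu in EDUCATION_LEVELS:
        cf.dist[(population, sex, edu)] = exposure.distributions(
            donor, sex, edu, risk_factor)
    t_high = exposure.distributions(population, sex, "high", risk_factor)
    d_high = exposure.distributions(donor, sex, "high", risk_factor)
    cf.clamped[(population, sex)] = _weighted_paf(t_high, d_high, rr_mat,
                                                  high_deaths) < 0
    return cf


def select_best_practice(mortality: StratifiedMortality,
                         exposure: ExposureTable, rr: RelativeRiskTable,
                         sex: str, risk_factor: str) -> str:
    """Pick the donor population for a best-practice scenario.

    The donor is the population with the smallest low-educated overall
    upward-levelling PAF (clamped below at 0), among *eligible*
    populations — those whose high-educated RR-weighted exposure does not
    exceed the cross-population median, so that small inequality cannot
    stem from uniformly high exposure.  Ties break lexicographically on
    population id, which makes selection deterministic.
    """
    candidates = [p for p in exposure.populations
                  if exposure.available(p, sex, risk_factor)
                  and mortality.has(p, sex)]
    if not candidates:
        raise ValidationError(
            f"no population has exposure data for ({sex!r}, {risk_factor!r});"
            f" set an explicit donor override in the config")
    cats = exposure.categories[risk_factor]
    rr_mat = rr.matrix(risk_factor, cats, sex)
    high_level = {p: rr_weighted_exposure(
        exposure.distributions(p, sex, "high", risk_factor), rr_mat)
        for p in candidates}
    cutoff = float(np.median(list(high_level.values())))
    eligible = [p for p in candidates if high_level[p] <= cutoff]
    if not eligible:  # cannot happen with a finite median, kept for safety
        raise ValidationError(
            f"no eligible best-practice donor for ({sex!r}, {risk_factor!r});"
            f" set an explicit donor override in the config")

    def levelled_paf(p: str) -> float:
        low = exposure.distributions(p, sex, "low", risk_factor)
        high = exposure.distributions(p, sex, "high", risk_factor)
        deaths = mortality.deaths_vector(p, sex, "low")
        return max(0.0, _weighted_paf(low, high, rr_mat, deaths))

    return min(eligible, key=lambda p: (levelled_paf(p), p))


def resolve_donors(mortality: StratifiedMortality, exposure: ExposureTable,
                   rr: RelativeRiskTable, risk_factor: str,
                   overrides: dict | None = None) -> dict:
    """Donor population per sex, honouring explicit config overrides."""
    overrides = overrides or {}
    donors = {}
    for sex in SEXES:
        if sex in overrides:
            donors[sex] = overrides[sex]
        else:
            donors[sex] = select_best_practice(mortality, exposure, rr, sex,
                                               risk_factor)
    return donors


@dataclasses.dataclass
class ScenarioResult:
    """Engine output for one scenario x risk factor.

    ``summary`` has one row per population x sex (status ok/ref/na, clamp
    flag, overall PAFs per education group, observed and counterfactual
    age-adjusted rates, RD/RR and their reductions); ``detail`` one row
    per population x sex x education x age group plus an overall 30-79 row
    (PAF, deaths, saved deaths, observed and counterfactual rates).
    """

    spec: ScenarioSpec
    summary: pd.DataFrame
    detail: pd.DataFrame

    def for_population(self, population: str, sex: str) -> pd.Series:
        s = self.summary
        row = s[(s["population"] == population) & (s["sex"] == sex)]
        if row.empty:
            raise KeyError((population, sex))
        return row.iloc[0]


def _nan_summary(population: str, sex: str, spec: ScenarioSpec,
                 status: str) -> dict:
    out = {"population": population, "sex": sex,
           "risk_factor": spec.risk_factor, "scenario": spec.type,
           "status": status, "clamped": False,
           "donor": spec.donors.get(sex) if spec.donors else None}
    for c in ("paf_low", "paf_mid", "paf_high", "paf_low_unclamped",
              "rate_low_obs", "rate_high_obs", "rate_low_cf", "rate_high_cf",
              "rd_obs", "rr_obs", "rd_cf", "rr_cf", "delta_rd",
              "rel_reduction_pct", "delta_rd_unclamped",
              "rel_reduction_pct_unclamped"):
        out[c] = float("nan")
    return out


def run_scenario(mortality: StratifiedMortality, exposure: ExposureTable,
                 rr: RelativeRiskTable, spec: ScenarioSpec,
                 weights: np.ndarray | str = "population") -> ScenarioResult:
    """Run one scenario for every population x sex.

    ``weights`` is either ``"population"`` (each population's own
    all-education person-years distribution over the four age groups, per
    sex) or an explicit 4-vector of standardisation weights.
    """
    if spec.type == BEST_PRACTICE and set(spec.donors) < set(SEXES):
        raise ValidationError("best practice spec must name a donor per sex; "
                              "use resolve_donors() first")
    rf = spec.risk_factor
    summaries: list[dict] = []
    details: list[dict] = []
    for pop in mortality.populations:
        for sex in SEXES:
            if not mortality.has(pop, sex):
                continue
            if not exposure.available(pop, sex, rf) or (
                    spec.type == BEST_PRACTICE
                    and not exposure.available(spec.donors[sex], sex, rf)):
                summaries.append(_nan_summary(pop, sex, spec, "na"))
                continue
            cats = exposure.categories[rf]
            rr_mat = rr.matrix(rf, cats, sex)
            if spec.type == UPWARD_LEVELLING:
                cf = build_upward_levelling(
                    exposure, rr, pop, sex, rf,
                    low_deaths=mortality.deaths_vector(pop, sex, "low"))
                status = "ok"
            else:
                donor = spec.donors[sex]
                cf = build_best_practice(
                    exposure, rr, pop, donor, sex, rf,
                    high_deaths=mortality.deaths_vector(pop, sex, "high"))
                status = "ref" if donor == pop else "ok"

            w = (mortality.standard_weights(pop, sex)
                 if isinstance(weights, str) else validate_weights(weights))
            adj_obs: dict[str, float] = {}
            adj_cf: dict[str, float] = {}
            paf_overall: dict[str, float] = {}
            for edu in EDUCATION_LEVELS:
                cur = exposure.distributions(pop, sex, edu, rf)
                pafs = age_specific_pafs(cur, cf.dist[(pop, sex, edu)], rr_mat)
                deaths = mortality.deaths_vector(pop, sex, edu)
                py = mortality.person_years_vector(pop, sex, edu)
                rate = deaths / py * 100_000.0
                rate_cf = rate * (1.0 - pafs)
                paf_overall[edu] = overall_paf(pafs, deaths) if deaths.sum() > 0 else 0.0
                adj_obs[edu] = age_adjusted_rate(rate, w)
                adj_cf[edu] = age_adjusted_rate(rate_cf, w)
                for a, age in enumerate(AGE_GROUPS):
                    details.append({
                        "population": pop, "sex": sex, "education": edu,
                        "age_group": age, "paf": pafs[a],
                        "deaths": deaths[a], "saved_deaths": pafs[a] * deaths[a],
                        "rate_obs": rate[a], "rate_cf": rate_cf[a]})
                details.append({
                    "population": pop, "sex": sex, "education": edu,
                    "age_group": "30-79", "paf": paf_overall[edu],
                    "deaths": deaths.sum(),
                    "saved_deaths": paf_overall[edu] * deaths.sum(),
                    "rate_obs": adj_obs[edu], "rate_cf": adj_cf[edu]})

            rd_obs, rr_obs = rd_rr(adj_obs["low"], adj_obs["high"])
            rd_cf, rr_cf = rd_rr(adj_cf["low"], adj_cf["high"])
            delta_rd, rel_red = scenario_reductions(rd_obs, rr_obs, rd_cf, rr_cf)
            clamped = bool(cf.clamped.get((pop, sex), False)) and spec.clamp
            row = {"population": pop, "sex": sex, "risk_factor": rf,
                   "scenario": spec.type, "status": status, "clamped": clamped,
                   "donor": spec.donors.get(sex) if spec.donors else None,
                   "paf_low_unclamped": paf_overall["low"],
                   "paf_mid": paf_overall["mid"], "paf_high": paf_overall["high"],
                   "rate_low_obs": adj_obs["low"], "rate_high_obs": adj_obs["high"],
                   "rate_low_cf": adj_cf["low"], "rate_high_cf": adj_cf["high"],
                   "rd_obs": rd_obs, "rr_obs": rr_obs,
                   "rd_cf": rd_cf, "rr_cf": rr_cf,
                   "delta_rd_unclamped": delta_rd,
                   "rel_reduction_pct_unclamped": rel_red}
            if clamped:
                row.update(paf_low=0.0, delta_rd=0.0, rel_reduction_pct=0.0)
            elif spec.type == UPWARD_LEVELLING and spec.clamp:
                # levelling up is defined never to widen inequality
                row.update(paf_low=max(0.0, paf_overall["low"]),
                           delta_rd=max(0.0, delta_rd),
                           rel_reduction_pct=max(0.0, rel_red)
                           if not np.isnan(rel_red) else rel_red)
            else:
                row.update(paf_low=paf_overall["low"], delta_rd=delta_rd,
                           rel_reduction_pct=rel_red)
            summaries.append(row)

    summary = pd.DataFrame(summaries).sort_values(
        ["population", "sex"]).reset_index(drop=True)
    detail = pd.DataFrame(details)
    return ScenarioResult(spec=spec, summary=summary, detail=detail)
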