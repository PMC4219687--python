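"""Shared builders and fixtures: tiny hand-constructed datasets."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from pafineq.data import (AGE_GROUPS, EDUCATION_LEVELS, SEXES, ExposureTable,
                          RelativeRiskTable, StratifiedMortality)

SMOKING_CATS = ["never", "former", "current"]
SMOKING_RR = [1.0, 1.3, 2.0]


def mortality_frame(populations=("A",), deaths=50.0, person_years=100_000.0):
    """Full-grid mortality table with constant cells."""
    rows = [{"population": p, "sex": s, "education": e, "age_group": a,
             "deaths": deaths, "person_years": person_years}
            for p, s, e, a in itertools.product(populations, SEXES,
                                                EDUCATION_LEVELS, AGE_GROUPS)]
    return pd.DataFrame(rows)


def exposure_frame(dists: dict, populations=("A",), risk_factor="smoking",
                   categories=SMOKING_CATS, survey_n=1000):
    """Exposure table from {education: [p_i, ...]}, same across sex/age.

    ``dists`` may also be keyed (population, education) for per-population
    distributions.
    """
    rows = []
    for p, s, e, a in itertools.product(populations, SEXES,
                                        EDUCATION_LEVELS, AGE_GROUPS):
        dist = dists.get((p, e), dists.get(e))
        for cat, prop in zip(categories, dist):
            rows.append({"population": p, "sex": s, "education": e,
                         "age_group": a, "risk_factor": risk_factor,
                         "category": cat, "proportion": prop,
                         "survey_n": survey_n})
    return pd.DataFrame(rows)


def rr_frame(categories=SMOKING_CATS, rrs=SMOKING_RR, risk_factor="smoking"):
    return pd.DataFrame([{"risk_factor": risk_factor, "category": c, "rr": r}
                         for c, r in zip(categories, rrs)])


def build(mort_df, exp_df, rr_df):
    return (StratifiedMortality.from_frame(mort_df),
            ExposureTable.from_frame(exp_df),
            RelativeRiskTable.from_frame(rr_df))


@pytest.fixture
def toy_dataset():
    """One population, a clear smoking gradient (low worse than high)."""
    return build(mortality_frame(),
                 exposure_frame({"low": [0.3, 0.3, 0.4],
                                 "mid": [0.4, 0.3, 0.3],
                                 "high": [0.5, 0.3, 0.2]}),
                 rr_frame())


@pytest.fixture
def reverse_dataset():
    """One population where the low educated are the more favourable group."""
    return build(mortality_frame(),
                 exposure_frame({"low": [0.6, 0.2, 0.2],
                                 "mid": [0.5, 0.25, 0.25],
                                 "high": [0.4, 0.3, 0.3]}),
                 rr_frame())


@pytest.fixture
def uniform_dataset():
    """Exposure identical across education: no inequality anywhere."""
    d = [0.5, 0.3, 0.2]
    return build(mortality_frame(),
                 exposure_frame({"low": d, "mid": d, "high": d}),
                 rr_frame())


def random_distribution(rng: np.random.Generator, k: int) -> np.ndarray:
    p = rng.dirichlet(np.ones(k) * 2.0)
    return p / p.sum()
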