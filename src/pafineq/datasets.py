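"""Bundled reference data.

``european_estimates.csv`` holds published per-population estimates for 21
European populations (early 2000s): the low-educated PAF per risk factor
and sex (in %, with 95% CI) and the reduction of the low-vs-high mortality
rate difference (deaths per 100,000 person-years) under the upward
levelling and best-practice scenarios.  Cells flagged ``na`` had no
survey data; ``ref`` marks the scenario's donor population.  The table is
used to validate median-summary reporting and as a realistic demo input.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .metrics import median_summary

MEASURES = ("paf_pct", "rd_reduction_upward", "rd_reduction_best_practice")


def load_published_estimates() -> pd.DataFrame:
    """Long table: measure, population, risk_factor, sex, value, CI, flag."""
    ref = importlib.resources.files("pafineq") / "datasets" / "european_estimates.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["flag"] = df["flag"].fillna("")
    return df


def published_median(measure: str, risk_factor: str, sex: str,
                     precision: int | None = None,
                     estimates: pd.DataFrame | None = None) -> float:
    """Recompute a summary-row median from the per-population values.

    Excludes na and donor ("ref") cells, matching the published summary
    rows; ``precision`` applies half-up rounding (1 decimal for PAFs,
    integers for rate-difference reductions).
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    df = estimates if estimates is not None else load_published_estimates()
    sub = df[(df["measure"] == measure) & (df["risk_factor"] == risk_factor)
             & (df["sex"] == sex)]
    if sub.empty:
        raise KeyError((measure, risk_factor, sex))
    values = [v if f == "" else f for v, f in zip(sub["value"], sub["flag"])]
    if precision is None:
        precision = 1 if measure == "paf_pct" else 0
    return median_summary(values, precision=precision)
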