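"""statsmodels-style front end: a scenario model fitted to stratified data.

:class:`PAFScenarioModel` bundles the three input tables with a scenario
specification; :meth:`PAFScenarioModel.fit` runs the engine (and,
optionally, the prevalence bootstrap) and returns
:class:`ScenarioResults`, which carries the estimates, their confidence
intervals and a printable summary.

Example
-------
>>> from pafineq import simulate, PAFScenarioModel
>>> mort, exp, rr, truth = simulate.generate(seed=1, noise="none")
>>> res = PAFScenarioModel(mort, exp, rr, scenario="upward_levelling",
...                        risk_factor="smoking").fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSettings, bootstrap_paf
from .data import (SEXES, AnalysisConfig, ExposureTable, RelativeRiskTable,
                   StratifiedMortality, ValidationError)
from .metrics import median_summary, round_half_up
from .scenarios import (BEST_PRACTICE, ScenarioResult, ScenarioSpec,
                        resolve_donors, run_scenario)


class PAFScenarioModel:
    """Counterfactual exposure scenario applied to a stratified dataset.

    Parameters
    ----------
    mortality, exposure, relative_risks
        Validated input tables (see :mod:`pafineq.data`).
    scenario
        ``"upward_levelling"`` or ``"best_practice"`` (or a ready
        :class:`~pafineq.scenarios.ScenarioSpec`).
    risk_factor
        Which risk factor to run; required unless a spec is given.
    weights
        Age-standardisation weights: ``"population"`` (each population's
        own all-education person-years split) or an explicit 4-vector.
    donors
        Optional ``{sex: population}`` override for best practice; missing
        sexes are resolved by donor selection.
    clamp
        Apply the scenarios' zero rules to reported reductions.
    """

    def __init__(self, mortality: StratifiedMortality, exposure: ExposureTable,
                 relative_risks: RelativeRiskTable,
                 scenario: str | ScenarioSpec = "upward_levelling",
                 risk_factor: str | None = None,
                 weights="population", donors: dict | None = None,
                 clamp: bool = True):
        self.mortality = mortality
        self.exposure = exposure
        self.relative_risks = relative_risks
        self.weights = weights
        if isinstance(scenario, ScenarioSpec):
            self.spec = scenario
        else:
            if risk_factor is None:
                raise ValidationError("risk_factor is required")
            if risk_factor not in exposure.risk_factors:
                raise ValidationError(
                    f"unknown risk factor {risk_factor!r}; exposure table has "
                    f"{exposure.risk_factors}")
            sp_donors = {}
            if scenario == BEST_PRACTICE:
                sp_donors = resolve_donors(mortality, exposure, relative_risks,
                                           risk_factor, overrides=donors)
            self.spec = ScenarioSpec(type=scenario, risk_factor=risk_factor,
                                     donors=sp_donors, clamp=clamp)

    @classmethod
    def from_config(cls, config: AnalysisConfig,
                    mortality: StratifiedMortality, exposure: ExposureTable,
                    relative_risks: RelativeRiskTable) -> "PAFScenarioModel":
        return cls(mortality, exposure, relative_risks,
                   scenario=config.scenario, risk_factor=config.risk_factor,
                   weights=config.weights,
                   donors=(config.donors or {}).get(config.risk_factor),
                   clamp=config.clamp)

    def fit(self, bootstrap: BootstrapSettings | int | None = None,
            seed: int | None = None) -> "ScenarioResults":
        """Run the scenario engine; optionally bootstrap the PAF CIs.

        ``bootstrap`` may be a replicate count or full settings; ``seed``
        overrides the settings' seed.
        """
        result = run_scenario(self.mortality, self.exposure,
                              self.relative_risks, self.spec,
                              weights=self.weights)
        cis = None
        if bootstrap is not None:
            if isinstance(bootstrap, int):
                bootstrap = BootstrapSettings(replicates=bootstrap, seed=seed,
                                              clamp=self.spec.clamp)
            elif seed is not None:
                bootstrap = BootstrapSettings(replicates=bootstrap.replicates,
                                              seed=seed, level=bootstrap.level,
                                              clamp=bootstrap.clamp)
            rng = np.random.default_rng(bootstrap.seed)
            rows = []
            for _, row in result.summary.iterrows():
                if row["status"] == "na":
                    rows.append({"population": row["population"],
                                 "sex": row["sex"], "paf_low": np.nan,
                                 "ci_lower": np.nan, "ci_upper": np.nan})
                    continue
                ci = bootstrap_paf(self.mortality, self.exposure,
                                   self.relative_risks, row["population"],
                                   row["sex"], self.spec, bootstrap, rng=rng)
                rows.append({"population": row["population"],
                             "sex": row["sex"], "paf_low": ci.point,
                             "ci_lower": ci.lower, "ci_upper": ci.upper})
            cis = pd.DataFrame(rows)
        return ScenarioResults(self, result, cis)


class ScenarioResults:
    """Fitted scenario: estimates, uncertainties and report tables."""

    def __init__(self, model: PAFScenarioModel, result: ScenarioResult,
                 conf_int_frame: pd.DataFrame | None):
        self.model = model
        self.spec = result.spec
        self.result = result
        self._ci = conf_int_frame

    @property
    def summary_frame(self) -> pd.DataFrame:
        """Per population x sex estimates (see ScenarioResult.summary)."""
        return self.result.summary

    @property
    def detail_frame(self) -> pd.DataFrame:
        return self.result.detail

    def conf_int(self) -> pd.DataFrame:
        if self._ci is None:
            raise ValidationError("fit with bootstrap=... to get intervals")
        return self._ci

    def median_row(self, column: str = "paf_low", sex: str | None = None,
                   precision: int | None = None) -> dict | float:
        """Median over populations, excluding na and donor (ref) rows."""
        s = self.result.summary
        out = {}
        for sx in SEXES if sex is None else [sex]:
            sub = s[(s["sex"] == sx) & (s["status"] == "ok")]
            out[sx] = median_summary(sub[column], precision=precision)
        return out if sex is None else out[sex]

    def summary(self, precision: int = 1) -> str:
        """Human-readable results table."""
        s = self.result.summary.copy()
        head = [f"Scenario: {self.spec.type}", f"Risk factor: {self.spec.risk_factor}"]
        if self.spec.donors:
            head.append("Donor populations: "
                        + ", ".join(f"{sx}: {d}" for sx, d in self.spec.donors.items()))
        cols = {"population": s["population"], "sex": s["sex"],
                "status": s["status"]}
        paf = s["paf_low"] * 100
        cols["PAF_low_%"] = paf.map(lambda v: "na" if pd.isna(v)
                                    else f"{round_half_up(v, precision):.{precision}f}")
        if self._ci is not None:
            merged = s.merge(self._ci, on=["population", "sex"],
                             suffixes=("", "_b"))
            cols["95%_CI"] = [
                "na" if pd.isna(lo) else
                f"({round_half_up(lo * 100, precision):.{precision}f}-"
                f"{round_half_up(hi * 100, precision):.{precision}f})"
                for lo, hi in zip(merged["ci_lower"], merged["ci_upper"])]
        cols["dRD_per_100k"] = s["delta_rd"].map(
            lambda v: "na" if pd.isna(v) else f"{round_half_up(v, 0):.0f}")
        cols["rel_red_%"] = s["rel_reduction_pct"].map(
            lambda v: "na" if pd.isna(v) else f"{round_half_up(v, 1):.1f}")
        cols["clamped"] = s["clamped"].map({True: "0*", False: ""})
        table = pd.DataFrame(cols)
        med = self.median_row("paf_low")
        foot = ("All (median PAF_low_%): "
                + ", ".join(f"{sx}: "
                            + ("na" if pd.isna(v) else f"{round_half_up(v * 100, precision):.{precision}f}")
                            for sx, v in med.items()))
        return "\n".join(head + ["", table.to_string(index=False), "", foot,
                                 "0*: zero by scenario convention "
                                 "(reverse gradient / unfavourable donor)"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ScenarioResults {self.spec.type} {self.spec.risk_factor} "
                f"({len(self.result.summary)} population-sex rows)>")
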