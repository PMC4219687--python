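"""Stratified data model and CSV I/O.

All analyses run on three tidy tables:

* mortality — deaths and person-years per population x sex x education x
  age-group cell (registry data, treated as fixed);
* exposure — risk-factor category proportions per cell plus the survey
  sample size they were estimated from;
* relative risks — the multiplicative effect of each exposure category on
  all-cause mortality, optionally sex- and/or age-specific.

Education is collapsed to the three ISCED-derived levels (low / mid / high)
and adult ages to four bands covering 30-79.  Validation is strict: any
malformed row is reported with its stratum key, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

SEXES: tuple[str, ...] = ("men", "women")
EDUCATION_LEVELS: tuple[str, ...] = ("low", "mid", "high")
AGE_GROUPS: tuple[str, ...] = ("30-44", "45-59", "60-69", "70-79")

#: tolerance for category proportions summing to 1 (survey tables are rounded)
PROPORTION_TOL = 1e-6


class SchemaError(ValueError):
    """A table is missing columns or uses unknown stratum labels."""


class ValidationError(ValueError):
    """A table is structurally fine but violates a domain invariant."""


def _normalise_age(label: str) -> str:
    # accept en-dash variants as printed in publications
    return str(label).replace("–", "-").replace("—", "-").strip()


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def _check_labels(df: pd.DataFrame, what: str) -> None:
    for col, allowed in (("sex", SEXES), ("education", EDUCATION_LEVELS),
                         ("age_group", AGE_GROUPS)):
        bad = df.loc[~df[col].isin(allowed)]
        if not bad.empty:
            row = bad.iloc[0]
            raise SchemaError(
                f"{what}: unknown {col} label {row[col]!r} in row "
                f"{dict(row[['population', 'sex', 'education', 'age_group']])}"
            )


@dataclasses.dataclass(frozen=True)
class StratifiedMortality:
    """Deaths and person-years per population x sex x education x age cell.

    Every (population, sex) present must carry the full 3 education x 4 age
    grid; partially observed strata are rejected so downstream aggregation
    never mixes observed and missing cells.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StratifiedMortality":
        _require_columns(df, ("population", "sex", "education", "age_group",
                              "deaths", "person_years"), "mortality")
        df = df.copy()
        df["age_group"] = df["age_group"].map(_normalise_age)
        _check_labels(df, "mortality")
        df["deaths"] = pd.to_numeric(df["deaths"])
        df["person_years"] = pd.to_numeric(df["person_years"])
        key = ["population", "sex", "education", "age_group"]
        dup = df.duplicated(subset=key)
        if dup.any():
            raise ValidationError(
                f"mortality: duplicate stratum {dict(df.loc[dup.idxmax(), key])}")
        for _, row in df.iterrows():
            k = dict(row[key])
            if row["deaths"] < 0:
                raise ValidationError(f"mortality: negative deaths in {k}")
            if row["person_years"] <= 0:
                raise ValidationError(f"mortality: non-positive person_years in {k}")
            if row["deaths"] > row["person_years"]:
                raise ValidationError(
                    f"mortality: deaths exceed person_years in {k}")
        # full grid per (population, sex)
        expect = len(EDUCATION_LEVELS) * len(AGE_GROUPS)
        counts = df.groupby(["population", "sex"]).size()
        short = counts[counts != expect]
        if not short.empty:
            raise ValidationError(
                f"mortality: incomplete education x age grid for "
                f"{list(short.index)} (expected {expect} cells each)")
        df = df.sort_values(key).reset_index(drop=True)
        return cls(df)

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def rates(self, per: float = 100_000.0) -> pd.DataFrame:
        """Return the table with a mortality ``rate`` column (per `per` py)."""
        out = self.data.copy()
        out["rate"] = out["deaths"] / out["person_years"] * per
        return out

    def _slice(self, population: str, sex: str, education: str) -> pd.DataFrame:
        d = self.data
        sub = d[(d["population"] == population) & (d["sex"] == sex)
                & (d["education"] == education)]
        return sub.set_index("age_group").loc[list(AGE_GROUPS)]

    def deaths_vector(self, population: str, sex: str, education: str) -> np.ndarray:
        """Deaths over the four age groups, in age order."""
        return self._slice(population, sex, education)["deaths"].to_numpy(float)

    def person_years_vector(self, population: str, sex: str,
                            education: str) -> np.ndarray:
        return self._slice(population, sex, education)["person_years"].to_numpy(float)

    def rate_vector(self, population: str, sex: str, education: str,
                    per: float = 100_000.0) -> np.ndarray:
        s = self._slice(population, sex, education)
        return (s["deaths"] / s["person_years"] * per).to_numpy(float)

    def standard_weights(self, population: str, sex: str) -> np.ndarray:
        """All-education person-years share per age group (default standard)."""
        d = self.data
        sub = d[(d["population"] == population) & (d["sex"] == sex)]
        py = sub.groupby("age_group")["person_years"].sum().loc[list(AGE_GROUPS)]
        w = py.to_numpy(float)
        return w / w.sum()

    def has(self, population: str, sex: str) -> bool:
        d = self.data
        return bool(((d["population"] == population) & (d["sex"] == sex)).any())

    def to_csv(self, path, header_lines: Iterable[str] = ()) -> None:
        _write_csv(self.data, path, header_lines)


@dataclasses.dataclass(frozen=True)
class ExposureTable:
    """Risk-factor category proportions (and survey n) per stratum.

    ``categories`` maps each risk factor to its ordered category labels,
    reference category first.  Missingness is recorded at the
    population x sex x risk-factor level: a stratum is either fully present
    (all education x age x category rows) or entirely absent ("na" in
    reports); partial strata are rejected.
    """

    data: pd.DataFrame
    categories: dict[str, list[str]]
    _dist: dict = dataclasses.field(default_factory=dict, repr=False, compare=False)
    _n: dict = dataclasses.field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExposureTable":
        _require_columns(df, ("population", "sex", "education", "age_group",
                              "risk_factor", "category", "proportion",
                              "survey_n"), "exposure")
        df = df.copy()
        df["age_group"] = df["age_group"].map(_normalise_age)
        _check_labels(df, "exposure")
        df["proportion"] = pd.to_numeric(df["proportion"])
        df["survey_n"] = pd.to_numeric(df["survey_n"])
        if (df["proportion"] < -PROPORTION_TOL).any() or (df["proportion"] > 1 + PROPORTION_TOL).any():
            bad = df[(df["proportion"] < -PROPORTION_TOL)
                     | (df["proportion"] > 1 + PROPORTION_TOL)].iloc[0]
            raise ValidationError(f"exposure: proportion outside [0, 1] in "
                                  f"{dict(bad[['population', 'sex', 'education', 'age_group', 'risk_factor', 'category']])}")
        if df["survey_n"].isna().any():
            bad = df[df["survey_n"].isna()].iloc[0]
            raise ValidationError(
                f"exposure: missing survey_n for "
                f"{dict(bad[['population', 'sex', 'education', 'age_group', 'risk_factor']])};"
                f" supply the survey sample size (or a conservative default)")
        if (df["survey_n"] < 2).any():
            bad = df[df["survey_n"] < 2].iloc[0]
            raise ValidationError(
                f"exposure: survey_n < 2 for "
                f"{dict(bad[['population', 'sex', 'education', 'age_group', 'risk_factor']])}")

        # category order: first appearance per risk factor; reference first
        categories: dict[str, list[str]] = {}
        for rf, sub in df.groupby("risk_factor", sort=False):
            seen: list[str] = []
            for c in sub["category"]:
                if c not in seen:
                    seen.append(c)
            if len(seen) < 2:
                raise ValidationError(
                    f"exposure: risk factor {rf!r} has fewer than 2 categories")
            categories[str(rf)] = seen

        strat = ["population", "sex", "education", "age_group", "risk_factor"]
        sums = df.groupby(strat)["proportion"].sum()
        off = sums[(sums - 1.0).abs() > PROPORTION_TOL]
        if not off.empty:
            raise ValidationError(
                f"exposure: proportions sum to {off.iloc[0]:.6f} (not 1) in "
                f"stratum {dict(zip(strat, off.index[0]))}")
        # renormalise to exactly 1 after validation
        df["proportion"] = df["proportion"] / df.groupby(strat)["proportion"].transform("sum")

        # completeness per (population, sex, risk_factor): all edu x age x cat
        for (pop, sex, rf), sub in df.groupby(["population", "sex", "risk_factor"]):
            cats = categories[rf]
            expect = len(EDUCATION_LEVELS) * len(AGE_GROUPS) * len(cats)
            if len(sub) != expect:
                raise ValidationError(
                    f"exposure: partial stratum for ({pop!r}, {sex!r}, {rf!r}):"
                    f" {len(sub)} rows, expected {expect}; drop it entirely to"
                    f" mark it na")
            if sub.duplicated(subset=["education", "age_group", "category"]).any():
                raise ValidationError(
                    f"exposure: duplicate category rows in ({pop!r}, {sex!r}, {rf!r})")

        df = df.reset_index(drop=True)
        obj = cls(df, categories)
        obj._build_cache()
        return obj

    def _build_cache(self) -> None:
        for (pop, sex, edu, rf), sub in self.data.groupby(
                ["population", "sex", "education", "risk_factor"]):
            cats = self.categories[rf]
            pivot = sub.pivot(index="age_group", columns="category",
                              values="proportion")
            pivot = pivot.loc[list(AGE_GROUPS), cats]
            self._dist[(pop, sex, edu, rf)] = pivot.to_numpy(float)
            n = sub.pivot_table(index="age_group", values="survey_n",
                                aggfunc="first").loc[list(AGE_GROUPS), "survey_n"]
            self._n[(pop, sex, edu, rf)] = n.to_numpy(float)

    @property
    def risk_factors(self) -> list[str]:
        return list(self.categories)

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def reference(self, risk_factor: str) -> str:
        return self.categories[risk_factor][0]

    def available(self, population: str, sex: str, risk_factor: str) -> bool:
        return (population, sex, "high", risk_factor) in self._dist

    def distributions(self, population: str, sex: str, education: str,
                      risk_factor: str) -> np.ndarray:
        """(4, k) array of category proportions over age groups."""
        try:
            return self._dist[(population, sex, education, risk_factor)]
        except KeyError:
            raise KeyError(
                f"exposure not available for ({population!r}, {sex!r}, "
                f"{education!r}, {risk_factor!r})") from None

    def survey_n(self, population: str, sex: str, education: str,
                 risk_factor: str) -> np.ndarray:
        """Survey sample size per age group for one stratum."""
        return self._n[(population, sex, education, risk_factor)]

    def to_csv(self, path, header_lines: Iterable[str] = ()) -> None:
        _write_csv(self.data, path, header_lines)


@dataclasses.dataclass(frozen=True)
class RelativeRiskTable:
    """Relative mortality risk per exposure category.

    Rows without a sex or age_group broadcast to all sexes / age groups
    (meta-analytic RRs come at varying granularity); the most specific
    matching row wins.  The first category listed per factor is the
    reference and must carry RR exactly 1.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RelativeRiskTable":
        _require_columns(df, ("risk_factor", "category", "rr"), "relative risk")
        df = df.copy()
        for opt in ("sex", "age_group"):
            if opt not in df.columns:
                df[opt] = pd.NA
        df["age_group"] = df["age_group"].map(
            lambda v: _normalise_age(v) if pd.notna(v) and str(v).strip() != "" else pd.NA)
        df["sex"] = df["sex"].map(
            lambda v: v if pd.notna(v) and str(v).strip() != "" else pd.NA)
        bad_sex = df["sex"].dropna()[~df["sex"].dropna().isin(SEXES)]
        if not bad_sex.empty:
            raise SchemaError(f"relative risk: unknown sex {bad_sex.iloc[0]!r}")
        bad_age = df["age_group"].dropna()[~df["age_group"].dropna().isin(AGE_GROUPS)]
        if not bad_age.empty:
            raise SchemaError(f"relative risk: unknown age_group {bad_age.iloc[0]!r}")
        df["rr"] = pd.to_numeric(df["rr"])
        if not np.isfinite(df["rr"]).all() or (df["rr"] <= 0).any():
            bad = df[~np.isfinite(df["rr"]) | (df["rr"] <= 0)].iloc[0]
            raise ValidationError(
                f"relative risk: rr must be finite and > 0, got {bad['rr']!r} "
                f"for ({bad['risk_factor']!r}, {bad['category']!r})")
        key = ["risk_factor", "category", "sex", "age_group"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key)].iloc[0]
            raise ValidationError(f"relative risk: duplicate row {dict(dup[key])}")
        # reference category = first listed per factor; RR forced to exactly 1
        for rf, sub in df.groupby("risk_factor", sort=False):
            ref = sub["category"].iloc[0]
            rows = (df["risk_factor"] == rf) & (df["category"] == ref)
            if (df.loc[rows, "rr"] - 1.0).abs().max() > 1e-9:
                raise ValidationError(
                    f"relative risk: reference category {ref!r} of {rf!r} "
                    f"must have rr = 1")
            df.loc[rows, "rr"] = 1.0
        return cls(df.reset_index(drop=True))

    def reference(self, risk_factor: str) -> str:
        sub = self.data[self.data["risk_factor"] == risk_factor]
        if sub.empty:
            raise KeyError(f"no relative risks for {risk_factor!r}")
        return sub["category"].iloc[0]

    def lookup(self, risk_factor: str, category: str, sex: str,
               age_group: str) -> float:
        d = self.data
        cand = d[(d["risk_factor"] == risk_factor) & (d["category"] == category)
                 & (d["sex"].isna() | (d["sex"] == sex))
                 & (d["age_group"].isna() | (d["age_group"] == age_group))]
        if cand.empty:
            raise KeyError(f"no relative risk for ({risk_factor!r}, "
                           f"{category!r}, {sex!r}, {age_group!r})")
        spec = cand["sex"].notna().astype(int) + cand["age_group"].notna().astype(int)
        best = cand[spec == spec.max()]
        if len(best) > 1 and best["rr"].nunique() > 1:
            raise ValidationError(
                f"relative risk: ambiguous broadcast for ({risk_factor!r}, "
                f"{category!r}, {sex!r}, {age_group!r})")
        return float(best["rr"].iloc[0])

    def matrix(self, risk_factor: str, categories: list[str],
               sex: str) -> np.ndarray:
        """(4, k) RR array over age groups x given category order."""
        out = np.empty((len(AGE_GROUPS), len(categories)))
        for a, age in enumerate(AGE_GROUPS):
            for i, cat in enumerate(categories):
                out[a, i] = self.lookup(risk_factor, cat, sex, age)
        return out

    def to_csv(self, path, header_lines: Iterable[str] = ()) -> None:
        _write_csv(self.data, path, header_lines)


@dataclasses.dataclass
class CounterfactualExposure:
    """Counterfactual category proportions P' per stratum.

    ``dist`` maps (population, sex, education) to a (4, k) array over age
    groups; ``clamped`` flags population x sex pairs where the scenario's
    zero rule fired (the reported inequality reduction is then exactly 0);
    ``missing`` collects population x sex pairs with no usable exposure.
    """

    risk_factor: str
    scenario: str
    dist: dict
    clamped: dict
    missing: set
    donors: Mapping[str, str] | None = None


@dataclasses.dataclass
class AnalysisConfig:
    """Run configuration (YAML-serialisable)."""

    scenario: str = "upward_levelling"
    risk_factor: str | None = None
    bootstrap_b: int = 1000
    seed: int = 0
    weights: str | list[float] = "population"
    precision: int = 1
    clamp: bool = True
    donors: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bootstrap_b < 1:
            raise ValidationError("bootstrap.B must be >= 1")
        if isinstance(self.weights, (list, tuple)):
            w = np.asarray(self.weights, float)
            if len(w) != len(AGE_GROUPS) or abs(w.sum() - 1) > 1e-9 or (w < 0).any():
                raise ValidationError(
                    "standardisation.weights must be 4 nonnegative values summing to 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        boot = raw.get("bootstrap", {}) or {}
        std = raw.get("standardisation", {}) or {}
        rep = raw.get("report", {}) or {}
        return cls(
            scenario=raw.get("scenario", "upward_levelling"),
            risk_factor=raw.get("risk_factor"),
            bootstrap_b=int(boot.get("B", 1000)),
            seed=int(boot.get("seed", 0)),
            weights=std.get("weights", "population"),
            precision=int(rep.get("precision", 1)),
            clamp=bool(raw.get("clamp", True)),
            donors=raw.get("donors", {}) or {},
        )

    def to_yaml(self, path) -> None:
        raw = {
            "scenario": self.scenario,
            "risk_factor": self.risk_factor,
            "bootstrap": {"B": self.bootstrap_b, "seed": self.seed},
            "standardisation": {"weights": self.weights},
            "report": {"precision": self.precision},
            "clamp": self.clamp,
            "donors": self.donors,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _write_csv(df: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_mortality(path) -> StratifiedMortality:
    """Read a tidy mortality CSV (see :class:`StratifiedMortality`)."""
    return StratifiedMortality.from_frame(_read_csv(path))


def load_exposure(path) -> ExposureTable:
    """Read a tidy exposure CSV (see :class:`ExposureTable`)."""
    return ExposureTable.from_frame(_read_csv(path))


def load_relative_risks(path) -> RelativeRiskTable:
    """Read a relative-risk CSV (see :class:`RelativeRiskTable`)."""
    return RelativeRiskTable.from_frame(_read_csv(path))
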