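"""Report rendering: publication-shaped tables and run manifests.

Reports are wide tables with one row per population, one column per risk
factor x sex, a final "All" median row (excluding na and donor cells), an
impact band per cell, and the table conventions: "na" for unavailable
data, "ref" for the donor population, and "0*" for reductions forced to
zero by a scenario's clamp rule.  Machine-readable flags live in a
parallel long table; every output file starts with a comment header
carrying the run manifest (config hash, seed, input checksums, version).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math

import pandas as pd

from . import __version__
from .data import SEXES, AnalysisConfig, _write_csv
from .metrics import band, median_summary, round_half_up
from .scenarios import ScenarioResult


@dataclasses.dataclass
class RunManifest:
    """Provenance header: identical manifests imply identical outputs."""

    config_hash: str
    seed: int | None
    input_checksums: dict
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(cls, config: AnalysisConfig | dict | None = None,
               seed: int | None = None,
               input_paths: dict | None = None) -> "RunManifest":
        cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) \
            else (config or {})
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        sums = {}
        for name, path in (input_paths or {}).items():
            with open(path, "rb") as fh:
                sums[name] = hashlib.sha256(fh.read()).hexdigest()[:16]
        return cls(config_hash=hashlib.sha256(blob).hexdigest()[:16],
                   seed=seed, input_checksums=sums,
                   timestamp=datetime.datetime.now(datetime.timezone.utc)
                   .strftime("%Y-%m-%dT%H:%M:%SZ"))

    def header_lines(self) -> list[str]:
        lines = [f"pafineq {self.version}",
                 f"config sha256:{self.config_hash} seed:{self.seed}"]
        lines += [f"input {n} sha256:{c}" for n, c in self.input_checksums.items()]
        lines.append(f"written {self.timestamp}")
        return lines


def format_cell(value: float, status: str = "ok", clamped: bool = False,
                precision: int = 0) -> str:
    """One report cell: value at report precision, or na / ref / 0*."""
    if status == "na" or (isinstance(value, float) and math.isnan(value)):
        return "na"
    if status == "ref":
        return "ref"
    if clamped:
        return "0*"
    v = round_half_up(value, precision)
    return f"{v:.{precision}f}"


def scenario_table(results: dict[str, ScenarioResult], value: str = "paf",
                   precision: int | None = None) -> pd.DataFrame:
    """Wide report from one or more fitted risk factors.

    ``results`` maps risk-factor name to a :class:`ScenarioResult`;
    ``value`` is ``"paf"`` (low-educated overall PAF in %, banded at 3/10)
    or ``"rd_reduction"`` (drop in the low-vs-high rate difference in
    deaths per 100,000 person-years, banded at 20/80).  Rows are
    populations plus a final ``All`` median row.
    """
    if value not in ("paf", "rd_reduction"):
        raise ValueError("value must be 'paf' or 'rd_reduction'")
    col, scale = ("paf_low", 100.0) if value == "paf" else ("delta_rd", 1.0)
    if precision is None:
        precision = 1 if value == "paf" else 0

    populations: list[str] = []
    for res in results.values():
        for p in res.summary["population"]:
            if p not in populations:
                populations.append(p)
    populations.sort()

    out = pd.DataFrame({"population": populations + ["All"]})
    for rf, res in results.items():
        s = res.summary
        for sex in SEXES:
            cells, med_input = [], []
            for pop in populations:
                row = s[(s["population"] == pop) & (s["sex"] == sex)]
                if row.empty:
                    cells.append("na")
                    continue
                row = row.iloc[0]
                v = row[col] * scale
                cells.append(format_cell(v, row["status"], row["clamped"],
                                         precision))
                if row["status"] == "ok":
                    med_input.append(0.0 if row["clamped"] else v)
            med = median_summary(med_input, precision=precision)
            cells.append("na" if math.isnan(med) else f"{med:.{precision}f}")
            out[f"{rf}_{sex}"] = cells
    return out


def results_long(results: dict[str, ScenarioResult]) -> pd.DataFrame:
    """Machine-readable long table with explicit status/clamp flags."""
    frames = [res.summary.assign(risk_factor=rf) for rf, res in results.items()]
    return pd.concat(frames, ignore_index=True)


def band_table(table: pd.DataFrame, value: str = "paf") -> pd.DataFrame:
    """Impact band per cell of a :func:`scenario_table` output."""
    kind = "paf" if value == "paf" else "rd_reduction"
    out = table.copy()
    for c in out.columns:
        if c == "population":
            continue
        out[c] = [band(float(v), kind) if v not in ("na", "ref")
                  else v for v in ("0" if x == "0*" else x for x in out[c])]
    return out


def render_markdown(table: pd.DataFrame) -> str:
    """GitHub-style markdown for a wide report table."""
    cols = list(table.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def write_table(table: pd.DataFrame, path,
                manifest: RunManifest | None = None) -> None:
    """CSV with the manifest as a comment header."""
    _write_csv(table, path, manifest.header_lines() if manifest else ())
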