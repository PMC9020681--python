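"""Result tables and reproducibility metadata.

The base-case table mirrors the published layout: one column of absolute
values per arm plus incremental columns versus the reference, costs rounded
to the nearest euro with thousands separators, health outcomes to two
decimals.  Machine-readable exports are plain floats.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from .engine import ArmResult, Incremental, compare_arms

__all__ = ["base_case_table", "format_base_case_table", "scenario_table",
           "RunManifest"]

_COST_ROWS = ("drug_acquisition", "drug_administration", "event_management",
              "total_costs")
_ROW_LABELS = {
    "drug_acquisition": "Drug acquisition costs",
    "drug_administration": "Drug administration costs",
    "event_management": "Clinical event management costs",
    "total_costs": "Total costs",
    "total_qalys": "Total QALYs",
    "total_ly": "Total LY",
    "ischaemic_strokes": "Ischaemic strokes",
    "myocardial_infarctions": "Myocardial infarctions",
    "ich": "ICH",
    "gi_bleeding": "GI bleeding",
    "icer_qaly": "Incremental cost/QALY",
    "icer_lyg": "Incremental cost/LYG",
}


def _values(r: ArmResult) -> dict[str, float]:
    return {
        "drug_acquisition": r.drug_cost,
        "drug_administration": r.admin_cost,
        "event_management": r.event_cost,
        "total_costs": r.total_cost,
        "total_qalys": r.qalys,
        "total_ly": r.life_years,
        "ischaemic_strokes": r.events.get("is", 0.0),
        "myocardial_infarctions": r.events.get("mi", 0.0),
        "ich": r.events.get("ich", 0.0),
        "gi_bleeding": r.events.get("gi", 0.0),
    }


def base_case_table(results: Mapping[str, ArmResult],
                    reference: str = "vka") -> pd.DataFrame:
    """Tidy base-case results: absolute and incremental outcomes per arm.

    Columns are ``<arm>`` for absolute values and ``<arm>_incr`` for the
    increment versus the reference; ICER rows are only filled for comparators.
    """
    if reference not in results:
        raise KeyError(f"reference arm {reference!r} not in results "
                       f"({list(results)})")
    ref = results[reference]
    ref_vals = _values(ref)
    rows = list(ref_vals) + ["icer_qaly", "icer_lyg"]
    table = pd.DataFrame(index=rows)
    table[reference] = [ref_vals.get(r) for r in rows]
    for arm, res in results.items():
        if arm == reference:
            continue
        vals = _values(res)
        inc: Incremental = compare_arms(ref, res)
        table[arm] = [vals.get(r) for r in rows]
        incr = {r: vals[r] - ref_vals[r] for r in ref_vals}
        incr["icer_qaly"] = inc.icer_qaly
        incr["icer_lyg"] = inc.icer_lyg
        table[f"{arm}_incr"] = [incr.get(r) for r in rows]
    return table


def format_base_case_table(table: pd.DataFrame) -> str:
    """Printed layout: euros to the nearest unit, health outcomes to 2 dp."""
    out = table.copy().astype(object)
    health_rows = {"total_qalys", "total_ly", "ischaemic_strokes",
                   "myocardial_infarctions", "ich", "gi_bleeding"}
    for row in out.index:
        for col in out.columns:
            v = table.loc[row, col]
            if v is None or pd.isna(v):
                out.loc[row, col] = ""
            elif row in health_rows:
                out.loc[row, col] = f"{v:.2f}"
            else:
                out.loc[row, col] = f"{v:,.0f}"
    out.index = [_ROW_LABELS[r] for r in out.index]
    return out.to_string()


def scenario_table(scenario_results: Mapping[str, "ScenarioResult"]) -> pd.DataFrame:
    """Scenario x arm table of ICERs per QALY (euros)."""
    rows = {}
    for name, sr in scenario_results.items():
        rows[name] = {arm: inc.icer_qaly for arm, inc in sr.incrementals.items()}
    return pd.DataFrame(rows).T


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written beside every result file."""

    command: str
    config_path: str
    config_sha256: str
    life_table_path: str
    life_table_sha256: str
    seed: int | None
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config_path, life_table_path,
               seed: int | None = None) -> "RunManifest":
        from . import __version__
        return cls(
            command=command,
            config_path=str(config_path),
            config_sha256=_sha256(config_path),
            life_table_path=str(life_table_path),
            life_table_sha256=_sha256(life_table_path),
            seed=seed,
            package_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
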