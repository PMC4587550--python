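"""Result serialization and run manifests.

Tabular results go to CSV, summaries to JSON, and every output directory
gets a manifest recording the configuration hash, seed and scenario names
so each file set is traceable to exactly one run.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .budget import BudgetProjection
from .cea import CEAResult, PSAResult, TornadoResult
from .parameters import ParameterSet, params_to_csv
from .pathway import CohortTable

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "config_hash", "write_results", "read_records", "write_records"]

_MONEY_FMT = "%.2f"
_COUNT_FMT = "%.1f"


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    n_iter: int | None
    scenario_names: list[str]
    package_version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def config_hash(params: ParameterSet) -> str:
    """Stable digest of a parameter set (flat-CSV canonical form)."""
    csv_text = params_to_csv(params).to_csv(index=False)
    return hashlib.sha256(csv_text.encode()).hexdigest()[:16]


def _round_money(df: pd.DataFrame) -> pd.DataFrame:
    return df


def write_results(result, out_dir, manifest: RunManifest | None = None) -> list[Path]:
    """Serialize any result object; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, CohortTable):
        path = out / f"cohort_{result.scenario}.csv"
        result.summary_frame().to_csv(path, index=False, float_format=_COUNT_FMT)
        written.append(path)
        full = out / f"cohort_{result.scenario}_full.csv"
        result.to_frame().to_csv(full, index=False, float_format=_COUNT_FMT)
        written.append(full)
        totals = out / f"cohort_{result.scenario}_totals.json"
        totals.write_text(json.dumps(
            {k: round(v, 3) for k, v in result.totals().items()}, indent=2) + "\n")
        written.append(totals)
    elif isinstance(result, CEAResult):
        path = out / "cea_summary.json"
        path.write_text(json.dumps(result.as_dict(), indent=2) + "\n")
        written.append(path)
    elif isinstance(result, PSAResult):
        draws = out / "draws.csv"
        result.draws_frame().to_csv(draws, index=False, float_format="%.6g")
        written.append(draws)
        ceac = out / "ceac.csv"
        result.ceac.to_csv(ceac, index=False, float_format="%.6g")
        written.append(ceac)
        summary = out / "psa_summary.json"
        summary.write_text(json.dumps({
            "n_iter": result.n_iter,
            "seed": result.seed,
            "median_icer": result.median,
            "cri_low": result.cri_low,
            "cri_high": result.cri_high,
            "n_cost_saving": result.n_cost_saving,
            "n_dominated": result.n_dominated,
        }, indent=2) + "\n")
        written.append(summary)
    elif isinstance(result, TornadoResult):
        path = out / "tornado.csv"
        result.rows.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        summary = out / "tornado_summary.json"
        summary.write_text(json.dumps(
            {"baseline_icer": result.baseline_icer}, indent=2) + "\n")
        written.append(summary)
    elif isinstance(result, BudgetProjection):
        path = out / "budget.csv"
        result.rows.to_csv(path, index=False, float_format=_MONEY_FMT)
        written.append(path)
    elif isinstance(result, pd.DataFrame):
        path = out / "records.csv"
        result.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    elif isinstance(result, list) and all(isinstance(r, CEAResult) for r in result):
        path = out / "scenario_cea.json"
        path.write_text(json.dumps([r.as_dict() for r in result], indent=2) + "\n")
        written.append(path)
    else:
        raise TypeError(f"no writer for result type {type(result).__name__}")

    if manifest is not None:
        written.append(manifest.write(out))
    for path in written:
        logger.info("wrote %s", path)
    return written


def write_records(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False, float_format="%.6g")
    return path


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)
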