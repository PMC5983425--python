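"""Tabular output writers and the run manifest.

CSVs are the authoritative numerical outputs; each JSON mirror carries the
full-precision values plus euro-truncated display values. A manifest is
written alongside every output set so a run can be reproduced
bit-identically for the deterministic analyses.
"""

from __future__ import annotations

import datetime as _dt
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable

import pandas as pd

from .microsim import CohortSummary, PatientRecord, cohort_frame
from .psa import PSAResult
from .sensitivity import SweepPoint, TornadoEntry
from .tree import IncrementalResult, StrategyResult, floor_eur

__all__ = [
    "package_version",
    "write_manifest",
    "strategy_frame",
    "write_strategies",
    "incremental_dict",
    "write_incremental",
    "sweep_frame",
    "write_sweep",
    "tornado_frame",
    "write_tornado",
    "write_psa",
    "write_patients",
]


def package_version() -> str:
    try:
        return version("ifmiecon")
    except PackageNotFoundError:  # running from a source tree
        return "0+unknown"


def write_manifest(
    out_dir: Path,
    subcommand: str,
    config: str | None,
    seed: int,
    n_draws: int | None,
    extra: dict | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": str(config) if config else None,
        "seed": seed,
        "n_draws": n_draws,
        "output_dir": str(out_dir),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "package_version": package_version(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path


def strategy_frame(results: Iterable[StrategyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strategy": r.strategy,
            "expected_surgeries": r.expected_surgeries,
            "expected_cost_eur": r.expected_cost_eur,
            "expected_cost_exact": r.expected_cost,
        }
        for r in results
    )


def write_strategies(results: Iterable[StrategyResult], out_dir: Path) -> Path:
    path = Path(out_dir) / "strategies.csv"
    strategy_frame(results).to_csv(path, index=False)
    return path


def incremental_dict(res: IncrementalResult) -> dict:
    d = {
        "delta_surgeries": res.delta_surgeries,
        "delta_cost": res.delta_cost,
        "delta_cost_eur": int(round(res.delta_cost)),
    }
    if res.ci_surgeries is not None:
        d["ci_surgeries"] = list(res.ci_surgeries)
    if res.ci_cost is not None:
        d["ci_cost"] = list(res.ci_cost)
    if res.n_draws is not None:
        d["n_draws"] = res.n_draws
    if res.seed is not None:
        d["seed"] = res.seed
    return d


def write_incremental(res: IncrementalResult, out_dir: Path, name: str = "incremental.json") -> Path:
    path = Path(out_dir) / name
    path.write_text(json.dumps(incremental_dict(res), indent=2) + "\n", encoding="utf-8")
    return path


def sweep_frame(sweep: Iterable[SweepPoint]) -> pd.DataFrame:
    rows = []
    for p in sweep:
        row = {
            "rr": p.rr,
            "delta_surgeries": p.delta_surgeries,
            "delta_cost": p.delta_cost,
        }
        if p.ci_surgeries is not None:
            row["ci_surgeries_low"], row["ci_surgeries_high"] = p.ci_surgeries
        if p.ci_cost is not None:
            row["ci_cost_low"], row["ci_cost_high"] = p.ci_cost
        rows.append(row)
    return pd.DataFrame(rows)


def write_sweep(sweep: Iterable[SweepPoint], out_dir: Path) -> Path:
    path = Path(out_dir) / "sweep.csv"
    sweep_frame(sweep).to_csv(path, index=False)
    return path


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": e.parameter,
            "low_input": e.low_input,
            "high_input": e.high_input,
            "low_result": e.low_result,
            "high_result": e.high_result,
            "range": e.range,
        }
        for e in entries
    )


def write_tornado(entries: Iterable[TornadoEntry], out_dir: Path) -> Path:
    path = Path(out_dir) / "tornado.csv"
    tornado_frame(entries).to_csv(path, index=False)
    return path


def write_psa(res: PSAResult, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    summary = {
        "n_draws": res.n_draws,
        "seed": res.seed,
        "mode": res.mode,
        "mean_delta_surgeries": res.mean_delta_surgeries,
        "mean_delta_cost": res.mean_delta_cost,
        "ci_surgeries": list(res.ci_surgeries),
        "ci_cost": list(res.ci_cost),
        "ci_cost_eur": [floor_eur(res.ci_cost[0]), floor_eur(res.ci_cost[1])],
    }
    path = out_dir / "psa.json"
    path.write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    if res.draws is not None:
        res.draws.to_csv(out_dir / "psa_draws.csv", index=False)
    return path


def write_patients(records: list[PatientRecord], summary: CohortSummary, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    cohort_frame(records).to_csv(out_dir / "patients.csv", index=False)
    path = out_dir / "cohort_summary.json"
    path.write_text(
        json.dumps(
            {
                "strategy": summary.strategy,
                "n_patients": summary.n_patients,
                "mean_surgeries": summary.mean_surgeries,
                "se_surgeries": summary.se_surgeries,
                "mean_cost": summary.mean_cost,
                "se_cost": summary.se_cost,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return path
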