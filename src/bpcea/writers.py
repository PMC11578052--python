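"""Result writers and the run manifest.

Every command writes a ``manifest.json`` alongside its outputs recording
the configuration path, command, seed, package version and timestamp, so
any result file is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import FrontierResult, StrategyResult
from .engine import CohortTrace
from .sensitivity import CEACCurve, PSAResult


@dataclass
class RunManifest:
    config_path: str
    command: str
    seed: int | None
    version: str
    timestamp: str
    output_dir: str

    @classmethod
    def create(
        cls, config_path: str | Path, command: str, seed: int | None, output_dir: str | Path
    ) -> "RunManifest":
        return cls(
            config_path=str(config_path),
            command=command,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            output_dir=str(output_dir),
        )

    def write(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path


def write_trace(trace: CohortTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_strategy_table(results: list[StrategyResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "strategy": [r.name for r in results],
            "total_cost_usd": [round(r.total_cost, 2) for r in results],
            "total_qaly": [r.total_qaly for r in results],
            "lifetime_cvd_incidence": [r.cvd_incidence for r in results],
        }
    ).to_csv(path, index=False)


def write_frontier(frontier: FrontierResult, path: str | Path) -> None:
    """Frontier classification as CSV (.csv suffix) or JSON (anything else)."""
    records = frontier.to_records()
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2)


def write_tornado(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_psa(result: PSAResult, path: str | Path) -> None:
    result.iterations.to_csv(path, index=False)


def write_ceac(curve: CEACCurve, path: str | Path) -> None:
    curve.table.to_csv(path)
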