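"""Plain-text input/output: trip logs (JSONL), daily trajectories (CSV) and
run manifests (JSON).

All outputs are diffable text; a manifest echoes the configuration, seed and
package version so any run can be re-executed from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import SimConfig
from .errors import IntegrityError
from .trips import TripRecord


def write_trips(path: str | Path, records: list[TripRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_trips(path: str | Path) -> list[TripRecord]:
    """Read a JSONL trip log, validating every record's conditioning
    invariants; violations raise with the offending line number."""
    out: list[TripRecord] = []
    field_names = {f.name for f in dataclasses.fields(TripRecord)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                data = json.loads(line)
            except json.JSONDecodeError as exc:
                raise IntegrityError(f"{path}: line {lineno}: malformed JSON ({exc})") from exc
            unknown = set(data) - field_names
            if unknown:
                raise IntegrityError(f"{path}: line {lineno}: unknown field(s) {sorted(unknown)}")
            try:
                rec = TripRecord(**data).validate()
            except (TypeError, IntegrityError) as exc:
                raise IntegrityError(f"{path}: line {lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_daily(path: str | Path, daily: pd.DataFrame) -> None:
    daily.to_csv(path, index=False)


def read_daily(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunManifest:
    """Everything needed to re-execute a run: config echo, seed, version."""

    command: str
    seed: int
    config: dict
    outputs: dict
    version: str = __version__

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def sim_config(self) -> SimConfig:
        return SimConfig.from_dict(self.config)


def write_run(outdir: str | Path, command: str, config: SimConfig, seed: int,
              daily: pd.DataFrame, trips: list[TripRecord]) -> None:
    """Standard output layout: trips.jsonl, daily.csv, manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trips(outdir / "trips.jsonl", trips)
    write_daily(outdir / "daily.csv", daily)
    RunManifest(
        command=command, seed=seed, config=config.to_dict(),
        outputs={"trips": "trips.jsonl", "daily": "daily.csv"},
    ).save(outdir / "manifest.json")
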