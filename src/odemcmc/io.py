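"""Persistence for datasets, runs and study configurations.

A run is stored as a CSV trace (parameter columns plus the log-posterior)
with a side-car JSON of metadata; human-inspectable text formats are used
throughout.  Study configurations load from YAML or JSON; a hash of the
canonical configuration is stamped into every run artifact so that reports
refuse to mix runs from different configurations unless forced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from odemcmc.samplers import SamplerConfig, SamplerRun
from odemcmc.study import ScenarioSpec

__all__ = [
    "StudyConfig",
    "config_hash",
    "save_run",
    "load_run",
    "run_artifact_name",
]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a canonicalized configuration dictionary."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class StudyConfig:
    """Declarative study description loaded from YAML/JSON."""

    benchmark: str
    scenarios: list[dict]
    n_runs: int = 100
    n_iter: int = 1_000_000
    master_seed: int = 0
    data_seed: int = 0
    data_csv: Optional[str] = None  # user-supplied dataset instead of synthetic
    output_dir: str = "runs"

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        raw = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "benchmark": self.benchmark,
            "scenarios": self.scenarios,
            "n_runs": self.n_runs,
            "n_iter": self.n_iter,
            "master_seed": self.master_seed,
            "data_seed": self.data_seed,
            "data_csv": self.data_csv,
        }

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def scenario_specs(self) -> list[ScenarioSpec]:
        specs = []
        for sc in self.scenarios:
            sc = dict(sc)
            name = sc.pop("name")
            init = sc.pop("init", "rnd")
            n_runs = sc.pop("n_runs", self.n_runs)
            n_iter = sc.pop("n_iter", self.n_iter)
            ms_n_starts = sc.pop("ms_n_starts", 100)
            ms_delta = sc.pop("ms_delta", 10.0)
            specs.append(ScenarioSpec(
                name=name, config=SamplerConfig(**sc), init=init,
                n_runs=n_runs, n_iter=n_iter, ms_n_starts=ms_n_starts,
                ms_delta=ms_delta,
            ))
        return specs


def run_artifact_name(scenario: str, run_index: int) -> str:
    return f"{scenario}_run{run_index:04d}"


def save_run(directory, run: SamplerRun, run_index: int = 0,
             cfg_hash: str = "") -> Path:
    """Write trace CSV + metadata JSON; returns the trace path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = run_artifact_name(run.scenario or run.algorithm, run_index)
    d = run.trace.shape[1]
    frame = pd.DataFrame(run.trace,
                         columns=[f"theta{i + 1}" for i in range(d)])
    frame["log_posterior"] = run.log_posterior_trace
    trace_path = directory / f"{stem}.csv"
    frame.to_csv(trace_path, index=False, float_format="%.17g")
    meta = {
        "algorithm": run.algorithm,
        "settings": run.settings,
        "seed": run.seed,
        "problem": run.problem,
        "scenario": run.scenario,
        "cpu_seconds": run.cpu_seconds,
        "acceptance_rate": run.acceptance_rate,
        "n_iter": run.n_iter,
        "config_hash": cfg_hash,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return trace_path


def load_run(directory, stem: str) -> tuple[SamplerRun, str]:
    """Load a run artifact; returns (run, config hash)."""
    directory = Path(directory)
    frame = pd.read_csv(directory / f"{stem}.csv",
                        float_precision="round_trip")
    meta = json.loads((directory / f"{stem}.json").read_text())
    logpost = frame.pop("log_posterior").to_numpy()
    run = SamplerRun(
        trace=frame.to_numpy(),
        log_posterior_trace=logpost,
        cpu_seconds=meta["cpu_seconds"],
        acceptance_rate=meta["acceptance_rate"],
        algorithm=meta["algorithm"],
        settings=meta["settings"],
        seed=meta["seed"],
        problem=meta["problem"],
        scenario=meta["scenario"],
    )
    return run, meta.get("config_hash", "")


def load_all_runs(directory) -> tuple[list[SamplerRun], set[str]]:
    """Load every run artifact in a directory (sorted by stem)."""
    directory = Path(directory)
    runs, hashes = [], set()
    for meta_path in sorted(directory.glob("*.json")):
        stem = meta_path.stem
        if not (directory / f"{stem}.csv").exists():
            continue
        run, h = load_run(directory, stem)
        runs.append(run)
        hashes.add(h)
    return runs, hashes
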