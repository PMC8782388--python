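"""Pipeline orchestration: generate -> measure -> weights -> analyze -> report.

Each stage reads and writes plain CSV artifacts in the output directory, so
stages can be re-run in isolation on pre-existing tables.  A run manifest
(config echo, seed, stage list, artifact digests, package version) is
written last; re-running with the same config and seed reproduces
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import composition_table
from .crosswave import crosswave_table
from .effects import run_two_stage
from .io import load_interviews, write_cohort
from .model import ConfigError
from .reports import render_tables
from .simulate import SimConfig, generate_dataset
from .weights import BoostingParams, weights_for_sample

log = logging.getLogger("egowave")

ALL_STAGES = ("generate", "measure", "weights", "analyze", "report")

_SIM_KEYS = set(SimConfig.__dataclass_fields__)
_RUN_KEYS = {"flag_version", "weight_method", "boosting", "stages"}


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str]
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamp: str = ""
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _SIM_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return raw


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict | SimConfig | None = None,
    outdir: str | Path = "egowave_out",
    seed: int | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> RunManifest:
    """Execute the requested stages in order; any failure halts with stage
    context.  Returns the run manifest (also written to ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, SimConfig):
        sim_cfg, run_cfg = config, {}
    else:
        raw = dict(config or {})
        run_cfg = {k: raw.pop(k) for k in list(raw) if k in _RUN_KEYS}
        sim_cfg = SimConfig(**raw)
    if seed is not None:
        sim_cfg.seed = int(seed)
    flag_version = run_cfg.get("flag_version", "ever")
    weight_method = run_cfg.get("weight_method", "boosting")
    bp = BoostingParams(**run_cfg.get("boosting", {}))
    stages = tuple(run_cfg.get("stages", stages))

    manifest = RunManifest(
        config={**sim_cfg.to_dict(), **run_cfg},
        seed=sim_cfg.seed,
        stages=list(stages),
    )

    current = "load"
    try:
        if "generate" in stages:
            current = "generate"
            ego_df, alter_df, tie_df = generate_dataset(sim_cfg)
            from .io import Cohort

            write_cohort(Cohort(ego_df, alter_df, tie_df), outdir)
        cohort = load_interviews(outdir / "ego.csv", outdir / "alter.csv", outdir / "tie.csv")

        if "measure" in stages:
            current = "measure"
            composition_table(cohort.alters).to_csv(outdir / "composition.csv", index=False)
            crosswave_table(cohort.alters, cohort.ties, flag_version=flag_version).to_csv(
                outdir / "crosswave.csv", index=False
            )
        if "weights" in stages:
            current = "weights"
            wt, bal = weights_for_sample(
                cohort.egos, cohort.alters, cohort.ties,
                method=weight_method, params=bp, seed=sim_cfg.seed,
            )
            wt.to_csv(outdir / "weights.csv", index=False)
            bal.to_csv(outdir / "balance.csv", index=False)
        if "analyze" in stages:
            current = "analyze"
            results = run_two_stage(
                cohort.egos, cohort.alters, cohort.ties,
                weight_method=weight_method, boosting_params=bp,
                flag_version=flag_version, seed=sim_cfg.seed,
            )
            results.to_csv(outdir / "results.csv", index=False)
        if "report" in stages:
            current = "report"
            results = pd.read_csv(outdir / "results.csv")
            (outdir / "report.md").write_text(render_tables(results))
    except Exception as exc:
        exc.add_note(f"pipeline stage {current!r} failed")
        log.error("[%s] failed: %s", current, exc)
        raise

    for p in sorted(outdir.iterdir()):
        if p.suffix in (".csv", ".md") and p.is_file():
            manifest.artifacts[p.name] = _sha256(p)
    manifest.timestamp = datetime.now(timezone.utc).isoformat()
    manifest.write(outdir / "manifest.json")
    return manifest
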