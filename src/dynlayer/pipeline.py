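"""End-to-end pipeline orchestration with file-based staging.

Stages run in fixed order — simulate → tvfc → build → detect → metrics →
stats — each reading the previous stage's files and writing its own under
the output directory, with a JSON done-marker recording the configuration
hash.  A stage is skipped when its marker matches the current configuration
and no upstream stage re-ran in this invocation; deleting a stage directory
therefore regenerates that stage and everything downstream.  All randomness
derives from ``base_seed``, so rerunning with the same configuration
reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import metrics as rm
from .community import MultilayerPartition, PartitionEnsemble, run_ensemble
from .experiments import tidy_metric_table
from .metrics import RSNMapping
from .multilayer import SIMILARITY_VARIANTS, build_multilayer
from .simulate import SimulationConfig, generate_group_timeseries, \
    make_rsn_mapping, write_fixture_bundle
from .stats import spearman, ttest_by_level
from .tvfc import compute_tvfc

__all__ = ["PipelineConfig", "ConfigError", "DataError", "StageError",
           "run_pipeline", "STAGES"]

log = logging.getLogger("dynlayer")

STAGES = ("simulate", "tvfc", "build", "detect", "metrics", "stats")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(RuntimeError):
    """Missing or malformed input data."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable pipeline configuration.

    Unknown keys are rejected on construction from a mapping, and the config
    is echoed verbatim into every output manifest.
    """

    out_dir: str
    input_dir: str | None = None
    simulate: dict | None = None
    trim_edges: int = 0
    binarize_rule: str = "positive"
    similarity: str = "literal"
    gamma: float = 1.0
    n_runs: int = 100
    base_seed: int = 0
    levels: tuple[str, ...] = ("whole_brain", "rsn", "rsn_pair", "node")
    group_order: tuple[str, str] = ("B", "A")
    equal_var: bool = True
    include_self: bool = True

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ConfigError("need either input_dir or a simulate section")
        if self.similarity not in SIMILARITY_VARIANTS:
            raise ConfigError(f"similarity must be one of {SIMILARITY_VARIANTS}")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        bad = set(self.levels) - set(rm.AGGREGATION_LEVELS)
        if bad:
            raise ConfigError(f"unknown aggregation level(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("levels", "group_order"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["group_order"] = list(self.group_order)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _marker(stage_dir: Path) -> Path:
    return stage_dir / "_done.json"


def _is_fresh(stage_dir: Path, digest: str) -> bool:
    m = _marker(stage_dir)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_digest") == digest
    except json.JSONDecodeError:
        return False


def _finish(stage_dir: Path, digest: str, stage: str) -> None:
    _marker(stage_dir).write_text(json.dumps(
        {"stage": stage, "config_digest": digest, "version": __version__}))


def _bundle_dir(config: PipelineConfig, out: Path) -> Path:
    if config.simulate is not None:
        return out / "bundle"
    return Path(config.input_dir)


def _read_subjects(bundle: Path) -> pd.DataFrame:
    f = bundle / "subjects.csv"
    if not f.exists():
        raise DataError(f"missing {f}")
    return pd.read_csv(f)


def _read_mapping(bundle: Path) -> RSNMapping:
    f = bundle / "mapping.csv"
    if not f.exists():
        raise DataError(f"missing {f}")
    return RSNMapping.from_array(pd.read_csv(f)["subnetwork"])


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    sim = SimulationConfig(**config.simulate)
    sets = [generate_group_timeseries(sim, g)[0] for g in ("A", "B")]
    write_fixture_bundle(out / "bundle", sets, sim,
                         mapping=make_rsn_mapping(sim.n_regions),
                         overwrite=True)


def _stage_tvfc(config: PipelineConfig, out: Path) -> None:
    bundle = _bundle_dir(config, out)
    subjects = _read_subjects(bundle)
    stage = out / "tvfc"
    stage.mkdir(exist_ok=True)
    for sid in subjects["id"]:
        series = np.loadtxt(bundle / f"sub-{sid}.csv", delimiter=",", ndmin=2)
        stack = compute_tvfc(series, trim_edges=config.trim_edges)
        np.save(stage / f"sub-{sid}_tvfc.npy", stack.data)
        (stage / f"sub-{sid}_tvfc.json").write_text(json.dumps(
            {"axis_order": ["t", "n", "p"], "clamped": True,
             "trim_edges": config.trim_edges}))


def _stage_build(config: PipelineConfig, out: Path) -> None:
    bundle = _bundle_dir(config, out)
    subjects = _read_subjects(bundle)
    stage = out / "omega"
    stage.mkdir(exist_ok=True)
    for sid in subjects["id"]:
        net = _load_network(config, out, sid)
        np.savetxt(stage / f"sub-{sid}_omega.csv", net.omega,
                   delimiter=",", fmt="%.10g")
        (stage / f"sub-{sid}_omega.json").write_text(json.dumps(
            {"rule": config.binarize_rule, "similarity": config.similarity}))


def _load_network(config: PipelineConfig, out: Path, sid: str):
    f = out / "tvfc" / f"sub-{sid}_tvfc.npy"
    if not f.exists():
        raise DataError(f"missing {f}; run the tvfc stage first")
    from .tvfc import TVFCStack
    stack = TVFCStack(data=np.load(f), clamped=True)
    return build_multilayer(stack, rule=config.binarize_rule,
                            similarity=config.similarity)


def _subject_seed(config: PipelineConfig, index: int) -> int:
    return config.base_seed + 10_000 * index


def _stage_detect(config: PipelineConfig, out: Path) -> None:
    bundle = _bundle_dir(config, out)
    subjects = _read_subjects(bundle)
    stage = out / "partitions"
    stage.mkdir(exist_ok=True)
    for idx, sid in enumerate(subjects["id"]):
        net = _load_network(config, out, sid)
        seed = _subject_seed(config, idx)
        ens = run_ensemble(net, gamma=config.gamma, n_runs=config.n_runs,
                           base_seed=seed)
        sdir = stage / f"sub-{sid}"
        if sdir.exists():
            shutil.rmtree(sdir)
        sdir.mkdir()
        for r, run in enumerate(ens.runs):
            np.savetxt(sdir / f"run-{r:03d}.csv", run.labels,
                       delimiter=",", fmt="%d")
        (sdir / "summary.json").write_text(json.dumps(
            {"q": [run.q_value for run in ens.runs],
             "seeds": [run.seed for run in ens.runs],
             "gamma": config.gamma, "similarity": config.similarity,
             "rule": config.binarize_rule, "base_seed": seed}))


def _load_ensemble(out: Path, sid: str) -> PartitionEnsemble:
    sdir = out / "partitions" / f"sub-{sid}"
    summary_file = sdir / "summary.json"
    if not summary_file.exists():
        raise DataError(f"missing {summary_file}; run the detect stage first")
    summary = json.loads(summary_file.read_text())
    runs = []
    for r, (q, seed) in enumerate(zip(summary["q"], summary["seeds"])):
        labels = np.loadtxt(sdir / f"run-{r:03d}.csv", delimiter=",",
                            dtype=np.int64, ndmin=2)
        runs.append(MultilayerPartition(labels=labels, q_value=q, seed=seed))
    return PartitionEnsemble(runs=runs, base_seed=summary["base_seed"])


def _stage_metrics(config: PipelineConfig, out: Path) -> None:
    bundle = _bundle_dir(config, out)
    subjects = _read_subjects(bundle)
    mapping = _read_mapping(bundle)
    stage = out / "metrics"
    stage.mkdir(exist_ok=True)
    (stage / "allegiance").mkdir(exist_ok=True)
    from .experiments import SubjectMetrics
    frames = []
    for sid, group in zip(subjects["id"], subjects["group"]):
        net = _load_network(config, out, sid)
        ens = _load_ensemble(out, sid)
        ma = rm.module_allegiance(ens)
        sm = SubjectMetrics(
            coupling=net.mean_coupling(per_node=True),
            promiscuity=rm.promiscuity(ens),
            recruitment=rm.recruitment(ma, mapping,
                                       include_self=config.include_self),
            integration=rm.integration(ma, mapping),
            allegiance=ma,
            pair_integration=rm.pair_integration(ma, mapping),
            q_values=ens.q_values)
        np.savetxt(stage / "allegiance" / f"sub-{sid}_ma.csv", ma,
                   delimiter=",", fmt="%.10g")
        frames.append(tidy_metric_table(sid, str(group), sm, mapping))
    long_table = pd.concat(frames, ignore_index=True)
    long_table = long_table[long_table["level"].isin(config.levels)]
    long_table.to_csv(stage / "metrics_long.csv", index=False)
    for level in config.levels:
        long_table[long_table["level"] == level].to_csv(
            stage / f"metrics_{level}.csv", index=False)
    (stage / "metrics.json").write_text(json.dumps(
        {"n_runs": config.n_runs, "include_self": config.include_self,
         "similarity": config.similarity, "rule": config.binarize_rule}))


def _stage_stats(config: PipelineConfig, out: Path) -> None:
    bundle = _bundle_dir(config, out)
    subjects = _read_subjects(bundle)
    table_file = out / "metrics" / "metrics_long.csv"
    if not table_file.exists():
        raise DataError(f"missing {table_file}; run the metrics stage first")
    table = pd.read_csv(table_file)
    stage = out / "stats"
    stage.mkdir(exist_ok=True)
    results = ttest_by_level(table, group_order=config.group_order,
                             equal_var=config.equal_var)
    results.to_csv(stage / "group_stats.csv", index=False)
    rows = []
    wb = table[table["level"] == "whole_brain"].set_index("subject")
    scores = subjects.set_index("id")["score"]
    for metric, sub in wb.groupby("metric"):
        vals = sub.loc[scores.index.intersection(sub.index), "value"]
        r, p = spearman(vals.to_numpy(), scores.loc[vals.index].to_numpy())
        rows.append({"metric": metric, "level": "whole_brain",
                     "r": r, "p": p, "n": len(vals)})
    pd.DataFrame(rows).to_csv(stage / "spearman.csv", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "tvfc": _stage_tvfc,
    "build": _stage_build,
    "detect": _stage_detect,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
}

_STAGE_DIRS = {
    "simulate": "bundle", "tvfc": "tvfc", "build": "omega",
    "detect": "partitions", "metrics": "metrics", "stats": "stats",
}


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all applicable) and write the
    output manifest.  Returns a summary dict with per-stage status."""
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    if config.simulate is None:
        requested = [s for s in requested if s != "simulate"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    status: dict[str, str] = {}
    ran_upstream = False
    for stage in STAGES:
        if stage not in requested:
            continue
        stage_dir = out / _STAGE_DIRS[stage]
        if not ran_upstream and _is_fresh(stage_dir, digest):
            status[stage] = "cached"
            log.info("stage %s: cached", stage)
            continue
        t0 = time.time()
        marker = _marker(stage_dir)
        if marker.exists():
            marker.unlink()  # mark stale while running
        try:
            _STAGE_FUNCS[stage](config, out)
        except (ConfigError, DataError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc
        _finish(stage_dir, digest, stage)
        ran_upstream = True
        status[stage] = "ran"
        log.info("stage %s: %.2fs", stage, time.time() - t0)
    manifest = {"config": config.to_dict(), "config_digest": digest,
                "version": __version__, "stages": status}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
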