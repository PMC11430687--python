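"""Synthetic two-group BOLD-like time series with planted dynamic structure.

Each subject's signal is a sequence of epochs.  Within an epoch the N
regional signals are draws from a zero-mean multivariate normal whose
correlation is ``within_block_corr`` for region pairs in the same planted
module and ``cross_block_corr`` otherwise; a moving-average filter then
band-limits the draws (slow oscillatory structure, as in band-passed BOLD)
and white noise of SD ``noise_sd`` is added.  Epoch lengths are geometric
with a floor, and at each epoch boundary the module assignment is redrawn
with a group-specific probability, planting a community partition that
switches over time.  A synthetic clinical score is tied linearly to each
subject's realized switch count, so correlation recovery is testable
downstream.

Groups differ only through their ``switch_prob`` and ``within_block_corr``
entries, letting experiments plant directional group contrasts in switching
rate and cross-community mixing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import RSN_NAMES

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "TimeSeriesSet",
    "generate_group_timeseries",
    "make_rsn_mapping",
    "write_fixture_bundle",
    "read_bundle",
]

GROUPS = ("A", "B")


def _per_group(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        if set(value) != set(GROUPS):
            raise ValueError(f"{name} mapping must have keys {GROUPS}")
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group synthetic experiment.

    ``switch_prob`` and ``within_block_corr`` may be scalars or per-group
    mappings ``{"A": ..., "B": ...}``.  Defaults echo the scale of a typical
    resting-state acquisition: 90 regions, 142 usable volumes.
    """

    n_subjects_per_group: int = 20
    n_regions: int = 90
    n_timepoints: int = 142
    n_modules: int = 4
    epoch_length_mean: float = 20.0
    switch_prob: float | Mapping[str, float] = 0.3
    within_block_corr: float | Mapping[str, float] = 0.6
    cross_block_corr: float = 0.1
    noise_sd: float = 0.3
    score_coupling: float = 0.0
    score_noise_sd: float = 1.0
    smooth_width: int = 3
    min_epoch_length: int = 5
    seed: int = 0
    _switch: dict[str, float] = field(init=False, repr=False, compare=False)
    _within: dict[str, float] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_regions < 2:
            raise ValueError("need >= 1 subject and >= 2 regions")
        if not 2 <= self.n_modules <= self.n_regions:
            raise ValueError("n_modules must be in [2, n_regions]")
        if self.epoch_length_mean < self.min_epoch_length:
            raise ValueError("epoch_length_mean must be >= min_epoch_length")
        object.__setattr__(self, "_switch",
                           _per_group(self.switch_prob, "switch_prob"))
        object.__setattr__(self, "_within",
                           _per_group(self.within_block_corr, "within_block_corr"))
        for g in GROUPS:
            w, c = self._within[g], self.cross_block_corr
            if not 0.0 <= c < w < 1.0:
                raise ValueError(
                    f"require 0 <= cross_block_corr < within_block_corr < 1; "
                    f"group {g} has within={w}, cross={c}")
            if not 0.0 <= self._switch[g] <= 1.0:
                raise ValueError(f"switch_prob for group {g} not in [0, 1]")
        # positive-definiteness of the block correlation under the balanced
        # initial partition; redraws only permute regions, preserving spectrum
        part = _balanced_partition(self.n_regions, self.n_modules)
        for g in GROUPS:
            C = _block_correlation(part, self._within[g], self.cross_block_corr)
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"block covariance not positive definite for group {g}: "
                    f"within={self._within[g]}, cross={self.cross_block_corr}, "
                    f"n_modules={self.n_modules}") from None

    def group_params(self, group: str) -> tuple[float, float]:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        return self._switch[group], self._within[group]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_switch")
        d.pop("_within")
        d["switch_prob"] = self._switch
        d["within_block_corr"] = self._within
        return d


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted into a generated group.

    ``partition_schedules[s][i, t]`` is the module label (1-based, contiguous)
    of region i at timepoint t for subject s; ``switch_counts[s]`` counts the
    epoch boundaries at which the schedule actually changed.
    """

    partition_schedules: list[np.ndarray]
    switch_counts: np.ndarray
    scores: np.ndarray


@dataclass(frozen=True)
class TimeSeriesSet:
    """Per-subject (T, N) signal matrices with group labels and scores."""

    series: list[np.ndarray]
    subject_ids: list[str]
    group: str
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.series)


def _balanced_partition(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module assignment, labels 1..K."""
    chunks = np.array_split(np.arange(n_regions), n_modules)
    return np.concatenate(
        [np.full(len(chunk), m + 1) for m, chunk in enumerate(chunks)])


def _block_correlation(partition: np.ndarray, within: float,
                       cross: float) -> np.ndarray:
    same = partition[:, None] == partition[None, :]
    C = np.where(same, within, cross)
    np.fill_diagonal(C, 1.0)
    return C


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    out = np.empty_like(x)
    for col in range(x.shape[1]):
        out[:, col] = np.convolve(x[:, col], kernel, mode="same")
    return out


def _draw_epoch_lengths(rng: np.random.Generator, total: int, mean: float,
                        minimum: int) -> list[int]:
    """Geometric lengths (mean ``mean``, floor ``minimum``) covering
    ``total`` timepoints; the last epoch is truncated to fit."""
    p = 1.0 / (mean - minimum + 1.0)
    lengths: list[int] = []
    covered = 0
    while covered < total:
        length = minimum - 1 + int(rng.geometric(p))
        length = min(length, total - covered)
        lengths.append(length)
        covered += length
    return lengths


def _redraw_partition(rng: np.random.Generator, current: np.ndarray,
                      n_modules: int) -> np.ndarray:
    """Balanced random module assignment guaranteed to differ from
    ``current``."""
    base = np.sort(current)  # same module sizes, reshuffled membership
    for _ in range(100):
        candidate = rng.permutation(base)
        if not np.array_equal(candidate, current):
            return candidate
    raise RuntimeError("could not draw a distinct partition")  # pragma: no cover


def _simulate_subject(rng: np.random.Generator, config: SimulationConfig,
                      switch_prob: float, within: float
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    N, T = config.n_regions, config.n_timepoints
    partition = _balanced_partition(N, config.n_modules)
    lengths = _draw_epoch_lengths(rng, T, config.epoch_length_mean,
                                  config.min_epoch_length)
    schedule = np.empty((N, T), dtype=np.int64)
    signal = np.empty((T, N))
    switch_count = 0
    t0 = 0
    for e, length in enumerate(lengths):
        if e > 0 and rng.random() < switch_prob:
            new = _redraw_partition(rng, partition, config.n_modules)
            if not np.array_equal(new, partition):
                switch_count += 1
            partition = new
        C = _block_correlation(partition, within, config.cross_block_corr)
        L = np.linalg.cholesky(C)
        Z = rng.standard_normal((length, N))
        signal[t0:t0 + length] = Z @ L.T
        schedule[:, t0:t0 + length] = partition[:, None]
        t0 += length
    signal = _moving_average(signal, config.smooth_width)
    signal = signal + config.noise_sd * rng.standard_normal((T, N))
    return signal, schedule, switch_count


def generate_group_timeseries(config: SimulationConfig, group: str
                              ) -> tuple[TimeSeriesSet, PlantedTruth]:
    """Generate one group's subjects with their planted ground truth.

    Deterministic given ``(config.seed, group)``: each subject draws from an
    independent substream of a seed sequence keyed by the group index.
    """
    switch_prob, within = config.group_params(group)
    g_idx = GROUPS.index(group)
    series, schedules, counts = [], [], []
    for s in range(config.n_subjects_per_group):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, g_idx, s]))
        signal, schedule, n_switch = _simulate_subject(
            rng, config, switch_prob, within)
        series.append(signal)
        schedules.append(schedule)
        counts.append(n_switch)
    counts = np.array(counts)
    score_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, g_idx, 10_000]))
    scores = (config.score_coupling * counts
              + config.score_noise_sd * score_rng.standard_normal(len(counts)))
    ids = [f"{group}{s+1:03d}" for s in range(config.n_subjects_per_group)]
    ts = TimeSeriesSet(series=series, subject_ids=ids, group=group,
                       scores=scores)
    truth = PlantedTruth(partition_schedules=schedules,
                         switch_counts=counts, scores=scores)
    return ts, truth


def make_rsn_mapping(n_regions: int) -> pd.DataFrame:
    """Synthetic region→subnetwork table: five contiguous near-equal RSNs.

    Columns ``region_index`` (1-based), ``region_name``, ``subnetwork``.
    """
    chunks = np.array_split(np.arange(n_regions), len(RSN_NAMES))
    rows = []
    for rsn, chunk in zip(RSN_NAMES, chunks):
        for i in chunk:
            rows.append({"region_index": int(i) + 1,
                         "region_name": f"R{i+1:03d}",
                         "subnetwork": rsn})
    return pd.DataFrame(rows)


def write_fixture_bundle(path: str | Path, sets: Sequence[TimeSeriesSet],
                         config: SimulationConfig,
                         mapping: pd.DataFrame | None = None,
                         overwrite: bool = False) -> dict:
    """Write a plain-text data bundle and return its manifest.

    Layout: one headerless CSV per subject (rows = timepoints, columns =
    regions), ``subjects.csv`` (id, group, score), ``mapping.csv`` and a
    ``manifest.json`` echoing the config and seed.  Refuses to overwrite an
    existing manifest unless ``overwrite`` is set.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest_path = path / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace the bundle")
    if mapping is None:
        mapping = make_rsn_mapping(config.n_regions)
    files = []
    subject_rows = []
    for ts in sets:
        for sid, mat, score in zip(ts.subject_ids, ts.series, ts.scores):
            fname = f"sub-{sid}.csv"
            np.savetxt(path / fname, mat, delimiter=",", fmt="%.10g")
            files.append(fname)
            subject_rows.append({"id": sid, "group": ts.group,
                                 "score": float(score)})
    pd.DataFrame(subject_rows).to_csv(path / "subjects.csv", index=False)
    mapping.to_csv(path / "mapping.csv", index=False)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "files": files}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def read_bundle(path: str | Path
                ) -> tuple[list[TimeSeriesSet], pd.DataFrame, dict]:
    """Read back a bundle written by :func:`write_fixture_bundle`.

    Returns one :class:`TimeSeriesSet` per group, the mapping table and the
    manifest.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    subjects = pd.read_csv(path / "subjects.csv")
    mapping = pd.read_csv(path / "mapping.csv")
    sets = []
    for group, sub in subjects.groupby("group", sort=True):
        series = [np.loadtxt(path / f"sub-{sid}.csv", delimiter=",", ndmin=2)
                  for sid in sub["id"]]
        sets.append(TimeSeriesSet(series=series,
                                  subject_ids=list(sub["id"]),
                                  group=str(group),
                                  scores=sub["score"].to_numpy(float)))
    return sets, mapping, manifest
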