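"""Dynamic reconfiguration metrics from a partition ensemble.

Three node-level quantities summarize how a node's community membership
behaves over time, each averaged over the ensemble of optimization runs:

* **promiscuity** P_i = (m_i − 1)/(M − 1): the fraction of a run's M
  communities that node i visits (m_i distinct ids across layers); 0 means
  the node stays in one community, 1 that it visits all of them.
* **recruitment** R_iS: the node's mean module allegiance to the members of
  its own resting-state subnetwork S.
* **integration** I_iS: its mean allegiance to nodes outside S.

Module allegiance MA_ij is the probability, over layers and runs, that
nodes i and j carry the same community label.  Recruitment and integration
decompose the MA row mean exactly:
``(n_S·R_i + (N−n_S)·I_i)/N = mean_j MA_ij`` when the self term is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import PartitionEnsemble

__all__ = [
    "RSNMapping",
    "RSN_NAMES",
    "promiscuity",
    "module_allegiance",
    "recruitment",
    "integration",
    "pair_integration",
    "aggregate",
]

RSN_NAMES = ("MAN", "VN", "AN", "DMN", "LSN")

AGGREGATION_LEVELS = ("whole_brain", "rsn", "rsn_pair", "node")


@dataclass(frozen=True)
class RSNMapping:
    """Assignment of every region to one resting-state subnetwork."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(RSN_NAMES)
        if unknown:
            raise ValueError(f"unknown subnetwork label(s): {sorted(unknown)}")

    @classmethod
    def from_array(cls, labels) -> "RSNMapping":
        return cls(labels=tuple(str(x) for x in labels))

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def subnetworks(self) -> tuple[str, ...]:
        """Subnetworks present, in canonical RSN order."""
        present = set(self.labels)
        return tuple(s for s in RSN_NAMES if s in present)

    def members(self, subnetwork: str) -> np.ndarray:
        return np.array([lab == subnetwork for lab in self.labels])

    def sizes(self) -> dict[str, int]:
        return {s: int(self.members(s).sum()) for s in self.subnetworks}


def promiscuity(ensemble: PartitionEnsemble) -> np.ndarray:
    """Per-node promiscuity, averaged over runs.

    Within each run, m_i counts the distinct community ids node i takes
    across layers and M the distinct ids anywhere in that run's partition
    (a layer-spanning community counts once).  P_i = (m_i − 1)/(M − 1), with
    the degenerate single-community run (M = 1) scored 0.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    per_run = []
    for run in ensemble.runs:
        labels = run.labels  # (N, T)
        M = len(np.unique(labels))
        m = np.array([len(np.unique(row)) for row in labels], dtype=float)
        if M == 1:
            per_run.append(np.zeros(labels.shape[0]))
        else:
            per_run.append((m - 1.0) / (M - 1.0))
    return np.mean(per_run, axis=0)


def module_allegiance(ensemble: PartitionEnsemble) -> np.ndarray:
    """N×N co-assignment probability over all layers and runs."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    labels = ensemble.label_array()  # (R, N, T)
    R, N, T = labels.shape
    ma = np.zeros((N, N))
    for r in range(R):
        ma += (labels[r, :, None, :] == labels[r, None, :, :]).sum(axis=-1)
    return ma / (R * T)


def _check_mapping(ma: np.ndarray, mapping: RSNMapping) -> None:
    if ma.shape[0] != mapping.n_regions:
        raise ValueError(
            f"mapping covers {mapping.n_regions} regions but MA is {ma.shape[0]}×{ma.shape[1]}")
    for s in mapping.subnetworks:
        if mapping.members(s).sum() == 0:
            raise ValueError(f"subnetwork {s} is empty")


def recruitment(ma: np.ndarray, mapping: RSNMapping,
                include_self: bool = True) -> np.ndarray:
    """Per-node recruitment: mean allegiance to the node's own subnetwork.

    The sum runs over every member j of the node's subnetwork including the
    node itself (MA_ii = 1); ``include_self=False`` excludes the self term
    and divides by n_S − 1.
    """
    _check_mapping(ma, mapping)
    out = np.empty(mapping.n_regions)
    for s in mapping.subnetworks:
        mask = mapping.members(s)
        n_s = mask.sum()
        sums = ma[np.ix_(mask, mask)].sum(axis=1)
        if include_self:
            out[mask] = sums / n_s
        else:
            if n_s < 2:
                raise ValueError(f"subnetwork {s} has a single node; "
                                 "cannot exclude the self term")
            out[mask] = (sums - np.diag(ma)[mask]) / (n_s - 1)
    return out


def integration(ma: np.ndarray, mapping: RSNMapping) -> np.ndarray:
    """Per-node integration: mean allegiance to nodes outside the node's
    subnetwork, I_iS = Σ_{j∉S} MA_ij / (N − n_S)."""
    _check_mapping(ma, mapping)
    N = mapping.n_regions
    out = np.empty(N)
    for s in mapping.subnetworks:
        mask = mapping.members(s)
        n_s = mask.sum()
        if n_s == N:
            raise ValueError("a single subnetwork covers all regions; "
                             "integration is undefined")
        out[mask] = ma[np.ix_(mask, ~mask)].sum(axis=1) / (N - n_s)
    return out


def pair_integration(ma: np.ndarray, mapping: RSNMapping) -> pd.DataFrame:
    """Mean allegiance between every unordered pair of distinct subnetworks.

    One row per pair, columns ``rsn_a``, ``rsn_b``, ``integration``.
    """
    _check_mapping(ma, mapping)
    subs = mapping.subnetworks
    rows = []
    for i, s1 in enumerate(subs):
        for s2 in subs[i + 1:]:
            block = ma[np.ix_(mapping.members(s1), mapping.members(s2))]
            rows.append({"rsn_a": s1, "rsn_b": s2,
                         "integration": float(block.mean())})
    return pd.DataFrame(rows)


def aggregate(node_values: np.ndarray, mapping: RSNMapping,
              level: str) -> pd.DataFrame:
    """Aggregate per-node values by unweighted means at the requested level.

    ``level`` is one of ``whole_brain`` (grand mean), ``rsn`` (per-subnetwork
    means) or ``node`` (identity).  Subnetwork-pair summaries come from
    :func:`pair_integration`, which needs the full allegiance matrix.
    """
    node_values = np.asarray(node_values, dtype=float)
    if level == "whole_brain":
        return pd.DataFrame({"unit": ["whole_brain"],
                             "value": [float(node_values.mean())]})
    if level == "rsn":
        rows = [{"unit": s, "value": float(node_values[mapping.members(s)].mean())}
                for s in mapping.subnetworks]
        return pd.DataFrame(rows)
    if level == "node":
        return pd.DataFrame({"unit": [f"node_{i+1}" for i in range(node_values.size)],
                             "value": node_values})
    raise ValueError(f"unknown aggregation level {level!r}; "
                     f"expected one of {AGGREGATION_LEVELS}")
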