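"""Dynamic community-structure measures: flexibility, module allegiance,
recruitment, and integration, summarized per resting-state network (RSN).

Flexibility of a node is the fraction of adjacent-layer transitions at which
its community label changes, averaged over optimization repetitions.  The
module allegiance matrix P gives, for each node pair, the probability of
co-assignment to the same community across layers and repetitions.
Recruitment of an RSN is the mean allegiance among its own nodes (temporal
coherence); integration is the mean allegiance between its nodes and all
other RSNs' nodes (temporal mixing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityEnsemble

#: canonical seven-system order used throughout the package
DEFAULT_SYSTEMS = ("VIS", "SM", "DAN", "SVAN", "LIMB", "CON", "DMN")

#: measure order of the per-subject feature vector
MEASURES = ("flexibility", "recruitment", "integration")


@dataclass
class RSNPartition:
    """Mapping of each node to one named system.

    Parameters
    ----------
    labels : sequence of str, length n_nodes
        System label of each node.
    systems : sequence of str, optional
        System order for reporting; defaults to the seven canonical RSNs
        restricted to those present, preserving canonical order.
    """

    labels: np.ndarray
    systems: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        present = set(self.labels.tolist())
        if not self.systems:
            canon = [s for s in DEFAULT_SYSTEMS if s in present]
            extra = sorted(present - set(DEFAULT_SYSTEMS))
            self.systems = tuple(canon + extra)
        missing = present - set(self.systems)
        if missing:
            raise ValueError(f"labels contain systems not in system order: {missing}")
        for s in self.systems:
            if not np.any(self.labels == s):
                raise ValueError(f"system {s!r} has no nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    def members(self, system: str) -> np.ndarray:
        return np.flatnonzero(self.labels == system)

    @classmethod
    def from_sizes(cls, sizes: list[int], systems: tuple[str, ...] | None = None) -> "RSNPartition":
        systems = tuple(systems) if systems else DEFAULT_SYSTEMS[: len(sizes)]
        if len(systems) != len(sizes):
            raise ValueError("one system name per size required")
        labels = np.repeat(np.asarray(systems, dtype=object), sizes)
        return cls(labels=labels, systems=systems)


@dataclass
class AllegianceMatrix:
    """Node x node co-assignment probabilities; symmetric, unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("allegiance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("allegiance matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("allegiance values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("allegiance diagonal must be 1")
        self.values = v


def node_flexibility(labels: np.ndarray) -> np.ndarray:
    """Per-node flexibility of one assignment: label changes / (L - 1)."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("flexibility needs a node x layer matrix with >= 2 layers")
    changes = labels[:, 1:] != labels[:, :-1]
    return changes.mean(axis=1)


def ensemble_node_flexibility(ensemble: CommunityEnsemble) -> np.ndarray:
    """Per-node flexibility averaged over optimization repetitions."""
    per_rep = np.stack([node_flexibility(a.labels) for a in ensemble.assignments])
    return per_rep.mean(axis=0)


def ensemble_flexibility(
    ensemble: CommunityEnsemble, partition: RSNPartition
) -> pd.Series:
    """Per-RSN flexibility: repetition-averaged node values, averaged per system."""
    if partition.n_nodes != ensemble.n_nodes:
        raise ValueError("partition and ensemble node counts differ")
    node_flex = ensemble_node_flexibility(ensemble)
    return pd.Series(
        {s: float(node_flex[partition.members(s)].mean()) for s in partition.systems},
        name="flexibility",
    )


def module_allegiance(ensemble: CommunityEnsemble) -> AllegianceMatrix:
    """Fraction of (layer, repetition) samples in which node pairs co-assign.

    Computed per layer-repetition via one-hot community indicators, so the
    accumulation is a sum of rank-``k`` Gram matrices rather than an explicit
    pairwise loop.
    """
    n = ensemble.n_nodes
    acc = np.zeros((n, n))
    count = 0
    for a in ensemble.assignments:
        for s in range(a.n_layers):
            col = a.labels[:, s]
            uniq, codes = np.unique(col, return_inverse=True)
            onehot = np.zeros((n, len(uniq)))
            onehot[np.arange(n), codes] = 1.0
            acc += onehot @ onehot.T
            count += 1
    p = acc / count
    np.fill_diagonal(p, 1.0)
    return AllegianceMatrix(values=p)


def recruitment(
    allegiance: AllegianceMatrix, partition: RSNPartition, include_diagonal: bool = True
) -> pd.Series:
    """Per-RSN recruitment: mean allegiance among the system's own nodes.

    By default the mean runs over all ordered within-system pairs including
    the diagonal, so a system whose nodes always share a community scores
    exactly 1.  ``include_diagonal=False`` restricts to distinct pairs.
    """
    if partition.n_nodes != allegiance.values.shape[0]:
        raise ValueError("partition and allegiance node counts differ")
    out = {}
    for s in partition.systems:
        idx = partition.members(s)
        block = allegiance.values[np.ix_(idx, idx)]
        if include_diagonal:
            out[s] = float(block.mean())
        else:
            if len(idx) < 2:
                raise ValueError(f"system {s!r} needs >= 2 nodes without the diagonal")
            out[s] = float((block.sum() - np.trace(block)) / (len(idx) * (len(idx) - 1)))
    return pd.Series(out, name="recruitment")


def integration(allegiance: AllegianceMatrix, partition: RSNPartition) -> pd.Series:
    """Per-RSN integration: mean allegiance between the system and all others."""
    if partition.n_systems < 2:
        raise ValueError("integration needs at least 2 systems")
    if partition.n_nodes != allegiance.values.shape[0]:
        raise ValueError("partition and allegiance node counts differ")
    all_idx = np.arange(partition.n_nodes)
    out = {}
    for s in partition.systems:
        idx = partition.members(s)
        other = np.setdiff1d(all_idx, idx)
        out[s] = float(allegiance.values[np.ix_(idx, other)].mean())
    return pd.Series(out, name="integration")


def subject_features(
    ensemble: CommunityEnsemble,
    partition: RSNPartition,
    allegiance: AllegianceMatrix | None = None,
) -> pd.Series:
    """Per-subject dynamic feature vector: 3 measures x n_systems values.

    Order is measure-major (all flexibilities, then recruitments, then
    integrations), each in the partition's system order; index labels are
    ``measure_SYSTEM``.  Seven systems give the canonical 21 features.
    """
    if allegiance is None:
        allegiance = module_allegiance(ensemble)
    flex = ensemble_flexibility(ensemble, partition)
    rec = recruitment(allegiance, partition)
    integ = integration(allegiance, partition)
    values, index = [], []
    for name, series in (("flexibility", flex), ("recruitment", rec), ("integration", integ)):
        for s in partition.systems:
            values.append(series[s])
            index.append(f"{name}_{s}")
    return pd.Series(values, index=index, dtype=float)


def feature_names(partition: RSNPartition) -> list[str]:
    return [f"{m}_{s}" for m in MEASURES for s in partition.systems]
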