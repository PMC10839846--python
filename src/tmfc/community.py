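"""Multilayer community detection by generalized modularity maximization.

The quality function generalizes Newman–Girvan modularity to ordered layers:

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * P_ijs) * delta_sr
                               + delta_ij * omega_jsr ] * delta(g_is, g_jr)

where ``A_ijs`` are the intralayer weights, ``P_ijs = k_i k_j / (2 m_s)`` is
the per-layer configuration-model (Newman–Girvan) expectation, ``gamma`` the
intralayer resolution, and ``omega_jsr = omega`` for the same node in
adjacent layers (ordinal coupling) and 0 otherwise.  ``2mu`` counts the
total intralayer strength over layers plus every interlayer coupling in both
directions.

The optimizer is a stochastic Louvain scheme on the supra-modularity matrix:
randomized single-slot moves to local optimality, community aggregation, and
repetition until no move improves Q.  Because the landscape is rugged, the
analysis runs many independent repetitions and works with the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .networks import LayerMatrix, TemporalMultilayerNetwork

_GAIN_TOL = 1e-12


@dataclass
class ModularityParams:
    """Parameters of the multilayer modularity optimization.

    ``omega`` is the interlayer coupling used when the pipeline builds the
    network; the quality function itself always reads the coupling stored on
    the :class:`TemporalMultilayerNetwork`, which is authoritative.
    """

    gamma: float = 1.0
    omega: float = 0.5
    n_repetitions: int = 100
    max_passes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class CommunityAssignment:
    """One optimization's node x layer community labels (positive integers)."""

    labels: np.ndarray
    q_value: float
    converged: bool = True
    q_trace: list[float] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


@dataclass
class CommunityEnsemble:
    """Community assignments across independent optimization repetitions."""

    assignments: list[CommunityAssignment]
    params: ModularityParams

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("ensemble must contain at least one assignment")
        shape = self.assignments[0].labels.shape
        if any(a.labels.shape != shape for a in self.assignments):
            raise ValueError("all assignments must share node/layer dimensions")

    @property
    def n_nodes(self) -> int:
        return self.assignments[0].n_nodes

    @property
    def n_layers(self) -> int:
        return self.assignments[0].n_layers

    def label_array(self) -> np.ndarray:
        """Labels as a (n_repetitions, n_nodes, n_layers) integer array."""
        return np.stack([a.labels for a in self.assignments])


def layer_null_model(layer: LayerMatrix | np.ndarray) -> np.ndarray:
    """Newman–Girvan expected weights of one layer: ``k_i k_j / (2 m)``.

    This is the expectation under degree-preserving edge randomization.  An
    empty layer (total strength zero) returns the zero matrix.
    """
    w = layer.weights if isinstance(layer, LayerMatrix) else np.asarray(layer, float)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return np.zeros_like(w)
    return np.outer(k, k) / two_m


def supra_modularity_matrix(
    net: TemporalMultilayerNetwork, gamma: float = 1.0
) -> tuple[sparse.csr_matrix, float]:
    """Build the supra-modularity matrix B and the normalization 2mu.

    Slot ordering is layer-major: slot ``s * N + i`` is node ``i`` in layer
    ``s``.  Intralayer blocks are ``A_s - gamma * P_s``; adjacent layers are
    coupled on the diagonal with weight ``omega``.
    """
    n, L = net.n_nodes, net.n_layers
    blocks = []
    two_mu = 0.0
    for lay in net.layers:
        w = lay.weights
        two_mu += w.sum()
        blocks.append(sparse.csr_matrix(w - gamma * layer_null_model(lay)))
    B = sparse.block_diag(blocks, format="csr")
    if L > 1 and net.omega > 0:
        off = np.full(n * (L - 1), net.omega)
        coupling = sparse.diags([off, off], offsets=[n, -n], shape=(n * L, n * L))
        B = (B + coupling).tocsr()
        two_mu += 2.0 * net.omega * n * (L - 1)
    return B, two_mu


def _slot_labels(labels: np.ndarray, n: int, L: int) -> np.ndarray:
    """Node x layer labels -> layer-major supra vector of 0-based codes."""
    labels = np.asarray(labels)
    if labels.shape != (n, L):
        raise ValueError(f"labels must have shape ({n}, {L}), got {labels.shape}")
    flat = labels.T.reshape(-1)
    _, codes = np.unique(flat, return_inverse=True)
    return codes


def _partition_total(B: sparse.csr_matrix, slot_labels: np.ndarray) -> float:
    """Sum of B over ordered slot pairs in the same community (diagonal included)."""
    k = int(slot_labels.max()) + 1
    S = sparse.csr_matrix(
        (np.ones(len(slot_labels)), (np.arange(len(slot_labels)), slot_labels)),
        shape=(len(slot_labels), k),
    )
    return float((S.T @ B @ S).diagonal().sum())


def multilayer_modularity(
    assignment: CommunityAssignment | np.ndarray,
    net: TemporalMultilayerNetwork,
    params: ModularityParams | None = None,
) -> float:
    """Evaluate the multilayer modularity Q of a node x layer assignment."""
    gamma = params.gamma if params is not None else 1.0
    labels = assignment.labels if isinstance(assignment, CommunityAssignment) else assignment
    B, two_mu = supra_modularity_matrix(net, gamma=gamma)
    if two_mu == 0:
        return 0.0
    codes = _slot_labels(labels, net.n_nodes, net.n_layers)
    return _partition_total(B, codes) / two_mu


def _compact(labels: np.ndarray) -> np.ndarray:
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _move_phase(B: sparse.csr_matrix, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """Randomized single-slot moves to a local optimum of the partition total.

    Ties (and gains below tolerance) keep the current community.  Returns
    whether any move was made.  The self-entry B_vv is excluded from the
    gain: it travels with the node and cancels from every comparison.
    """
    n = B.shape[0]
    indptr, indices, data = B.indptr, B.indices, B.data
    n_comm = int(labels.max()) + 1
    improved = False
    moved = True
    while moved:
        moved = False
        for v in rng.permutation(n):
            lo, hi = indptr[v], indptr[v + 1]
            idx, dat = indices[lo:hi], data[lo:hi]
            keep = idx != v
            if not keep.all():
                idx, dat = idx[keep], dat[keep]
            if idx.size == 0:
                continue
            w = np.bincount(labels[idx], weights=dat, minlength=n_comm)
            cur = labels[v]
            best = int(np.argmax(w))
            if w[best] > w[cur] + _GAIN_TOL and best != cur:
                labels[v] = best
                moved = True
                improved = True
    return improved


def _aggregate(B: sparse.csr_matrix, labels: np.ndarray) -> sparse.csr_matrix:
    k = int(labels.max()) + 1
    S = sparse.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), labels)),
        shape=(len(labels), k),
    )
    return (S.T @ B @ S).tocsr()


def _louvain(B: sparse.csr_matrix, rng: np.random.Generator, depth: int = 0) -> np.ndarray:
    labels = np.arange(B.shape[0])
    improved = _move_phase(B, labels, rng)
    labels = _compact(labels)
    k = int(labels.max()) + 1
    if not improved or k == B.shape[0] or depth > 64:
        return labels
    sub = _louvain(_aggregate(B, labels), rng, depth + 1)
    return sub[labels]


def genlouvain_optimize(
    net: TemporalMultilayerNetwork,
    params: ModularityParams,
    rep_seed: int,
    _precomputed: tuple[sparse.csr_matrix, float] | None = None,
) -> CommunityAssignment:
    """One stochastic generalized-Louvain maximization of multilayer Q.

    Alternates slot-level move phases with aggregated Louvain passes until
    no single slot move (nor any aggregated merge) increases Q, so the
    returned assignment is locally optimal at the level of individual
    node-layer slots.  Deterministic given ``rep_seed``.
    """
    B, two_mu = (
        _precomputed if _precomputed is not None
        else supra_modularity_matrix(net, gamma=params.gamma)
    )
    rng = np.random.default_rng(rep_seed)
    n_slots = B.shape[0]
    labels = np.arange(n_slots)
    q_trace: list[float] = []
    converged = False
    q = _partition_total(B, labels)
    for _ in range(params.max_passes):
        _move_phase(B, labels, rng)
        labels = _compact(labels)
        sub = _louvain(_aggregate(B, labels), rng)
        labels = _compact(sub[labels])
        q_new = _partition_total(B, labels)
        q_trace.append(q_new / two_mu if two_mu else 0.0)
        if q_new <= q + _GAIN_TOL:
            converged = True
            break
        q = q_new
    if not converged:
        warnings.warn(
            f"modularity optimization did not stabilize in {params.max_passes} "
            "passes; returning best partition so far",
            RuntimeWarning,
            stacklevel=2,
        )
    n, L = net.n_nodes, net.n_layers
    node_layer = labels.reshape(L, n).T
    node_layer = _compact(node_layer.reshape(-1)).reshape(n, L) + 1  # 1-based
    q_value = _partition_total(B, labels) / two_mu if two_mu else 0.0
    return CommunityAssignment(
        labels=node_layer, q_value=q_value, converged=converged, q_trace=q_trace
    )


def write_ensemble(ensemble: CommunityEnsemble, path) -> None:
    """Write an ensemble as a compact long-format CSV.

    Columns: repetition, layer, node, label (all 0-based except the
    positive community labels).
    """
    import pandas as pd

    arr = ensemble.label_array()  # reps x nodes x layers
    reps, nodes, layers = arr.shape
    rep_idx, node_idx, layer_idx = np.meshgrid(
        np.arange(reps), np.arange(nodes), np.arange(layers), indexing="ij"
    )
    pd.DataFrame({
        "repetition": rep_idx.ravel(), "layer": layer_idx.ravel(),
        "node": node_idx.ravel(), "label": arr.ravel(),
    }).to_csv(path, index=False)


def read_ensemble(path, params: ModularityParams | None = None) -> CommunityEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    import pandas as pd

    frame = pd.read_csv(path)
    reps = int(frame["repetition"].max()) + 1
    nodes = int(frame["node"].max()) + 1
    layers = int(frame["layer"].max()) + 1
    arr = np.empty((reps, nodes, layers), dtype=int)
    arr[frame["repetition"], frame["node"], frame["layer"]] = frame["label"]
    assignments = [CommunityAssignment(labels=arr[r], q_value=np.nan)
                   for r in range(reps)]
    return CommunityEnsemble(
        assignments=assignments,
        params=params or ModularityParams(n_repetitions=reps),
    )


def repeat_optimization(
    net: TemporalMultilayerNetwork, params: ModularityParams
) -> CommunityEnsemble:
    """Run ``n_repetitions`` independent optimizations from derived seeds.

    Repetition seeds are spawned from the master seed with
    ``numpy.random.SeedSequence``, so the ensemble is reproducible and the
    repetitions are statistically independent.
    """
    pre = supra_modularity_matrix(net, gamma=params.gamma)
    seeds = np.random.SeedSequence(params.seed).generate_state(params.n_repetitions)
    assignments = [
        genlouvain_optimize(net, params, int(s) % (2**31), _precomputed=pre)
        for s in seeds
    ]
    return CommunityEnsemble(assignments=assignments, params=params)
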